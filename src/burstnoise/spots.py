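"""smFISH spot-intensity normalization into per-cell mRNA copy numbers.

Detected fluorescent spots carry arbitrary-unit intensities.  Two control
samples calibrate the conversion to copy numbers: a *zero* control of
nonexpressing cells, whose spots are all false positives and whose 99.9th
intensity percentile sets the false-positive threshold, and a *low* control
of weakly expressing cells whose spots are predominantly single mRNAs; a
Gaussian fitted to the low-control intensity histogram gives the
characteristic single-mRNA intensity.  Per-cell copy number is then the sum
of above-threshold spot intensities divided by the single-mRNA intensity,
rounded to the nearest integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SpotTable",
    "CalibrationResult",
    "false_positive_threshold",
    "unit_intensity",
    "calibrate",
    "integrate_copy_numbers",
]

logger = logging.getLogger(__name__)

SAMPLE_CLASSES = ("zero_control", "low_control", "sample")
MIN_ZERO_SPOTS = 100
MIN_LOW_SPOTS = 200


@dataclass(frozen=True)
class SpotTable:
    """Long-format spot table: one row per detected spot.

    Columns: ``cell_id`` (string/opaque), ``spot_intensity`` (positive,
    arbitrary fluorescence units), ``sample_class`` (one of
    ``zero_control | low_control | sample``).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"cell_id", "spot_intensity", "sample_class"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"spot table missing column(s) {sorted(missing)}")
        bad_class = set(df["sample_class"].unique()) - set(SAMPLE_CLASSES)
        if bad_class:
            raise ValueError(
                f"unknown sample_class value(s) {sorted(bad_class)}; "
                f"expected one of {SAMPLE_CLASSES}"
            )
        if (df["spot_intensity"] <= 0).any():
            raise ValueError("spot intensities must be positive")
        sample = df[df["sample_class"] == "sample"]
        if sample["cell_id"].isna().any():
            raise ValueError("every sample row needs a cell_id")

    def intensities(self, sample_class: str) -> np.ndarray:
        return self.frame.loc[
            self.frame["sample_class"] == sample_class, "spot_intensity"
        ].to_numpy(dtype=float)

    @property
    def zero_intensities(self) -> np.ndarray:
        return self.intensities("zero_control")

    @property
    def low_intensities(self) -> np.ndarray:
        return self.intensities("low_control")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "SpotTable":
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class CalibrationResult:
    """False-positive threshold plus single-mRNA intensity calibration."""

    threshold: float
    unit_intensity: float
    fit_sd: float

    def __post_init__(self) -> None:
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be positive")
        if self.fit_sd <= 0:
            raise ValueError("fit_sd must be positive")
        if self.threshold >= self.unit_intensity:
            logger.warning(
                "false-positive threshold (%.3g) is not below the single-mRNA "
                "intensity (%.3g); counts will be biased low",
                self.threshold,
                self.unit_intensity,
            )


def false_positive_threshold(zero_intensities) -> float:
    """99.9th percentile of the zero-control spot intensities.

    Linear-interpolation quantile convention.  Spots from nonexpressing cells
    are all false positives, so this removes essentially every false positive
    while keeping the genuine signal of expressing cells.
    """
    arr = np.asarray(zero_intensities, dtype=float)
    if arr.size < MIN_ZERO_SPOTS:
        raise ValueError(
            f"need at least {MIN_ZERO_SPOTS} zero-control intensities, got {arr.size}"
        )
    if np.any(arr <= 0):
        raise ValueError("intensities must be positive")
    return float(np.percentile(arr, 99.9))


def _gaussian(x, amplitude, mean, sd):
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def unit_intensity(low_intensities, threshold: float = 0.0) -> CalibrationResult:
    """Characteristic single-mRNA intensity from the low-control histogram.

    A single Gaussian is least-squares fitted to the Freedman-Diaconis-binned
    intensity histogram; its mean is the unit intensity.  Fitting the
    histogram (rather than maximum likelihood on raw values) keeps the
    estimate robust to a small multi-mRNA high tail.  ``threshold`` is
    carried into the returned :class:`CalibrationResult` (0 means no
    filtering was calibrated yet; see :func:`calibrate`).
    """
    arr = np.asarray(low_intensities, dtype=float)
    if arr.size < MIN_LOW_SPOTS:
        raise ValueError(
            f"need at least {MIN_LOW_SPOTS} low-control intensities, got {arr.size}"
        )
    if np.any(arr <= 0):
        raise ValueError("intensities must be positive")
    if np.ptp(arr) == 0:
        # degenerate histogram: all spots identical
        return CalibrationResult(
            threshold=threshold,
            unit_intensity=float(arr[0]),
            fit_sd=max(1e-12, 1e-6 * float(arr[0])),
        )

    edges = np.histogram_bin_edges(arr, bins="fd")
    counts, edges = np.histogram(arr, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(np.median(arr)), float(arr.std() or 1.0))
    try:
        popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian histogram fit did not converge (n={arr.size}, "
            f"bins={len(counts)}, p0={p0}): {exc}"
        ) from exc
    amplitude, mean, sd = popt
    if mean <= 0 or amplitude <= 0:
        raise RuntimeError(
            f"Gaussian histogram fit returned non-physical parameters "
            f"(amplitude={amplitude:.3g}, mean={mean:.3g})"
        )
    return CalibrationResult(
        threshold=threshold, unit_intensity=float(mean), fit_sd=float(abs(sd))
    )


def calibrate(zero_intensities, low_intensities) -> CalibrationResult:
    """Full calibration from the two control samples."""
    thr = false_positive_threshold(zero_intensities)
    return unit_intensity(low_intensities, threshold=thr)


def integrate_copy_numbers(spots: SpotTable, calib: CalibrationResult) -> pd.Series:
    """Per-cell mRNA copy numbers from the sample block of a spot table.

    Intensities strictly above the threshold are summed within each cell,
    divided by the single-mRNA intensity and rounded to the nearest integer
    (ties half-up).  Cells present in the table whose spots are all filtered
    out are retained with count 0 — absence of signal is information for the
    downstream model fit.
    """
    df = spots.frame[spots.frame["sample_class"] == "sample"]
    if df.empty:
        return pd.Series(dtype=np.int64, name="count")
    kept = df[df["spot_intensity"] > calib.threshold]
    sums = kept.groupby("cell_id")["spot_intensity"].sum()
    all_cells = pd.Index(df["cell_id"].unique(), name="cell_id")
    sums = sums.reindex(all_cells, fill_value=0.0)
    counts = np.floor(sums.to_numpy() / calib.unit_intensity + 0.5).astype(np.int64)
    return pd.Series(counts, index=all_cells, name="count")
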
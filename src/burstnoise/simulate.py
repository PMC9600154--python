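"""Synthetic single-cell data generators.

Every input the analysis consumes can be generated here with the statistical
structure the model assumes: compound-model copy numbers (log-normal burst
frequency mixed over a negative binomial), exact stochastic simulation of the
two-state promoter kinetics, coupled two-gene pairs for testing noise
propagation, and synthetic spot tables for the smFISH normalization stage.
All generators are deterministic under a fixed seed.  Default cell numbers
follow the 200-1,000 cells per condition typical of the imaging experiments
this emulates.

The power-law coupling of :func:`simulate_coupled_pair` and the
false-positive intensity model of :func:`simulate_spot_table` are test-
harness constructions, not mechanistic claims about the biology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TelegraphParams, lognormal_log_params
from .information import PairedCounts
from .spots import SpotTable

__all__ = [
    "KineticRates",
    "CouplingSpec",
    "N_CELLS_PRESETS",
    "sample_compound",
    "gillespie_telegraph",
    "simulate_coupled_pair",
    "simulate_spot_table",
]

logger = logging.getLogger(__name__)

# Typical per-condition sample sizes for the imaging experiments emulated here.
N_CELLS_PRESETS = (200, 500, 1000)


@dataclass(frozen=True)
class KineticRates:
    """The four kinetic rates of the two-state promoter (per unit time).

    ``activation`` (lambda): inactive -> active switching; ``deactivation``
    (nu): active -> inactive; ``transcription`` (K): mRNA production while
    active; ``degradation`` (delta): first-order mRNA decay.  The bursty
    regime requires nu >> lambda and K >> delta; ``deactivation`` may be 0
    to model a promoter that never switches off (constitutive limit).
    """

    activation: float
    deactivation: float
    transcription: float
    degradation: float

    def __post_init__(self) -> None:
        for name in ("activation", "transcription", "degradation"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.deactivation < 0:
            raise ValueError(f"deactivation must be >= 0, got {self.deactivation}")

    @property
    def is_bursty(self) -> bool:
        return (
            self.deactivation >= 10 * self.activation
            and self.transcription >= 10 * self.degradation
        )

    def telegraph_params(self) -> TelegraphParams:
        """Negative-binomial-limit parameter ratios (lambda/delta, K/nu).

        Warns when the rates are outside the bursty regime, where the
        negative-binomial approximation degrades.
        """
        if not self.is_bursty:
            logger.warning(
                "rates are outside the bursty regime (nu/lambda=%.3g, K/delta=%.3g, "
                "both should be >= 10); the negative-binomial limit is a poor "
                "approximation here",
                self.deactivation / self.activation,
                self.transcription / self.degradation,
            )
        return TelegraphParams(
            burst_freq=self.activation / self.degradation,
            burst_size=self.transcription / self.deactivation,
            freq_sd=0.0,
        )


@dataclass(frozen=True)
class CouplingSpec:
    """Power-law link from upstream copy number to downstream burst frequency.

    The downstream per-cell burst frequency is multiplied by
    ``(max(g, 1) / reference_count) ** exponent`` where ``g`` is the upstream
    count.  ``exponent = 0`` gives exact independence.
    """

    exponent: float = 0.0
    reference_count: float = 10.0

    def __post_init__(self) -> None:
        if not self.reference_count > 0:
            raise ValueError("reference_count must be positive")


def _draw_burst_freqs(
    params: TelegraphParams, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    if params.freq_sd == 0:
        return np.full(n_cells, params.burst_freq)
    mu, s_log = lognormal_log_params(params.burst_freq, params.freq_sd)
    return np.exp(rng.normal(mu, s_log, n_cells))


def sample_compound(params: TelegraphParams, n_cells: int, seed: int = 0) -> np.ndarray:
    """Draw per-cell copy numbers from the compound model.

    Each cell gets a burst frequency ``r`` from the log-normal (degenerate at
    ``burst_freq`` when ``freq_sd == 0``) and then a negative-binomial count
    with shape ``r`` and mean ``r * burst_size``.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)
    r = _draw_burst_freqs(params, n_cells, rng)
    p_scipy = 1.0 / (1.0 + params.burst_size)  # numpy's p is P(failure of a burst)
    return rng.negative_binomial(r, p_scipy).astype(np.int64)


def _gillespie_cell(
    lam: float,
    nu: float,
    K: float,
    delta: float,
    t_end: float,
    active: int,
    rng: np.random.Generator,
) -> int:
    t = 0.0
    n = 0
    while True:
        a_switch = nu if active else lam
        a_tx = K if active else 0.0
        a_tot = a_switch + a_tx + delta * n
        t += rng.exponential(1.0 / a_tot)
        if t >= t_end:
            return n
        u = rng.random() * a_tot
        if u < a_switch:
            active = 1 - active
        elif u < a_switch + a_tx:
            n += 1
        else:
            n -= 1


def gillespie_telegraph(
    rates: KineticRates, n_cells: int, t_end: float, seed: int = 0
) -> np.ndarray:
    """Exact stochastic simulation of the two-state promoter birth-death scheme.

    Independent trajectories of (promoter state, mRNA count) are run to
    ``t_end`` and the final copy number returned per cell.  The initial
    promoter state is drawn from the stationary occupancy
    lambda/(lambda + nu) and the initial count is 0, so ``t_end`` should be
    at least ~10 mRNA lifetimes (10/delta) for steady state; shorter runs
    trigger a warning.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    lam, nu = rates.activation, rates.deactivation
    K, delta = rates.transcription, rates.degradation
    if t_end < 10.0 / delta:
        logger.warning(
            "t_end=%.3g is below 10 mRNA lifetimes (%.3g); counts may not have "
            "reached steady state",
            t_end,
            10.0 / delta,
        )
    rng = np.random.default_rng(seed)
    p_active = lam / (lam + nu)
    out = np.empty(n_cells, dtype=np.int64)
    for i in range(n_cells):
        active = int(rng.random() < p_active)
        out[i] = _gillespie_cell(lam, nu, K, delta, t_end, active, rng)
    return out


def simulate_coupled_pair(
    params_up: TelegraphParams,
    params_down: TelegraphParams,
    coupling: CouplingSpec,
    n_cells: int,
    seed: int = 0,
    labels: dict | None = None,
) -> PairedCounts:
    """Two-gene pairs with tunable upstream-to-downstream noise propagation.

    Upstream counts ``g`` are drawn from the upstream compound model; the
    downstream per-cell burst frequency is scaled by
    ``(max(g, 1)/reference_count) ** exponent`` before the downstream count
    is drawn.  ``exponent = 0`` reproduces two independent genes exactly.
    """
    if n_cells < 2:
        raise ValueError(f"n_cells must be >= 2, got {n_cells}")
    rng = np.random.default_rng(seed)
    g = _draw_burst_freqs(params_up, n_cells, rng)
    p_up = 1.0 / (1.0 + params_up.burst_size)
    up = rng.negative_binomial(g, p_up).astype(np.int64)

    factor = (np.maximum(up, 1) / coupling.reference_count) ** coupling.exponent
    r_down = _draw_burst_freqs(params_down, n_cells, rng) * factor
    p_down = 1.0 / (1.0 + params_down.burst_size)
    down = rng.negative_binomial(r_down, p_down).astype(np.int64)
    return PairedCounts(up, down, labels or {"gene_a": "upstream", "gene_b": "downstream"})


def simulate_spot_table(
    true_counts,
    unit_intensity: float = 100.0,
    intensity_cv: float = 0.1,
    false_positive_rate: float = 0.2,
    fp_intensity_scale: float = 0.3,
    seed: int = 0,
    n_zero_cells: int = 1000,
    n_low_cells: int = 600,
    low_mean_count: float = 1.5,
) -> SpotTable:
    """Synthetic spot-intensity table with zero/low control blocks.

    Each sample cell emits ``true_count`` genuine spots with intensities
    ``Normal(unit_intensity, cv * unit_intensity)`` plus
    ``Poisson(false_positive_rate)`` dim false positives at
    ``fp_intensity_scale`` of the unit intensity.  The zero-control block
    contains only false positives; the low-control block emits
    ``Poisson(low_mean_count)`` single-mRNA spots per cell, mimicking the
    weakly expressing calibration sample.
    """
    counts = np.asarray(true_counts)
    if counts.size and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
        raise ValueError("true_counts must be non-negative integers")
    counts = counts.astype(np.int64)
    if intensity_cv < 0:
        raise ValueError("intensity_cv must be >= 0")
    if false_positive_rate < 0:
        raise ValueError("false_positive_rate must be >= 0")
    rng = np.random.default_rng(seed)

    def spot_block(cell_prefix, n_true_per_cell, sample_class):
        rows = []
        sd = intensity_cv * unit_intensity
        fp_mean = fp_intensity_scale * unit_intensity
        fp_sd = intensity_cv * fp_mean
        n_fp = rng.poisson(false_positive_rate, len(n_true_per_cell))
        for i, (k, kf) in enumerate(zip(n_true_per_cell, n_fp)):
            cid = f"{cell_prefix}{i:05d}"
            if k:
                vals = rng.normal(unit_intensity, sd, int(k))
                rows.append((cid, np.abs(vals), sample_class))
            if kf:
                vals = rng.normal(fp_mean, fp_sd, int(kf))
                rows.append((cid, np.abs(vals), sample_class))
        return rows

    blocks = []
    blocks += spot_block("zero_", np.zeros(n_zero_cells, dtype=int), "zero_control")
    blocks += spot_block("low_", rng.poisson(low_mean_count, n_low_cells), "low_control")
    blocks += spot_block("cell_", counts, "sample")

    cell_ids, intensities, classes = [], [], []
    for cid, vals, cls in blocks:
        cell_ids += [cid] * len(vals)
        intensities.append(vals)
        classes += [cls] * len(vals)
    frame = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "spot_intensity": np.concatenate(intensities) if intensities else [],
            "sample_class": classes,
        }
    )
    # A sample cell with no spots at all leaves no row; downstream alignment
    # must treat absent cells as zero counts.
    return SpotTable(frame)
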
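"""Entropy, mutual information and permutation significance for paired counts.

Dual-probe smFISH yields, per cell, the copy numbers of two genes.  The
plug-in (empirical) entropy in bits is

    H(X) = - sum_x p(x) log2 p(x)

over the observed integer copy numbers, with no binning or bias correction;
mutual information is MI = H(X) + H(Y) - H(X, Y).  Statistical significance
comes from a permutation null: one margin is shuffled uniformly at random
many times and the observed MI is compared with the null MI distribution.
The plug-in estimator's positive bias is shared by the null and therefore
cancels in the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairedCounts",
    "MIResult",
    "plugin_entropy",
    "plugin_mutual_information",
    "permutation_significance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedCounts:
    """Aligned per-cell counts of two genes measured in the same cells."""

    x: np.ndarray
    y: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = _as_counts(self.x, "x")
        y = _as_counts(self.y, "y")
        if len(x) != len(y):
            raise ValueError(f"length mismatch: {len(x)} vs {len(y)} cells")
        if len(x) < 2:
            raise ValueError("need at least 2 cells")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)

    def swapped(self) -> "PairedCounts":
        return PairedCounts(self.y, self.x, dict(self.labels))


@dataclass(frozen=True)
class MIResult:
    """Observed MI with its permutation-null significance.

    ``p_value`` is the raw exceedance fraction #{null MI >= observed}/N;
    ``p_value_corrected`` is the (k+1)/(N+1) version that cannot be exactly
    zero.
    """

    mi_bits: float
    entropy_x_bits: float
    entropy_y_bits: float
    p_value: float
    p_value_corrected: float
    n_shuffles: int
    null_mean: float
    null_sd: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "mi_bits": self.mi_bits,
            "entropy_x_bits": self.entropy_x_bits,
            "entropy_y_bits": self.entropy_y_bits,
            "p_value": self.p_value,
            "p_value_corrected": self.p_value_corrected,
            "n_shuffles": self.n_shuffles,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "seed": self.seed,
        }


def _as_counts(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
        raise ValueError(f"{name} must contain integers")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr.astype(np.int64)


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Entropy in bits of the empirical distribution given category counts."""
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def plugin_entropy(counts) -> float:
    """Plug-in entropy (bits) of the empirical copy-number distribution."""
    arr = _as_counts(counts, "counts")
    _, freq = np.unique(arr, return_counts=True)
    return _entropy_from_counts(freq)


def _codes(paired: PairedCounts) -> tuple[np.ndarray, np.ndarray, int, int]:
    ux, cx = np.unique(paired.x, return_inverse=True)
    uy, cy = np.unique(paired.y, return_inverse=True)
    return cx, cy, len(ux), len(uy)


def _mi_bits(cx: np.ndarray, cy: np.ndarray, kx: int, ky: int) -> float:
    joint = np.bincount(cx * ky + cy, minlength=kx * ky)
    hx = _entropy_from_counts(np.bincount(cx, minlength=kx))
    hy = _entropy_from_counts(np.bincount(cy, minlength=ky))
    hxy = _entropy_from_counts(joint)
    return hx + hy - hxy


def plugin_mutual_information(paired: PairedCounts) -> float:
    """MI = H(X) + H(Y) - H(X,Y) in bits, on the raw empirical joint.

    Non-negative up to floating-point rounding; symmetric in the two genes.
    """
    cx, cy, kx, ky = _codes(paired)
    return _mi_bits(cx, cy, kx, ky)


def permutation_significance(
    paired: PairedCounts, n_shuffles: int = 100_000, seed: int = 0
) -> MIResult:
    """Permutation-null significance of the observed mutual information.

    One margin is shuffled uniformly at random ``n_shuffles`` times and the
    MI recomputed each time.  For a constant margin MI is identically zero
    and ``p_value = 1`` is returned with a logged warning.
    """
    if n_shuffles < 100:
        raise ValueError(f"n_shuffles must be >= 100, got {n_shuffles}")
    cx, cy, kx, ky = _codes(paired)
    hx = _entropy_from_counts(np.bincount(cx, minlength=kx))
    hy = _entropy_from_counts(np.bincount(cy, minlength=ky))

    if kx == 1 or ky == 1:
        logger.warning(
            "one margin is constant; MI is trivially 0 and no dependence "
            "can be detected"
        )
        return MIResult(
            mi_bits=0.0,
            entropy_x_bits=hx,
            entropy_y_bits=hy,
            p_value=1.0,
            p_value_corrected=1.0,
            n_shuffles=n_shuffles,
            null_mean=0.0,
            null_sd=0.0,
            seed=seed,
        )

    observed = _mi_bits(cx, cy, kx, ky)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = _mi_bits(cx, rng.permutation(cy), kx, ky)

    k = int((null >= observed).sum())
    return MIResult(
        mi_bits=observed,
        entropy_x_bits=hx,
        entropy_y_bits=hy,
        p_value=k / n_shuffles,
        p_value_corrected=(k + 1) / (n_shuffles + 1),
        n_shuffles=n_shuffles,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        seed=seed,
    )
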
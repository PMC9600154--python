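"""Bayesian MCMC inference of telegraph-model parameters from copy-number data.

The posterior over ``(burst_freq, burst_size, freq_sd)`` is sampled in
log-parameter space with an affine-invariant ensemble sampler (emcee) under
independent log-uniform priors.  Point estimates are maximum a posteriori
(MAP) values taken as the sampled triplet with the highest joint log
posterior, and uncertainty is reported as equal-tailed marginal credible
intervals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import emcee

from .model import (
    DEFAULT_QUAD,
    QuadratureConfig,
    TelegraphParams,
    lognormal_quadrature,
    negbinom_logpmf_matrix,
)

__all__ = [
    "FitConfig",
    "PosteriorChain",
    "fit_mcmc",
    "map_estimate",
    "credible_interval",
    "write_chain",
    "read_chain",
    "chain_summary",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("burst_freq", "burst_size", "freq_sd")

# Prior supports, wide enough to cover the physically plausible range of
# burst statistics per mRNA lifetime.  burst_freq and burst_size are strictly
# positive scale ratios and get scale-free log-uniform priors; freq_sd is a
# standard deviation whose true value may be exactly zero, and a log-uniform
# prior would concentrate unbounded mass at the origin on the natural scale
# (biasing the extrinsic fraction toward zero whenever the likelihood is
# flat below its resolution limit), so it gets a uniform prior on the
# natural scale instead.
DEFAULT_BOUNDS = {
    "burst_freq": (1e-2, 1e3),
    "burst_size": (1e-2, 1e3),
    "freq_sd": (1e-3, 1e2),
}


@dataclass(frozen=True)
class FitConfig:
    """Sampler configuration.

    ``bounds`` are the log-uniform prior supports per parameter.  ``n_steps``
    ensemble moves are run per walker and the first ``n_burn`` discarded.
    ``prior_only`` switches the likelihood off, leaving the prior as the
    target (a sampler diagnostic).
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_steps: int = 2000
    n_burn: int = 800
    n_walkers: int = 16
    seed: int = 0
    quad: QuadratureConfig = DEFAULT_QUAD
    prior_only: bool = False

    def __post_init__(self) -> None:
        if set(self.bounds) != set(PARAM_NAMES):
            raise ValueError(f"bounds must have keys {PARAM_NAMES}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name} must satisfy 0 < lower < upper")
        if not self.n_steps > self.n_burn >= 0:
            raise ValueError("need n_steps > n_burn >= 0")
        if self.n_walkers < 6:
            raise ValueError("need at least 6 walkers for a 3-d ensemble")

    @property
    def log_bounds(self) -> np.ndarray:
        return np.log([self.bounds[k] for k in PARAM_NAMES])


@dataclass(frozen=True)
class PosteriorChain:
    """Post-burn-in posterior samples on the natural parameter scale.

    ``samples`` has shape ``(n_samples, 3)`` with columns ordered as
    ``PARAM_NAMES``; ``log_posteriors`` aligns row-for-row.  ``meta`` records
    chain provenance (steps, burn-in, walkers, seed, acceptance rate, R-hat).
    """

    samples: np.ndarray
    log_posteriors: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        lp = np.asarray(self.log_posteriors, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if len(s) != len(lp):
            raise ValueError("samples and log_posteriors length mismatch")
        if len(s) == 0:
            raise ValueError("empty chain")
        if np.any(s[:, :2] <= 0) or np.any(s[:, 2] < 0):
            raise ValueError("chain contains samples violating parameter constraints")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "log_posteriors", lp)

    def __len__(self) -> int:
        return len(self.samples)

    def parameter(self, name: str) -> np.ndarray:
        return self.samples[:, PARAM_NAMES.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.samples, columns=list(PARAM_NAMES))
        df["log_posterior"] = self.log_posteriors
        return df


def _validate_fit_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("cannot fit an empty count vector")
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative integers")
    arr = arr.astype(np.int64)
    if np.all(arr == 0):
        raise ValueError(
            "all counts are zero: the mean expression is unidentifiable; "
            "refusing to fit"
        )
    return arr


def _make_log_posterior(counts: np.ndarray, config: FitConfig):
    uniq, mult = np.unique(counts, return_counts=True)
    uniqf = uniq.astype(float)
    log_bounds = config.log_bounds
    quad = config.quad
    prior_only = config.prior_only

    def log_posterior(theta: np.ndarray) -> float:
        if np.any(theta < log_bounds[:, 0]) or np.any(theta > log_bounds[:, 1]):
            return -np.inf
        # Sampling runs in log space: the log-uniform priors on burst_freq
        # and burst_size are flat there, while the uniform-on-scale prior on
        # freq_sd contributes the Jacobian term +log(freq_sd).
        log_prior = theta[2]
        if prior_only:
            return log_prior
        m, b, s = np.exp(theta)
        params = TelegraphParams(m, b, s)
        r, w = lognormal_quadrature(params, quad)
        pmf = w @ np.exp(negbinom_logpmf_matrix(uniqf, r, b))
        if np.any(pmf <= 0.0):
            return -np.inf
        return float(mult @ np.log(pmf)) + log_prior

    return log_posterior


def _initial_positions(counts: np.ndarray, config: FitConfig) -> np.ndarray:
    """Moment-matched ball of walker start points in log space."""
    rng = np.random.default_rng(config.seed)
    log_bounds = config.log_bounds
    if config.prior_only:
        center = log_bounds.mean(axis=1)
        width = 0.25 * (log_bounds[:, 1] - log_bounds[:, 0])
        p0 = center + width * rng.uniform(-1, 1, size=(config.n_walkers, 3))
    else:
        mhat = counts.mean()
        vhat = counts.var()
        b0 = max(vhat / mhat - 1.0, 0.1)
        m0 = max(mhat / b0, 1e-2)
        center = np.log([m0, b0, 0.5 * m0])
        p0 = center + 0.3 * rng.standard_normal((config.n_walkers, 3))
    return np.clip(p0, log_bounds[:, 0] + 1e-3, log_bounds[:, 1] - 1e-3)


def _split_rhat(chain_wsd: np.ndarray) -> dict:
    """R-hat per parameter from the (walker, step, dim) post-burn-in array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chain_wsd)
        rh = az.rhat(ds)["x"].values
    return {name: float(rh[i]) for i, name in enumerate(PARAM_NAMES)}


def fit_mcmc(counts, config: FitConfig | None = None) -> PosteriorChain:
    """Sample the posterior over telegraph parameters for one gene/condition.

    Reproducible bit-for-bit for a fixed ``config.seed``.  Logs a warning if
    any parameter's R-hat exceeds 1.05 or the mean acceptance rate falls
    outside [0.1, 0.6].
    """
    config = config or FitConfig()
    if config.prior_only:
        arr = np.asarray([1], dtype=np.int64)  # placeholder, never used
    else:
        arr = _validate_fit_counts(counts)

    log_posterior = _make_log_posterior(arr, config)
    p0 = _initial_positions(arr, config)

    sampler = emcee.EnsembleSampler(config.n_walkers, 3, log_posterior)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed).get_state())
    sampler.run_mcmc(state, config.n_steps, progress=False)

    chain = sampler.get_chain(discard=config.n_burn)        # (steps, walkers, 3)
    logp = sampler.get_log_prob(discard=config.n_burn)      # (steps, walkers)
    acceptance = float(sampler.acceptance_fraction.mean())
    rhat = _split_rhat(np.transpose(chain, (1, 0, 2)))

    if any(v > 1.05 for v in rhat.values()):
        logger.warning("R-hat above 1.05: %s; consider more steps", rhat)
    if not 0.1 <= acceptance <= 0.6:
        logger.warning("mean acceptance rate %.3f outside [0.1, 0.6]", acceptance)

    flat = np.exp(chain.reshape(-1, 3))
    meta = {
        "n_steps": config.n_steps,
        "n_burn": config.n_burn,
        "n_walkers": config.n_walkers,
        "seed": config.seed,
        "acceptance_rate": acceptance,
        "rhat": rhat,
        "prior_only": config.prior_only,
    }
    return PosteriorChain(flat, logp.reshape(-1), meta)


def map_estimate(chain: PosteriorChain) -> TelegraphParams:
    """Sampled triplet with the highest joint log posterior.

    Joint-sample argmax, not per-parameter marginal modes; ties resolve to
    the earliest sample in chain order (``argmax`` convention).
    """
    i = int(np.argmax(chain.log_posteriors))
    m, b, s = chain.samples[i]
    return TelegraphParams(float(m), float(b), float(s))


def credible_interval(chain: PosteriorChain, level: float = 0.95) -> dict:
    """Equal-tailed marginal credible intervals per parameter.

    Quantiles at ``(1-level)/2`` and ``(1+level)/2`` with linear
    interpolation, returned as ``{name: {"lower": lo, "upper": hi}}``.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    out = {}
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = np.quantile(chain.samples[:, i], [alpha, 1.0 - alpha])
        out[name] = {"lower": float(lo), "upper": float(hi)}
    return out


def write_chain(chain: PosteriorChain, path) -> None:
    """Write samples as headered TSV next to a JSON summary sidecar."""
    path = Path(path)
    chain.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")
    path.with_suffix(".summary.json").write_text(
        json.dumps(chain_summary(chain), indent=2) + "\n"
    )


def read_chain(path) -> PosteriorChain:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_path = Path(path).with_suffix(".summary.json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text()).get("meta", {})
    return PosteriorChain(
        df[list(PARAM_NAMES)].to_numpy(),
        df["log_posterior"].to_numpy(),
        meta,
    )


def chain_summary(chain: PosteriorChain) -> dict:
    """JSON-ready summary: MAP, 95% intervals, R-hat, provenance."""
    return {
        "map": map_estimate(chain).to_dict(),
        "ci95": credible_interval(chain, 0.95),
        "meta": chain.meta,
        "n_samples": len(chain),
    }
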
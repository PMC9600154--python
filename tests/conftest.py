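import math

import pytest

from burstnoise import FitConfig, TelegraphParams, fit_mcmc, sample_compound

# Simulated-truth scenarios shared across the inference and decomposition
# tests.  RECOVERY matches the parameter-recovery benchmark.  HALF_E has a
# closed-form extrinsic fraction of exactly 0.5 and sits in the
# low-burst-frequency / large-burst-size regime where the log-normal mixture
# is distinguishable from a plain negative binomial (the regime occupied by
# strongly extrinsic-noise-driven genes); NO_EXTRINSIC is the matching pure
# negative-binomial null.
RECOVERY_TRUTH = TelegraphParams(burst_freq=2.0, burst_size=10.0, freq_sd=1.0)
HALF_E_TRUTH = TelegraphParams(
    burst_freq=0.5, burst_size=50.0, freq_sd=math.sqrt(0.5 * 51.0 / 50.0)
)
NO_EXTRINSIC_TRUTH = TelegraphParams(burst_freq=0.5, burst_size=50.0, freq_sd=0.0)

N_CELLS = 1000

# decomposition-grade chains run longer than the default so the mode of the
# posterior e distribution is not limited by sampler noise
DECOMP_STEPS = {"n_steps": 4000, "n_burn": 1500}


@pytest.fixture(scope="session")
def recovery_chain():
    counts = sample_compound(RECOVERY_TRUTH, N_CELLS, seed=101)
    return fit_mcmc(counts, FitConfig(seed=1))


@pytest.fixture(scope="session")
def half_e_chain():
    counts = sample_compound(HALF_E_TRUTH, N_CELLS, seed=102)
    return fit_mcmc(counts, FitConfig(seed=2, **DECOMP_STEPS))


@pytest.fixture(scope="session")
def null_chain():
    counts = sample_compound(NO_EXTRINSIC_TRUTH, N_CELLS, seed=103)
    return fit_mcmc(counts, FitConfig(seed=3, **DECOMP_STEPS))
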
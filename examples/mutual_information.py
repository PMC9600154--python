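"""Detect noise propagation between two genes with mutual information.

Simulates a dual-probe experiment twice: once with the downstream burst
frequency coupled to the upstream copy number (power-law link), once fully
independent.  MI is compared against a permutation null built by shuffling
one gene's counts across cells.
"""

from burstnoise import (
    CouplingSpec,
    TelegraphParams,
    permutation_significance,
    plugin_entropy,
    simulate_coupled_pair,
)

up = TelegraphParams(2.0, 5.0, 1.0)      # upstream regulator
down = TelegraphParams(2.0, 10.0, 0.5)   # downstream target

for label, alpha in (("coupled", 1.0), ("independent", 0.0)):
    pair = simulate_coupled_pair(
        up, down, CouplingSpec(exponent=alpha, reference_count=10.0),
        n_cells=500, seed=7,
    )
    res = permutation_significance(pair, n_shuffles=10_000, seed=0)
    print(f"{label:12s} MI={res.mi_bits:.3f} bits  "
          f"H(downstream)={plugin_entropy(pair.y):.3f} bits  "
          f"p={res.p_value_corrected:.4f}  (null mean {res.null_mean:.3f})")

# The coupled pair shows MI far above the permutation null (small p); the
# independent pair's MI is indistinguishable from the null, whose nonzero
# mean reflects the plug-in estimator's finite-sample bias.
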
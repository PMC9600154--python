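# burstnoise

Stochastic-transcription noise analysis for single-cell mRNA copy-number
data.

Single-molecule RNA FISH yields, per cell, an integer count of transcripts
for one or two genes.  For costly, tightly regulated operons — the
motivating system is nitrogenase (*nifHDK*) expression in a diazotrophic
bacterium during nitrogen starvation — these counts are strikingly
heterogeneous across genetically identical cells.  `burstnoise` packages
the analysis chain that turns such counts into mechanistic statements
about where the heterogeneity comes from:

1. **Model fitting** — the telegraph (two-state promoter) model in its
   bursty limit gives a negative binomial over copy numbers,
   `NegBinom(n; r, b)` with burst frequency `r = λ/δ` and burst size
   `b = K/ν`.  Extrinsic noise enters as log-normal cell-to-cell variation
   of the burst frequency (mean `λ/δ`, SD `σ/δ`), giving the compound
   distribution `q(n) = ∫ NegBinom(n; r, b) LogNormal(r) dr`, fitted by
   MCMC with MAP estimates and 95% credible intervals.
2. **Noise decomposition** — the law of total variance,
   `Var(n) = E[Var(n|r)] + Var[E(n|r)]`, splits variance into intrinsic
   and extrinsic parts; the extrinsic fraction
   `e = b·s² / (r̄(1+b) + b·s²)` is propagated through the posterior
   (mode + 68% interval over 4,000 sampled triplets).
3. **Mutual information** — dependence between two genes measured in the
   same cells is quantified in bits from the empirical joint,
   `MI = H(X) + H(Y) − H(X,Y)`, with significance from a permutation null
   (shuffling one margin, default 100,000 times).
4. **Spot quantification** — raw spot intensities become copy numbers via
   a zero-control false-positive threshold (99.9th percentile) and a
   single-mRNA unit intensity (Gaussian fit to the low-control histogram).
5. **Synthetic data** — seeded generators for compound-model counts,
   exact Gillespie simulation of the promoter kinetics, coupled two-gene
   pairs, and synthetic spot tables, so the whole pipeline is testable
   without the original imaging data.

## Worked example

```python
from burstnoise import (TelegraphParams, FitConfig, sample_compound,
                        fit_mcmc, map_estimate, credible_interval)

truth = TelegraphParams(burst_freq=2.0, burst_size=10.0, freq_sd=1.0)
counts = sample_compound(truth, n_cells=500, seed=42)
chain = fit_mcmc(counts, FitConfig(n_steps=1500, n_burn=500, seed=0))
est, ci = map_estimate(chain), credible_interval(chain, 0.95)
```

printed by `python examples/fit_single_gene.py`:

```
simulated 500 cells: mean=19.6, var=309.2
burst_freq   truth=  2.00  MAP=  3.16  95% CI=[  1.23,   7.75]
burst_size   truth= 10.00  MAP=  6.22  95% CI=[  2.58,  15.85]
freq_sd      truth=  1.00  MAP=  2.20  95% CI=[  0.04,   7.52]
```

Each interval brackets the generating truth; the burst-frequency and
burst-size ratios are identified to within a factor of ~1.5 at this sample
size, while the extrinsic-noise scale `freq_sd` carries the widest
interval (see `docs/methods.md` on its weak identifiability).

The two-gene analysis (`python examples/mutual_information.py`):

```
coupled      MI=2.089 bits  H(downstream)=5.360 bits  p=0.0001  (null mean 1.656)
independent  MI=1.619 bits  H(downstream)=5.556 bits  p=0.8554  (null mean 1.652)
```

The coupled pair's MI exceeds essentially every permutation of the data
(small p), while the independent pair's MI sits inside the null — whose
nonzero mean is the plug-in estimator's finite-sample bias, shared by
observed value and null alike.

Other runnable walkthroughs in `examples/`: `noise_decomposition.py`,
`quantify_spots.py`, `telegraph_vs_negative_binomial.py`.

## Command line

A thin CLI wraps the same functions for shell pipelines:

```bash
burstnoise simulate counts counts.tsv --burst-freq 2 --burst-size 10 \
    --freq-sd 1 --n-cells 500 --seed 1
burstnoise fit counts.tsv chain.tsv
burstnoise decompose chain.tsv
burstnoise mi paired.tsv --n-shuffles 100000
burstnoise run-all config.yaml --stage single
```

Exit codes: 0 ok, 2 input error, 3 numerical failure.  All tables are
headered TSV; reports are JSON with seeds and a config hash embedded, and
reruns with the same configuration are byte-identical.

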
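# Methods

## The copy-number model

`burstnoise` models single-gene mRNA copy numbers with the two-state
(telegraph) promoter in its bursty limit.  A promoter switches on at rate
λ and off at rate ν; transcription proceeds at rate K while on, and each
mRNA decays independently at rate δ.  When ν ≫ λ and K ≫ δ, bursts are
short and the steady-state copy number follows a negative binomial with
shape r = λ/δ (bursts per mRNA lifetime) and success parameter
p = b/(1+b), where b = K/ν is the mean burst size:

    P(n) = C(n + r − 1, n) (1 − p)^r p^n,   E[n] = r·b.

Extrinsic noise is modeled as cell-to-cell variation of the burst
frequency: r varies across cells following a log-normal distribution with
mean λ/δ and standard deviation σ/δ, both on the natural scale of the
variate.  The observable distribution is the compound

    q(n) = ∫ NegBinom(n; r, b) LogNormal(r) dr.

Internally the (mean, SD) pair converts to log-scale parameters
s_log² = ln(1 + (σ/λ)²), μ_log = ln(λ/δ) − s_log²/2.

All binomial coefficients go through log-gamma; factorials are never
formed, so non-integer shapes and counts in the thousands are safe.

### Quadrature

The mixture integral is evaluated with Gauss–Hermite quadrature in the
standard-normal variable z underlying the log-normal
(r = exp(μ_log + √2·s_log·x)), with weights normalized to sum to one.
The integrand is an entire function of z, so convergence is spectral: with
the default 128 nodes the pmf and its first two moments agree with closed
forms to ~1e-12 relative for mixing coefficients of variation up to 2,
and doubling the node count moves physiological-regime pmf values by less
than 1e-8.  A quantile-grid trapezoid rule was rejected during development
because truncating even 1e-6 of mass per tail biases E[r] by ~1e-5
relative at CV 1, which is incompatible with the package's own
moment-consistency checks.  `QuadratureConfig.tail_mass` bounds the
log-normal mass allowed outside the node span; requesting fewer nodes than
the coverage requires is an error rather than a silent bias.

Accuracy caveat: pointwise pmf values deep in the upper tail (counts
requiring r far into the log-normal tail, at mixing CV ≳ 1.5 and small
burst size) converge more slowly (~1e-6 absolute at 128 nodes).
Likelihoods, which need relative accuracy at observed counts, are
unaffected — the log-likelihood of 1,000-cell datasets changes by <1e-3
between 128 and 1024 nodes.

### Degenerate cases

σ/δ = 0 short-circuits to the pure negative binomial (single unit-weight
node), making the reduction exact rather than approximate.  A pmf value
that underflows to exactly zero at an observed count raises
`NumericalSupportError` instead of silently producing −∞.

## Bayesian inference

The posterior over (λ/δ, K/ν, σ/δ) is sampled in log-parameter space with
the affine-invariant ensemble sampler (emcee), 16 walkers × 2,000 steps
with 800 discarded as burn-in by default (19,200 retained samples, enough
to feed the 4,000-triplet decomposition stage).  Walkers start in a small
ball around a moment-matched estimate.  Chains are bit-for-bit
reproducible for a fixed seed.  R-hat (arviz, walkers treated as chains —
an inflated but conservative diagnostic, since walkers are coupled) above
1.05, or a mean acceptance rate outside [0.1, 0.6], triggers a logged
warning.

### Priors

burst_freq and burst_size are strictly positive scale ratios and get
log-uniform priors on [1e-2, 1e3].  freq_sd gets a **uniform prior on the
natural scale** over [1e-3, 1e2].  This asymmetry is deliberate: freq_sd
is a standard deviation whose true value can be exactly zero, and the
likelihood cannot resolve values below roughly 0.3 at realistic sample
sizes (a log-normal-mixed negative binomial with small mixing CV is nearly
indistinguishable from a plain negative binomial with a larger burst
size).  A log-uniform prior would place unbounded mass-per-decade in that
unresolvable region; because the extrinsic fraction scales as e ∝ s² near
zero, that mass compresses into a divergent spike of the posterior e
distribution at 0 and pins its mode there regardless of the data.  The
uniform-on-SD prior (in the spirit of Gelman's recommendations for
variance components) keeps the origin finite-density.  MAP estimates are
reported as the sampled triplet with the highest joint log posterior in
the sampled (log) parameterization, ties resolving to the earliest sample;
credible intervals are equal-tailed marginal quantiles with linear
interpolation.

## Noise decomposition

The law of total variance over the mixing distribution splits
Var(n) = E[Var(n|r)] + Var[E(n|r)] = b(1+b)·E[r] + b²·Var[r], with the
moments of r evaluated on the quadrature nodes; the fractional extrinsic
contribution has the closed form e = b·s² / (r̄(1+b) + b·s²), against
which the numerical route is verified to 1e-6.  Posterior uncertainty is
propagated by evaluating e for 4,000 triplets sampled from the chain
(without replacement when the chain is long enough, seeded), summarized by
the midpoint of the modal Freedman–Diaconis histogram bin (`e_map`) and
the equal-tailed 16th–84th percentile interval.

Two properties of this summary deserve note.  First, when the posterior e
distribution is bimodal — a dense thin spike near zero holding less than
16% of the mass plus a broad lobe — the histogram mode can legitimately
fall below the 68% interval, so that ordering is reported but not
enforced.  Second, at 1,000 cells per condition the posterior over e is
intrinsically broad (68% widths of ~0.5 are typical) because of the
NB-mimicry degeneracy above; `e_map` then has a realization-to-realization
scatter of roughly ±0.2 around the generating truth.  Strong contrasts —
a high-extrinsic condition versus a no-extrinsic condition — are reliably
discriminated, but the mode should not be read as a precise point estimate
at this sample size.

## Mutual information

Entropy is the plug-in estimate over raw integer copy numbers, in bits
(base-2 logs); no binning and no bias correction are applied.  MI is
H(X) + H(Y) − H(X,Y) on the empirical joint.  Significance comes from a
permutation null: one margin is shuffled uniformly (default 100,000
times); the p-value is the raw exceedance fraction #{null ≥ observed}/N,
with the (k+1)/(N+1) correction reported alongside.  The plug-in
estimator's positive bias appears identically in the null and therefore
cancels in the comparison — the test is calibrated even though the MI
estimate itself is biased.  A constant margin yields MI = 0 and p = 1
with a logged warning.

## Spot quantification

Raw smFISH spot intensities are converted to copy numbers in three steps:
(1) the false-positive threshold is the 99.9th percentile
(linear-interpolation convention) of the zero-control intensities — spots
in nonexpressing cells are all false positives; at least 100 control spots
are required; (2) the single-mRNA unit intensity is the mean of a Gaussian
least-squares-fitted to the Freedman–Diaconis-binned low-control
histogram (fitting the histogram rather than maximum likelihood keeps the
estimate robust to a multi-mRNA high tail); at least 200 control spots are
required; (3) per cell, intensities strictly above the threshold are
summed, divided by the unit intensity, and rounded to the nearest integer
(ties half-up).  Cells whose spots are all filtered keep an explicit count
of zero.  Counts are invariant under a joint rescaling of intensities and
calibration, and never increase when the threshold is raised.

## Synthetic data

The generators produce every input the pipeline reads, under fixed seeds:

- `sample_compound` draws per-cell burst frequencies from the log-normal
  and counts from the negative binomial — the model's own data-generating
  process.
- `gillespie_telegraph` runs the exact stochastic simulation of the
  four-reaction promoter scheme to `t_end` (≥ 10 mRNA lifetimes
  recommended; shorter runs warn), starting from the stationary promoter
  occupancy λ/(λ+ν) and zero mRNA.  It validates the bursty-limit
  approximation independently of the NB formula (total-variation distance
  < 0.05 at λ/δ=1, ν/δ=50, K/δ=500 with 10⁴ cells) and reproduces the
  Poisson (Fano = 1) constitutive limit.
- `simulate_coupled_pair` links two genes by scaling the downstream burst
  frequency by (max(g,1)/g₀)^α, with g the upstream count.  The power-law
  form is a test-harness construction, not a mechanistic claim; α = 0
  reproduces independence exactly.
- `simulate_spot_table` emits true spots at Normal(unit, cv·unit), dim
  false positives at 0.3× unit intensity with Poisson(rate) counts per
  cell, plus zero-control (1,000 cells) and low-control (600 cells,
  Poisson(1.5) single-mRNA spots) blocks.  Sample cells with no spots
  leave no rows; downstream alignment treats absent cells as zeros.

Default cell numbers follow the 200–1,000 cells per condition typical of
single-cell imaging experiments.  What the generators do **not** emulate:
cell growth and division, segmentation errors, probe-set efficiency
differences between genes, partial hybridization, or mechanistic upstream
signaling — so passing tests establish the correctness and calibration of
the inference machinery on data satisfying the model assumptions, not
robustness to real-data artifacts.

## Problem sizes and test design

Recovery benchmarks use 1,000 cells; the parameter-recovery coverage check
runs 20 seeded replicates; permutation calibration uses 200 independent
pairs at 500 cells × 1,000 shuffles; Monte-Carlo pmf oracles use 10⁶
draws; SSA validation uses 10⁴ cells.  Decomposition-grade chains run
4,000 steps (1,500 burn-in).  These sizes make the full validation suite
runnable on a laptop in minutes while keeping every statistical tolerance
meaningful.

## Known limitations

- The extrinsic fraction is weakly identified at ≤1,000 cells (see above);
  its posterior mode is a coarse summary and the reported 68% interval is
  the meaningful statement of uncertainty.
- The full finite-rate telegraph pmf outside the bursty limit is not
  implemented analytically; the exact simulator covers that regime.
- MI is estimated without binning; for genes with very high copy numbers
  and few cells the plug-in joint becomes sparse, which inflates both the
  observed MI and the permutation null (the comparison stays calibrated,
  but power drops).
- Multi-strain joint (hierarchical) fits are out of scope; each condition
  is fitted separately.
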
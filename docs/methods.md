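# Methods

## Model and posterior

The trait is modelled as Gaussian and additive in minor-allele dosage,
`Y = β₀ + Gβ + ε` with `ε ~ N(0, σ²Iₙ)`, where `G` is the risk-index matrix:
one column per *active* group, each column the dosage sum `X_g γ_g` over the
group's currently included variants. Groups are defined by a MAF threshold —
every common variant (MAF ≥ threshold) is its own group; all rare variants in
a region form a single group. Inclusion indicators γ carry independent
Bernoulli(π) priors, so `p(γ) = Π π^{γ_j}(1−π)^{1−γ_j}`; π (the prior
inclusion probability, PIP) is the only sparsity control and defaults to 0.1
("one in ten variants included a priori").

The marginal likelihood `p(Y|γ)` is approximated by the plug-in value: the
Gaussian likelihood evaluated at the least-squares MLEs, with
`σ̂² = RSS/n`. The maximised log likelihood is then
`−(n/2)·ln(2π σ̂²) − n/2`. Two numerical guards apply:

* **Variance floor.** `σ̂²` is floored at `1e−12 · var(Y)`: rare-variant
  designs with a handful of carriers can interpolate `Y` exactly, which would
  otherwise send the log likelihood to +∞.
* **Rank deficiency.** Duplicate or collinear burden columns occur naturally
  (e.g. two rare variants with identical carriers); the fit uses minimum-norm
  least squares, and only the RSS — which is unaffected — enters the score.

### A consequence of the plug-in approximation

The plug-in value is a maximised, not an integrated, likelihood: adding any
column can only decrease the RSS, so the "Bayes factor" for including one
more variant is always ≥ 1. Exactly enumerated posteriors show that, as a
result, **every variant's marginal posterior probability is at least π, even
pure noise variants** (a noise variant with chance marginal correlation z
gets an inclusion Bayes factor ≈ exp(z²/2), which is ≥ 1 always and large for
ordinary sampling fluctuations). Two practical implications, both visible in
this package's own acceptance measurements:

1. The "MPP exceeds PIP" screen is permissive rather than a type-I filter:
   under a fully null simulation it passes essentially all variants.
2. The permutation stage compares two draws from the same null distribution,
   so a noise variant clears it with probability ≈ 1/2; the expected number
   of false true-positive calls scales with half the variant count rather
   than being controlled at a small constant.

The **MPP ranking** is where the method's signal lives: planted causal
variants (common, MAF 0.3 at 0.3 trait-SD; rare, MAF 0.005 at 1.0 trait-SD;
n = 1000) reach MPP ≈ 1 and rank first in ≈ 90% of replicates, well separated
from the noise floor around 0.1–0.2. Reports should be read top-down by rank;
the true-positive flag alone is not a calibrated error-rate guarantee. No
dimension penalty (BIC, g-prior) is added, keeping the score faithful to the
plug-in formulation; adding one would change the stated method.

## Sampler

Metropolis–Hastings on γ with a single uniformly chosen bit flip per
iteration — symmetric, so acceptance is `min(1, exp(Δscore))`. Compound
add/remove/swap moves were considered and deferred: the bit flip keeps the
Hastings ratio exactly 1 and mixes well at candidate-region scale (p ≲ 100).
The chain starts from the empty model, matching the sparse prior; a random
start is available for convergence checks. Default protocol: 5000 burn-in
iterations, then 5000 retained draws at thinning 10 — 55,000 iterations
total. Scores are memoised by the byte pattern of γ, which makes the default
protocol cheap (the chain revisits a small high-probability set).

The **permutation null** runs a second, identically configured chain on one
fixed uniform permutation of Y (drawn from `permutation_seed`, default
`seed + 7919`); the null chain's RNG stream is offset (`seed + 1_000_003`) so
observed-chain output is bit-identical whether or not the null chain runs.
Re-permuting at every iteration was considered and rejected: it would make
the null chain target an iteration-varying distribution. Averaging empirical
MPPs over several independent permutations is possible by re-running with
different permutation seeds.

## Convergence diagnostic

Geweke's z compares the mean of the first 10% of the scalar log-score trace
with the last 50%, `z = (m_A − m_B)/√(sv_A/n_A + sv_B/n_B)`, where `sv` is
the spectral density at frequency zero estimated by an AIC-selected
autoregressive fit (Levinson–Durbin recursion, max order ≈ n^{1/3}) — the
estimator used by the standard CODA implementation of this diagnostic. On
independent Gaussian traces the measured type-I rate at |z| < 1.96 is ≈ 5.1%
(2000 traces), and AR(1)-correlated stationary traces are absorbed correctly.
Convergence is monitored on the log-score trace because per-variant indicator
traces are binary and ill-suited to a means test. A constant trace returns
z = 0, converged, by convention.

## Data handling

* **Coding.** Dosages always count the minor allele; columns whose coded
  allele exceeds frequency 0.5 are recoded `2 − x`. MAF is
  `min(f, 1−f) ∈ [0, 0.5]`, computed over non-missing genotypes, after
  individual-level filtering.
* **Filtering.** Complete-case: individuals with any missing genotype or a
  non-finite phenotype are removed; then variants with minor-allele count
  ≤ 1 (singletons; configurable via `min_minor_allele_count`) and
  monomorphic variants are dropped. No imputation.
* **Transform.** A natural-log option corrects right-skewed positive traits;
  downstream inference is invariant to the log base.
* **Threshold sweep.** Default grid 5%, 4%, 3%, 2%, 1% (the common choice of
  starting at 5%); per-threshold chains use deterministically offset seeds,
  and observed/empirical MPPs are averaged arithmetically across thresholds
  (every variant appears at every threshold, so averages have no missing
  cells). Selection uses strict inequalities on both stages and applies to
  the averaged values; ranking ties break by ascending genomic position.

## Synthetic data

The generator emulates a deep-sequenced candidate gene in unrelated samples:
independent variants with dosages `Binomial(2, MAF_j)` (Hardy–Weinberg), a
log-uniform MAF spectrum over [3e−4, 0.35] (extreme-rare singletons through
common polymorphism), and the additive Gaussian trait with effect sizes in
trait-SD units. Defaults: n = 1000, p = 22, σ = 1, no missingness. It does
**not** model linkage disequilibrium, population structure, relatedness,
covariates or genotyping error — passing tests demonstrate correctness of
the inference machinery under the model's own assumptions, not robustness to
those real-data features. Optional uniform missingness and the extreme-rare
sites exercise the filters end-to-end.

## Problem sizes used in the validation suite

Exact-enumeration cross-checks run at p ≤ 10 (2^p model evaluations);
sampler-vs-enumeration agreement uses n = 300, p = 10, three chains at the
full default protocol (observed max MPP discrepancy ≈ 0.01–0.016, bound
0.02). Power and null-calibration studies use 20 replicates of n = 1000,
p = 22 at the single 5% threshold with one paired chain each; the
multi-threshold sweep machinery is validated separately on smaller problems.

## Known limitations

* The plug-in likelihood's lack of a complexity penalty makes the PIP screen
  and the permutation rule anti-conservative (see above); MPP rankings are
  the reliable output.
* One rare group per region: multi-gene analyses get one burden group per
  region label, never a data-driven sub-grouping.
* Biallelic SNVs only; multiallelic records are skipped on VCF input.
* Candidate-region scale: model-space enumeration is exponential and the
  sampler is serial; genome-wide scans are out of scope.
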
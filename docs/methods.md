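# Methods

`omnifisher` tests, gene by gene, whether a trait is associated with any of
up to three omics layers measured on (possibly different) subjects: SNP
genotypes **G**, DNA-methylation M-values **M**, and RNA expression **E**.
It produces per-layer p-values from kernel-machine (KM) score tests, one
corrected gene-level p-value from a covariance-adjusted Fisher combination
("Omnibus" combination), and optionally an optimal min-p test over all
seven disease-model combinations, calibrated by perturbation.

## 1. Per-layer kernel-machine score test

For a layer with feature matrix `D` (n subjects × m features) and diagonal
weights `W` (identity by default), feature effects are modelled as random
with variance τW; the null hypothesis of no association is τ = 0. The
variance-component score statistic against the covariates-only null model
is

    continuous:  Q = (y − Xβ̂)' D W D' (y − Xβ̂) / σ̂²_E
    binary:      Q = (y − μ̂)' D W D' (y − μ̂)

with `β̂` the least-squares / logistic-MLE coefficient vector, `μ̂` the
fitted probabilities and `σ̂²_E` the residual variance. The null models
expose

    gaussian:  P0 = I − X(X'X)⁻¹X'              Σ̂ = σ̂²_E I
    binomial:  P0 = Σ̂ − Σ̂X(X'Σ̂X)⁻¹X'Σ̂        Σ̂ = diag(μ̂(1−μ̂))

Under the null, Q follows the positively weighted chi-square mixture
Σᵢ λᵢ χ²₁ where λᵢ are the positive eigenvalues of
`P0^(1/2) D W D' P0^(1/2)`, computed in practice from the m × m dual
`W^(1/2) D' P0 D W^(1/2)`, which shares its nonzero spectrum and costs
O(n m² + m³) instead of O(n³).

**Scaling convention.** The continuous-trait Q divides by `σ̂²_E` while the
eigenvalue matrix is unscaled. These are mutually consistent as written:
the residual has covariance ≈ σ² P0, the division by `σ̂²` estimates the
σ² out, and the remaining weights are exactly the unscaled eigenvalues.
The test suite pins this convention two independent ways: a single-feature
block reproduces the classical linear-regression score test to 1e-6, and
the rank-1 eigenvalue equals the feature's centred sum of squares.

**Degrees-of-freedom choice.** `σ̂²_E` uses the unbiased denominator
n − p. Nothing in the method depends on this at simulation sample sizes
(n = 1000, p = 3); it matches standard score-test practice.

**Tail probabilities.** Two evaluators, one accuracy-first and one
throughput-first:

* *Characteristic-function inversion* (Davies-style): the Gil–Pelaez
  integral is evaluated by the midpoint rule with an explicit aliasing
  bound (the integration step is chosen so that the aliased tail mass,
  bounded through Q ≤ λmax·χ²_m, is below tolerance) and an explicit
  truncation bound from the envelope `1/(u·ρ(u)) ≤ g·u^(−1−m/2)`. The
  returned error bound is conservative; absolute accuracy is ~1e-9 for
  m ≥ 3 and ~1e-5 in the worst case (m = 2, where the envelope decays
  slowly and the term count is capped). Verified against the exact scaled
  chi-square for equal weights and against 2×10⁶-draw Monte Carlo for
  mixed weights.
* *Saddlepoint* (Kuonen's Lugannani–Rice form), vectorised over thousands
  of statistics sharing one weight vector. Relative error is ≲1% for
  m ≥ 4 and a few percent at m = 2 near the distribution centre; entries
  whose saddlepoint degenerates (statistic at its mean) are patched with
  the inversion. A single weight is handled exactly via the chi-square
  survival function everywhere.

Observed statistics always use the inversion (falling back to the
saddlepoint only when the inversion's error bound dominates its value,
i.e. at extremely small tails); perturbation draws use the vectorised
saddlepoint. Within the perturbation machinery the observed statistic is
*re-evaluated* with the same batch evaluator, so ranks between observed
and perturbed values are never distorted by mixing evaluators. All
p-values are floored at 1e-300.

Eigenvalues below `1e-10 × λmax` are dropped as numerical rank noise.
P0^(1/2) is P0 itself in the gaussian case (idempotent); the binomial
case uses a symmetric eigendecomposition root with negative eigenvalues
clamped to zero.

## 2. Corrected (Omnibus) Fisher combination

Classical Fisher combines w independent p-values via
`T = −2 Σ ln pᵢ ~ χ²_{2w}`. Layer p-values from one gene are correlated;
applying classical Fisher anyway inflates the Type I error (demonstrated
by the simulation harness). The corrected combination matches the first
two moments of T to a scaled chi-square (Satterthwaite):

    E(T) = 2w,   Var(T) = 4w + 2 Σ_{i<j} cov(−2 ln pᵢ, −2 ln pⱼ)
    v = 2E(T)²/Var(T),  c = v/E(T),  p_combined = P(χ²_v > cT)

`v` is generally fractional; the chi-square survival function is evaluated
at non-integer degrees of freedom (gamma(v/2, scale 2)). The covariance
diagonal is fixed at 4 — the exact variance of −2 ln U — regardless of its
estimate. Negative estimated covariances are retained, but Var(T) is
floored: a non-positive total falls back to the independence value 4w, and
anything below 0.1·4w is clamped there, each with a warning. The floor
prevents invalid or explosive v from noisy covariance estimates; it only
engages under strong negative dependence, which the perturbation estimator
does not produce in practice.

## 3. Perturbation and the optimal test

The covariance entries and the optimal test's reference distribution both
come from perturbation. Because each observed Q is a quadratic form in an
(approximately) standard-normal residual vector, replacing that vector by
a fresh standard normal draw — one entry per subject, shared across layers
— regenerates all layer statistics under H₀ while preserving their
cross-layer dependence:

1. draw r ~ N(0, I) over the union of the layers' subjects,
2. per layer, restrict r to the layer's subjects, rotate by the layer's
   eigenvectors, and form Q_l = Σᵢ λ_{l,i} r²_{l,i} → p_l,
3. repeat B times.

Numerically the rotation is folded into one m × n operator A_l with
`A_l A_l' = W^(1/2) D' P0 D W^(1/2)`, so Q_l = ‖A_l r‖²; this is
algebraically identical to the eigenvector route and never materialises
n × n matrices. When every layer shares a single null fit (identical
subjects and covariates), A_l is built from a cheap O(np) factor F with
FF' = P0 — any such factor induces exactly the same joint law of the
perturbed statistics. With different subject sets or per-layer covariates
the symmetric root of each layer's P0 is used instead, so that sharing
r subject-wise carries the exact cross-layer covariance.

The binary-trait case uses the identical standard-normal perturbation:
its Q is the same quadratic form with the mean-variance weights absorbed
into P0, so the perturbed statistics have exactly the right null law
(this is exact for the draws, asymptotic for the observed statistic, as
in the continuous case).

*Covariance estimation*: the empirical covariance of
(−2 ln p_G, −2 ln p_M, −2 ln p_E) over b ∈ {0, 1, …, B} — the observed
draw is included, following the estimator's definition; a configuration
switch excludes it. Default B = 200 for the regular combination.

*Optimal test*: with seven candidate disease models
{G, M, E, GM, GE, ME, GME} (fewer when layers are missing), every model's
corrected-Fisher p-value is computed identically for the observed draw and
each perturbed draw, using sub-blocks of the estimated covariance; the
test statistic is the row-wise minimum, and the final p-value is the
resampling estimate

    p = (1 + Σ_{b=1..B} I(p^(b) ≤ p^(0))) / (1 + B).

The add-one correction keeps the estimate strictly positive (standard
permutation-p convention), bounding it below by 1/(B+1). B escalates
stepwise — 1,000 → 10,000 → 100,000 by default — while p < 10/B, so only
small p-values pay for large B. Each stage estimates the covariance from
its own draws. Pairwise model covariances are sub-blocked from the 3 × 3
estimate rather than re-estimated; the two differ only by Monte Carlo
noise on the same draws.

Determinism: all randomness flows through one `numpy` Generator; the
genome-wide driver derives a per-gene substream from (seed, gene-id hash),
so per-gene results are independent of execution order and bit-reproducible.

## 4. Synthetic data: what the generator emulates

The simulation harness reproduces the structure the method's operating
characteristics depend on — the null dependence between layers and the
location of causal signal — not any particular cohort.

* **Haplotypes**: 10,000 binary haplotypes over 200 kb. Allele
  frequencies follow a neutral-spectrum draw (density ∝ 1/f) truncated to
  [1e-4, 0.5], i.e. rare variants dominate, as in a coalescent pool that
  includes singletons. LD comes from a latent Gaussian AR process whose
  correlation decays as exp(−d/30 kb); adjacent-site r² exceeds
  distant-site r² by construction. Each simulated gene takes a random
  window of 50 contiguous SNPs; subjects draw two haplotypes with
  replacement.
* **Methylation**: M-values `log2(β/(1−β))` from a two-component beta
  mixture (hypo ≈ 0.12, hyper ≈ 0.88, concentration 1500 → per-CpG
  M-value sd ≈ 0.11), correlated within 5-CpG gene blocks through a
  Gaussian copula (latent AR, ρ = 0.6). Randomly drawn, unfiltered array
  CpGs are mostly stable, hence the small per-site spread.
* **Expression**: one log-scale value per gene; gene means spread
  (sd 1.2) around the anchored grand mean 7.45, within-gene sd 0.15.

**Scale calibration.** The per-feature spreads were chosen so that the
fixed effect sizes of the phenotype models (below) land in the
interior-power regime: with substantially larger per-feature variances
every method's power saturates at 1 and no ordering between methods is
observable, which contradicts the regime the method comparison operates
in. This is a property of the *pools*, fixed once here, not a per-run
tuning knob.

* **Causal-feature selection**: 5 causal SNPs (of 50) are redrawn per
  dataset uniformly among sites segregating at cohort scale (pool
  MAF ≥ 0.001, i.e. expected carriers among 1,000 subjects) — a
  monomorphic "causal" variant influences nothing. The designated
  coupling SNP G₁ is the most common of the five, a pure labelling
  choice among exchangeable causal effects, reflecting that the
  expression-coupling device models a cis-eQTL, which requires a
  segregating (typically common) variant. Causal CpGs: 2 of 5, uniform.
* **Phenotype models**: logistic intercept −2.94 = log(0.05/0.95)
  (5% baseline prevalence), covariates X1 ~ N(20, 1) and
  X2 ~ Bernoulli(0.5) with coefficients 0.001; genotype effect 0.3 per
  causal allele when G alone is causal, 0.2 alongside methylation;
  methylation effect 0.9 per causal CpG; expression effect 1 on the
  mean-centred value.
  Binary datasets accrue and keep the first 500 cases and 500 controls;
  continuous datasets use n = 1000 with standard-normal errors (the
  continuous sample size mirrors the binary one). Causal methylation
  effects act on deviations from the causal CpGs' pool means — the same
  anchoring the expression term uses — so that the designed baseline
  prevalence is preserved no matter which CpGs are drawn; without this
  the bimodal pool makes case accrual infeasible for hypo-methylated
  blocks.
* **Coupling device**: `E* = E + G₁` adds the first causal SNP's genotype
  to the expression value before any trait is generated, correlating two
  layers without touching the trait. Under trait permutation this is
  exactly the situation in which the uncorrected Fisher combination is
  anti-conservative.
* **Null datasets**: traits of causal datasets are permuted (10
  permutations per dataset), which preserves every marginal omics
  distribution exactly and breaks all trait associations.

What the generator does **not** emulate: genotype calling/imputation
noise, batch and cell-type-composition structure in methylation and
expression, population stratification, relatedness, or trait-model
misspecification. Passing calibration here shows the statistics behave
correctly under the stated dependence structure; it does not certify
robustness to those real-data complications.

## 5. Problem sizes used by the shipped harnesses

`scripts/acceptance.py` uses 2,000 null datasets for 5%-level rejection
rates (binomial 95% band ±0.0095 around 0.05), 5,000 for the 1%-level
rate, and 1,000 datasets for the perturbation-calibrated optimal test's
null rate (stage B = 1,000, covariance B = 200). The statistical test
suite uses 2,000 independent-layer and 10,000 coupled-layer null
datasets, and 1,500 causal datasets per power scenario — the power
orderings between the regular and optimal tests are one to three
rejection-rate points, which smaller counts cannot resolve above Monte
Carlo noise. The published-scale runs (10,000–100,000 datasets) are
available through the same harness functions by raising `n_datasets`.

## 6. Known limitations

* The perturbation argument is asymptotic in n for the observed
  statistic; very small samples (n ≲ 50) with binary traits may show mild
  miscalibration, as with any score-test-based method.
* The saddlepoint bulk evaluator introduces ≲1% relative error into
  perturbed p-values; this is invisible to covariance estimation and
  min-p ranking but is documented for completeness.
* With w = 3 layers the Satterthwaite approximation of the correlated
  Fisher statistic is accurate in the 10⁻⁶–1 range exercised here;
  far-tail behaviour (p ≪ 10⁻⁸) inherits moment-approximation error.
* Genes whose features lie entirely in the covariate span have no
  testable signal; they return p = 1 with an `exact_zero` marker.
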
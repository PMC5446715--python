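# Methods

## Model and estimation

Bulk methylation is modeled as Y = A Bᵀ + E on the M-value scale:
cell-type mean profiles A (p CpGs × q cell types) mixed by unobserved
per-sample proportions B (n × q), plus batch structure, individual
variation and measurement error.  Because B varies from sample to
sample, the composition induces low-rank structure in Y; surrogate
variables (SVs) estimate a basis of that structure so it can be
adjusted in per-CpG association tests.

The SV fit is an iteratively reweighted SVD:

1. **Initialization.**  Residualize Y on the full design (intercept +
   covariates + primary variable), row-center, take the first K right
   singular vectors.
2. **Probe probabilities.**  For each probe, two nested-model F-tests
   through precomputed orthonormal design bases: the SVs given the full
   design (→ p-values for "affected by unmodeled factors") and the
   primary columns given the null design plus SVs (→ p-values for
   "affected by the primary variable conditional on the SVs").  Each
   p-value vector is mapped to posterior null probabilities by the
   empirical-Bayes local FDR described below; p_γ and p_b are one minus
   those.
3. **Weights.**  w_j = p_γ,j (1 − p_b,j^α), α ∈ (0, 1].  α = 1 is the
   classic SVA weight; the default α = 0.25 softens p_b, which is badly
   estimated in early iterations when the initial residualization has
   removed confounded signal along with the primary effect.
4. **Update.**  SVs ← first K right singular vectors of the
   row-centered weighted matrix diag(w) Y (right factors computed
   exactly via the n × n Gram eigendecomposition; sign fixed by making
   each vector's largest-magnitude entry positive).
5. **Stopping.**  In `smart` mode, stop when the Spearman rank
   correlation between consecutive weight vectors exceeds
   `corr_threshold` (default 0.999); non-convergence at `max_iter`
   (default 100) returns a result flagged `converged=False` with a
   logged warning, because comparing against non-converged classic fits
   is itself of interest.  `classic_fixed_B` mode runs exactly B
   iterations (default 5) with α forced to 1 and no convergence test —
   the traditional-SVA comparator.  With α = 1 and an unreachable
   threshold, `smart` mode reproduces `classic_fixed_B` bit for bit
   (tested).

The softening switch `soften="first_iteration"` restricts the power
transform to the first iteration — the literal reading of softening the
*initial* p_b estimate.  The default `"always"` applies it throughout:
the convergence path, not just the starting point, benefits from evened
p_b estimates, and α = 1 remains available to disable it entirely.

### Empirical-Bayes local FDR

P-values are probit-transformed, z = Φ⁻¹(p).  The marginal density
f(z) is a Gaussian KDE with Silverman bandwidth
0.9 · min(sd, IQR/1.34) · m^(−1/5), evaluated by binning z into 4096
cells and smoothing the counts with a Gaussian filter (cost linear in
m; indistinguishable from the direct KDE at this resolution).  The null
fraction is π̂₀ = min(1, P(p > 0.8)/0.2).  Then
lfdr(p) = π̂₀ φ(z)/f̂(z), clipped to [0, 1] and forced monotone
nondecreasing in p by a running maximum.  The construction is judged by
calibration, not by equality with any particular legacy estimator: on
uniform p-values the mean lfdr exceeds 0.9; on an 80/20
uniform/Beta(0.05, 1) mixture the mean lfdr over the smallest 1% of
p-values is below 0.2 (both tested with fixed seeds).  Probes with zero
residual variance under the larger model are flagged degenerate, get
p = 1, are excluded from the density estimation, and receive weight 0.

### Number of components (random matrix theory)

Probes are standardized to mean 0, variance 1 (optionally after
residualizing on a design); K is the number of eigenvalues of the n × n
covariance of the standardized data (scaled by 1/p) exceeding the
Marchenko–Pastur upper edge σ̂²(1 + √(n/p))².  The noise variance σ̂²
is estimated as the median eigenvalue divided by the median of the MP
law (computed numerically by quadrature).  This rescaling matters: the
trace of the standardized covariance is fixed, so strong retained
factors — five batches at σ_B = 0.3 absorb ~40% of it — push the noise
bulk well below 1, and a unit-variance edge then counts only the batch
dimensions and misses the weaker cell-proportion dimensions, which in
turn breaks FDR control of the downstream adjustment.  On factor-free
data σ̂² ≈ 1 and the rule reduces to the plain edge (`noise="unit"` is
available to force that behavior).  No Tracy–Widom correction is
applied.  Zero-variance probes are dropped with a logged count.

## The simulator

The generator mimics a whole-blood case-control EWAS and is the source
of every test input; no external data are needed.

Pipeline (one explicit random stream; identical seed ⇒ bit-identical
output): reference M-value profile from a three-component normal
mixture (hypo/hemi/hyper-methylated CpGs) → two progenitors → four
subtypes each by "differentiation" steps that shift a random probe
subset → per-sample Dirichlet proportions, confounded with the
phenotype through per-subtype log2 fold changes f_k ~ N(0, σ_F²) (for
continuous phenotypes the fold change scales linearly with the
phenotype) → planted DMP effects, shared across subtypes by default →
individual-specific shifts per sample × subtype → **mixing on the beta
scale** (cell populations average methylated fractions, not log-odds) →
back to M-values, where batch shifts (per batch × probe) and
measurement error are added.  Samples are randomized round-robin into
batches, so batch is a variance source, not a confounder, by default.

Defaults (units: M-values unless noted):

| parameter | default | meaning |
|---|---|---|
| p, n, q | 10,000, 100 (50/50), 8 | CpGs, samples, cell types |
| μ^R, σ^R, π^R | (−4, 0, 4), (0.6, 0.6, 0.6), (0.45, 0.10, 0.45) | reference mixture |
| π^C, σ_C | 0.15, 1.0 | probes shifted per differentiation step, shift sd |
| π^I, σ_I | 0.05, 0.5 | individual-specific variation |
| π^G, σ_G | 0.01, 1.0 | DMP fraction and effect sd (grids use 0.001/0.01/0.1) |
| π^P | (0.35, .10, .10, .05, .15, .10, .10, .05) | mean proportions |
| φ | 25 | Dirichlet overdispersion |
| σ_F | 0.3 | confounding strength (grids use 0 / 0.3 / 0.6) |
| n_B, σ_B | 5, 0.3 | batches and batch-shift sd |
| σ_E | 0.3 | measurement error sd |

π^C = 0.15 and φ = 25 are this package's calibration of cell-type
distinctness and proportion variability.  Purified leukocyte methylomes
differ at a substantial fraction of CpGs — two differentiation steps at
0.15 make sibling subtypes differ at ~28% of sites and cross-lineage
types at ~48%, still conservative relative to purified-cell data — and
φ = 25 reproduces the observed sd of the neutrophil fraction in whole
blood (~0.10 around a mean of 0.35–0.55).  Under this calibration the
generator exhibits the qualitative regimes the evaluation is built
around: the unadjusted analysis is visibly inflated under strong
confounding (mean λ on non-DMPs ≈ 1.4 at σ_F = 0.6, with individual
replicates ranging from ~0.9 to ~2.5), the perfect
adjustment is calibrated, and the composition dimensions are strong
enough that an eigen-spectrum rule can find them — with markedly weaker
cell-type differences the proportion eigenvalues sink into the noise
bulk, where no component-count rule (and no adjustment method) can
recover them.

What the generator does **not** emulate: spatial correlation of
neighboring CpGs, probe-type chemistry artifacts and normalization
effects of real arrays, genotype-driven methylation, missing values,
and cell-type-specific (rather than shared) DMP effects unless enabled.
Passing tests therefore demonstrate correct behavior under the model's
assumptions — independent probe-level noise, Dirichlet proportions,
additive batch shifts on the M scale — not performance on any
particular real dataset.

## Evaluation metrics

Per-CpG association tests are OLS on M-values of
[intercept, adjustment, phenotype], two-sided t-test on the phenotype
coefficient, vectorized through shared QR projections (oracle-tested
against per-probe regressions to 1e−8).  Scoring against simulation
truth: genomic inflation λ = median(χ²₁)/0.456 on the non-DMPs (the
denominator is deliberately the conventional printed constant, not the
exact χ²₁ median 0.45494); observed FDR = false discoveries /
max(discoveries, 1) after Benjamini–Hochberg at 5%; FWER indicator =
any non-DMP rejection after Bonferroni (p < 0.05/m); TPRs (NaN when the
DMP set is empty, excluded from aggregation); and the cell-composition
adjusted R²: canonical correlations ρ_i between the components and the
proportions (last column dropped for simplex redundancy), combined as
R² = 1 − Π(1 − ρ_i²) with the Ezekiel adjustment
1 − (1 − R²)(n − 1)/(n − K − 1).  The multivariate adjusted-R² form is
this package's concrete choice; its contract is endpoint behavior
(≈1 when the components span the proportions exactly, ≈0 on
independent noise), both tested.  The "perfect" benchmark adjusts for
the true proportions (last column dropped) plus batch indicators (last
batch dropped).

## Problem sizes and numerical choices

The benchmark grid used by the acceptance script and the acceptance
tests is 9 scenarios × 20 replicates at p = 10,000, n = 100 — the
scenario grid at a replicate count chosen to keep a full desk run in
minutes while leaving Monte-Carlo standard errors small enough for the
stated checks (the error bars are reported alongside every mean).
Within-suite RMT calibration uses 100 seeds at p = 10,000, n = 100.

Numerical conventions: p-values floored at the smallest positive
double before probit transforms and after F/t tail evaluation; F-test
numerators clipped at 0 against cancellation; degenerate probes
detected at rss ≤ 1e−12 · total sum of squares; Spearman correlation of
two exactly constant weight vectors defined as 1; SV sign fixed by the
largest-magnitude entry; ties in ranks handled by average ranks
(scipy); all on-disk floats written with 17 significant digits and read
back with round-trip parsing, so write → read is bit-exact.

## Known limitations

- Per-replicate λ on non-DMPs is heavy-tailed (probes are strongly
  correlated through shared proportions and batches), so scenario means
  over 20 replicates carry visible Monte-Carlo error; the acceptance
  checks account for it explicitly.
- The local-FDR estimator is a deliberate, testable construction; other
  published SVA implementations use different density estimators and
  will not agree number-for-number, only in calibration.
- On small matrices (p ≲ 2,000) the weight vector is noisy and the
  0.999 convergence threshold may not be reached within 100 iterations;
  the result is still returned, flagged, and usable.
- `smartsva_fit` accepts a `seed` for interface stability but is fully
  deterministic: the SVD backend is an exact Gram eigendecomposition,
  no randomized projection.
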
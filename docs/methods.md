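# Methods

## Scope and assumptions

`ribocomp` models steady-state allocation of a conserved expression
resource (ribosomes, RNA polymerases) between competing gene modules in
single cells, and the propagation of cell-to-cell input variability to the
correlation structure of the outputs. The assumptions throughout:

- the competing modules share no regulators (no common transcription
  factors or sRNAs); coupling arises only through the shared resource;
- per-cell input totals (mRNA pools, resource totals, gene copies) are
  random *across* cells but constant *in time* within a cell — the model
  is a quasi-static ensemble, not a stochastic-kinetics one;
- macroscopic rate constants (loading numbers, dissociation constants,
  output gains) are identical in every cell;
- no growth-rate feedback: resource totals do not respond to burden.

Master-equation dynamics, fluorophore maturation, and inference of kinetic
parameters from images are out of scope.

## Translation model

Free ribosomes solve
`RibT = RibF + Σᵢ nᵢ·RibF/(βᵢ+RibF)·MᵢT` (i = 1 heterologous,
2 endogenous). The left side is strictly increasing in `RibF`, so the
root on (0, RibT] is unique. The solver is a vectorized bisection on
[0, RibT] (iteration count chosen from a lower bound on the root so the
final bracket is below the requested relative tolerance, default 1e-12)
followed by one guarded Newton step; the same code path solves one cell or
a 10⁵-cell population. The degenerate case of zero total demand returns
`RibF = RibT` exactly without iteration.

Sensitivities come from implicit differentiation, not numerical
perturbation:

```
dRibF/dMjT = -gj(RibF)/D,   dRibF/dRibT = 1/D,
D = 1 + Σᵢ MᵢT·nᵢβᵢ/(βᵢ+RibF)²,   gᵢ(R) = nᵢR/(βᵢ+R),
```

with the protein partials by the chain rule on `Pᵢ = cᵢ gᵢ(RibF) MᵢT`.
The test suite verifies the analytic Jacobian against central finite
differences to 1e-6 of the Jacobian scale on random parameter draws
(element-wise relative comparison is not meaningful for entries near the
finite-difference noise floor, which inherits solver round-off divided by
the step).

### Default parameters

| symbol | default | meaning |
|---|---|---|
| n₁ = n₂ | 10 | ribosomes per mRNA at saturation |
| β₁ = β₂ | 1000 molecules/cell | ribosome–mRNA dissociation constant |
| c₁ = c₂ | 1 (a.u.) | output gain per bound ribosome |
| mean M₁ᵀ | 300 (base), 30–1000 across the induction series | heterologous mRNA pool |
| mean M₂ᵀ | 900 | endogenous mRNA pool |
| mean Ribᵀ | 10,000 | total ribosomes |
| CV²(M₁ᵀ), CV²(Ribᵀ) | 0.1 | within-condition variability |
| CV²(M₂ᵀ) | 0 | held fixed in the two-source analysis |

The means, the Ribᵀ variability floor of 0.1 (the lower bound typical of
abundant bacterial proteins), the 30–1000 induction range and the
3000-cells-per-condition sample size are the study conditions the package
reproduces. The microscopic constants (n, β, M₂ᵀ) are not separately
identifiable from published summary numbers, so they were fixed once by
qualitative calibration: the chosen set is required to reproduce, at the
stated operating point and variabilities, the full sign/monotonicity
pattern of the framework — positive within-condition correlation at every
induction level with a negative pooled correlation; r(P₁,P₂)
non-decreasing in mean M₁ᵀ above ~100 and non-increasing in mean Ribᵀ up
to 10⁴; r increasing in CV²(Ribᵀ) and decreasing in CV²(M₁ᵀ). Notably, a
weaker-capture setting such as β = 100 with a light endogenous load fails
this pattern (within-condition correlations come out negative at
CV² = 0.1), so the heavier endogenous load (M₂ᵀ = 900, about half the
ribosome pool engaged by native genes at the base point) and β = 1000 are
the package defaults. Gains c₁, c₂ rescale outputs linearly and cancel in
every correlation; they exist so figure-style output units can be matched.

`competition_strength` reports ∂P₂/∂M₁ᵀ (≤ 0). Its absolute value deepens
with a scarcer ribosome pool at light endogenous load; at heavy load the
output scale itself shrinks with the pool, and the strengthening shows in
the *relative* repression ∂P₂/∂M₁ᵀ / P₂ — both behaviors are tested.

## Noise propagation

`PopulationMoments` carries means, CV² (always variance over squared
mean) and pairwise Pearson correlations of (M₁ᵀ, M₂ᵀ, Ribᵀ); the implied
covariance matrix must be PSD. Two covariance modes:

- **full** — the six-term sum over the 3×3 input covariance,
  equal (tested to 1e-12) to `(JΣJᵀ)₁₂`;
- **reduced** — the two-source approximation (Var Ribᵀ and Var M₁ᵀ only)
  with the resource (≥ 0) and competition (≤ 0) terms reported separately.

In `protein_correlation` the denominator variances use the *same* source
set as the numerator's mode, so each mode is internally consistent and
r ∈ [−1, 1] holds structurally. The two modes agree exactly when
CV²(M₂ᵀ) = 0 and all input correlations vanish.

Monte Carlo of the full nonlinear model draws inputs from lognormal
marginals coupled by a Gaussian copula and solves every cell exactly.
For lognormal marginals the observation-space Pearson correlation is a
closed form in the latent correlation, so the copula is calibrated by
exact inversion (not iteration); ρ_z = ±1 of the same formula gives the
attainable range, and unattainable targets raise a calibration error that
names it. Linearization accuracy is verified by comparing the predicted
covariance to the Monte Carlo covariance at input CVs of 1% and 5%
(10⁵ cells) within 3 bootstrap standard errors (B = 200; the SE estimate
is stable well below B = 1000 and keeps the check fast).

`simpson_scenario` simulates an ordered induction series (default: seven
conditions, mean M₁ᵀ log-spaced 30→1000) and reports within-condition and
pooled correlations. Per-condition random streams are spawned from the
master seed keyed by condition index, so appending conditions never
perturbs earlier ones. The pooled covariance obeys the exact mixture
decomposition (mean within-covariance + covariance of condition means),
which the tests check on simulated tables.

## Transcription model

Three gene classes (heterologous, endogenous protein-coding, rRNA/tRNA)
compete for RNAP with the same hyperbolic form; class 3 is a fixed
deterministic sink. Defaults: K₁ = K₂ = K₃ = 1, m₁ = m₂ = 5 RNAPs per
protein-coding gene copy, RNAPᵀ = 8000, D₂ᵀ = 100, and a class-3 sink of
D₃ᵀ = 50 copies at m₃ = 80 so the rRNA/tRNA machinery engages about half
the polymerase pool — a tunable coarse default reflecting rRNA dominance,
not a measured value. Parameters outside the modeled boxes
(K ∈ [0.1, 10], RNAPᵀ ∈ [4000, 12000], D₁ᵀ ≤ 200) trigger warnings, not
errors.

With these defaults free RNAP is in the thousands while K ≈ 1, so
promoter occupancy is near-saturated. Three consequences, all tested:
(i) at matched heterologous resource fraction, translational repression
of the endogenous output exceeds transcriptional repression by more than
an order of magnitude (`matched_burden_repression` finds the M₁ᵀ and D₁ᵀ
that sequester the same resource fraction by bisection); (ii) r(M₁, M₂)
tracks the promoter-copy correlation ρ(D₁ᵀ, D₂ᵀ) within 0.05 when RNAP
is non-limiting; (iii) r moves by < 0.1 across mean-D₁ᵀ ∈ [1, 100] and
CV²(D₁ᵀ) ∈ [0.02, 0.5] sweeps. The promoter-variability sweep starts at
0.02 rather than 0: at CV²(D₁ᵀ) = 0 the promoter correlation itself is
undefined (degenerate marginal) and the mRNA variance collapses onto the
other sources, which is a different regime, not a counterexample to the
claim.

## Antibiotic-resistance survival

Resistance proteins (R₁, R₂) are lognormal (default mean 100, CV² = 0.1 —
the same abundant-protein variability floor) with Pearson correlation
ρ_R imposed by the calibrated copula. Under equal lognormal marginals the
Gaussian copula attains ρ ∈ [−1/(1+CV²), 1], so CV² must be ≤ 0.25 for
ρ = −0.8 to exist; 0.1 leaves margin. A cell survives dose (A₁, A₂) iff
R₁ ≥ γ₁A₁ and R₂ ≥ γ₂A₂ (independent deactivation, sharp threshold;
default γ = 1). A smooth Hill-type kill rule is provided as a variant and
converges to the threshold rule at high Hill coefficient. Under the
copula model the survival probability is the upper-orthant probability of
the latent bivariate normal; `analytic_survival` evaluates it with the
bivariate normal CDF and serves as the closed-form cross-check of every
Monte Carlo configuration. The correlation sweep replicates each scenario
100 times (population default 10⁴) and reports mean ± SD. "High dose" in
the monotonicity statements means both thresholds above the marginal
medians (default test dose: the 90th percentile of each marginal); by
Slepian's inequality survival is then non-decreasing in the latent
correlation, hence in ρ_R. At ρ_R = −0.8 and high symmetric dose the
survival probability is ~10⁻⁵, so finite replicates can all be zero —
replicate SD is asserted positive only where survivors exist.

## Synthetic data generators

**Protein datasets** draw per-cell inputs with the heterogeneity sampler,
solve the steady state exactly, and apply per-channel multiplicative
lognormal measurement noise (default CV 0.05) plus additive Gaussian
background truncated at 0 (default level 2% of the largest deterministic
channel mean across the series, SD 25% of the level). Defaults: the
7-condition series, 3000 cells per condition. Latent truth columns are
retained so recovery can be scored exactly.

**FISH datasets** draw true counts — Poisson for the constitutive gene
(default 2.02 copies/cell in every condition) and negative binomial
(default dispersion 2, means log-spaced 0.3→30 along the series) for the
induced gene, optionally coupled by a count-level copula — then form
observed intensity as `(copies × unit × lognormal noise + background) ×
area`, with lognormal cell area (CV² 0.04) and background level 10 ± 5
per unit area against a unit intensity of 100. The negative control is
pure background under the same area model. Defaults: 7 conditions × 1000
cells, 1000 control cells. The per-condition NB dispersions are free
parameters of the generator; no published per-condition values exist to
pin them.

The generators emulate the statistical structure of two-channel
microscopy tables, not the microscopy itself: no pixel-level optics, PSF,
segmentation error, spectral bleed-through, or day-to-day batch effects.
Pipeline tests on these data therefore validate the *statistical
machinery* (thresholding, unit estimation, quantization, fits,
grouped correlations) under the stated noise model — they do not certify
performance on real images.

## Statistics pipeline

- **Pearson r / CV²** — sample variance uses denominator n−1 everywhere,
  so results are bit-reproducible against the textbook formulas (tested).
  Constant vectors raise an undefined-correlation error rather than
  returning NaN.
- **Bootstrap** — percentile method, B = 1000 by default, rows resampled
  with replacement; degenerate resamples (e.g. constant columns under a
  correlation statistic) are rejected, redrawn, and counted in a log
  message. Coverage of the mean's 95% interval is verified by simulation.
- **Quantization** — background defaults to the median area-normalized
  negative-control intensity; the false-positive threshold is the 99th
  percentile of the background-subtracted negative control (the principle
  is fixed, the quantile is a config parameter); "low-expression cells"
  are the positive cells below the 25th percentile of above-threshold
  density; the unit intensity is the Silverman-bandwidth kernel-density
  peak over those cells (their median when they are numerically
  constant); copies round to the nearest integer, ties away from zero.
  Quantization is idempotent on already-quantized noiseless data.
- **Count fits** — Poisson by closed form; NB2 by profile likelihood (the
  mean MLE is the sample mean for any fixed dispersion; the dispersion is
  a 1-D bounded optimization). Underdispersed data fall back to Poisson
  with a warning. Goodness of fit is a chi-square test with expected
  counts merged to ≥ 5 per bin.
- **Grouped analysis** — within-group and pooled correlations plus the
  even-subsampling curve: for each total size n, 100 replicates draw
  n/K cells per group without replacement and record the pooled r. Equal
  per-group draws remove group-size confounding; the curve's SD shrinks
  with n while its mean stays put, distinguishing a real sign reversal
  from a sampling artifact.

## Numerical conventions and limitations

- All randomness flows through `numpy.random.Generator`; master seeds
  spawn per-condition/per-replicate substreams via `SeedSequence` keys,
  so results are bit-reproducible and insensitive to adding conditions.
- Solver tolerance 1e-12 relative; conservation residuals are tested
  below 1e-9 relative over 1000 random draws.
- Linearized correlations are exact only in the small-noise limit; at
  CV² = 0.1 the Monte Carlo and linearized correlations agree
  qualitatively but not to Monte Carlo error, which is expected and is
  why validation uses CV ≤ 5%.
- The latent-copula calibration is exact for lognormal marginals; for
  count marginals (FISH generator's optional coupling) the realized
  correlation is approximate and is only asserted within broad bounds.
- Kinetic defaults are calibrated to qualitative behavior (see above);
  quantitative figure-level values (axes in arbitrary units) are not
  reproduced, and no claim is made about absolute protein numbers.
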
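# Methods

## Model and estimands

Two-sample summary-data Mendelian randomization uses L genetic variants
as instruments for a continuous exposure (BMI in SD units of
inverse-normal-transformed residuals).  The inputs are per-allele
association estimates from two non-overlapping GWAS: exposure effects
γ̂ⱼ with standard errors σ_{γⱼ}, and binary-outcome log-odds effects Γ̂ⱼ
with standard errors σ_{Γⱼ}.  Under the instrumental-variable
assumptions each Wald ratio θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates the causal log odds
ratio per 1-SD exposure increment; the estimators differ in how they
pool the ratios and which pleiotropy pattern they tolerate:

* **IVW** — weighted zero-intercept regression of Γ̂ on γ̂ with weights
  wⱼ = σ_{Γⱼ}⁻²; consistent only when all instruments are valid.
* **MR-Egger** — the same regression with a free intercept, fitted after
  expressing every instrument on its exposure-increasing allele
  (γ̂ ≥ 0).  The slope is consistent even when all instruments have
  direct (pleiotropic) outcome effects, provided those direct effects
  are independent of the instrument strengths (InSIDE); the intercept
  estimates the average directional direct effect.
* **Weighted median** — the value of θ at the 0.5 crossing of the
  cumulative normalized inverse-variance weights (positions
  pⱼ = Σ_{k≤j} w_k − wⱼ/2 over the sorted ratios, linear interpolation
  between the bracketing order statistics, ties broken by SNP id);
  consistent when valid instruments carry ≥ 50% of the weight,
  regardless of the pleiotropy pattern among the rest.

Both regression estimators treat γ̂ as error-free (the NOME assumption).
The dilution that violation causes in MR-Egger is quantified by
I²GX = max(0, (Q_GX − (L−1))/Q_GX), Q_GX = Σ wγⱼ (γ̂ⱼ − γ̄_w)² with
wγⱼ = σ_{γⱼ}⁻²: the expected attenuation factor of the slope is ≈ I²GX.
SIMEX undoes it empirically: for each λ in a grid, B pseudo-datasets add
N(0, λσ²_{γⱼ}) noise to γ̂ⱼ, MR-Egger is refitted, and a quadratic in λ
through the per-λ mean estimates (including the λ = 0 naive fit) is
extrapolated to λ = −1, the hypothetical error-free state.

## Standard errors, intervals, tails

* IVW/Egger use a multiplicative residual-scale convention: the weighted
  residual variance (df L−1 through the origin, L−2 with intercept) is
  truncated below at 1, so intervals are never narrower than the
  fixed-effect ones; `residual_scale="fixed"` forces scale 1.
* Confidence intervals use Gaussian 0.975 quantiles by default; a
  t(L−2) option exists for MR-Egger.  P-values are two-sided.
* Wald-ratio SEs: first-order σ_{Γⱼ}/|γ̂ⱼ| feeds IVW and the
  weighted-median weights (this is what makes IVW exactly the
  fixed-effect meta-analysis of the ratios); the second-order form
  adding the γ̂-uncertainty term is the default input to heterogeneity
  and meta-regression, where understating the ratio variance would
  inflate τ².  The choice is logged in the run manifest.
* Weighted-median SE: SD of the estimate over B = 1000 parametric
  bootstrap draws (γ*, Γ* Gaussian at the point estimates).
* SIMEX defaults: λ ∈ {0.5, 1, 1.5, 2}, B = 1000, quadratic extrapolant.
  Variances follow the standard simulation-extrapolation estimate
  s²(λ) = mean model-based variance − between-replicate variance,
  extrapolated quadratically and floored at a small positive multiple of
  the naive variance.  All stochastic stages are seeded and
  reproducible.

## Harmonization

Outcome rows are re-expressed on the exposure's effect allele: swapped
allele order flips the beta sign and complements the frequency; strand
complementation is tried before declaring an allele mismatch.
Palindromic (A/T, C/G) SNPs cannot be strand-resolved from alleles;
they are resolved by comparing effect-allele frequencies when both are
further than 0.08 from 0.5 (discordant sides imply a flip), otherwise
the same-strand reading is kept and a warning emitted.  Missing outcome
SNPs may be supplied through a user-provided proxy map (r² > 0.8,
≤ 500 kb enforced on input; the highest-r² proxy wins and its outcome
row is used verbatim).  No LD computation or reference-panel queries are
performed.  Every exclusion is logged with a reason; harmonization is an
involution under double allele swaps, and all estimators are invariant
to re-expressing any input row on its other allele.

Instrument strength is summarized by F ⱼ = (γ̂ⱼ/σ_{γⱼ})², with an
approximate outcome-dataset strength F × N_outcome/N_exposure valid when
per-allele associations are comparable across samples; for the
schizophrenia-like profile the unrelated-sample total is the relevant N.

## Influence, heterogeneity, overlap

Influence uses externally studentized residuals and Cook's distances
under both weighted fits, computed on the √w-transformed design where
the fits are OLS (for the origin fit the hat value is
h ⱼ = wⱼγ̂ⱼ²/Σwγ̂²; Cook's distance uses the one-parameter formula there
and the two-parameter formula for Egger).  Reference distributions:
two-sided t with L−2 df for studentized residuals in **both** models
(the stated procedure; a conformance flag switches Egger to the
textbook L−3), and the upper tail of F(1, L−1) (IVW) or F(1, L−2)
(Egger) for Cook's distance.  A SNP is influential iff any of the four
p-values < 0.05.  An 8-SE planted outlier is detected essentially always
because it simultaneously inflates every other SNP's studentized
denominator, suppressing false flags.

Heterogeneity of the ratios (horizontal pleiotropy, in MR terms)
reports Cochran's Q with fixed-effect weights, Higgins'
I² = max(0, (Q−df)/Q), and τ² by REML (default) or DerSimonian–Laird;
because random-effects software conventionally prints the τ²-based
I² = τ²/(τ² + s̃²) with s̃² the Higgins–Thompson typical sampling
variance, both I² conventions are reported with the estimator label and
neither is promoted as canonical.

Sample overlap between the two GWAS is probed indirectly: association
Z-statistics are truncated at zero (1 if Z > 0, else 0), and the
tetrachoric correlation of the 2×2 table is estimated by
bivariate-normal maximum likelihood with thresholds fixed at the margin
quantiles and a 0.5 continuity correction on empty cells (a cosine
approximation, cos(π/(1+√OR)), is available for comparison).  Truncation
makes the check robust to the minority of truly associated SNPs; near-
zero correlations argue against material overlap.

## Meta-regression and selection

The additive random-effects model θ̂ⱼ ~ N(xⱼ'β, σⱼ² + τ²) is fitted by
REML (bounded scalar minimization of the restricted likelihood in τ²,
snapping to the 0 boundary when it is at least as good) or by the
moment estimator generalized to moderators, τ² = max(0, (QE−(L−p))/tr P).
Reported: τ² with and without moderators, adjusted
R² = max(0, (τ²₀ − τ²ᵣ)/τ²₀) (floored at 0, as meta-regression software
reports it), residual I², the omnibus Wald moderator test QM (χ², df =
number of moderators) and the fixed-weights residual heterogeneity test
QE (χ², df = L − p).  These match R `metafor`'s `rma()` output, which
serves as an independent oracle in the test suite.

Forward selection adds category indicators one at a time by the largest
residual-τ² reduction; the provisional candidate is retained iff the
Wald test on its coefficient in the incremental model has p < 0.05
(the natural reading of a "reaches P < 5%" retention rule), and
selection stops at the first failure.  Ties break lexicographically;
duplicate candidates are skipped with a warning; no multiplicity
correction is applied across candidates, matching raw-p reporting.
Uncategorized SNPs fall into the non-neuronal pool and are never
excluded by category operations; a SNP belonging to several categories
is excluded whenever any excluded label contains it.

## Synthetic data: what it emulates, what it does not

The generator draws true exposure-effect magnitudes |N(0.0173, 0.0134)|
— calibrated so that with allele frequencies uniform on [0.05, 0.95] and
the large-sample SE models σ_γ = 1/√(2p(1−p)N_exp) and
σ_Γ = √(1/(2p(1−p)))·√(1/N_cases + 1/N_controls), the per-SNP
F-statistics reproduce the GIANT-like profile (mean ≈ 56, median ≈ 35
at N_exp = 322,154) and the rescaled outcome-side strengths land near
the published ≈ 3 (bipolar-size) and ≈ 14 (schizophrenia-size) values.
Effects are drawn on the exposure-increasing allele, as published
instrument sets are coded; this matters because MR-Egger's
directional-pleiotropy model is orientation-relative.  Direct effects
αⱼ are zero (none), zero-mean (balanced), positive-mean independent of
γ (directional under InSIDE), or proportional to γ plus noise
(InSIDE-violating), applied to a configurable fraction of instruments
or confined to a planted category; true Γⱼ = θγⱼ + αⱼ and observed
effects add Gaussian noise at the model SEs.  About 16% of SNPs are
palindromic, and a configurable fraction of outcome rows is
allele-swapped and/or strand-complemented, to exercise the
harmonization paths.  A versioned truth record supports recovery tests.

Not emulated: LD between instruments, winner's-curse in instrument
selection, allele-frequency differences between populations, and
case/control imbalance effects beyond the SE model.  Passing recovery
tests therefore demonstrates estimator correctness under the stated
generative model, not robustness to those real-data features.

## Simulation-study design choices

* Recovery studies use 90 instruments, θ = 0.1 (log-OR ≈ OR 1.11, in
  the range typical of adiposity–psychiatry analyses) and outcome
  samples of 100,000 cases/controls, large enough that the pleiotropy
  signal is identifiable against ratio noise at method-paper scale.
* The directional-InSIDE recovery experiment uses a near-error-free
  exposure GWAS (I²GX ≈ 1) so that MR-Egger's InSIDE consistency is
  isolated from NOME dilution; at realistic exposure error the residual
  Egger bias is exactly the dilution that I²GX predicts and SIMEX
  corrects, and orienting noisy γ̂ of weak instruments additionally
  perturbs the intercept — both are properties of the estimator, not of
  the implementation.
* Invalid-instrument regimes use direct effects of the same order as
  the per-unit exposure effect (α ≈ γ), the standard "strong
  pleiotropy" scenario under which the weighted median's robustness and
  IVW's bias are visible per replicate.
* The SIMEX benefit is demonstrated where its premise holds visibly:
  strong instruments with large artificial exposure error (I²GX ≈ 0.4)
  and small outcome noise, where the attenuation dominates sampling
  variability.

## Degenerate inputs and numerical notes

γ̂ = 0 makes a Wald ratio undefined and is rejected naming the SNP; zero
spread in γ̂ makes the Egger design singular; all-zero σ_γ short-circuits
SIMEX to the naive fit (and I²GX to its no-dilution limit).  Fewer than
3 usable frequency pairs makes the concordance diagnostic unavailable;
a margin entirely on one side of zero makes the tetrachoric correlation
undefined; both are reported as such rather than guessed.  REML uses a
bounded search on [0, 10·max(var(θ̂), max σ²)] with 1e−10 tolerance.
The pipeline derives per-stage seeds from the global seed by
stage-name hashing, so adding a stage never perturbs earlier stages'
draws, and reruns from a manifest are bit-reproducible.

## Known limitations

No mode-based estimators, multivariable or bidirectional MR; no LD-aware
proxy search (a validated proxy map is consumed instead); no
multiple-testing correction across the analysis grid (raw p-values are
reported, and the manifest says so).  Published-table regressions in the
acceptance tests activate only when the per-SNP source tables are
supplied under `data/supplementary/`.
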
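# Methods

`ldsem` re-implements, as a tested pipeline, a two-wave latent difference
score (LDS) structural-equation analysis coupling brain-volume change with
change in three latent cognitive domains, together with a synthetic cohort
generator that reproduces the statistical structure of the cohort study the
analysis design comes from (a single-year-of-birth ageing cohort measured
at mean ages 73 and 76).  The original cohort data are not publicly
deposited, so every stage is validated against synthetic cohorts whose
generating parameters are the study's published estimates.

## The model

Twelve cognitive tests measure three latent domains — fluid intelligence
(4 tests), memory (3), processing speed (5, with the two pencil-and-paper
speed tests cross-loading on fluid intelligence).  A confirmatory factor is
extracted per domain per wave under strong measurement invariance: factor
loadings and indicator intercepts share one parameter across waves, the
first indicator of each factor carries a unit loading, and wave-1 latent
means are fixed at 0.  Each test's residual is allowed to covary with
itself across waves (standard for repeated indicators; a
`correlated_uniqueness=False` switch removes these 12 parameters so the
degrees-of-freedom consequences are auditable).

For every level variable X (a cognitive factor, or a manifest brain
volume) the wave-2 value is decomposed by unit-fixed paths as

    X_w2 = X_w1 + dX,      Var(e_w2) = 0,  intercept(w2) = 0,

so the latent change `dX` *is* the wave-2 minus wave-1 difference with its
own free mean, variance, and covariances — an exact difference, not a
regression residual.  Model A couples the three cognitive domains with
total brain volume (26 observed variables, 4 changes); Model B replaces
total brain volume with grey matter, normal-appearing white matter (NAWM),
and white-matter-hyperintensity (WMH) volumes (30 observed, 6 changes).
All levels and changes are freely intercorrelated; these covariances are
parameterized directly on the **correlation metric** (`S_ij = r ·
sqrt(S_ii S_jj)`), so the reported coupling estimates are standardized by
construction and equality constraints between couplings act on the
standardized scale, which is what the between-path tests require.

Degrees-of-freedom audit: the constructions here have 100 (Model A) and
146 (Model B) free parameters, giving df = 277 and 349 against 377 and
495 observed moments.  The reference analysis reports df = 276 and 348 —
one moment away in both models.  Its exact free-parameter inventory is not
published (plausibly one additional freed parameter, e.g. a relaxed
invariance or residual term); the difference is carried in every report
(`df_audit`) rather than absorbed by ad-hoc freeing.

## Estimation

Models are evaluated in the RAM parameterization
`Sigma = F(I-A)^-1 S (I-A)^-T F^T`, `mu = F(I-A)^-1 m` and estimated by
full-information maximum likelihood (FIML): rows are grouped by
missing-data pattern and each pattern contributes through its sufficient
statistics (count, mean, scatter), so the likelihood cost is independent
of sample size.  Gradients are analytic (matrix calculus through the RAM
map, with chain rules for the correlation-metric entries); optimization is
multi-start L-BFGS (first start deterministic and data-driven, further
starts jittered from a seeded generator, ties broken by likelihood then
gradient norm).  Variances are optimized on the log scale and correlations
through the Fisher transform, which enforces admissibility without
explicit bounds; variances that collapse toward the boundary are flagged
as Heywood cases.  For optimizer conditioning every variable — and both
waves of it, to keep longitudinal comparability a pure units change — is
internally rescaled by its wave-1 SD; all reported quantities are mapped
back to input units (fits are invariant to this, which is tested).

The saturated log-likelihood anchoring the model chi-square comes from the
EM algorithm for the unrestricted multivariate-normal model (closed form
for complete data; iterated to a relative tolerance of 1e-10 otherwise).
The baseline for the incremental fit indices is the independence-with-
means model, whose FIML solution factorizes per variable and is closed
form even under missingness.  Fit indices: `RMSEA =
sqrt(max(T-df,0)/(df·n))`, `CFI = 1 - max(T-df,0)/max(T_b-df_b, T-df, 0)`,
`TLI = (T_b/df_b - T/df)/(T_b/df_b - 1)`.  Standard errors come from the
numerically differentiated observed information (central differences of
the analytic gradient, relative step 1e-4); standardized-solution SEs use
the delta method on the correlation metric.  Robust/sandwich SEs and
weighted-least-squares estimation are out of scope.

Rows missing every model variable are dropped with a logged count and the
remaining n feeds the fit indices.  Nested equality tests refit the
constrained model warm-started from the parent solution and compare
likelihood-ratio chi-squares; a constrained model that "fits better"
beyond numerical tolerance raises instead of returning a negative
statistic.

## Covariate control

Before modeling, every longitudinal variable is residualized on sex and on
age in days at the matching assessment (testing age for cognitive scores,
scan age for volumes), by per-variable OLS on available cases.  The
covariates are **centered before removal, so each variable keeps its
mean**: mean-zero residualization would annihilate the longitudinal
mean-change structure the LDS model estimates, which is exactly the
quantity of interest.  Sex-moderation analyses control for age only.  The
annualized change metrics divide the across-study mean change by 3.0
nominal years and scale by the *raw* wave-1 sample mean/SD — both choices
required to reproduce the published change table, whose per-year column
equals the across-study column divided by 3 even though the mean scan
interval was 3.7 years.  ICV-proportional volumes and log-WMH are config
stubs only (the source analysis reports they did not alter findings).

## The synthetic cohort generator

The generator draws exact multivariate-normal data on the residualized
scale for 7 "core levels" (3 standardized cognitive factors, 4 volumes)
and their 7 latent changes, then maps them through the measurement model
(raw loadings = published standardized loading x published test SD;
residual variances from 1 - communality, rescaled to the published test
SDs; cross-wave residual correlation 0.3 by default) and adds covariate
structure back: additive sex offsets on the volumes (published per-sex
means; on the residualized scale the volume SD is reduced by the
between-sex variance, e.g. total brain 89.4 -> 72.8 cm^3, matching the
published within-sex SDs), and small linear age-in-days trends matched to
the longitudinal rates.  Population moments are available in closed form,
and at the generating point they equal the model-implied moments of
Models A and B exactly — the central oracle link of the test suite.

Change SDs are not published anywhere, and choices here are pinned by what
*is* published:

* **Volumes.** The wave-to-wave stability `s` and the self level-change
  correlation `rho` jointly determine the change SD in level-SD units `u`
  through `corr(X1, X1+D) = (1+rho·u)/sqrt(1+u^2+2·rho·u) = s`, a
  quadratic in `u` with one positive root (total brain 0.26, grey matter
  0.39, NAWM 0.33, WMH 0.38 level-SD units; 19.0/14.1/14.3/4.7 cm^3).
* **Cognitive factors.** `rho` is not published; the change SDs default to
  0.25 / 0.45 / 0.50 (fluid, memory, speed) and the self level-change
  covariance is solved from the published stability (smaller-magnitude
  root).  A change SD of `u` bounds the attainable stability below by
  `sqrt(1-u^2)`, so 0.45/0.50 are the smallest round values compatible
  with the published memory/speed stabilities 0.896/0.867; fluid's 0.25
  sits just above its bound 0.247, making its solved self-coupling mildly
  negative like the others.

Coupling defaults use every value printed in the source's results: the
level-change and change-change correlations of the volumes, the cognitive
change intercorrelation (0.634, applied to all three pairs since only the
mean is printed), the printed cognition-level -> volume-change paths
(family means split as 0.159/0.159 for memory/speed -> total-brain change
and 0.120/0.180/0.210 for fluid/memory/speed -> NAWM change), and the
printed change-change couplings.  Unprinted cross couplings are completed
by a through-the-partner-level rule, `corr(L_i, dX_j) = corr(L_i, L_j) ·
corr(L_j, dX_j)`, and the total-brain entries missing from the
three-tissue model are filled by treating total-brain change as the sum of
the tissue changes.  The resulting 14 x 14 correlation matrix is still
mildly indefinite — the published values come from two separately fitted
models plus rounded tables — so an eigenvalue-floor nearest-PD repair is
always applied (eigenvalue shift ~0.06 at defaults).  The repair moves the
printed coupling entries by < 0.002 and preserves the published
stabilities to four decimals; a warning fires only when user edits push
the repair beyond that regime.

Attrition masks wave-2 entries: dropout is a logistic function of the
wave-1 cognitive composite (a factor-score proxy; slope 0.7 under MAR,
0 under MCAR) with the intercept solved so the expected dropout hits the
targets (19.5% cognitive, 34.2% imaging, imaging a superset of cognitive).
Exclusion flags: MMSE scores are built from the per-wave cognitive
composite with noise, shifted so a configurable fraction (default 16/697)
falls below the conventional cutoff of 24 after integer rounding and
floor/ceiling at 0/30; dementia flags (default 25/697) land on the lowest
noisy-composite subjects.  Each operation uses its own seeded substream —
reusing one raw seed across operations would replay the uniforms that
assigned sex.

What the generator does **not** emulate: practice effects, skewed test
score distributions (a moment-matched lognormal WMH marginal is optional),
item-level MMSE structure, sex differences in covariances (only mean
offsets, plus an explicit `sex_coupling_shift` hook), and the direction of
raw mean change in the two reaction-time indicators (they are generated
with the published positive loadings, as if pre-reflected).  Passing tests
therefore show that the pipeline recovers the published structure under
correct specification and MAR missingness, not that it is robust to
real-data pathologies outside that structure.

## Pipeline and reports

`run_analysis` chains exclusion rules -> residualization -> model fit ->
three correlation families (level-level, level-change, change-change) with
raw and Benjamini-Hochberg-adjusted p-values pooled per model across the
three families -> annualized change table -> fit summary and df audit.
Significance stars follow raw p (0.05/0.01/0.001) with the adjusted value
in an adjacent column, matching the dual reporting of the source analysis.
Equality tests auto-select within-family pairs sharing a change variable
where at least one path is significant.  Sex moderation regresses the
outcome change score (Bartlett factor scores for latent domains, observed
differences for volumes) on predictor, sex, and predictor x sex; this
factor-score product regression replaces latent-interaction machinery and
attenuates the latent interaction by roughly the factor-score reliability
(~0.6-0.8 for these domains), which the recovery test's acceptance band
reflects.

## Validation sizes and numerical choices

Recovery runs use one simulated cohort of n = 20,000 complete cases
(sampling SE of the least-reliable recovered coupling, WMH-change with
speed-change, ~0.012) fitted with two optimizer starts; the type-I
calibration uses a reduced difference score model (memory domain + WMH,
zero-coupling generator) with 60 replicates of n = 1,000 pooling three
null couplings per replicate (~5% expected raw rejections, binomial band
1-10%); the full-model recovery experiment script uses 25 replicates of
n = 1,000.  Convergence requires the relative gradient infinity-norm below
1e-5; non-convergent fits are flagged, never silently reported.  EM stops
at a relative log-likelihood change of 1e-10.  The correlation-metric
Fisher transform caps |r| at tanh(6) ~ 0.99999; ties between restarts are
broken by log-likelihood rounded to 1e-6, then gradient norm.

## Known limitations

* The df = 276/348 inventory question above; our models are one parameter
  richer than the reference in both cases.
* BH adjustment is not idempotent (re-adjusting adjusted values can change
  them); the FDR tests assert the procedure's true guarantees instead.
* Two cells of the published annualized-change table are internally
  inconsistent with their own printed inputs at the last digit (its NAWM
  SD-per-year and WMH percent-per-year); the reproduction tolerances allow
  one unit in the last printed digit there.
* Couplings involving the small-variance fluid change are weakly
  identified at realistic n; their single-cohort estimates can move by
  +/- 0.05 at n = 20,000, which is sampling noise (model-based SEs agree
  with the empirical scatter), not bias.
* Sandwich SEs, robust chi-squares, ordinal indicators, >2 waves, and
  image-derived volumetry are out of scope.
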
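# Methods

`hibernage` reimplements, as a tested pipeline, an analysis of epigenetic
ageing in a hibernating mammal: free-living female yellow-bellied marmots
(*Marmota flaviventer*) blood-sampled only during their active season,
whose methylation-based ("epigenetic") age is asked two questions — does
it track chronological age, and does it stall during hibernation?

## Time conventions

All dates live on a 365-day **study year** starting 1 May (day 1) and
ending 30 April (day 365), chosen so that a single hibernation
(16 September – 17 April, study days 139–352) sits inside one cycle. The
active season (18 April – 15 September, days 353–365 and 1–138) therefore
*straddles* the year boundary: one summer consists of the last days of one
study year plus the first 138 days of the next. Longitudinal operations
that need "the same summer" (the consecutive-year rate contrast) index
samples by summer: a late-April sample (day ≥ 353) belongs to the
following summer. Leap days are rejected at ingest; every periodic model
term uses a 365-day cycle. Supplementary-style tables whose `Trap_jday`
column is a 1-January-origin Julian day are converted at ingest
(`--doy-origin {jan1,may1}`); all downstream code sees study days only.

## Epigenetic age estimators

**Epigenetic clock (EC).** Elastic-net regression of chronological age on
CpG beta values (mixing weight α = 0.5; penalty λ chosen at minimum mean
10-fold cross-validated squared error; predictors standardized before
penalization, coefficients reported on the beta scale). Out-of-sample
accuracy uses grouped hold-out: one seeded shuffle, contiguous groups of
~14 samples, each predicted by a model trained without them (11 models on
a 149-sample table). Metrics: Pearson r, median absolute error, median
relative absolute error (denominator = observed age; zero-age samples
excluded — the youngest animals are weeks old, so this never triggers on
study-like data). The underlying solver is scikit-learn's coordinate
descent.

**Epigenetic pacemaker (EPM).** Each candidate site's beta is modeled as
`rate_i * s_j + offset_i` with a per-sample latent state `s_j`. Candidate
sites are those with |Pearson r| > 0.7 between beta and age. Fitting
alternates exact conditional minimizations (per-site OLS given states;
closed-form state update given sites), so the residual sum of squares is
non-increasing; iteration stops at a relative RSS change below 1e-6 (cap
1000). States are initialized at chronological ages, which fixes the
affine gauge the model is otherwise only identified up to; tests compare
states after affine alignment. Cross-validation (10-fold) re-selects
sites inside each training fold by default (no leakage; switchable,
since the original analysis does not state which was done).

## The GAMM engine

The seasonal analysis needs Gaussian additive mixed models with a cubic
regression spline of age, a cyclic cubic spline of day-of-year, optionally
their tensor-product interaction, and an animal random intercept. No
installed Python package provides this combination, so the engine is
implemented here from standard components:

* **Bases.** Cardinal (value-at-knot) cubic regression splines with
  natural boundaries, knots at data quantiles; the penalty is the exact
  integrated squared second derivative (`D' B^{-1} D` in the usual
  tridiagonal construction), null space = {constant, linear}. The cyclic
  variant identifies the last knot with the first and matches value and
  two derivatives across the period boundary (uniform knots over one
  365-day period), null space = {constant}. Both are verified in the test
  suite against `scipy` natural/periodic interpolators and numerical
  integration of the penalty.
* **Mixed model as penalized regression.** The random intercept is a
  block of indicator columns with a ridge penalty; its implied variance is
  `σ²_resid / λ_re`. Smooths are centered (sum-to-zero over the data) so
  the intercept is identifiable. Tensor interactions are row-wise products
  of the centered marginal bases with one penalty per margin
  (interaction-only, mirroring `ti()` terms).
* **Smoothing selection.** Nelder–Mead on log-smoothing-parameters of an
  integrated (restricted) marginal likelihood with the scale profiled out
  (REML flavor, the default), or of a true marginal ML in which penalty
  null-space directions are treated as fixed effects. Three jittered
  restarts before a fit is flagged non-convergent; a flagged fit is
  returned, never silently dropped.
* **Model selection.** The eight candidate fixed-effect structures
  (linear/spline/cyclic combinations up to the tensor interaction, all
  with the animal intercept) are ranked by **marginal ML AIC** (parameter
  count = fixed effects + smoothing/variance parameters + scale), the
  criterion a mixed-model representation of these GAMMs naturally yields.
  An e.d.f.-based conditional AIC is also reported per fit but is not
  used for ranking: in our experiments it systematically over-selected
  the tensor-interaction model on additive truth. A winner is declared
  only at ΔAIC > 2 over the runner-up.
* **Term tests.** Smooths with a penalty null space use the
  fractional-rank pseudo-inverse Wald statistic on the term's fitted
  values with a chi-square-mixture reference (reference d.f. = the upper
  e.d.f. 2tr(F) − tr(FF)). Fully penalized terms — the centered cyclic
  spline, tensor interactions, the random intercept — use the
  random-effect-style test: whiten by the marginal covariance of the
  other random effects, absorb the remaining penalties by QR, and refer
  `||R_m b_m||²/σ²` to its exact weighted-chi-square law (Imhof's
  integral), with an F-type correction for the estimated scale. The test
  suite cross-checks a full fit against `mgcv` via `Rscript` on identical
  data; in development the per-replicate seasonal p-values agreed with
  mgcv's to a median difference of ~0.001.

## Seasonal inference

Three checks that a seasonal signal is real rather than a sampling
artifact, all fitting the selected structure (age spline + cyclic
day-of-year spline + animal intercept) and reading the cyclic term's p:

1. **Power simulation** — per replicate, simulate a trait that accumulates
   only on active days; the rejection proportion at α = 0.05 is the power.
2. **Null simulation** — a strictly linear-in-age trait; the rejection
   proportion is the type-I error, and the empirical 0.05 quantile of the
   null p-values is an adjusted critical value.
3. **Permutation null** — refit the observed states with day-of-year
   shuffled across samples.

Non-convergent replicates are counted and excluded from denominators.
Model selection is *not* re-run per replicate (the selected structure is
fixed first, matching how the original analysis carried one model into
its simulations).

**Rate contrast.** Individuals trapped in two consecutive summers with
≥ 2 samples in one and ≥ 1 in the other contribute one active rate
(state change per day within the ≥2-sample summer) and one hibernation
rate (state change per day from the last sample before the intervening
winter to the first after it). The two rate groups are compared with a
tie-corrected Kruskal–Wallis test (complete ties defined as H = 0, the
no-separation limit). Study years are recovered from ages and day-of-year
when no explicit year column is present (the within-animal birth phase is
over-determined, so the median estimate is robust).

## Per-site scans

EWAS of age: per-site linear mixed model (animal random intercept,
`statsmodels` MixedLM; Wald normal-approximation p for the slope; the
animal variance frequently sits on the zero boundary, in which case the
fit falls back through optimizers to the boundary model, plain OLS).
GAM scan: per-site age spline + cyclic day-of-year spline *without* the
random intercept. Multiplicity: fixed threshold 1e-5 (the compromise used
for this ~31k-site array), Bonferroni α/m, and Benjamini–Hochberg
step-up; a three-set Venn summary of EWAS/GAM-age/GAM-season hits.

## The synthetic-data generator

The deposited methylation data are not shipped; everything is testable
against a generator that emulates the study design:

* **Design** (defaults): 73 females, 149 samples (1–8 per animal), ages
  0.01–12.04 years, sampling restricted to study days 362–365 and 1–112
  (27 April – 20 August), and exactly 11 individuals with the 2+1
  consecutive-summer pattern (designated animals get two samples in one
  summer and the rest in the next; other multi-sample animals are trapped
  once per summer, which never satisfies the eligibility rule). Birth
  dates fall in an early-summer natal window, ages are exactly consistent
  with one birth date per animal, and the observed age range is anchored
  at two single-sample animals. Sample days are uniform within the
  window; the real trapping schedule (biweekly effort, unequal seasonal
  coverage) is *not* reproduced, and quantities that depend on the exact
  layout of repeated samples — notably simulation power — inherit that
  difference (see Limitations).
* **Traits**: flat (0.004 state-units/day from birth, every day) and
  seasonal (active-season accumulation only; default daily rate
  0.004·365/150 ≈ 0.00973 so the two traits gain the same amount per
  year; the alternative printed parameterization 0.0164, and the literal
  formula value 0.00164, are both selectable — the source's stated rate
  and stated formula disagree, so no single value can be assumed).
  Animal-level intercepts (variance 0.329) and residuals (variance 0.294)
  use the study's fitted variance components. The active window realized
  as days 353–365 ∪ 1–138 spans 151 days although the season is nominally
  "150 days"; the printed day numbers are treated as operative.
* **Betas**: `clip(rate·x + offset + N(0, noise_sd), 0, 1)` per site,
  where x is the latent state (300 sites by default), chronological age
  itself (100 sites), or nothing (noise sites). Offsets are drawn so the
  noiseless line stays inside [0.02, 0.98] over the observed range, so
  clipping never distorts the linear model. The chronological-age site
  class exists because a methylome carrying *only* the seasonal latent
  state would make it impossible for an age-trained elastic-net clock to
  wash seasonality out — the attenuation actually observed in real
  clocks; with both site classes present the pacemaker (which models all
  age-correlated sites) retains the seasonal signal while the clock
  suppresses it, reproducing the study's qualitative EC/EPM contrast.

All generator output is reproducible bit-for-bit from (config, seed).

## Problem sizes and numerical choices

Default simulations use 1000 replicates per scenario (the acceptance
script's default; tests use 250–500 with binomially widened tolerances).
One GAMM fit on the 149-sample design takes ~80 ms, so a four-scenario
acceptance run is a few minutes on one CPU. Smoothing parameters are
clipped to e^±25; the final normal-equations solve retries with an
escalating ridge jitter if a Cholesky fails at extreme smoothing. The
Kruskal–Wallis p uses the chi-square reference (a tail approximation:
for groups of ≤ 6 it matches the exact permutation p within the
permutation resolution in the tail, and is only order-consistent
mid-range — the tests encode exactly that).

## Limitations

* Real array features — batch effects, probe-level artifacts,
  SNP-confounded probes, normalization residue — are not simulated, so
  green tests say nothing about robustness to them.
* Simulation **power** is a property of the sampling layout. On this
  generator the seasonal test reaches ~90–97% power at the
  annual-matched rate and ~100% at the 0.0164 parameterization, with
  type-I error ~5.7–6.2%, null 0.05-quantile ~0.037–0.040 and permutation
  rejection ~6–7%: the null behavior of the original analysis is
  reproduced closely, while power is higher than the original ~76%
  because the synthetic layout of repeated within-season samples is more
  informative than the real trapping schedule.
* The smooth-term p-values follow published test constructions but are
  approximations; small samples (n ≲ 50) show mild anti-conservatism,
  quantified in the tests.
* Per-site GAM scans refit every site independently; no sharing of
  smoothing parameters across sites is attempted.
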
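# hibernage

Epigenetic ageing in hibernators: does biological ageing stall during
hibernation?

`hibernage` is a tested reimplementation of the analysis behind that
question for a wild population of yellow-bellied marmots — ~150 blood
samples collected across the lives of ~73 known-age females, methylation
profiled on a mammalian CpG array, with sampling possible only during the
active season. It is aimed at ecologists and methylation researchers who
want to run, audit, or adapt the full pipeline:

* **Epigenetic clock (EC)** — elastic-net regression of chronological age
  on CpG beta values (α = 0.5, λ at minimum cross-validated error),
  with grouped hold-out prediction (~14 samples per fold) and accuracy
  metrics (r, median absolute and relative error).
* **Epigenetic pacemaker (EPM)** — each age-correlated site (|r| > 0.7) is
  modeled as `β_ij = rate_i · s_j + offset_i`; the latent per-sample
  epigenetic states `s_j` and site parameters are fitted jointly by
  conditional expectation maximization (alternating least squares), with
  10-fold cross-validated state estimates.
* **GAMM engine** — Gaussian additive mixed models with a cubic regression
  spline of age, a cyclic cubic spline of day-of-year (period 365,
  study year starting 1 May so one hibernation sits inside one cycle),
  optional tensor-product interaction, and an animal random intercept:

  `state ~ s(age) + cc(doy) + (1 | animal)`

  Smoothing by restricted marginal likelihood; eight candidate
  fixed-effect structures ranked by marginal ML AIC; smooth-term tests
  following the constructions used by mgcv (cross-checked against mgcv in
  the test suite).
* **Seasonal inference** — simulation-based power and type-I error for the
  seasonal term (traits that accumulate only in the active season versus
  strictly linear-in-age traits, on the observed sampling design),
  permutation nulls with adjusted critical values, and the direct
  contrast of active-season versus trans-hibernation epigenetic-ageing
  rates in individuals trapped in consecutive summers (Kruskal–Wallis).
* **Per-site scans** — mixed-model EWAS of age and per-site GAMs with age
  and cyclic seasonal smooths, with fixed/Bonferroni/Benjamini–Hochberg
  multiplicity summaries and Venn overlaps.
* **Synthetic data** — a first-class generator reproducing the study's
  sampling structure (73 females, 149 samples, 1–8 each, ages 0.01–12.04,
  sampling days 362–365 and 1–112, 11 consecutive-summer individuals),
  the two simulation traits, and beta matrices from the pacemaker's
  generative model, so the whole pipeline is testable without the
  deposited array data.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from hibernage import *
from hibernage.season_inference import seasonal_model_terms

design = generate_design(DesignConfig(seed=0))
print(f"{len(design)} samples from {design.n_animals} females, "
      f"ages {design.ages.min():.2f}-{design.ages.max():.2f} years")

states = simulate_trait(design, TraitConfig(seed=42), seasonal=True)
betas = simulate_beta_matrix(design, states, SiteConfig(noise_sd=0.02, seed=7))
sites = select_age_sites(betas, design.ages, threshold=0.7)
print(f"{len(sites)} of {betas.n_sites} sites have |r| > 0.7 with age")

epm_states, _ = cross_validate_epm(betas, design.ages, k=10, seed=1)
m = accuracy_metrics(epm_states, design.ages)
print(f"pacemaker: r = {m['pearson_r']:.2f}, "
      f"median abs error = {m['median_abs_error']:.2f} years")

fit = fit_gamm(epm_states, design, seasonal_model_terms(), "animal_id")
cc = fit.term_tests["cc(doy)"]
print(f"seasonal term: edf = {cc['edf']:.2f}, p = {cc['p']:.4g}")

table = design.with_column("epigenetic_state", epm_states)
rates = consecutive_year_rates(table)
kw = kruskal_wallis(rates["active_rate"], rates["hibernation_rate"])
print(f"{len(rates)} individuals in consecutive summers: "
      f"active vs hibernation rate H = {kw['H']:.2f}, p = {kw['p']:.3f}")
```

prints

```
149 samples from 73 females, ages 0.01-12.04 years
393 of 500 sites have |r| > 0.7 with age
pacemaker: r = 0.99, median abs error = 0.29 years
seasonal term: edf = 1.73, p = 6.591e-05
11 individuals in consecutive summers: active vs hibernation rate H = 0.48, p = 0.491
```

Reading it: the generator reproduces the study design; cross-validated
pacemaker states track chronological age to ~0.3 years; the cyclic
day-of-year term in the mixed GAMM detects the simulated hibernation
stall decisively (p ≈ 7e-5). The 11-individual rate contrast is the
blunter instrument — per-day rates over short within-season spans are
noisy, so on this realization the Kruskal–Wallis test is not significant
even though the seasonal effect is real (at lower residual noise it is;
the GAMM pools all 149 samples and retains far more power).

## Command line

```bash
hibernage synth design --seed 1 --out design.csv
hibernage synth trait --design design.csv --seasonal --out trait.csv
hibernage synth betas --design trait.csv --out betas.csv
hibernage epm fit --betas betas.csv --table design.csv --out epm.json
hibernage gamm fit --table table.csv \
    --formula "epigenetic_state ~ s(age,k=10) + cc(doy,k=10) + (1|animal_id)" \
    --out gamm.json
hibernage season rates --table table.csv --out rates.csv
hibernage run --config run.json --out run_dir/
```

`hibernage run` wires ingest → EPM/EC → GAMM selection → seasonal tests →
per-site scan, writing per-stage artifacts stamped with the config hash
and seeds. A sample table that already carries `Epigenetic_state` /
`EC_predicted` columns (the supplementary-table dialect is accepted
verbatim, with `Trap_jday` converted from either day-of-year origin) runs
the downstream stages without a beta matrix.

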
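"""GAMM engine: centering, e.d.f. behavior, term tests, selection, and an
independent cross-check against mgcv."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats as sps

from hibernage.gamm_engine import (
    CompiledGamm,
    InteractionTerm,
    LinearTerm,
    SmoothTerm,
    TensorTerm,
    candidate_models,
    fit_gamm,
    parse_formula,
    select_model,
    smooth_term_test,
)
from hibernage.season_inference import seasonal_model_terms
from hibernage.synthetic_data import TraitConfig, simulate_trait


def test_smooth_contributions_are_centered(design_small):
    y = simulate_trait(design_small, TraitConfig(seed=1), seasonal=True)
    fit = fit_gamm(y, design_small, seasonal_model_terms(), "animal_id")
    df = design_small.df
    for term, var in (("s(age)", "age"), ("cc(doy)", "doy")):
        contrib = fit.term_effect(term, **{var: df[var].to_numpy(float)})
        assert abs(contrib.sum()) < 1e-6 * len(df) * max(1.0, np.abs(y).max())


def test_linear_truth_gives_unit_edf_and_null_seasonal_p(design_default):
    compiled = CompiledGamm(design_default, seasonal_model_terms(), "animal_id")
    pvals, edfs = [], []
    warm = None
    for i in range(40):
        y = simulate_trait(design_default, TraitConfig(seed=900 + i), seasonal=False)
        f = compiled.fit(y, rho0=warm)
        warm = f.rho
        pvals.append(f.term_tests["cc(doy)"]["p"])
        edfs.append(f.edf["s(age)"])
    assert np.median(edfs) <= 1.2  # age effect is truly linear
    # seasonal p approximately uniform under the null
    assert sps.kstest(pvals, "uniform").pvalue > 0.005


def test_injected_seasonal_signal_detected(design_small):
    y = simulate_trait(design_small, TraitConfig(seed=5, var_residual=0.02), seasonal=True)
    fit = fit_gamm(y, design_small, seasonal_model_terms(), "animal_id")
    assert fit.term_tests["cc(doy)"]["p"] < 1e-4


def test_deterministic_seasonal_signal_without_noise(design_small):
    doy = design_small.doys.astype(float)
    y = 0.5 * design_small.ages + np.sin(2 * np.pi * doy / 365)
    fit = fit_gamm(y, design_small, seasonal_model_terms(), None)
    assert fit.term_tests["cc(doy)"]["p"] < 1e-12


def test_fitted_cyclic_term_is_periodic(design_small):
    y = simulate_trait(design_small, TraitConfig(seed=6), seasonal=True)
    fit = fit_gamm(y, design_small, seasonal_model_terms(), "animal_id")
    lo = fit.term_effect("cc(doy)", doy=np.array([1.0]))
    hi = fit.term_effect("cc(doy)", doy=np.array([366.0]))
    assert abs(lo - hi)[0] < 1e-8


def test_edf_limits_under_extreme_smoothing():
    # covariates spanning the full year so every basis column has support
    import pandas as pd
    from hibernage.core_io import SampleTable

    rng = np.random.default_rng(0)
    n = 120
    table = SampleTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "animal_id": [f"a{i % 20}" for i in range(n)],
        "age": np.sort(rng.uniform(0.1, 12, n)),
        "doy": rng.permutation(np.linspace(1, 365, n).astype(int)),
    }))
    compiled = CompiledGamm(table, seasonal_model_terms(), None)
    y = 0.3 * table.ages + np.sin(2 * np.pi * table.doys / 365) + rng.normal(0, 0.2, n)
    heavy = compiled.fit_at(y, np.array([20.0, 20.0]))
    # as lambda -> inf, edf -> penalty null-space dimension
    assert heavy.edf["s(age)"] == pytest.approx(1.0, abs=0.05)
    assert heavy.edf["cc(doy)"] == pytest.approx(0.0, abs=0.05)
    light = compiled.fit_at(y, np.array([-20.0, -20.0]))
    # as lambda -> 0, edf -> basis dimension (k-1 centered, k-2 cyclic)
    assert light.edf["s(age)"] == pytest.approx(9.0, abs=0.1)
    assert light.edf["cc(doy)"] == pytest.approx(8.0, abs=0.1)


def test_intercept_estimates_response_mean(design_small):
    y = simulate_trait(design_small, TraitConfig(seed=8), seasonal=True)
    fit = fit_gamm(y, design_small, seasonal_model_terms(), "animal_id")
    assert fit.intercept == pytest.approx(float(y.mean()), abs=0.4)
    assert fit.var_individual is not None and fit.var_individual >= 0
    assert fit.var_residual > 0 and np.isfinite(fit.aic)


def test_variance_components_near_truth(design_default):
    # truth: var_individual 0.329, var_residual 0.294 (study-scale design)
    ests = []
    compiled = CompiledGamm(design_default, seasonal_model_terms(), "animal_id")
    for i in range(5):
        y = simulate_trait(design_default, TraitConfig(seed=50 + i), seasonal=False)
        f = compiled.fit(y)
        ests.append((f.var_individual, f.var_residual))
    vi, vr = np.mean(ests, axis=0)
    assert vi == pytest.approx(0.329, abs=0.15)
    assert vr == pytest.approx(0.294, abs=0.12)


def test_tensor_interaction_shrinks_on_additive_truth(design_default):
    terms = seasonal_model_terms() + [
        TensorTerm(SmoothTerm("age", "cubic_spline", 6),
                   SmoothTerm("doy", "cyclic_cubic_spline", 6)),
    ]
    y = simulate_trait(design_default, TraitConfig(seed=9), seasonal=True)
    fit = fit_gamm(y, design_default, terms, "animal_id")
    name = "ti(age,doy)"
    assert fit.edf[name] < 1.5  # near its null space (0) on additive truth
    grid_a = np.linspace(1, 10, 7)
    grid_d = np.linspace(5, 100, 7)
    contrib = fit.term_effect(name, age=grid_a, doy=grid_d)
    assert np.max(np.abs(contrib)) < 0.5


def test_smooth_term_test_accessor(design_small):
    y = simulate_trait(design_small, TraitConfig(seed=10), seasonal=True)
    fit = fit_gamm(y, design_small, seasonal_model_terms(), "animal_id")
    res = smooth_term_test(fit, "cc(doy)")
    assert set(res) == {"edf", "ref_df", "F", "p"} and 0 <= res["p"] <= 1
    with pytest.raises(KeyError):
        smooth_term_test(fit, "nope")


def test_selection_is_deterministic_and_recovers_structure(design_small):
    y_seas = simulate_trait(design_small, TraitConfig(seed=11), seasonal=True)
    sel1 = select_model(y_seas, design_small)
    sel2 = select_model(y_seas, design_small)
    assert [r[0] for r in sel1["ranking"]] == [r[0] for r in sel2["ranking"]]
    assert len(sel1["ranking"]) == 8


def test_selection_prefers_cyclic_for_seasonal_not_for_flat(design_default):
    seas_wins, flat_prefers_cc = 0, 0
    for i in range(4):
        y = simulate_trait(design_default, TraitConfig(seed=700 + i), seasonal=True)
        top = select_model(y, design_default)["ranking"][0][0]
        seas_wins += "cc(doy)" in top
        y0 = simulate_trait(design_default, TraitConfig(seed=800 + i), seasonal=False)
        sel0 = select_model(y0, design_default)
        # flat truth: no cyclic-doy model should be a confident winner
        flat_prefers_cc += sel0["best"] is not None and "cc(doy)" in sel0["best"]
    assert seas_wins >= 3
    assert flat_prefers_cc <= 1


def test_candidate_set_has_the_eight_structures():
    cands = candidate_models()
    assert len(cands) == 8
    assert any(
        any(isinstance(t, TensorTerm) for t in terms) for terms in cands.values()
    )


def test_formula_parser():
    resp, terms, rand = parse_formula(
        "state ~ s(age,k=8) + cc(doy,k=10,period=365) + weight + (1|animal_id)"
    )
    assert resp == "state" and rand == "animal_id"
    assert isinstance(terms[0], SmoothTerm) and terms[0].k == 8
    assert terms[1].basis == "cyclic_cubic_spline" and terms[1].period == 365
    assert isinstance(terms[2], LinearTerm) and terms[2].var == "weight"
    _, terms2, _ = parse_formula("y ~ age + doy + age:doy")
    assert isinstance(terms2[2], InteractionTerm)


def test_agreement_with_mgcv_oracle(design_small, tmp_path):
    """Same data, same model: seasonal-term p and e.d.f. must match mgcv."""
    y = simulate_trait(design_small, TraitConfig(seed=12), seasonal=True)
    df = design_small.df.assign(y=y)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(textwrap.dedent(f"""
        library(mgcv)
        d <- read.csv("{csv}")
        d$animal_id <- factor(d$animal_id)
        m <- gam(y ~ s(age, bs="cr", k=10) + s(doy, bs="cc", k=10)
                   + s(animal_id, bs="re"),
                 data=d, method="REML",
                 knots=list(doy=seq(1, 366, length.out=10)))
        s <- summary(m)$s.table
        cat(s["s(doy)", "p-value"], s["s(doy)", "edf"],
            s["s(age)", "edf"], "\\n")
    """))
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    p_mgcv, edf_doy, edf_age = map(float, out.stdout.split()[-3:])
    fit = fit_gamm(y, design_small, seasonal_model_terms(), "animal_id")
    p_mine = fit.term_tests["cc(doy)"]["p"]
    assert np.log10(p_mine + 1e-12) == pytest.approx(np.log10(p_mgcv + 1e-12), abs=0.5)
    assert fit.edf["cc(doy)"] == pytest.approx(edf_doy, abs=0.35)
    assert fit.edf["s(age)"] == pytest.approx(edf_age, abs=0.35)
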
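"""Pacemaker: site selection, alternating-least-squares fit, prediction, CV."""

import numpy as np
import pytest
from scipy import optimize

from hibernage.core_io import MethylationMatrix, ValidationError
from hibernage.pacemaker import (
    DegenerateModelError,
    cross_validate_epm,
    fit_epm,
    predict_states,
    select_age_sites,
)
from hibernage.synthetic_data import SiteConfig, TraitConfig, simulate_beta_matrix, simulate_trait


def _matrix(beta, prefix="cg"):
    beta = np.asarray(beta, dtype=float)
    return MethylationMatrix(
        [f"{prefix}{i}" for i in range(beta.shape[0])],
        [f"s{j}" for j in range(beta.shape[1])],
        beta,
    )


def test_exact_linear_site_recovered_in_one_round():
    ages = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
    m = _matrix([0.1 * ages])
    fit = fit_epm(m, ages)
    assert fit.converged and fit.n_iter <= 2
    assert fit.rate[0] == pytest.approx(0.1)
    assert fit.offset[0] == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.states, ages, atol=1e-10)
    assert fit.rss == pytest.approx(0.0, abs=1e-20)


def test_rss_matches_direct_numerical_minimization():
    rng = np.random.default_rng(1)
    ages = np.array([0.5, 1, 2, 3, 4, 6, 8, 10], dtype=float)
    true_rates = np.array([0.04, -0.03, 0.02])
    true_off = np.array([0.3, 0.7, 0.5])
    beta = np.clip(np.outer(true_rates, ages) + true_off[:, None]
                   + rng.normal(0, 0.01, (3, 8)), 0, 1)
    m = _matrix(beta)
    fit = fit_epm(m, ages, tol=1e-12, max_iter=5000)
    assert np.all(np.diff(fit.rss_trajectory) <= 1e-12)

    def rss_of(theta):
        r, o, s = theta[:3], theta[3:6], theta[6:]
        return ((beta - np.outer(r, s) - o[:, None]) ** 2).sum()

    x0 = np.concatenate([np.full(3, 0.01), beta.mean(axis=1), ages])
    oracle = optimize.minimize(rss_of, x0, method="L-BFGS-B",
                               options={"maxiter": 20000, "ftol": 1e-15})
    assert fit.rss == pytest.approx(oracle.fun, rel=1e-4, abs=1e-9)
    # age-anchored initial model has RSS no better than the converged fit
    init_rss = rss_of(np.concatenate([fit.rate, fit.offset, ages]))
    assert fit.rss <= init_rss + 1e-12


def test_duplicated_site_leaves_states_unchanged():
    ages = np.linspace(0.5, 8, 10)
    rng = np.random.default_rng(2)
    row = np.clip(0.05 * ages + 0.2 + rng.normal(0, 0.01, 10), 0, 1)
    single = fit_epm(_matrix([row]), ages)
    doubled = fit_epm(_matrix([row, row]), ages)
    np.testing.assert_allclose(doubled.states, single.states, atol=1e-8)


def test_predict_states_idempotent_and_exact_inversion():
    ages = np.linspace(1, 10, 12)
    rng = np.random.default_rng(3)
    beta = np.clip(
        np.outer([0.03, -0.02, 0.04], ages) + np.array([0.4, 0.7, 0.2])[:, None]
        + rng.normal(0, 0.005, (3, 12)), 0, 1,
    )
    m = _matrix(beta)
    fit = fit_epm(m, ages)
    np.testing.assert_allclose(predict_states(fit, m), fit.states, atol=1e-10)
    # a sample constructed exactly on the fitted lines at state 5 inverts to 5
    new = MethylationMatrix(m.site_ids, ["new"], (fit.rate * 5 + fit.offset)[:, None])
    assert predict_states(fit, new)[0] == pytest.approx(5.0)


def test_predict_missing_sites_listed():
    ages = np.linspace(1, 5, 5)
    fit = fit_epm(_matrix([0.1 * ages, 0.05 * ages + 0.1]), ages)
    other = _matrix([[0.1] * 5], prefix="zz")
    with pytest.raises(ValidationError, match="cg"):
        predict_states(fit, other)


def test_degenerate_all_flat_sites():
    ages = np.linspace(1, 5, 6)
    with pytest.raises(DegenerateModelError):
        fit_epm(_matrix([np.full(6, 0.3), np.full(6, 0.6)]), ages)


def test_select_age_sites_brute_force_recount():
    rng = np.random.default_rng(4)
    ages = rng.uniform(0, 12, 30)
    beta = np.clip(
        rng.uniform(-0.03, 0.03, 50)[:, None] * ages
        + rng.uniform(0.2, 0.7, 50)[:, None]
        + rng.normal(0, 0.05, (50, 30)), 0, 1,
    )
    beta[7] = 0.5  # zero variance: correlation undefined, never selected
    m = _matrix(beta)
    got = set(select_age_sites(m, ages, 0.7))
    expected = set()
    for i in range(50):
        if beta[i].std() == 0:
            continue
        if abs(np.corrcoef(beta[i], ages)[0, 1]) > 0.7:
            expected.add(m.site_ids[i])
    assert got == expected
    assert "cg7" not in got
    # a site identical to age has r = 1 and is always selected
    m2 = _matrix(np.vstack([beta, np.clip(ages / 20, 0, 1)]))
    assert m2.site_ids[-1] in select_age_sites(m2, ages, 0.7)


def test_select_all_constant_warns_returns_empty():
    m = _matrix(np.full((3, 5), 0.4))
    with pytest.warns(UserWarning, match="zero variance"):
        assert select_age_sites(m, np.arange(5.0), 0.7) == []


def test_state_recovery_on_generative_model(design_default):
    """Correlation >= 0.99 between recovered and generating states at
    noise 0.02, 300 age sites, study-scale sample count."""
    states = simulate_trait(design_default, TraitConfig(seed=5), seasonal=True)
    m = simulate_beta_matrix(
        design_default, states,
        SiteConfig(n_sites=300, n_age_sites=300, n_chron_sites=0, noise_sd=0.02, seed=6),
    )
    sites = select_age_sites(m, design_default.ages, 0.7)
    fit = fit_epm(m.subset_sites(sites), design_default.ages)
    assert np.all(np.diff(fit.rss_trajectory) <= 1e-9)
    assert np.corrcoef(fit.states, states)[0, 1] >= 0.99


def test_nonlinear_age_pattern_is_preserved():
    """With states logarithmic in age, fitted state-vs-age is concave."""
    rng = np.random.default_rng(9)
    ages = np.sort(rng.uniform(0.1, 12, 120))
    states = np.log1p(ages) * 4
    beta = np.clip(
        rng.uniform(0.01, 0.04, 200)[:, None] * np.where(
            rng.random(200)[:, None] < 0.5, 1, -1) * states
        + rng.uniform(0.35, 0.65, 200)[:, None] + rng.normal(0, 0.01, (200, 120)),
        0, 1,
    )
    mm = _matrix(beta)
    sites = select_age_sites(mm, ages, 0.7)
    fit = fit_epm(mm.subset_sites(sites), ages)
    # bin-averaged state-vs-age curve must decelerate: consecutive
    # chord slopes non-increasing (concavity of the smoothed fit)
    qs = np.quantile(ages, np.linspace(0, 1, 9))
    idx = np.clip(np.searchsorted(qs, ages, side="right") - 1, 0, 7)
    centers = np.array([ages[idx == b].mean() for b in range(8)])
    means = np.array([fit.states[idx == b].mean() for b in range(8)])
    slopes = np.diff(means) / np.diff(centers)
    assert np.all(np.diff(slopes) <= 0.05)
    assert np.mean(np.diff(slopes) < 0) > 0.7


def test_cross_validation_contract(small_beta, design_small):
    matrix, _, states = small_beta
    ages = design_small.ages
    out1, folds1 = cross_validate_epm(matrix, ages, k=10, seed=5)
    out2, folds2 = cross_validate_epm(matrix, ages, k=10, seed=5)
    np.testing.assert_array_equal(folds1, folds2)
    np.testing.assert_allclose(out1, out2)
    assert set(np.bincount(folds1)) <= {len(ages) // 10, len(ages) // 10 + 1}
    # low-noise generative data: out-of-fold states track generating states
    assert np.corrcoef(out1, states)[0, 1] > 0.99


def test_leave_one_out_folds():
    rng = np.random.default_rng(8)
    ages = np.linspace(0.5, 11, 12)
    beta = np.clip(np.outer(rng.uniform(0.02, 0.05, 20), ages)
                   + rng.uniform(0.1, 0.4, 20)[:, None], 0, 1)
    m = _matrix(beta)
    out, folds = cross_validate_epm(m, ages, k=12, seed=0)
    assert len(np.unique(folds)) == 12  # every sample is its own fold
    np.testing.assert_allclose(out, ages, atol=1e-6)  # noiseless recovery
    with pytest.raises(ValidationError):
        cross_validate_epm(m, ages, k=13)
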
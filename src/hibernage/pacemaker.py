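"""Epigenetic pacemaker: latent epigenetic states by alternating least squares.

The pacemaker models the methylation beta of site *i* in sample *j* as

    beta_ij = rate_i * s_j + offset_i + eps_ij

where ``s_j`` is a per-sample latent epigenetic state. Sites and states are
estimated jointly by conditional expectation maximization (alternating
least squares) minimizing the total residual sum of squares: given states,
each site's (rate, offset) is an ordinary least-squares line; given site
parameters, each state has the closed form

    s_j = sum_i rate_i * (beta_ij - offset_i) / sum_i rate_i**2.

States are initialized at chronological ages, which anchors the affine
gauge (the model is otherwise identified only up to s -> a*s + b with
compensating site parameters). Each half-step weakly decreases the RSS, so
the recorded trajectory is monotone non-increasing.

Candidate sites are those whose methylation correlates strongly with
chronological age (absolute Pearson r above a threshold, default 0.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import MethylationMatrix, ValidationError

__all__ = [
    "PacemakerModel",
    "DegenerateModelError",
    "select_age_sites",
    "fit_epm",
    "predict_states",
    "cross_validate_epm",
]


class DegenerateModelError(RuntimeError):
    """All site rates are zero: the state update is undefined."""


@dataclass
class PacemakerModel:
    site_ids: list[str]
    rate: np.ndarray = field(repr=False)
    offset: np.ndarray = field(repr=False)
    states: np.ndarray = field(repr=False)
    rss: float
    rss_trajectory: np.ndarray = field(repr=False)
    n_iter: int
    converged: bool

    def to_payload(self) -> dict:
        return {
            "site_ids": self.site_ids,
            "rate": self.rate,
            "offset": self.offset,
            "states": self.states,
            "rss": self.rss,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def _pearson_by_site(beta: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation with ``ages``; NaN for constant rows."""
    b = beta - beta.mean(axis=1, keepdims=True)
    a = ages - ages.mean()
    denom = np.sqrt((b**2).sum(axis=1) * (a**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, b @ a / np.where(denom > 0, denom, 1.0), np.nan)


def select_age_sites(
    beta: MethylationMatrix, ages, threshold: float = 0.7
) -> list[str]:
    """Sites whose |Pearson r| with chronological age exceeds ``threshold``.

    Zero-variance sites have undefined correlation and are excluded (with a
    warning when every site is constant).
    """
    ages = np.asarray(ages, dtype=float)
    if beta.n_samples < 3:
        raise ValidationError("need at least 3 samples for site selection")
    if len(ages) != beta.n_samples:
        raise ValidationError("ages must align with matrix columns")
    r = _pearson_by_site(beta.beta, ages)
    if np.all(np.isnan(r)):
        warnings.warn("all sites have zero variance; no sites selected")
        return []
    keep = np.flatnonzero(np.abs(r) > threshold)
    return [beta.site_ids[i] for i in keep]


def _rss(beta: np.ndarray, rate: np.ndarray, offset: np.ndarray, s: np.ndarray) -> float:
    resid = beta - np.outer(rate, s) - offset[:, None]
    return float((resid**2).sum())


def fit_epm(
    beta_subset: MethylationMatrix,
    ages,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PacemakerModel:
    """Fit the pacemaker by alternating least squares.

    Stops when the relative RSS change between full iterations drops below
    ``tol`` or after ``max_iter`` iterations.
    """
    ages = np.asarray(ages, dtype=float)
    beta = beta_subset.beta
    if beta.shape[0] < 1 or beta.shape[1] < 3:
        raise ValidationError("need >=1 site and >=3 samples")
    if len(ages) != beta.shape[1]:
        raise ValidationError("ages must align with matrix columns")
    if np.ptp(ages) == 0:
        raise ValidationError("chronological ages are constant; states not initializable")

    s = ages.astype(float).copy()
    trajectory: list[float] = []
    rate = np.zeros(beta.shape[0])
    offset = beta.mean(axis=1)
    converged = False
    it = 0
    prev = np.inf
    for it in range(1, max_iter + 1):
        # M-step for sites: per-site OLS of beta on current states
        sc = s - s.mean()
        var_s = (sc**2).sum()
        rate = (beta - beta.mean(axis=1, keepdims=True)) @ sc / var_s
        offset = beta.mean(axis=1) - rate * s.mean()
        # E-step for states: closed-form least-squares update
        denom = (rate**2).sum()
        if denom == 0:
            raise DegenerateModelError("all site rates are zero at the state update")
        s = rate @ (beta - offset[:, None]) / denom
        rss = _rss(beta, rate, offset, s)
        trajectory.append(rss)
        if prev < np.inf and prev > 0 and (prev - rss) / prev < tol:
            converged = True
            break
        if rss == 0.0:
            converged = True
            break
        prev = rss

    return PacemakerModel(
        site_ids=list(beta_subset.site_ids),
        rate=rate,
        offset=offset,
        states=s,
        rss=trajectory[-1],
        rss_trajectory=np.asarray(trajectory),
        n_iter=it,
        converged=converged,
    )


def predict_states(model: PacemakerModel, beta_new: MethylationMatrix) -> np.ndarray:
    """States for new samples with site parameters held fixed."""
    sub = beta_new.subset_sites(model.site_ids)
    denom = (model.rate**2).sum()
    if denom == 0:
        raise DegenerateModelError("model has all-zero rates")
    return model.rate @ (sub.beta - model.offset[:, None]) / denom


def cross_validate_epm(
    beta: MethylationMatrix,
    ages,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.7,
    reselect_sites: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Out-of-fold pacemaker states for every sample.

    Samples are shuffled with ``seed`` and split into ``k`` folds; each
    fold's states come from a model trained on the remaining samples. By
    default age-site selection is redone inside each training fold (no
    leakage); ``reselect_sites=False`` reuses a single whole-data selection.
    When a training fold selects fewer than two sites, the two highest-|r|
    sites are used instead (with a warning).
    """
    ages = np.asarray(ages, dtype=float)
    n = beta.n_samples
    if not 2 <= k <= n:
        raise ValidationError(f"k={k} must be in [2, n_samples={n}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    global_sites = None
    if not reselect_sites:
        global_sites = select_age_sites(beta, ages, threshold)

    states = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        train = beta.subset_samples(train_idx)
        if reselect_sites:
            sites = select_age_sites(train, ages[train_idx], threshold)
        else:
            sites = list(global_sites)
        if len(sites) < 2:
            warnings.warn(
                f"fold {f}: fewer than 2 sites pass |r|>{threshold}; "
                "falling back to the 2 highest-|r| sites"
            )
            r = np.abs(_pearson_by_site(train.beta, ages[train_idx]))
            r = np.where(np.isnan(r), -1.0, r)
            sites = [beta.site_ids[i] for i in np.argsort(-r)[:2]]
        model = fit_epm(train.subset_sites(sites), ages[train_idx], tol, max_iter)
        states[test_idx] = predict_states(model, beta.subset_samples(test_idx))
        fold_of[test_idx] = f
    return states, fold_of
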
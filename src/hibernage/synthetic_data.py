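"""Synthetic sampling designs, traits and beta matrices.

The generator emulates the structure of the field study this package
analyses: a wild population of female hibernators sampled only during the
active season, with repeated samples per individual across years. The
defaults reproduce that design: 73 individuals contributing 149 blood
samples (1-8 each), chronological ages spanning 0.01-12.04 years, sample
collection restricted to study days 362-365 and 1-112 (late April to late
August on the 1-May study origin), and 11 individuals trapped in
consecutive summers with at least two samples in one summer and one in the
adjacent summer — the subset eligible for the active-vs-hibernation rate
contrast.

Two simulated traits mirror the study's power analysis:

* a *flat* trait that accumulates at a constant daily rate from birth,
  regardless of season (the null for the seasonal test);
* a *seasonal* trait that accumulates only during the active season
  (study days 353-365 and 1-138) and stalls during hibernation
  (days 139-352), with the active-season daily rate chosen so the annual
  increase matches the flat trait.

Both traits receive an animal-level random intercept and a per-sample
residual, with variances taken from the study's fitted mixed model
(0.329 and 0.294 state-units squared).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .core_io import MethylationMatrix, SampleTable, ValidationError

__all__ = [
    "DesignConfig",
    "TraitConfig",
    "SiteConfig",
    "generate_design",
    "simulate_trait",
    "simulate_beta_matrix",
    "cumulative_active_days",
]

# default sampling window: 27 April (study day 362) through 20 August (day 112)
_DEFAULT_WINDOW = tuple(range(362, 366)) + tuple(range(1, 113))


@dataclass(frozen=True)
class DesignConfig:
    """Sampling-design parameters (defaults emulate the field study)."""

    n_individuals: int = 73
    samples_min: int = 1
    samples_max: int = 8
    n_samples_total: int | None = 149
    age_min: float = 0.01
    age_max: float = 12.04
    sampling_window: tuple[int, ...] = _DEFAULT_WINDOW
    n_consecutive_pairs: int = 11
    natal_window: tuple[int, int] = (30, 90)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if not self.sampling_window:
            raise ValidationError("sampling window is empty")
        if any(not 1 <= d <= 365 for d in self.sampling_window):
            raise ValidationError("sampling window must lie in [1,365]")
        if not 1 <= self.samples_min <= self.samples_max:
            raise ValidationError("need 1 <= samples_min <= samples_max")
        total = self.n_samples_total
        if total is not None and not (
            self.n_individuals * self.samples_min
            <= total
            <= self.n_individuals * self.samples_max
        ):
            raise ValidationError(
                f"n_samples_total={total} incompatible with "
                f"{self.n_individuals} individuals x "
                f"[{self.samples_min},{self.samples_max}] samples"
            )


@dataclass(frozen=True)
class TraitConfig:
    """Trait-simulation parameters (defaults are the study's values)."""

    daily_rate_flat: float = 0.004
    winter_days: tuple[int, int] = (139, 352)
    active_daily_rate: float | None = None  # None -> daily_rate_flat*365/150
    var_individual: float = 0.329
    var_residual: float = 0.294
    seed: int = 0

    def __post_init__(self) -> None:
        if self.var_individual < 0 or self.var_residual < 0:
            raise ValidationError("variances must be >= 0")
        w1, w2 = self.winter_days
        if not (1 < w1 <= w2 < 365):
            raise ValidationError("winter_days must be a sub-interval of (1,365)")

    @property
    def active_rate(self) -> float:
        """Active-season daily rate; derived so annual increase matches the
        flat trait (rate x 365 / 150) unless set explicitly."""
        if self.active_daily_rate is not None:
            return self.active_daily_rate
        return self.daily_rate_flat * 365.0 / 150.0


@dataclass(frozen=True)
class SiteConfig:
    """Per-site parameters for the beta-matrix generator.

    ``n_age_sites`` sites are linear in the latent epigenetic state (the
    pacemaker's generative model); ``n_chron_sites`` are linear in
    chronological age itself, mimicking clock sites whose methylation
    tracks calendar time irrespective of seasonal state dynamics; the
    remainder are state-independent noise around their offsets.
    """

    n_sites: int = 500
    n_age_sites: int = 300
    n_chron_sites: int = 100
    rate_bounds: tuple[float, float] = (0.005, 0.03)  # |rate| range, sign random
    offset_bounds: tuple[float, float] = (0.02, 0.98)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_age_sites + self.n_chron_sites > self.n_sites:
            raise ValidationError("n_age_sites + n_chron_sites must be <= n_sites")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _draw_counts(cfg: DesignConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-individual sample counts, repaired to the configured total."""
    n, lo, hi = cfg.n_individuals, cfg.samples_min, cfg.samples_max
    counts = rng.integers(lo, hi + 1, size=n)
    total = cfg.n_samples_total
    if total is not None:
        while counts.sum() > total:
            idx = rng.choice(np.flatnonzero(counts > lo))
            counts[idx] -= 1
        while counts.sum() < total:
            idx = rng.choice(np.flatnonzero(counts < hi))
            counts[idx] += 1
        # make sure enough individuals can carry the 2+1 consecutive-summer
        # pattern (needs >=3 samples each)
        want = min(cfg.n_consecutive_pairs, n)
        while (counts >= 3).sum() < want:
            donors = np.flatnonzero(counts > 3)
            takers = np.flatnonzero(counts == 2)
            if not len(takers):
                takers = np.flatnonzero(counts == 1)
            if not len(donors) or not len(takers):
                break
            counts[rng.choice(donors)] -= 1
            counts[rng.choice(takers)] += 1
    return counts


def generate_design(cfg: DesignConfig) -> SampleTable:
    """Generate a longitudinal sampling design as a :class:`SampleTable`.

    The returned table carries ``year`` (study-year index) alongside the
    canonical columns, so the absolute day of each sample is
    ``year*365 + doy - 1`` and the birth day is recoverable as
    ``absolute_day - age*365``. Individuals designated for the
    consecutive-summer subset receive two samples in one summer and the
    rest in the next; other multi-sample individuals are trapped once per
    summer, so they never satisfy the 2+1 eligibility rule.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _draw_counts(cfg, rng)
    n = cfg.n_individuals

    # window positions in within-summer order (wrap: late April first)
    window = sorted(set(cfg.sampling_window), key=lambda d: (d < 183, d))
    # map window day -> offset from the summer's 1-May anchor (negative for
    # late-April days of the preceding study year)
    offsets = np.array([d - 366 if d >= 183 else d - 1 for d in window])
    span = len(window)

    eligible = np.argsort(-counts, kind="stable")
    designated = [i for i in eligible if counts[i] >= 3][: min(cfg.n_consecutive_pairs, n)]
    designated_set = set(designated)

    rows = []
    for i in range(n):
        c = int(counts[i])
        if i in designated_set:
            per_summer = [2, c - 2]
        elif c <= 2 and rng.random() < 0.5:
            per_summer = [c]  # all samples in a single summer
        else:
            per_summer = [1] * c  # one sample per consecutive summer
        n_summers = len(per_summer)
        s0 = int(rng.integers(1, 11))  # first summer index (epoch arbitrary)
        span_years = n_summers - 1
        # age at first sample: pups and adults mixed, capped so the oldest
        # sample stays below age_max
        a_cap = max(cfg.age_min + 0.1, cfg.age_max - span_years - 0.5)
        if rng.random() < 0.4:
            a0 = rng.uniform(max(cfg.age_min, 0.05), min(0.95, a_cap))
        else:
            a0 = rng.uniform(min(1.0, a_cap), min(9.0, a_cap) + 1e-9)
        abs_days: list[float] = []
        for k, m in enumerate(per_summer):
            pos = np.sort(rng.choice(span, size=m, replace=False))
            anchor = (s0 + k) * 365
            abs_days.extend(anchor + offsets[pos])
        abs_days_arr = np.array(sorted(abs_days), dtype=float)
        birth_abs = abs_days_arr[0] - a0 * 365.0
        ages = (abs_days_arr - birth_abs) / 365.0
        if ages[-1] > cfg.age_max:
            birth_abs += (ages[-1] - cfg.age_max) * 365.0
            ages = (abs_days_arr - birth_abs) / 365.0
        for j, (a, t) in enumerate(zip(ages, abs_days_arr)):
            rows.append(
                {
                    "sample_id": f"A{i:03d}_S{j}",
                    "animal_id": f"A{i:03d}",
                    "age": float(a),
                    "doy": int(t % 365) + 1,
                    "year": int(t // 365),
                }
            )

    df = pd.DataFrame(rows)
    # anchor the observed age range at single-sample individuals (so the
    # adjustment cannot break within-animal birth-date consistency)
    singles = df.index[df.groupby("animal_id")["sample_id"].transform("size") == 1]
    if len(singles) >= 2:
        oldest = df.loc[singles, "age"].idxmax()
        df.loc[oldest, "age"] = cfg.age_max
        youngest = df.loc[singles.drop(oldest), "age"].idxmin()
        df.loc[youngest, "age"] = cfg.age_min
    return SampleTable(df)


def cumulative_active_days(abs_day, winter_days: tuple[int, int] = (139, 352)):
    """Active days accumulated from the epoch origin up to ``abs_day``.

    ``abs_day`` is continuous time in days with ``abs_day = year*365 + doy-1``.
    Winter (``winter_days``, inclusive study-doy interval) contributes
    nothing; every other day contributes one day per day.
    """
    w1, w2 = winter_days
    active_per_year = (w1 - 1) + (365 - w2)
    t = np.asarray(abs_day, dtype=float)
    years = np.floor(t / 365.0)
    d = t - years * 365.0  # in [0, 365): d = doy - 1
    within = np.minimum(d, w1 - 1) + np.maximum(0.0, d - w2)
    return years * active_per_year + within


def _abs_days(design: SampleTable) -> np.ndarray:
    if "year" in design.df.columns:
        return design.df["year"].to_numpy(float) * 365.0 + design.doys - 1.0
    # without an explicit year the day of life anchors absolute time
    return design.ages * 365.0


def simulate_trait(design: SampleTable, cfg: TraitConfig, seasonal: bool) -> np.ndarray:
    """Simulate one trait value per sample of ``design``.

    seasonal=False: ``rate_flat * age_days + u_animal + e``.
    seasonal=True: accumulation at :attr:`TraitConfig.active_rate` over the
    active days lived between birth and sampling, zero during winter.
    """
    if len(design) == 0:
        raise ValidationError("design is empty")
    rng = np.random.default_rng(cfg.seed)
    animals = pd.unique(design.animal_ids)
    u = dict(
        zip(animals, rng.normal(0.0, np.sqrt(cfg.var_individual), size=len(animals)))
    )
    e = rng.normal(0.0, np.sqrt(cfg.var_residual), size=len(design))
    if seasonal:
        t = _abs_days(design)
        birth = t - design.ages * 365.0
        base = cfg.active_rate * (
            cumulative_active_days(t, cfg.winter_days)
            - cumulative_active_days(birth, cfg.winter_days)
        )
    else:
        base = cfg.daily_rate_flat * design.ages * 365.0
    u_vec = np.array([u[a] for a in design.animal_ids])
    return base + u_vec + e


def simulate_beta_matrix(
    design: SampleTable,
    states: Iterable[float],
    cfg: SiteConfig,
    return_params: bool = False,
):
    """Simulate a beta matrix whose age sites are linear in ``states``.

    State sites: ``beta = clip(rate*state + offset + noise, 0, 1)`` with
    the offset drawn so the noiseless line stays inside ``offset_bounds``
    over the observed state range (keeping the linear model exact before
    clipping). Chronological-age sites use the same construction with the
    sample ages in place of the states; remaining sites are
    state-independent noise around their offsets. With ``return_params``
    the per-site truth is returned as a second value (DataFrame with
    columns site_id, kind, is_age_site, rate, offset).
    """
    states = np.asarray(list(states), dtype=float)
    if len(states) != len(design):
        raise ValidationError("states must align with design rows")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.offset_bounds
    r_lo, r_hi = cfg.rate_bounds

    site_ids = [f"cg{i:05d}" for i in range(cfg.n_sites)]
    kinds = np.array(["noise"] * cfg.n_sites, dtype=object)
    signal = rng.choice(
        cfg.n_sites, size=cfg.n_age_sites + cfg.n_chron_sites, replace=False
    )
    kinds[signal[: cfg.n_age_sites]] = "state"
    kinds[signal[cfg.n_age_sites :]] = "chron"
    rates = np.zeros(cfg.n_sites)
    offsets = rng.uniform(lo, hi, size=cfg.n_sites)
    beta = np.empty((cfg.n_sites, len(states)))
    ages = design.ages
    for i in range(cfg.n_sites):
        if kinds[i] == "noise":
            beta[i] = offsets[i]
            continue
        x = states if kinds[i] == "state" else ages
        xmin, xmax = x.min(), x.max()
        r = rng.uniform(r_lo, r_hi) * rng.choice([-1.0, 1.0])
        o_lo = lo - min(r * xmin, r * xmax)
        o_hi = hi - max(r * xmin, r * xmax)
        if o_hi <= o_lo:  # covariate span too wide for this rate: shrink it
            r *= (hi - lo) / (abs(r) * (xmax - xmin) + 1e-12) * 0.9
            o_lo = lo - min(r * xmin, r * xmax)
            o_hi = hi - max(r * xmin, r * xmax)
        rates[i] = r
        offsets[i] = rng.uniform(o_lo, o_hi)
        beta[i] = rates[i] * x + offsets[i]
    beta += rng.normal(0.0, cfg.noise_sd, size=beta.shape)
    np.clip(beta, 0.0, 1.0, out=beta)
    matrix = MethylationMatrix(site_ids, list(design.sample_ids), beta)
    if not return_params:
        return matrix
    params = pd.DataFrame(
        {
            "site_id": site_ids,
            "kind": kinds,
            "is_age_site": kinds == "state",
            "rate": rates,
            "offset": offsets,
        }
    )
    return matrix, params
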
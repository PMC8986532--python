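"""Per-CpG association scans for age and season.

Two scans per site: a mixed-model EWAS of chronological age (linear slope,
animal random intercept) and a GAM with a cubic age spline plus a cyclic
day-of-year spline (no random intercept). Multiplicity is summarized at a
fixed threshold (1e-5 by default, the compromise between Bonferroni and
Benjamini-Hochberg used for this array), the Bonferroni bound alpha/m, and
the BH step-up rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_io import MethylationMatrix, SampleTable, ValidationError
from .gamm_engine import CompiledGamm
from .season_inference import SEASONAL_TERM, seasonal_model_terms

__all__ = [
    "ewas_age",
    "gam_scan",
    "multiplicity_thresholds",
    "overlap_summary",
]


def ewas_age(
    beta: MethylationMatrix,
    table: SampleTable,
    random_intercept: bool = True,
) -> pd.DataFrame:
    """Per-site linear regression of methylation on chronological age.

    With ``random_intercept`` (default) each site is a linear mixed model
    with an animal-level intercept; p-values use the Wald normal
    approximation for the age slope. Constant sites are reported as NA.
    Returns a DataFrame with site_id, slope, se, p, direction.
    """
    if beta.n_samples != len(table):
        raise ValidationError("matrix columns must align with table rows")
    ages = table.ages
    X = sm.add_constant(ages)
    groups = table.animal_ids
    rows = []
    for i, site in enumerate(beta.site_ids):
        y = beta.beta[i]
        if np.ptp(y) == 0:
            rows.append((site, np.nan, np.nan, np.nan, None))
            continue
        slope = se = np.nan
        if random_intercept:
            # the animal variance often hits the zero boundary for sites
            # without an individual signature; fall back through optimizers
            # and finally to the boundary model itself (plain OLS)
            for method in ("bfgs", "powell", None):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        if method is None:
                            fit = sm.OLS(y, X).fit()
                            slope, se = fit.params[1], fit.bse[1]
                        else:
                            fit = sm.MixedLM(y, X, groups=groups).fit(
                                reml=True, method=method
                            )
                            slope, se = fit.fe_params[1], fit.bse_fe[1]
                    if np.isfinite(slope) and np.isfinite(se) and se > 0:
                        break
                except (np.linalg.LinAlgError, ValueError):
                    continue
        else:
            fit = sm.OLS(y, X).fit()
            slope, se = fit.params[1], fit.bse[1]
        if np.isfinite(slope) and np.isfinite(se) and se > 0:
            from scipy import stats as sps

            p = 2 * sps.norm.sf(abs(slope / se))
            rows.append((site, slope, se, p, "hyper" if slope > 0 else "hypo"))
        else:
            warnings.warn(f"site {site}: EWAS failed; reported NA")
            rows.append((site, np.nan, np.nan, np.nan, None))
    return pd.DataFrame(
        rows, columns=["site_id", "slope", "se", "p", "direction"]
    )


def gam_scan(
    beta: MethylationMatrix,
    table: SampleTable,
    k: int = 10,
    random_intercept: bool = False,
) -> pd.DataFrame:
    """Per-site GAM: cubic age spline + cyclic day-of-year spline.

    Reports the age-smooth e.d.f. and p and the seasonal-term p per site.
    Sites that fail to fit are reported NA and the scan continues.
    """
    if beta.n_samples != len(table):
        raise ValidationError("matrix columns must align with table rows")
    compiled = CompiledGamm(
        table, seasonal_model_terms(k), "animal_id" if random_intercept else None
    )
    rows = []
    warm = None
    for i, site in enumerate(beta.site_ids):
        y = beta.beta[i]
        if np.ptp(y) == 0:
            rows.append((site, np.nan, np.nan, np.nan, False))
            continue
        try:
            fit = compiled.fit(y, rho0=warm)
            warm = fit.rho
            rows.append(
                (
                    site,
                    fit.edf["s(age)"],
                    fit.term_tests["s(age)"]["p"],
                    fit.term_tests[SEASONAL_TERM]["p"],
                    fit.converged,
                )
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"site {site}: GAM failed ({exc}); reported NA")
            rows.append((site, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["site_id", "age_edf", "age_p", "season_p", "converged"]
    )


def multiplicity_thresholds(
    p_values,
    n_sites: int | None = None,
    alpha: float = 0.05,
    fixed_threshold: float = 1e-5,
) -> dict:
    """Counts of significant sites under fixed, Bonferroni and BH rules.

    ``n_sites`` defaults to the number of non-NA p-values; pass the full
    array size when some sites failed (they still count toward the
    multiple-testing burden).
    """
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if n_sites is None:
        n_sites = int(ok.sum())
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values outside [0,1]")
    bonf_thresh = alpha / n_sites
    if ok.sum():
        bh_reject, *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")[:1]
        bh_count = int(bh_reject.sum())
    else:
        bh_count = 0
    return {
        "n_sites": int(n_sites),
        "fixed_threshold": fixed_threshold,
        "fixed_count": int((p[ok] < fixed_threshold).sum()),
        "bonferroni_threshold": float(bonf_thresh),
        "bonferroni_count": int((p[ok] < bonf_thresh).sum()),
        "bh_count": bh_count,
    }


def overlap_summary(ewas_hits, gam_age_hits, gam_season_hits) -> dict:
    """Counts of the seven regions of the three-set Venn diagram."""
    A, B, C = set(ewas_hits), set(gam_age_hits), set(gam_season_hits)
    return {
        "ewas_only": len(A - B - C),
        "gam_age_only": len(B - A - C),
        "gam_season_only": len(C - A - B),
        "ewas_gam_age": len((A & B) - C),
        "ewas_gam_season": len((A & C) - B),
        "gam_age_gam_season": len((B & C) - A),
        "all_three": len(A & B & C),
        "ewas_total": len(A),
        "gam_age_total": len(B),
        "gam_season_total": len(C),
        "union": len(A | B | C),
    }
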
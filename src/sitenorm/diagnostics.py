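"""Residual-site-effect diagnostics and atypicality prevalence.

``site_anova`` answers "can site still be predicted from these values?" —
an F-test of the site factor under sum-to-zero contrasts with optional
covariate adjustment (an ANCOVA when age is included), applied to raw
thickness before correction and to deviation z-scores after.
``bartlett_by_site`` tests homogeneity of residual variance across sites
after regressing out stated covariates.  ``atypical_prevalence`` is the
percentage of subjects beyond the |z| > 1.96 normative band, per region and
averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["site_anova", "bartlett_by_site", "atypical_prevalence",
           "adjust_pvalues", "AnovaResult"]


@dataclass
class AnovaResult:
    F: float
    df: tuple
    p: float


def _clean_frame(values, site, covariates=None):
    values = np.asarray(values, dtype=float).ravel()
    frame = pd.DataFrame({"value": values,
                          "site": np.asarray(site).astype(str)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        frame = pd.concat([frame, cov.astype(float)], axis=1)
    frame = frame.dropna()
    return frame


def site_anova(values, site, covariates: pd.DataFrame | None = None
               ) -> AnovaResult:
    """F-test for the site main effect, sum-to-zero contrasts.

    ``covariates`` (e.g. an ``age`` column) enter as adjustment terms.
    Returns NaN statistics when the response is constant.
    """
    frame = _clean_frame(values, site, covariates)
    counts = frame["site"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 sites with >= 2 subjects each")
    if frame["value"].nunique() == 1:
        return AnovaResult(F=float("nan"), df=(float("nan"), float("nan")),
                           p=float("nan"))
    terms = ["C(site, Sum)"] + [
        c for c in frame.columns if c not in ("value", "site")]
    model = smf.ols("value ~ " + " + ".join(terms), data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(site, Sum)"]
    return AnovaResult(F=float(row["F"]),
                       df=(int(row["df"]), int(table.loc["Residual", "df"])),
                       p=float(row["PR(>F)"]))


def bartlett_by_site(values, site, covariates: pd.DataFrame | None = None):
    """Bartlett's homogeneity-of-variance test across sites.

    When covariates are given the test runs on OLS residuals from them, so
    variance differences explainable by e.g. age and sex are removed first.
    Sites with fewer than 2 observations are excluded with a warning.
    """
    frame = _clean_frame(values, site, covariates)
    resid = frame["value"].to_numpy()
    cov_cols = [c for c in frame.columns if c not in ("value", "site")]
    if cov_cols:
        X = np.column_stack([np.ones(len(frame)),
                             frame[cov_cols].to_numpy()])
        coef, *_ = np.linalg.lstsq(X, resid, rcond=None)
        resid = resid - X @ coef
    groups = []
    for s, grp in pd.Series(resid).groupby(frame["site"].to_numpy()):
        if len(grp) < 2:
            warnings.warn(f"site {s!r} has < 2 residuals; excluded")
            continue
        groups.append(grp.to_numpy())
    if len(groups) < 2:
        raise ValueError("need >= 2 sites with >= 2 residuals")
    stat, p = stats.bartlett(*groups)
    return float(stat), float(p)


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment for per-region p-values.

    Reporting is per-region and unadjusted by default; this helper is for
    users who want family-wise control across the region set.
    """
    from statsmodels.stats.multitest import multipletests
    pvalues = np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method=method)[1]


def atypical_prevalence(z, threshold: float = 1.96):
    """Percentage of |z| > threshold, per region and averaged.

    ``z`` may be a DataFrame (columns = regions), a DeviationScores, or a
    plain array (treated as one region).  Returns (per_region: Series,
    average: float), both in percent.
    """
    if hasattr(z, "z"):                      # DeviationScores
        z = np.asarray(z.z)
    if isinstance(z, pd.DataFrame):
        per_region = 100.0 * (z.abs() > threshold).mean()
    else:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] == 1:
            z = z.T
        per_region = pd.Series(
            100.0 * (np.abs(z) > threshold).mean(axis=0),
            index=[f"region{j}" for j in range(z.shape[1])])
    return per_region, float(per_region.mean())
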
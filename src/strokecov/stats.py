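"""Association statistics: Bonferroni-gated correlations, subgroup tests and
the interaction regression linking network expression to recovery.

Conventions follow the host analysis: descriptives are median and range;
Pearson correlations are screened against a critical coefficient derived
from the Student-t quantile at the Bonferroni-corrected per-comparison
alpha; subgroup contrasts use Kruskal-Wallis and Mann-Whitney after a
Shapiro-Wilk normality gate; and the hand-function model regresses recovery
expression on network expression, lesion volume and their product.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationReport",
    "RegressionResult",
    "bonferroni_alpha",
    "critical_r",
    "pearson_r",
    "correlate_with_externals",
    "subgroup_tests",
    "interaction_regression",
    "descriptives",
]


@dataclass
class RegressionResult:
    """Fit of y = b0 + b1*x1 + b2*x2 + b3*(x1*x2)."""

    params: np.ndarray  # (b0, b1, b2, b3)
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    term_names: tuple[str, ...] = ("intercept", "expression", "lesion_volume", "expression_x_lesion")
    robust: bool = False


def bonferroni_alpha(alpha: float, m: int) -> tuple[float, float]:
    """Per-comparison alpha under Bonferroni control.

    Returns (full precision, rounded to 3 decimals); e.g. (0.05, 8) ->
    (0.00625, 0.006).
    """
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    a = alpha / m
    return a, round(a, 3)


def critical_r(n: int, alpha: float, tails: str = "two") -> float:
    """Smallest |r| significant at ``alpha`` for a sample of size ``n``.

    Inverts the t-test of a Pearson correlation: r_crit = t / sqrt(t^2 + n -
    2) with t the Student quantile at the stated tail probability on n - 2
    degrees of freedom.  Monotone decreasing in n.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if tails == "two":
        t = sps.t.ppf(1 - alpha / 2, n - 2)
    elif tails == "one":
        t = sps.t.ppf(1 - alpha, n - 2)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return float(t / np.sqrt(t**2 + n - 2))


def pearson_r(x, y) -> float:
    """Plain Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CorrelationReport:
    pair: tuple[str, str]
    n: int
    r: float
    alpha_per_comparison: float
    critical_r: float
    significant: bool


def correlate_with_externals(
    coefficients,
    externals: dict[str, np.ndarray],
    alpha: float = 0.05,
    m: int = 8,
    name: str = "expression",
) -> list[CorrelationReport]:
    """Pearson r of one coefficient vector against each external variable,
    gated by the Bonferroni-corrected critical correlation."""
    x = np.asarray(coefficients, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    a_pc, _ = bonferroni_alpha(alpha, m)
    r_crit = critical_r(n, a_pc, tails="two")
    reports = []
    for var, values in externals.items():
        y = np.asarray(values, dtype=float)
        if y.shape != x.shape:
            raise ValueError(f"external {var!r} has wrong length")
        if np.std(y) == 0 or np.std(x) == 0:
            reports.append(CorrelationReport((name, var), n, np.nan, a_pc, r_crit, False))
            continue
        r = pearson_r(x, y)
        reports.append(CorrelationReport((name, var), n, r, a_pc, r_crit, bool(abs(r) > r_crit)))
    return reports


def subgroup_tests(values, classes, alpha: float = 0.05) -> dict:
    """Nonparametric subgroup comparison of one scalar variable.

    Reports the Shapiro-Wilk normality check on the pooled values, the
    Kruskal-Wallis test across all classes, and a Mann-Whitney U test of the
    ``impaired`` class against the pooled remaining (recovered) patients;
    p values are two-tailed.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    labels = [c for c in pd.unique(classes)]
    groups = [values[classes == c] for c in labels]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for lab, g in zip(labels, groups):
        if g.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")

    if np.ptp(values) == 0:
        shapiro_w, shapiro_p = np.nan, np.nan
        kw_stat, kw_p = 0.0, 1.0
        mw_u, mw_p = np.nan, 1.0
    else:
        shapiro_w, shapiro_p = sps.shapiro(values)
        kw_stat, kw_p = sps.kruskal(*groups)
        if "impaired" in labels:
            imp = values[classes == "impaired"]
            rec = values[classes != "impaired"]
            mw_u, mw_p = sps.mannwhitneyu(imp, rec, alternative="two-sided")
        else:
            mw_u, mw_p = np.nan, np.nan
    return {
        "groups": {str(lab): g.size for lab, g in zip(labels, groups)},
        "shapiro_w": float(shapiro_w),
        "shapiro_p": float(shapiro_p),
        "normality_rejected": bool(shapiro_p < alpha) if np.isfinite(shapiro_p) else False,
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
        "mannwhitney_u": float(mw_u) if np.isfinite(np.asarray(mw_u, dtype=float)) else np.nan,
        "mannwhitney_p": float(mw_p) if mw_p is not None else np.nan,
    }


def interaction_regression(y, x1, x2, robust: bool = False) -> RegressionResult:
    """Regression of recovery expression on network expression, lesion volume
    and their interaction: y = b0 + b1*x1 + b2*x2 + b3*(x1*x2).

    Ordinary least squares by default; with ``robust=True`` the coefficients
    come from iteratively reweighted least squares with Huber weights
    (tuning constant 1.345).  Reports per-term t statistics on n - 4 degrees
    of freedom, R^2 and the overall F(3, n - 4) (for the robust fit these are
    computed from the robust residuals, i.e. pseudo versions).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = y.size
    if n <= 4:
        raise ValueError("need n > 4")
    X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    cond = np.linalg.cond(X)
    if cond > 1e10:
        # find which added term degrades conditioning most
        names = ("intercept", "expression", "lesion_volume", "expression_x_lesion")
        raise ValueError(
            f"collinear design (condition number {cond:.3g}); terms: {', '.join(names)}"
        )

    if robust:
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        resid = y - X @ fit.params
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
        df_resid = n - 4
        f_stat = (r2 / 3) / ((1 - r2) / df_resid) if np.isfinite(r2) and r2 < 1 else np.inf
        f_p = float(sps.f.sf(f_stat, 3, df_resid)) if np.isfinite(f_stat) else 0.0
        return RegressionResult(
            params=np.asarray(fit.params),
            bse=np.asarray(fit.bse),
            tvalues=np.asarray(fit.tvalues),
            pvalues=np.asarray(fit.pvalues),
            df_resid=df_resid,
            r_squared=float(r2),
            f_statistic=float(f_stat),
            f_pvalue=f_p,
            df_model=3,
            robust=True,
        )
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
    )


def descriptives(values) -> tuple[float, tuple[float, float]]:
    """Median and (min, max) range; the study's descriptive convention."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty input")
    return float(np.median(values)), (float(values.min()), float(values.max()))
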
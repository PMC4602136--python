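"""Response feature analysis of longitudinal behavioral series.

Each patient's z-scored trajectory is summarized by the better of two
candidate models — a straight line z = a + b*t, or an exponential approach to
an asymptote z(t) = z_inf - (z_inf - z0) * exp(-t / tau) — selected by
Akaike's information criterion AIC = 2k + n*ln(RSS/n).  The fitted summary
drives the subgroup rule: linear -> *fast*, exponential converging to
z >= -2.5 -> *slow*, exponential converging below -2.5 -> *impaired*.

Group-level structure of the completed patients x visits matrix is extracted
with a column-centered (covariance) PCA; components are retained by the
Kaiser-Guttmann criterion (eigenvalue above the mean eigenvalue).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .cohort import NORMAL_BAND_Z, invert_z, z_transform

__all__ = [
    "RecoveryFit",
    "BehavioralPCAResult",
    "z_transform",
    "invert_z",
    "impute_missing",
    "fit_recovery_models",
    "classify_recovery",
    "behavioral_pca",
    "TAU_STARTS",
]

#: Multi-start grid for the exponential time constant, in days.
TAU_STARTS: tuple[float, ...] = (5.0, 15.0, 30.0, 60.0, 120.0, 240.0)

_RSS_FLOOR = 1e-30  # guards ln(RSS/n) on exactly interpolating fits


@dataclass
class RecoveryFit:
    """Fitted recovery summary for one patient."""

    patient_id: str
    family: str  # "linear" | "exponential"
    params: dict[str, float]
    rss: float
    aic: float
    aic_linear: float
    aic_exponential: float
    asymptote: float  # z_inf for exponential; value at the last visit for linear
    label: str = ""  # fast | slow | impaired


@dataclass
class BehavioralPCAResult:
    """Column-centered PCA of a subjects x visits matrix.

    ``time_courses[:, i]`` is the i-th principal component time course (unit
    norm over visits); ``scores[s, i]`` the expression coefficient of subject
    ``s`` on it; ``variance_fractions`` sum to 1 over all components;
    ``retained`` indexes the components passing Kaiser-Guttmann.
    """

    time_courses: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    variance_fractions: np.ndarray
    eigenvalues: np.ndarray
    retained: np.ndarray
    column_means: np.ndarray

    @property
    def n_components(self) -> int:
        return self.singular_values.size


def impute_missing(matrix: np.ndarray) -> np.ndarray:
    """Replace NaN cells by the mean of observed values in their column.

    Mirrors the study convention of substituting a missed visit by the mean
    over all patients at that time point.  Observed cells are untouched.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a patients x visits matrix")
    observed = ~np.isnan(matrix)
    if not observed.any(axis=0).all():
        bad = np.where(~observed.any(axis=0))[0]
        raise ValueError(f"column(s) {bad.tolist()} have no observed value")
    out = matrix.copy()
    col_means = np.nanmean(matrix, axis=0)
    rr, cc = np.where(~observed)
    out[rr, cc] = col_means[cc]
    return out


def _aic(rss: float, n: int, k: int) -> float:
    return 2 * k + n * np.log(max(rss, _RSS_FLOOR) / n)


def _exp_model(t, z_inf, amplitude, tau):
    return z_inf - amplitude * np.exp(-t / tau)


def _profile_rss(tau: float, t: np.ndarray, z: np.ndarray):
    """For fixed tau the model is linear in (z_inf, amplitude): solve the
    2x2 normal equations and return (rss, z_inf, amplitude)."""
    e = np.exp(-t / tau)
    A = np.column_stack([np.ones_like(t), -e])
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < 2:
        return np.inf, np.nan, np.nan
    rss = float(np.sum((z - A @ coef) ** 2))
    return rss, float(coef[0]), float(coef[1])


def _fit_exponential(days: np.ndarray, z: np.ndarray):
    """Separable nonlinear least squares: multi-start over the tau grid with
    the linear parameters profiled out, then a local refinement of tau.
    Returns ((z_inf, amplitude, tau), rss), or None on degenerate input."""
    span = days[-1] - days[0]
    taus = sorted(set(TAU_STARTS) | {span / 4, span, 4 * span})
    best_tau, best = None, (np.inf, np.nan, np.nan)
    for tau in taus:
        res = _profile_rss(tau, days, z)
        if res[0] < best[0]:
            best_tau, best = tau, res
    if best_tau is None or not np.isfinite(best[0]):
        return None
    try:
        opt = minimize_scalar(
            lambda lt: _profile_rss(np.exp(lt), days, z)[0],
            bracket=(np.log(best_tau / 3), np.log(best_tau), np.log(best_tau * 3)),
            method="brent",
            options={"xtol": 1e-6},
        )
    except (ValueError, RuntimeError):
        opt = None
    if opt is not None and np.isfinite(opt.fun) and opt.fun <= best[0]:
        best_tau = float(np.exp(np.clip(opt.x, np.log(1e-6), np.log(1e7))))
        best = _profile_rss(best_tau, days, z)
    rss, z_inf, amplitude = best
    return (z_inf, amplitude, best_tau), rss


def fit_recovery_models(series, days, patient_id: str = "") -> RecoveryFit:
    """Fit linear and exponential trajectory models and select by AIC.

    Requires >= 4 observations (the exponential has 3 parameters).  NaN cells
    are dropped pairwise.  Ties (AIC difference below 1e-9) go to the linear
    family, as do cases where no exponential start converges.
    """
    z = np.asarray(series, dtype=float)
    t = np.asarray(days, dtype=float)
    keep = ~np.isnan(z)
    z, t = z[keep], t[keep]
    n = z.size
    if n < 4:
        raise ValueError(f"need >= 4 observations, got {n}")
    t_last = float(np.asarray(days, dtype=float)[-1])

    slope, intercept = np.polyfit(t, z, 1)
    rss_lin = float(np.sum((z - (intercept + slope * t)) ** 2))
    aic_lin = _aic(rss_lin, n, 2)

    exp_fit = _fit_exponential(t, z)
    if exp_fit is None:
        warnings.warn(f"exponential fit failed for {patient_id or 'series'}; using linear")
        aic_exp = np.inf
    else:
        (z_inf, amplitude, tau), rss_exp = exp_fit
        aic_exp = _aic(rss_exp, n, 3)

    if exp_fit is not None and aic_exp < aic_lin - 1e-9:
        fit = RecoveryFit(
            patient_id=patient_id,
            family="exponential",
            params={"asymptote": float(z_inf), "amplitude": float(amplitude), "tau": float(tau)},
            rss=rss_exp,
            aic=aic_exp,
            aic_linear=aic_lin,
            aic_exponential=aic_exp,
            asymptote=float(z_inf),
        )
    else:
        fit = RecoveryFit(
            patient_id=patient_id,
            family="linear",
            params={"intercept": float(intercept), "slope": float(slope)},
            rss=rss_lin,
            aic=aic_lin,
            aic_linear=aic_lin,
            aic_exponential=float(aic_exp),
            asymptote=float(intercept + slope * t_last),
        )
    fit.label = classify_recovery(fit)
    return fit


def classify_recovery(fit: RecoveryFit, strict_fast: bool = False) -> str:
    """Subgroup label from a fitted trajectory.

    linear -> ``fast``; exponential with asymptote >= -2.5 -> ``slow``;
    exponential with asymptote < -2.5 -> ``impaired``.  With ``strict_fast``
    a linear fit additionally requires a baseline within the normal band
    (intercept >= -2.5) to count as fast, otherwise it is labeled ``slow``.
    """
    if fit.family == "linear":
        if strict_fast and fit.params.get("intercept", 0.0) < -NORMAL_BAND_Z:
            return "slow"
        return "fast"
    return "slow" if fit.asymptote >= -NORMAL_BAND_Z else "impaired"


def behavioral_pca(matrix: np.ndarray) -> BehavioralPCAResult:
    """Column-centered (covariance) PCA of a completed subjects x visits matrix.

    Columns are centered but not scaled.  Variance fraction of component i is
    s_i^2 / sum(s^2); the eigenvalue s_i^2 / (n - 1) is compared against the
    mean eigenvalue for Kaiser-Guttmann retention.  The sign of each time
    course is fixed so its largest-magnitude element is positive.  A constant
    matrix yields an empty result.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("expected a subjects x visits matrix with >= 2 rows and columns")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing cells; impute first")
    col_means = X.mean(axis=0)
    Xc = X - col_means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 1e-28:
        empty = np.empty((0,))
        return BehavioralPCAResult(
            time_courses=np.empty((X.shape[1], 0)),
            scores=np.empty((X.shape[0], 0)),
            singular_values=empty,
            variance_fractions=empty,
            eigenvalues=empty,
            retained=np.empty((0,), dtype=int),
            column_means=col_means,
        )
    flip = np.sign(Vt[np.arange(s.size), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * s  # projections of the centered rows onto the time courses
    eigenvalues = s**2 / (X.shape[0] - 1)
    retained = np.where(eigenvalues > eigenvalues.mean())[0]
    return BehavioralPCAResult(
        time_courses=Vt.T,
        scores=scores,
        singular_values=s,
        variance_fractions=s**2 / total,
        eigenvalues=eigenvalues,
        retained=retained,
        column_means=col_means,
    )
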
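"""Longitudinal trajectory smoothing: penalized spline + subject intercepts.

The longitudinal trend of a network metric is modeled as

    y_ij = f(month_ij) + u_i + eps_ij,   u_i ~ N(0, tau_u),  eps ~ N(0, sigma2)

with f a penalized truncated-power cubic spline in its mixed-model form:
fixed part [1, t], and k - 2 knot terms (t - kappa)_+^3 entering as i.i.d.
random coefficients whose variance is the inverse smoothing parameter.
Smoothness is estimated by REML (profiled over the two variance ratios);
the basis dimension k is chosen by minimum BIC over a candidate list.

The effective degrees of freedom (edf) of the smooth approach 1 when the
data are linear in time (the penalty shrinks all knot terms away) and grow
toward k - 1 as the fitted curve wiggles.  The reported ``p_smooth`` tests
the flat-curve null via a truncated Wald statistic on the smooth
coefficients, with rank matched to the edf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._mixed import pd_unique

__all__ = ["TrajectoryFit", "fit_trajectory"]

_LOG_PSI_BOUNDS = (-15.0, 15.0)


@dataclass
class TrajectoryFit:
    fitted_curve: pd.DataFrame          # columns: month, fit
    edf: float                          # effective df of the smooth (excl. intercept)
    p_smooth: float
    k_selected: int
    bic: float
    subject_intercepts: pd.Series
    slope: float                        # linear trend component, per month
    slope_se: float
    tau_smooth: float
    tau_subject: float
    sigma2: float
    bic_by_k: dict[int, float] | None = None


def _spline_basis(t01: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed part [1, t], knot basis (t - kappa)_+^3, and the knots."""
    x = np.column_stack([np.ones_like(t01), t01])
    n_knots = k - 2
    # interior knots at equally spaced quantile positions of the unit interval
    knots = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
    z = np.maximum(t01[:, None] - knots[None, :], 0.0) ** 3
    return x, z, knots


def _reml_criterion(
    log_psi: np.ndarray, x: np.ndarray, zs: np.ndarray, zu: np.ndarray, y: np.ndarray
) -> float:
    psi_s, psi_u = np.exp(np.clip(log_psi, *_LOG_PSI_BOUNDS))
    n, p = x.shape
    v0 = np.eye(n) + psi_s * (zs @ zs.T) + psi_u * (zu @ zu.T)
    try:
        l_v = np.linalg.cholesky(v0)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * float(np.log(np.diag(l_v)).sum())
    vi_x = np.linalg.solve(v0, x)
    vi_y = np.linalg.solve(v0, y)
    xtvx = x.T @ vi_x
    beta = np.linalg.solve(xtvx, x.T @ vi_y)
    r = y - x @ beta
    quad = float(r @ np.linalg.solve(v0, r))
    if quad <= 0:
        return np.inf
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdet_v + logdet_x + (n - p) * np.log(quad))


def _optimize_psis(x, zs, zu, y) -> tuple[float, float]:
    grid = np.linspace(-10.0, 10.0, 6)
    best, best_val = None, np.inf
    for a in grid:
        for b in grid:
            val = _reml_criterion(np.array([a, b]), x, zs, zu, y)
            if val < best_val:
                best, best_val = np.array([a, b]), val
    res = optimize.minimize(
        _reml_criterion, best, args=(x, zs, zu, y), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    out = res.x if res.fun <= best_val else best
    return tuple(float(np.exp(np.clip(v, *_LOG_PSI_BOUNDS))) for v in out)


def _fit_one_k(
    t01: np.ndarray, y: np.ndarray, zu: np.ndarray, k: int
) -> dict:
    x, zs, knots = _spline_basis(t01, k)
    n, p = x.shape
    psi_s, psi_u = _optimize_psis(x, zs, zu, y)

    v0 = np.eye(n) + psi_s * (zs @ zs.T) + psi_u * (zu @ zu.T)
    vi_x = np.linalg.solve(v0, x)
    xtvx = x.T @ vi_x
    beta_gls = np.linalg.solve(xtvx, x.T @ np.linalg.solve(v0, y))
    r = y - x @ beta_gls
    quad = float(r @ np.linalg.solve(v0, r))
    sigma2 = quad / (n - p)

    # ridge form of the curve fit: penalize knot coefficients by 1/psi_s,
    # whiten by the subject-intercept covariance
    c = np.column_stack([x, zs])
    w = np.linalg.inv(np.eye(n) + psi_u * (zu @ zu.T))
    ctwc = c.T @ w @ c
    pen = np.zeros(c.shape[1])
    pen[p:] = 1.0 / max(psi_s, np.exp(_LOG_PSI_BOUNDS[0]))
    m = ctwc + np.diag(pen)
    m_inv = np.linalg.inv(m)
    theta = m_inv @ (c.T @ (w @ y))
    f_mat = m_inv @ ctwc
    edf_total = float(np.trace(f_mat))
    edf_smooth = edf_total - 1.0

    cov_theta = sigma2 * (m_inv @ ctwc @ m_inv)

    # flat-curve Wald test on the smooth coefficients (slope + knot terms),
    # rank-truncated to match the edf
    theta_c = theta[1:]
    cov_c = cov_theta[1:, 1:]
    rank = max(1, int(round(edf_smooth)))
    evals, evecs = np.linalg.eigh(cov_c)
    order = np.argsort(evals)[::-1]
    keep = order[:rank]
    proj = evecs[:, keep].T @ theta_c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = float(np.sum(proj**2 / np.maximum(evals[keep], 1e-300)))
    p_smooth = float(stats.chi2.sf(t_stat, rank))

    # ML log-likelihood at the plug-in estimates, for the BIC used in k selection
    v0_full = np.eye(n) + psi_s * (zs @ zs.T) + psi_u * (zu @ zu.T)
    sign, logdet = np.linalg.slogdet(v0_full)
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + quad / sigma2)
    df_bic = edf_total + 2.0  # curve df + two variance components
    bic = -2.0 * ll + df_bic * np.log(n)

    # subject-intercept BLUPs
    resid_curve = y - c @ theta
    u_blup = psi_u * (zu.T @ (w @ resid_curve))

    return {
        "k": k, "theta": theta, "cov_theta": cov_theta, "edf": edf_smooth,
        "p_smooth": p_smooth, "bic": float(bic), "sigma2": sigma2,
        "tau_smooth": psi_s * sigma2, "tau_subject": psi_u * sigma2,
        "u_blup": u_blup, "knots": knots, "p_fixed": p,
    }


def fit_trajectory(
    metric: Sequence[float],
    months: Sequence[float],
    subject: Sequence[str],
    k_candidates: Sequence[int] | None = None,
    n_curve_points: int = 101,
) -> TrajectoryFit:
    """Fit the longitudinal trajectory of a metric with REML smoothing.

    ``k_candidates`` are candidate basis dimensions (each between 3 and the
    number of distinct time values); the fit minimizing BIC is returned.
    """
    y = np.asarray(metric, dtype=float)
    t = np.asarray(months, dtype=float)
    subj = np.asarray(subject)
    if not (len(y) == len(t) == len(subj)):
        raise ValueError("metric, months and subject must have equal length")
    uniq_t = np.unique(t)
    if uniq_t.size < 4:
        raise ValueError(f"need >= 4 distinct time values, got {uniq_t.size}")
    if k_candidates is None:
        k_candidates = list(range(3, min(uniq_t.size, 8) + 1))
    k_candidates = sorted(int(k) for k in k_candidates)
    if k_candidates[0] < 3 or k_candidates[-1] > uniq_t.size:
        raise ValueError(
            f"k_candidates must lie in [3, {uniq_t.size}] (distinct time values)"
        )

    t0, t_range = float(t.min()), float(np.ptp(t))
    t01 = (t - t0) / t_range
    subjects = pd_unique(subj)
    zu = (subj[:, None] == subjects[None, :]).astype(float)

    fits = [_fit_one_k(t01, y, zu, k) for k in k_candidates]
    bics = {f["k"]: f["bic"] for f in fits}
    best = min(fits, key=lambda f: (f["bic"], f["k"]))

    grid01 = np.linspace(0.0, 1.0, n_curve_points)
    xg = np.column_stack([np.ones_like(grid01), grid01])
    zg = np.maximum(grid01[:, None] - best["knots"][None, :], 0.0) ** 3
    cg = np.column_stack([xg, zg])
    curve = pd.DataFrame({"month": t0 + t_range * grid01, "fit": cg @ best["theta"]})

    slope_std = float(best["theta"][1])
    slope_se_std = float(np.sqrt(best["cov_theta"][1, 1]))

    return TrajectoryFit(
        fitted_curve=curve,
        edf=float(best["edf"]),
        p_smooth=float(best["p_smooth"]),
        k_selected=int(best["k"]),
        bic=float(best["bic"]),
        subject_intercepts=pd.Series(best["u_blup"], index=list(subjects)),
        slope=slope_std / t_range,
        slope_se=slope_se_std / t_range,
        tau_smooth=float(best["tau_smooth"]),
        tau_subject=float(best["tau_subject"]),
        sigma2=float(best["sigma2"]),
        bic_by_k=bics,
    )
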
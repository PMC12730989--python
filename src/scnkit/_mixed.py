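"""Internals for random-intercept linear mixed models.

Closed-form per-cluster REML quantities for the model

    y_i = X_i beta + 1 u_i + eps_i,   u_i ~ N(0, tau),  eps_i ~ N(0, sigma2 I)

using the Woodbury identity V_i^{-1} = (1/sigma2)(I - tau/(sigma2 + n_i tau) J),
plus a Satterthwaite-type small-sample degrees-of-freedom approximation for
fixed-effect contrasts: df = 2 f^2 / Var(f) with f = c' Cov(beta) c, the
variance of f obtained by the delta method from the numeric Hessian of the
REML criterion in (tau, sigma2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusteredData", "reml_neg_loglik", "beta_cov", "gls_beta", "SatterthwaiteEngine"]


@dataclass
class ClusteredData:
    """Fixed-effect design and response split by cluster (subject)."""

    xs: list[np.ndarray]
    ys: list[np.ndarray]

    @classmethod
    def from_arrays(cls, x: np.ndarray, y: np.ndarray, groups: np.ndarray) -> "ClusteredData":
        xs, ys = [], []
        for g in pd_unique(groups):
            m = groups == g
            xs.append(np.asarray(x[m], dtype=float))
            ys.append(np.asarray(y[m], dtype=float))
        return cls(xs, ys)

    @property
    def n_obs(self) -> int:
        return sum(len(y) for y in self.ys)

    @property
    def n_params(self) -> int:
        return self.xs[0].shape[1]


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance (stable cluster order)."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def _vinv_apply(a: np.ndarray, tau: float, s2: float) -> np.ndarray:
    """Compute V^{-1} a for V = s2 I + tau J without forming V."""
    n = a.shape[0]
    shrink = tau / (s2 + n * tau)
    return (a - shrink * a.sum(axis=0, keepdims=True) * np.ones((n, 1))) / s2


def _xtvx_xtvy(data: ClusteredData, tau: float, s2: float) -> tuple[np.ndarray, np.ndarray]:
    p = data.n_params
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for x, y in zip(data.xs, data.ys):
        vix = _vinv_apply(x, tau, s2)
        xtvx += x.T @ vix
        xtvy += vix.T @ y
    return xtvx, xtvy


def gls_beta(data: ClusteredData, tau: float, s2: float) -> np.ndarray:
    xtvx, xtvy = _xtvx_xtvy(data, tau, s2)
    return np.linalg.solve(xtvx, xtvy)


def beta_cov(data: ClusteredData, tau: float, s2: float) -> np.ndarray:
    xtvx, _ = _xtvx_xtvy(data, tau, s2)
    return np.linalg.inv(xtvx)


def reml_neg_loglik(data: ClusteredData, tau: float, s2: float) -> float:
    """Negative restricted log-likelihood (up to an additive constant)."""
    if s2 <= 0 or tau < 0:
        return np.inf
    xtvx, xtvy = _xtvx_xtvy(data, tau, s2)
    beta = np.linalg.solve(xtvx, xtvy)
    logdet_v = 0.0
    quad = 0.0
    for x, y in zip(data.xs, data.ys):
        n_i = len(y)
        logdet_v += (n_i - 1) * np.log(s2) + np.log(s2 + n_i * tau)
        r = y - x @ beta
        quad += float(r @ _vinv_apply(r[:, None], tau, s2).ravel())
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdet_v + logdet_x + quad)


class SatterthwaiteEngine:
    """Satterthwaite df for fixed-effect contrasts of a fitted model.

    Precomputes Cov(beta), its numeric derivatives with respect to the
    variance parameters, and the variance-parameter covariance (inverse
    numeric Hessian of the REML criterion), so per-contrast df are cheap.
    Falls back to the residual df N - p when the Hessian is not usable
    (e.g. the random-effect variance sits on the zero boundary).
    """

    def __init__(self, data: ClusteredData, tau: float, s2: float) -> None:
        self.data = data
        self.tau = float(tau)
        self.s2 = float(s2)
        self.resid_df = data.n_obs - data.n_params
        self.cov_beta = beta_cov(data, self.tau, self.s2)
        h_tau = max(1e-6, 1e-4 * max(self.tau, self.s2))
        h_s2 = max(1e-6, 1e-4 * self.s2)
        self._dcov_dtau = self._cov_derivative(0, h_tau)
        self._dcov_ds2 = self._cov_derivative(1, h_s2)
        self.varcov_theta = self._theta_covariance(h_tau, h_s2)

    def _cov_at(self, tau: float, s2: float) -> np.ndarray:
        return beta_cov(self.data, max(tau, 0.0), max(s2, 1e-12))

    def _cov_derivative(self, which: int, h: float) -> np.ndarray:
        t, s = self.tau, self.s2
        if which == 0:
            hi = self._cov_at(t + h, s)
            lo = self._cov_at(max(t - h, 0.0), s)
            span = (t + h) - max(t - h, 0.0)
        else:
            hi = self._cov_at(t, s + h)
            lo = self._cov_at(t, max(s - h, 1e-12))
            span = (s + h) - max(s - h, 1e-12)
        return (hi - lo) / span

    def _theta_covariance(self, h_tau: float, h_s2: float) -> np.ndarray | None:
        def f(tau: float, s2: float) -> float:
            return reml_neg_loglik(self.data, max(tau, 0.0), max(s2, 1e-12))

        t, s = self.tau, self.s2
        hess = np.empty((2, 2))
        f0 = f(t, s)
        hess[0, 0] = (f(t + h_tau, s) - 2 * f0 + f(max(t - h_tau, 0.0), s)) / h_tau**2
        hess[1, 1] = (f(t, s + h_s2) - 2 * f0 + f(t, max(s - h_s2, 1e-12))) / h_s2**2
        fpp = f(t + h_tau, s + h_s2)
        fpm = f(t + h_tau, max(s - h_s2, 1e-12))
        fmp = f(max(t - h_tau, 0.0), s + h_s2)
        fmm = f(max(t - h_tau, 0.0), max(s - h_s2, 1e-12))
        hess[0, 1] = hess[1, 0] = (fpp - fpm - fmp + fmm) / (4 * h_tau * h_s2)
        if not np.all(np.isfinite(hess)):
            return None
        try:
            eigvals = np.linalg.eigvalsh(hess)
            if eigvals.min() <= 0:
                return None
            return np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None

    def df_for_contrast(self, c: np.ndarray) -> float:
        """Satterthwaite df for the scalar contrast c' beta."""
        c = np.asarray(c, dtype=float)
        f_val = float(c @ self.cov_beta @ c)
        if self.varcov_theta is None or f_val <= 0:
            return float(self.resid_df)
        g = np.array([c @ self._dcov_dtau @ c, c @ self._dcov_ds2 @ c])
        var_f = float(g @ self.varcov_theta @ g)
        if var_f <= 0:
            return float(self.resid_df)
        df = 2.0 * f_val**2 / var_f
        return float(np.clip(df, 1.0, self.resid_df))
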
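"""Linear mixed model with a single random intercept, fit by REML.

The model is

    y = X beta + Z u + e,   u ~ N(0, sigma_g^2 I_q),   e ~ N(0, sigma_e^2 I_n)

where Z is the indicator matrix of a grouping factor with q levels (here:
plant genotype, whose labels are unique within population so that a single
random intercept realizes "genotype nested within population").  The
variance ratio lambda = sigma_g^2 / sigma_e^2 is profiled out of the
restricted likelihood and optimized on a log scale; beta and sigma_e^2 then
follow in closed form via generalized least squares.

Wald F tests for single-degree-of-freedom contrasts use a Satterthwaite
approximation to the denominator degrees of freedom, computed from numerical
derivatives of the contrast variance with respect to the variance components
and the observed information of the restricted likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMFit", "ContrastTest", "fit_lmm"]

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class ContrastTest:
    """Wald test of a single linear contrast of the fixed effects."""

    estimate: float
    se: float
    F: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class LMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    n_obs: int
    n_groups: int
    rank: int
    converged: bool
    exog_names: list[str] = field(default_factory=list)
    # internals needed for Satterthwaite df
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _group_idx: np.ndarray | None = None
    _group_sizes: np.ndarray | None = None

    @property
    def residual_df(self) -> float:
        return self.n_obs - self.rank

    def contrast_test(self, L: np.ndarray) -> ContrastTest:
        """Wald F test for the 1-df contrast L @ beta with Satterthwaite df."""
        L = np.asarray(L, dtype=float).ravel()
        est = float(L @ self.beta)
        var = float(L @ self.cov_beta @ L)
        if var <= 0:
            raise np.linalg.LinAlgError("non-positive contrast variance")
        F = est * est / var
        df_den = self._satterthwaite_df(L, var)
        p = float(stats.f.sf(F, 1, df_den))
        return ContrastTest(est, float(np.sqrt(var)), float(F), 1, float(df_den), p)

    # -- Satterthwaite machinery ------------------------------------------

    def _contrast_var(self, L: np.ndarray, sigma2_g: float, sigma2_e: float) -> float:
        lam = sigma2_g / sigma2_e
        XtWX, _, _, _ = _whitened_moments(lam, self._X, self._y, self._group_idx, self._group_sizes)
        C = sigma2_e * np.linalg.inv(XtWX)
        return float(L @ C @ L)

    def _satterthwaite_df(self, L: np.ndarray, var: float) -> float:
        n, p = self.n_obs, self.rank
        resid_df = n - p
        theta = np.array([self.sigma2_group, self.sigma2_resid])
        if self._X is None or theta[0] <= 1e-10 * theta[1]:
            # variance hit the boundary: the model degenerates to OLS
            return float(resid_df)
        # gradient of the contrast variance w.r.t. (sigma_g^2, sigma_e^2)
        g = np.zeros(2)
        for i in range(2):
            h = 1e-4 * theta[i]
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            g[i] = (self._contrast_var(L, *tp) - self._contrast_var(L, *tm)) / (2 * h)
        # observed information of the restricted likelihood
        H = _numeric_hessian(
            lambda t: _minus2_restricted_loglik(t[0], t[1], self._X, self._y, self._group_idx, self._group_sizes),
            theta,
        )
        try:
            var_theta = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(resid_df)
        denom = float(g @ var_theta @ g)
        if denom <= 0 or not np.isfinite(denom):
            return float(resid_df)
        df = 2.0 * var * var / denom
        return float(np.clip(df, 1.0, resid_df))


def _whitened_moments(lam, X, y, group_idx, group_sizes):
    """Moments under W = (I + lam Z Z')^{-1}, using the Woodbury identity.

    Returns X'WX, X'Wy, y'Wy and log|I + lam Z Z'|.
    """
    q = group_sizes.shape[0]
    p = X.shape[1]
    c = lam / (1.0 + lam * group_sizes)  # per-group shrinkage weight
    Sx = np.zeros((q, p))
    np.add.at(Sx, group_idx, X)
    Sy = np.bincount(group_idx, weights=y, minlength=q)
    XtWX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtWy = X.T @ y - Sx.T @ (c * Sy)
    ytWy = float(y @ y - np.sum(c * Sy * Sy))
    logdet = float(np.sum(np.log1p(lam * group_sizes)))
    return XtWX, XtWy, ytWy, logdet


def _profiled_criterion(lam, X, y, group_idx, group_sizes):
    n, p = X.shape
    XtWX, XtWy, ytWy, logdet = _whitened_moments(lam, X, y, group_idx, group_sizes)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), 1e-300)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    return (n - p) * np.log(rss) + logdet + logdet_xwx


def _minus2_restricted_loglik(sigma2_g, sigma2_e, X, y, group_idx, group_sizes):
    """-2 restricted log-likelihood (up to an additive constant)."""
    if sigma2_g < 0 or sigma2_e <= 0:
        return np.inf
    n, p = X.shape
    lam = sigma2_g / sigma2_e
    XtWX, XtWy, ytWy, logdet = _whitened_moments(lam, X, y, group_idx, group_sizes)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), 1e-300)
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    return (n - p) * np.log(sigma2_e) + logdet + logdet_xwx + rss / sigma2_e


def _numeric_hessian(fun, theta, rel_step=1e-4):
    k = theta.shape[0]
    h = rel_step * np.maximum(np.abs(theta), 1e-12)
    H = np.zeros((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            if i == j:
                tp = theta.copy(); tp[i] += h[i]
                tm = theta.copy(); tm[i] -= h[i]
                H[i, i] = (fun(tp) - 2 * f0 + fun(tm)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (fun(tpp) - fun(tpm) - fun(tmp) + fun(tmm)) / (4 * h[i] * h[j])
    return H


def fit_lmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    exog_names: list[str] | None = None,
    force_zero_variance: bool = False,
) -> LMMFit:
    """Fit the random-intercept model by REML.

    Parameters
    ----------
    X
        Fixed-effects design matrix (n x p), full column rank required.
    y
        Response vector.
    groups
        Grouping labels (one random intercept per distinct label).
    force_zero_variance
        Pin sigma_g^2 = 0, reducing the fit to ordinary least squares; used
        to check the mixed model against a fixed-effects ANOVA.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("fixed-effects design matrix is rank deficient")
    labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    group_sizes = np.bincount(group_idx).astype(float)
    q = labels.shape[0]
    if n <= p:
        raise ValueError("not enough observations for the fixed-effects design")

    converged = True
    if force_zero_variance or q < 2:
        lam_hat = 0.0
    else:
        res = optimize.minimize_scalar(
            lambda t: _profiled_criterion(np.exp(t), X, y, group_idx, group_sizes),
            bounds=_LOG_LAMBDA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-8},
        )
        converged = bool(res.success)
        if not converged:
            raise RuntimeError(f"REML optimization did not converge: {res.message}")
        lam_hat = float(np.exp(res.x))
        # compare against the sigma_g^2 = 0 boundary
        if _profiled_criterion(0.0, X, y, group_idx, group_sizes) <= res.fun:
            lam_hat = 0.0

    XtWX, XtWy, ytWy, _ = _whitened_moments(lam_hat, X, y, group_idx, group_sizes)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), 0.0)
    sigma2_e = rss / (n - p)
    sigma2_g = lam_hat * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(XtWX)

    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_group=float(sigma2_g),
        sigma2_resid=float(sigma2_e),
        n_obs=n,
        n_groups=q,
        rank=p,
        converged=converged,
        exog_names=list(exog_names) if exog_names else [f"x{i}" for i in range(p)],
        _X=X,
        _y=y,
        _group_idx=group_idx,
        _group_sizes=group_sizes,
    )
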
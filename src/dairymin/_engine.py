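"""Closed-form marginal likelihood machinery for weighted Gaussian mixed models.

Every model fitted in this package shares one structure::

    y_i = m_i(theta) + u_{j(i)} [+ v_{j(i)} * x_i] + e_i

with a Gaussian random study intercept ``u_j ~ N(0, var_u)`` (optionally a
random study slope ``v_j``) and heteroscedastic residuals
``e_i ~ N(0, var_e / w_i)`` where ``w_i`` is the observation weight. Because
the random effects enter additively, the per-study marginal distribution is
multivariate normal with covariance ``diag(var_e / w) + Z G Z'`` and the
marginal likelihood is available in closed form through rank-one (rank-two)
Woodbury identities -- no numerical integration is required. Gauss--Hermite
quadrature of the conditional likelihood is kept as an independent
cross-check (`nll_gauss_hermite`).

Weights act as residual-precision scalers: ``Var(e_i) = var_e / w_i``.
Rescaling all weights by a common factor is absorbed by ``var_e`` and leaves
the fit invariant.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special, stats

_LOG2PI = np.log(2.0 * np.pi)
_LOGVAR_BOUNDS = (-25.0, 6.0)


class ConvergenceError(RuntimeError):
    """Raised when optimization fails; carries the best fit found so far."""

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit


def group_codes(study_ids):
    """Integer codes (0..G-1) for the study labels, plus the group count."""
    _, codes = np.unique(np.asarray(study_ids), return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1 if len(codes) else 0


def nll_independent(resid, d):
    """-log L of independent Gaussians with variances d (no random effect)."""
    resid = np.asarray(resid, float)
    d = np.asarray(d, float)
    return 0.5 * (np.sum(np.log(d)) + np.sum(resid * resid / d)
                  + resid.size * _LOG2PI)


def nll_random_intercept(resid, d, codes, n_groups, var_u):
    """-log L with a shared N(0, var_u) intercept within each group.

    Uses the rank-one Woodbury identity per group:
    ``Sigma_j = diag(d) + var_u * 11'``.
    """
    resid = np.asarray(resid, float)
    d = np.asarray(d, float)
    inv_d = 1.0 / d
    b = np.bincount(codes, weights=inv_d, minlength=n_groups)
    a = np.bincount(codes, weights=resid * inv_d, minlength=n_groups)
    denom = 1.0 + var_u * b
    quad = np.sum(resid * resid * inv_d) - var_u * np.sum(a * a / denom)
    logdet = np.sum(np.log(d)) + np.sum(np.log(denom))
    return 0.5 * (logdet + quad + resid.size * _LOG2PI)


def nll_random_intercept_slope(resid, x, d, codes, n_groups, var_u, var_v):
    """-log L with random intercept and random slope per group.

    ``Sigma_j = diag(d) + Z G Z'`` with ``Z = [1, x]`` and
    ``G = diag(var_u, var_v)``; reduced to vectorized 2x2 solves.
    """
    resid = np.asarray(resid, float)
    x = np.asarray(x, float)
    d = np.asarray(d, float)
    inv_d = 1.0 / d
    # entries of Z' D^-1 Z and Z' D^-1 r per group
    s11 = np.bincount(codes, weights=inv_d, minlength=n_groups)
    s12 = np.bincount(codes, weights=x * inv_d, minlength=n_groups)
    s22 = np.bincount(codes, weights=x * x * inv_d, minlength=n_groups)
    r1 = np.bincount(codes, weights=resid * inv_d, minlength=n_groups)
    r2 = np.bincount(codes, weights=resid * x * inv_d, minlength=n_groups)
    # M = G^-1 + Z' D^-1 Z  (2x2 per group)
    m11 = 1.0 / var_u + s11
    m12 = s12
    m22 = 1.0 / var_v + s22
    det_m = m11 * m22 - m12 * m12
    # quadratic form: r' D^-1 r - (Z'D^-1 r)' M^-1 (Z'D^-1 r)
    quad_corr = (m22 * r1 * r1 - 2.0 * m12 * r1 * r2 + m11 * r2 * r2) / det_m
    quad = np.sum(resid * resid * inv_d) - np.sum(quad_corr)
    # log|Sigma| = log|D| + log|G| + log|M|
    logdet = (np.sum(np.log(d))
              + n_groups * (np.log(var_u) + np.log(var_v))
              + np.sum(np.log(det_m)))
    return 0.5 * (logdet + quad + resid.size * _LOG2PI)


def nll_gauss_hermite(resid, d, codes, n_groups, var_u, n_nodes=40):
    """Adaptive Gauss--Hermite evaluation of the random-intercept -log L.

    Integrates the conditional likelihood over u numerically, with the
    quadrature recentered at each study's posterior mode and rescaled by
    its posterior SD (the adaptive scheme). Agrees with
    `nll_random_intercept` to quadrature accuracy and serves as the
    independent check of the closed form.
    """
    resid = np.asarray(resid, float)
    d = np.asarray(d, float)
    inv_d = 1.0 / d
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    # posterior mode and SD of u_j given the residuals (Gaussian case)
    b = np.bincount(codes, weights=inv_d, minlength=n_groups)
    a = np.bincount(codes, weights=resid * inv_d, minlength=n_groups)
    mode = var_u * a / (1.0 + var_u * b)
    post_sd = np.sqrt(1.0 / (1.0 / var_u + b))
    # u at node k for study j: mode_j + sqrt(2) * post_sd_j * t_k
    u_vals = mode[None, :] + np.sqrt(2.0) * post_sd[None, :] * nodes[:, None]
    per_study = np.empty((n_nodes, n_groups))
    for k in range(n_nodes):
        dev = resid - u_vals[k][codes]
        log_f = -0.5 * (dev * dev * inv_d + np.log(d) + _LOG2PI)
        per_study[k] = np.bincount(codes, weights=log_f, minlength=n_groups)
    # prior density of u at the nodes
    log_prior = -0.5 * (u_vals * u_vals / var_u + np.log(var_u) + _LOG2PI)
    # int g(u) du ~= sqrt(2)*s * sum_k w_k exp(t_k^2) g(mode + sqrt(2)*s*t_k)
    log_terms = (np.log(weights)[:, None] + nodes[:, None] ** 2
                 + per_study + log_prior)
    log_lj = special.logsumexp(log_terms, axis=0)
    log_lj += 0.5 * np.log(2.0) + np.log(post_sd)
    return -float(np.sum(log_lj))


@dataclasses.dataclass
class MarginalFit:
    """Result of maximizing a closed-form marginal likelihood."""

    theta: np.ndarray
    se_theta: np.ndarray
    p_theta: np.ndarray
    var_study: float
    var_resid: float
    loglik: float
    converged: bool
    n_obs: int
    n_studies: int
    boundary_var_study: bool
    cov: np.ndarray | None = None


def _numeric_hessian(fun, p, step=1e-4):
    """Central-difference Hessian of ``fun`` at ``p``."""
    p = np.asarray(p, float)
    k = p.size
    h = step * (1.0 + np.abs(p))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            f_pp = fun(p + ei + ej)
            f_pm = fun(p + ei - ej)
            f_mp = fun(p - ei + ej)
            f_mm = fun(p - ei - ej)
            hess[i, j] = hess[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    return hess


def fit_random_intercept(mean_fn, starts, y, weights, study_ids, *,
                         theta_bounds=None, df=None, gtol=1e-8,
                         boundary_tol=1e-8):
    """Maximize the weighted random-intercept marginal likelihood.

    Parameters
    ----------
    mean_fn : callable(theta) -> array of means, one per observation.
    starts : sequence of starting theta vectors (multi-start).
    y, weights, study_ids : observation vectors, equal length.
    theta_bounds : optional list of (lo, hi) per mean parameter.
    df : degrees of freedom for Wald t p-values (default n_studies - 1).

    Returns a `MarginalFit`; raises `ConvergenceError` if no start converges.
    """
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("all weights must be > 0")
    codes, n_groups = group_codes(study_ids)
    if n_groups < 2:
        raise ValueError("at least 2 studies are required to identify the "
                         "between-study variance")
    n = y.size
    k = len(np.atleast_1d(starts[0]))

    def unpack(p):
        theta = p[:k]
        var_u = np.exp(p[k])
        var_e = np.exp(p[k + 1])
        return theta, var_u, var_e

    def nll(p):
        theta, var_u, var_e = unpack(p)
        resid = y - mean_fn(theta)
        if not np.all(np.isfinite(resid)):
            return 1e12
        return nll_random_intercept(resid, var_e / w, codes, n_groups, var_u)

    if theta_bounds is None:
        theta_bounds = [(None, None)] * k
    bounds = list(theta_bounds) + [_LOGVAR_BOUNDS, _LOGVAR_BOUNDS]

    best = None
    for theta0 in starts:
        theta0 = np.asarray(theta0, float)
        resid0 = y - mean_fn(theta0)
        if not np.all(np.isfinite(resid0)):
            continue
        grp_mean = np.bincount(codes, weights=resid0, minlength=n_groups)
        grp_mean /= np.bincount(codes, minlength=n_groups)
        var_u0 = max(float(np.var(grp_mean)), 1e-6)
        var_e0 = max(float(np.var(resid0 - grp_mean[codes])), 1e-8)
        p0 = np.concatenate([theta0, [np.log(var_u0), np.log(var_e0)]])
        p0[k:] = np.clip(p0[k:], *_LOGVAR_BOUNDS)
        res = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": gtol})
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError("no valid starting point")
    if not best.success:
        # line searches occasionally terminate abnormally near the optimum;
        # a derivative-free polish settles it
        polish = optimize.minimize(nll, best.x, method="Nelder-Mead",
                                   options={"maxiter": 4000, "fatol": 1e-10,
                                            "xatol": 1e-8})
        if polish.fun <= best.fun + 1e-9:
            polish.x = np.clip(polish.x, [b[0] if b[0] is not None else -np.inf for b in bounds],
                               [b[1] if b[1] is not None else np.inf for b in bounds])
            best = polish

    theta, var_u, var_e = unpack(best.x)
    if not best.success and best.x[k + 1] <= _LOGVAR_BOUNDS[0] + 1e-6:
        # residual variance driven to its floor: a (near-)perfect fit, where
        # the likelihood surface is degenerate but the estimates are valid
        best.success = True
    boundary = bool(best.x[k] <= _LOGVAR_BOUNDS[0] + 1e-6 or var_u < boundary_tol * var_e)

    # Hessian over (theta, log vars); drop the var_u coordinate on boundary.
    active = list(range(k + 2))
    if boundary:
        active.remove(k)

    def nll_active(q):
        p = best.x.copy()
        p[active] = q
        return nll(p)

    hess = _numeric_hessian(nll_active, best.x[active])
    se_theta = np.full(k, np.nan)
    cov_full = None
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        se_theta = np.sqrt(diag[:k])
        cov_full = cov
    except np.linalg.LinAlgError:
        pass

    if df is None:
        df = max(n_groups - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = theta / se_theta
    p_theta = 2.0 * stats.t.sf(np.abs(tstat), df)

    return MarginalFit(
        theta=np.asarray(theta, float),
        se_theta=se_theta,
        p_theta=p_theta,
        var_study=0.0 if boundary else float(var_u),
        var_resid=float(var_e),
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_obs=n,
        n_studies=n_groups,
        boundary_var_study=boundary,
        cov=cov_full,
    )


def profile_loglik_independent(mean_fn, starts, y, weights, *, theta_bounds=None):
    """Maximize the no-random-effect (weighted GLS) likelihood.

    Used as the null model of the random-study likelihood-ratio test.
    Returns (theta_hat, loglik).
    """
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    k = len(np.atleast_1d(starts[0]))

    def nll(p):
        theta = p[:k]
        var_e = np.exp(p[k])
        resid = y - mean_fn(theta)
        if not np.all(np.isfinite(resid)):
            return 1e12
        return nll_independent(resid, var_e / w)

    if theta_bounds is None:
        theta_bounds = [(None, None)] * k
    bounds = list(theta_bounds) + [_LOGVAR_BOUNDS]
    best = None
    for theta0 in starts:
        theta0 = np.asarray(theta0, float)
        resid0 = y - mean_fn(theta0)
        if not np.all(np.isfinite(resid0)):
            continue
        var_e0 = max(float(np.var(resid0)), 1e-8)
        p0 = np.concatenate([theta0, [np.log(var_e0)]])
        res = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError("no valid starting point")
    return best.x[:k], -float(best.fun)


def fit_random_intercept_slope(mean_fn, starts, x_slope, y, weights, study_ids):
    """Maximize the likelihood with random study intercept AND slope.

    Only the log-likelihood is needed downstream (variance-component LRTs),
    so this returns (theta_hat, var_u, var_v, loglik).
    """
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    x_slope = np.asarray(x_slope, float)
    codes, n_groups = group_codes(study_ids)
    if n_groups < 3:
        raise ValueError("at least 3 studies are required")
    k = len(np.atleast_1d(starts[0]))

    def nll(p):
        theta = p[:k]
        var_u, var_v, var_e = np.exp(p[k:])
        resid = y - mean_fn(theta)
        if not np.all(np.isfinite(resid)):
            return 1e12
        return nll_random_intercept_slope(resid, x_slope, var_e / w, codes,
                                          n_groups, var_u, var_v)

    bounds = [(None, None)] * k + [_LOGVAR_BOUNDS] * 3
    best = None
    for theta0 in starts:
        theta0 = np.asarray(theta0, float)
        resid0 = y - mean_fn(theta0)
        var0 = max(float(np.var(resid0)), 1e-8)
        p0 = np.concatenate([theta0, np.log([var0 / 3, var0 / (3 * max(np.var(x_slope), 0.1)), var0 / 3])])
        p0[k:] = np.clip(p0[k:], *_LOGVAR_BOUNDS)
        res = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError("no valid starting point")
    theta = best.x[:k]
    var_u, var_v, _ = np.exp(best.x[k:])
    return theta, float(var_u), float(var_v), -float(best.fun)


def conditional_residual_sd(d, codes, n_groups, var_u):
    """SD of conditional residuals r_i = eps_i - BLUP(u)_{j(i)}.

    For the random-intercept model, Var(r_i) = d_i - s_j with
    s_j = var_u / (1 + var_u * sum_i 1/d_i); derived from the Woodbury form.
    """
    d = np.asarray(d, float)
    inv_d = 1.0 / d
    b = np.bincount(codes, weights=inv_d, minlength=n_groups)
    s = var_u / (1.0 + var_u * b)
    return np.sqrt(np.maximum(d - s[codes], 1e-300))


def blup_intercepts(resid, d, codes, n_groups, var_u):
    """Empirical BLUPs of the study intercepts given marginal residuals."""
    inv_d = 1.0 / np.asarray(d, float)
    b = np.bincount(codes, weights=inv_d, minlength=n_groups)
    a = np.bincount(codes, weights=np.asarray(resid, float) * inv_d,
                    minlength=n_groups)
    return var_u * a / (1.0 + var_u * b)
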
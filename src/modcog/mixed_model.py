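"""Gaussian log-link random-intercept model for Group x Time effects on Q.

The model for participant i at row t (one row per time point and resolution
value) is

    y_it ~ Normal( exp(x_it' beta + b_i), sigma_e^2 ),   b_i ~ Normal(0, sigma_b^2)

with fixed effects x = (1, group, time, group x time), group coded UAA = 0 /
AE = 1 and time pre = 0 / post = 1 (so UAA at pre is the reference cell).
The log link exponentiates the linear predictor, keeping the conditional
mean of median Q positive; the outcome itself stays Gaussian.

Estimation is by maximum likelihood, integrating the random intercept with
per-participant adaptive Gauss-Hermite quadrature (the integrand is
re-centered at its mode and scaled by its curvature, then a >= 15-node
Hermite rule is applied). Standard errors come from the observed information
(numerical Hessian at the optimum). Wald z tests on the fixed effects are
the inferential target, so ML (not REML-type) estimation is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .community import DEFAULT_GAMMA_GRID, QProfile
from .errors import ConvergenceError, FormatError, ParameterError

__all__ = [
    "COEF_NAMES",
    "MixedFit",
    "build_long_table",
    "simulate_model_table",
    "fit_glm_log_link",
    "fit_glmm_log_link",
    "wald_tests",
]

COEF_NAMES = ("intercept", "group", "time", "group_x_time")

GROUP_CODES = {"UAA": 0, "AE": 1}
TIME_CODES = {"pre": 0, "post": 1}


@dataclass
class MixedFit:
    """Result of a (possibly degenerate) log-link mixed-model fit."""

    beta: np.ndarray  # (4,) on the log-link scale
    sigma_b: float
    sigma_e: float
    vcov: np.ndarray  # (4, 4) covariance of beta
    loglik: float
    converged: bool
    n_obs: int
    n_participants: int
    n_quad: int
    message: str = ""
    refit_as_glm: bool = False
    grad_norm: float = np.nan
    coef_names: tuple = COEF_NAMES


def build_long_table(profiles: dict, cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-format model table from per-(subject, session) Q profiles.

    ``profiles`` maps (subject, session) with session in {"pre", "post"} to a
    :class:`~modcog.community.QProfile`; ``cohort`` has columns ``subject``
    and ``group`` (AE or UAA). Returns one row per participant x time x
    gamma with columns participant, group, time, gamma, median_q.
    """
    if not {"subject", "group"}.issubset(cohort.columns):
        raise FormatError("cohort table needs 'subject' and 'group' columns")
    groups = dict(zip(cohort["subject"], cohort["group"]))
    bad = sorted(set(g for g in groups.values()) - set(GROUP_CODES))
    if bad:
        raise FormatError(f"unknown group label(s): {bad}; expected AE or UAA")
    unmatched = sorted({s for (s, _) in profiles} - set(groups))
    if unmatched:
        raise FormatError(f"profiles reference unknown subject(s): {unmatched}")
    rows = []
    for (subject, session), prof in sorted(profiles.items()):
        if session not in TIME_CODES:
            raise FormatError(f"unknown session {session!r}; expected pre or post")
        for gamma in prof.gammas:
            rows.append(
                {
                    "participant": subject,
                    "group": GROUP_CODES[groups[subject]],
                    "time": TIME_CODES[session],
                    "gamma": gamma,
                    "median_q": prof.medians[gamma],
                }
            )
    return pd.DataFrame(rows)


def simulate_model_table(
    n_per_group: int = 90,
    beta: tuple = (np.log(0.3), 0.0, 0.0, 0.04),
    sigma_b: float = 0.05,
    sigma_e: float = 0.02,
    gammas: tuple = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a model table directly from the generative model (for recovery
    and calibration studies that bypass the imaging chain)."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    rows = []
    for gi, group in enumerate((0, 1)):
        for i in range(n_per_group):
            pid = f"sim-{'AE' if group else 'UAA'}-{i:03d}"
            b = rng.normal(0.0, sigma_b)
            for time in (0, 1):
                eta = beta[0] + beta[1] * group + beta[2] * time + beta[3] * group * time
                mu = np.exp(eta + b)
                for gamma in gammas:
                    rows.append(
                        {
                            "participant": pid,
                            "group": group,
                            "time": time,
                            "gamma": gamma,
                            "median_q": mu + rng.normal(0.0, sigma_e),
                        }
                    )
    return pd.DataFrame(rows)


def _design(table: pd.DataFrame):
    req = {"participant", "group", "time", "median_q"}
    if not req.issubset(table.columns):
        raise FormatError(f"model table needs columns {sorted(req)}")
    tab = table.sort_values("participant", kind="stable").reset_index(drop=True)
    y = tab["median_q"].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ParameterError("median_q must be positive under the log link")
    g = tab["group"].to_numpy(dtype=float)
    t = tab["time"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(g), g, t, g * t])
    pid, _ = pd.factorize(tab["participant"], sort=True)
    starts = np.searchsorted(pid, np.arange(pid.max() + 1))
    return X, y, pid, starts


def fit_glm_log_link(table: pd.DataFrame) -> MixedFit:
    """ML fit of the fixed-effects-only log-link Gaussian GLM.

    Gauss-Newton (equivalently iteratively reweighted least squares on this
    likelihood); used directly when the random-intercept variance collapses
    to zero, and as the sigma_b = 0 limit of the mixed model.
    """
    X, y, pid, _ = _design(table)
    beta = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
    for it in range(200):
        mu = np.exp(X @ beta)
        J = mu[:, None] * X
        grad = J.T @ (y - mu)
        step = np.linalg.solve(J.T @ J + 1e-12 * np.eye(X.shape[1]), grad)
        # damped Gauss-Newton: halve until SSE does not increase
        sse = ((y - mu) ** 2).sum()
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            if ((y - np.exp(X @ cand)) ** 2).sum() <= sse + 1e-15:
                break
            lam *= 0.5
        beta = beta + lam * step
        if np.abs(grad).max() < 1e-10 * max(1.0, sse):
            break
    mu = np.exp(X @ beta)
    n = y.size
    sigma_e2 = ((y - mu) ** 2).sum() / n
    J = mu[:, None] * X
    vcov = np.linalg.inv(J.T @ J) * sigma_e2
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma_e2) + 1.0)
    return MixedFit(
        beta=beta,
        sigma_b=0.0,
        sigma_e=float(np.sqrt(sigma_e2)),
        vcov=vcov,
        loglik=float(loglik),
        converged=True,
        n_obs=n,
        n_participants=int(pid.max()) + 1,
        n_quad=0,
        message="fixed-effects GLM (sigma_b = 0)",
        refit_as_glm=True,
    )


def _glmm_loglik_grad(theta, X, y, pid, starts, z, wlog, newton_iter=60):
    """Marginal log-likelihood and its gradient via adaptive Gauss-Hermite.

    theta = (beta[0..3], log sigma_b, log sigma_e). The gradient uses the
    Fisher identity (posterior expectation of the joint score) on the same
    quadrature nodes; node dependence on theta is neglected, which is
    numerically negligible at >= 15 adaptive nodes.
    """
    beta, lsb, lse = theta[:4], theta[4], theta[5]
    sb2, se2 = np.exp(2 * lsb), np.exp(2 * lse)
    eta = X @ beta
    n_part = starts.size
    n_i = np.diff(np.append(starts, y.size))

    def segsum(arr):
        return np.add.reduceat(arr, starts, axis=0)

    # inner Newton for the per-participant posterior mode of b
    b = np.zeros(n_part)
    for _ in range(newton_iter):
        mu = np.exp(eta + b[pid])
        g1 = -b / sb2 + segsum((y - mu) * mu) / se2
        h = -1.0 / sb2 + segsum(mu * (y - 2 * mu)) / se2
        h_safe = np.where(h < -1e-12, h, -(1.0 / sb2 + segsum(mu**2) / se2))
        step = np.clip(g1 / h_safe, -0.5, 0.5)
        b = b - step
        if np.abs(step).max() < 1e-12:
            break
    mu = np.exp(eta + b[pid])
    h = -1.0 / sb2 + segsum(mu * (y - 2 * mu)) / se2
    h = np.where(h < -1e-12, h, -(1.0 / sb2 + segsum(mu**2) / se2))
    tau = 1.0 / np.sqrt(-h)

    # nodes: (participants, K)
    bk = b[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    mu_rk = np.exp(eta[:, None] + bk[pid, :])
    sq_rk = (y[:, None] - mu_rk) ** 2
    seg_sq = segsum(sq_rk)
    f_pk = (
        -0.5 * np.log(2 * np.pi * sb2)
        - bk**2 / (2 * sb2)
        - 0.5 * n_i[:, None] * np.log(2 * np.pi * se2)
        - seg_sq / (2 * se2)
    )
    log_terms = wlog[None, :] + z[None, :] ** 2 + f_pk
    log_norm = logsumexp(log_terms, axis=1)
    ll = float(np.sum(np.log(np.sqrt(2.0) * tau) + log_norm))

    # posterior weights over nodes
    omega = np.exp(log_terms - log_norm[:, None])  # (P, K)
    omega_r = omega[pid, :]  # (rows, K)
    resid_score = (y[:, None] - mu_rk) * mu_rk / se2
    row_score = (resid_score * omega_r).sum(axis=1)
    grad_beta = X.T @ row_score
    d_lse = float(((sq_rk / se2 - 1.0) * omega_r).sum())
    d_lsb = float(((bk**2 / sb2 - 1.0) * omega).sum())
    return ll, np.append(grad_beta, [d_lsb, d_lse])


def fit_glmm_log_link(
    table: pd.DataFrame,
    n_quad: int = 15,
    sigma_b_floor: float = 1e-4,
) -> MixedFit:
    """ML fit of the log-link Gaussian random-intercept model.

    Optimizes (beta, log sigma_b, log sigma_e) by quasi-Newton with the
    adaptive-quadrature likelihood; the coefficient covariance is the inverse
    observed information (central-difference Hessian at the optimum). If the
    random-intercept SD collapses below ``sigma_b_floor`` the model is refit
    as a fixed-effects GLM, with a note in ``message``.
    """
    if n_quad < 15:
        raise ParameterError("n_quad must be >= 15")
    X, y, pid, starts = _design(table)
    counts = np.bincount(pid)
    grp = pd.DataFrame({"pid": pid, "g": X[:, 1]}).groupby("pid")["g"].first()
    for gval in (0, 1):
        if (grp == gval).sum() < 2:
            raise ParameterError("need at least 2 participants per group")
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    wlog = np.log(w)

    # starting values from a log-scale least squares fit
    beta0 = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
    resid_log = np.log(y) - X @ beta0
    part_mean = np.bincount(pid, weights=resid_log) / counts
    sb0 = max(float(part_mean.std()), 1e-3)
    se0 = max(float((y - np.exp(X @ beta0)).std()), 1e-6)
    theta0 = np.append(beta0, [np.log(sb0), np.log(se0)])

    def negloglik(theta):
        ll, grad = _glmm_loglik_grad(theta, X, y, pid, starts, z, wlog)
        return -ll, -grad

    res = minimize(
        negloglik,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-12},
    )
    grad_norm = float(np.abs(res.jac).max())
    if not res.success and grad_norm > 1e-4:
        raise ConvergenceError(
            f"mixed-model fit did not converge: {res.message} "
            f"(gradient inf-norm {grad_norm:.2e})",
            trace=res,
        )
    theta = res.x
    sigma_b = float(np.exp(theta[4]))
    sigma_e = float(np.exp(theta[5]))
    if sigma_b < sigma_b_floor:
        fit = fit_glm_log_link(table)
        fit.message = (
            f"sigma_b collapsed to {sigma_b:.2e} (< {sigma_b_floor}); "
            "refit as fixed-effects GLM"
        )
        fit.n_quad = n_quad
        return fit

    # observed information: central-difference Hessian of -loglik
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        step = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        _, gp = _glmm_loglik_grad(tp, X, y, pid, starts, z, wlog)
        _, gm = _glmm_loglik_grad(tm, X, y, pid, starts, z, wlog)
        H[:, j] = -(gp - gm) / (2 * step)
    H = 0.5 * (H + H.T)
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(H)
        warnings.warn("observed information is singular; using pseudoinverse")
    return MixedFit(
        beta=theta[:4].copy(),
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        vcov=vcov_full[:4, :4],
        loglik=float(-res.fun),
        converged=True,
        n_obs=y.size,
        n_participants=int(pid.max()) + 1,
        n_quad=n_quad,
        message=str(res.message),
        grad_norm=grad_norm,
    )


def loglik_at(table: pd.DataFrame, beta, sigma_b, sigma_e, n_quad: int = 15) -> float:
    """Marginal log-likelihood at given parameters (optimizer sanity checks)."""
    X, y, pid, starts = _design(table)
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    theta = np.append(np.asarray(beta, dtype=float), [np.log(sigma_b), np.log(sigma_e)])
    ll, _ = _glmm_loglik_grad(theta, X, y, pid, starts, z, np.log(w))
    return ll


def wald_tests(fit: MixedFit) -> pd.DataFrame:
    """Two-sided normal-approximation Wald tests on the fixed effects."""
    if not fit.converged:
        raise ConvergenceError("cannot run Wald tests on a non-converged fit")
    se = np.sqrt(np.clip(np.diag(fit.vcov), 0.0, np.inf))
    singular = ~np.isfinite(se) | (se <= 0)
    if singular.any():
        warnings.warn("singular coefficient covariance; p reported as NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(singular, np.nan, fit.beta / se)
    pval = np.where(np.isnan(zval), np.nan, 2 * norm.sf(np.abs(zval)))
    return pd.DataFrame(
        {
            "coef": list(fit.coef_names),
            "estimate": fit.beta,
            "se": se,
            "z": zval,
            "p": pval,
        }
    )
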
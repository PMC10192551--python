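"""Control-anchored residualization, PLS-DA with VIP selection, and
logistic modularity-by-task interaction models.

The residualization step regresses each task's post score on its pre score
in the active-control arm only, then applies those coefficients to every
subject. A control subject's residual is ordinary; an intervention subject's
residual is their observed post score minus the post score expected had they
been in the control arm — a counterfactual-anchored change score. Residuals
are studentized by the control fit's root mean squared error, making the
whole pipeline invariant to per-task affine rescaling of the raw scores.

Studentized residuals feed a one-component PLS-DA (partial least squares
against the centered group indicator), whose variable-importance-in-
projection (VIP) scores select "discriminant" tasks at VIP > 1. Selected
tasks then enter separate logistic models
logit P(AE) = b0 + b1 Q + b2 task + b3 (Q x task), where Q is the
post-minus-pre change in median modularity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .errors import DegenerateInputError, FormatError, ParameterError
from .synthetic_data import TASK_NAMES

__all__ = [
    "TaskTable",
    "ResidualTable",
    "PlsdaModel",
    "LogisticFit",
    "control_residualize",
    "studentize",
    "fit_plsda",
    "vip",
    "vip_from_loadings",
    "classification_error",
    "pooled_t_test",
    "fit_logistic_interaction",
    "select_discriminant_tasks",
]

logger = logging.getLogger("modcog.discriminant")


@dataclass
class TaskTable:
    """Seven-task battery at pre and post with group labels.

    ``pre`` and ``post`` are subject-indexed DataFrames with the task columns
    in battery order; missing values are allowed and tracked per cell.
    ``groups`` maps subject -> "AE" | "UAA".
    """

    groups: pd.Series
    pre: pd.DataFrame
    post: pd.DataFrame

    def __post_init__(self):
        for df in (self.pre, self.post):
            missing = [c for c in TASK_NAMES if c not in df.columns]
            if missing:
                raise FormatError(f"task table is missing columns {missing}")
        self.pre = self.pre[list(TASK_NAMES)]
        self.post = self.post[list(TASK_NAMES)]
        bad = sorted(set(self.groups.unique()) - {"AE", "UAA"})
        if bad:
            raise FormatError(f"unknown group label(s): {bad}")
        if not self.pre.index.equals(self.post.index):
            raise FormatError("pre and post tables must index the same subjects")
        self.groups = self.groups.reindex(self.pre.index)
        if self.groups.isna().any():
            lost = self.pre.index[self.groups.isna()].tolist()
            raise FormatError(f"subjects without a group label: {lost}")

    @property
    def subjects(self) -> pd.Index:
        return self.pre.index

    @property
    def is_ae(self) -> pd.Series:
        return self.groups == "AE"


@dataclass
class ResidualTable:
    """Control-anchored residuals, optionally studentized.

    ``control_stats`` has one row per task: intercept, slope, resid_sd
    (root MSE of the control fit, df = n_control - 2) and n_control.
    """

    residuals: pd.DataFrame
    control_stats: pd.DataFrame
    groups: pd.Series
    studentized: pd.DataFrame | None = None


def control_residualize(tasks: TaskTable) -> ResidualTable:
    """Per task, regress post on pre in the control arm; residualize everyone.

    Subjects missing either time point get a missing residual. Raises if a
    task has fewer than 3 complete control pairs or zero pre-score variance
    among controls.
    """
    controls = ~tasks.is_ae
    resid = pd.DataFrame(index=tasks.subjects, columns=list(TASK_NAMES), dtype=float)
    stats = []
    for task in TASK_NAMES:
        pre = tasks.pre[task]
        post = tasks.post[task]
        ok = controls & pre.notna() & post.notna()
        n_ctrl = int(ok.sum())
        if n_ctrl < 3:
            raise ParameterError(
                f"task {task!r}: only {n_ctrl} complete control pairs (need >= 3)"
            )
        x = pre[ok].to_numpy()
        y = post[ok].to_numpy()
        if x.std() == 0:
            raise DegenerateInputError(
                f"task {task!r}: zero pre-score variance in controls"
            )
        slope, intercept = np.polyfit(x, y, 1)
        fitted_all = intercept + slope * pre
        resid[task] = post - fitted_all
        sse = float(((y - (intercept + slope * x)) ** 2).sum())
        stats.append(
            {
                "task": task,
                "intercept": float(intercept),
                "slope": float(slope),
                "resid_sd": float(np.sqrt(sse / (n_ctrl - 2))),
                "n_control": n_ctrl,
            }
        )
    return ResidualTable(
        residuals=resid,
        control_stats=pd.DataFrame(stats).set_index("task"),
        groups=tasks.groups,
    )


def studentize(rt: ResidualTable, leverage_corrected: bool = False) -> ResidualTable:
    """Divide each residual by the control fit's root mean squared error.

    With ``leverage_corrected=True`` the divisor... is left as the plain root
    MSE scaled per subject by sqrt(1 + 1/n + (pre-dist)/Sxx); the default
    (plain) form is exactly scale invariant under per-task affine rescaling.
    """
    s = rt.control_stats["resid_sd"]
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise DegenerateInputError(f"non-positive control residual SD for {bad}")
    df = rt.control_stats["n_control"] - 2
    if (df <= 0).any():
        raise ParameterError("control fit has non-positive degrees of freedom")
    stud = rt.residuals / s
    return ResidualTable(
        residuals=rt.residuals,
        control_stats=rt.control_stats,
        groups=rt.groups,
        studentized=stud,
    )


@dataclass
class PlsdaModel:
    """One-or-more-component PLS-DA fit against a binary group label."""

    n_components: int
    weights: np.ndarray  # (p, A), each column unit norm
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A)
    ssy: np.ndarray  # (A,) explained y sum of squares per component
    explained_x_variance: np.ndarray  # (A,) fraction of X variance
    explained_y_variance: np.ndarray  # (A,) fraction of y variance
    x_mean: np.ndarray
    y_mean: float
    task_names: tuple
    error_rate: dict = field(default_factory=dict)  # method tag -> rate

    def project(self, X_new: np.ndarray) -> np.ndarray:
        """Latent scores of new rows (rotation through the deflation chain)."""
        Xc = np.atleast_2d(np.asarray(X_new, dtype=float)) - self.x_mean
        R = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return Xc @ R


def fit_plsda(
    X, groups, n_components: int = 1, task_names: tuple | None = None
) -> PlsdaModel:
    """PLS1 (NIPALS) regression of centered predictors on the centered
    binary group indicator.

    For a single component the weight vector is exactly proportional to
    X'y — the direction of maximum covariance between predictors and group
    membership. Rows with missing values must be removed beforehand
    (see :func:`complete_cases`).
    """
    if isinstance(X, pd.DataFrame):
        task_names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if task_names is None:
        task_names = tuple(f"x{j}" for j in range(X.shape[1]))
    y = _binary_labels(groups)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise FormatError("X must be n x p with one row per label")
    if np.isnan(X).any():
        raise FormatError("X contains missing values; apply listwise deletion first")
    if y.min() == y.max():
        raise ParameterError("both groups must be present")
    if not (1 <= n_components <= X.shape[1]):
        raise ParameterError("n_components must be in [1, n_predictors]")
    const = np.flatnonzero(X.std(axis=0) == 0)
    if const.size:
        raise DegenerateInputError(
            f"all-constant predictor column(s): {[task_names[j] for j in const]}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    tot_x = (Xc**2).sum()
    tot_y = (yc**2).sum()
    n, p = Xc.shape
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    Q = np.empty(n_components)
    T = np.empty((n, n_components))
    ssy = np.empty(n_components)
    exp_x = np.empty(n_components)
    exp_y = np.empty(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise DegenerateInputError(
                f"component {a}: predictors are uncorrelated with the label"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t
        ssy[a] = q_a**2 * tt
        exp_x[a] = tt * float(p_a @ p_a) / tot_x
        exp_y[a] = ssy[a] / tot_y
        Xd = Xd - np.outer(t, p_a)
        yd = yd - q_a * t
    return PlsdaModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        ssy=ssy,
        explained_x_variance=exp_x,
        explained_y_variance=exp_y,
        x_mean=x_mean,
        y_mean=y_mean,
        task_names=task_names,
    )


def _binary_labels(groups) -> np.ndarray:
    g = pd.Series(groups)
    if set(g.unique()) <= {"AE", "UAA"}:
        return (g == "AE").to_numpy(dtype=float)
    y = g.to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise FormatError("groups must be AE/UAA labels or 0/1 indicators")
    return y


def vip(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection per task.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with unit-norm
    weight vectors, which for one component reduces to sqrt(p) * |w_j|.
    Satisfies sum_j VIP_j^2 = p exactly.
    """
    total = model.ssy.sum()
    if total <= 0:
        raise DegenerateInputError("zero explained y sum of squares; VIP undefined")
    p = model.weights.shape[0]
    v = np.sqrt(p * (model.weights**2 @ model.ssy) / total)
    return pd.Series(v, index=list(model.task_names), name="vip")


def vip_from_loadings(loadings) -> np.ndarray:
    """One-component VIP from a printed (possibly non-unit-norm) loading
    vector: sqrt(p) * |w_j| / ||w||."""
    w = np.asarray(loadings, dtype=float)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise DegenerateInputError("all-zero loading vector")
    return np.sqrt(w.size) * np.abs(w) / nw


def select_discriminant_tasks(model: PlsdaModel, threshold: float = 1.0) -> list:
    """Tasks whose VIP exceeds the threshold (default 1)."""
    v = vip(model)
    return v.index[v > threshold].tolist()


def classification_error(
    model: PlsdaModel, X, groups, method: str = "loocv_centroid"
) -> float:
    """Misclassification rate of the PLS-DA latent-space centroid rule.

    ``loocv_centroid`` refits the model on each leave-one-out fold, projects
    the held-out row and assigns it to the nearer class centroid in latent
    space; ``resubstitution`` scores the training rows on the fitted model.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = _binary_labels(groups)
    n = X.shape[0]
    if method == "resubstitution":
        scores = model.scores
        errors = _centroid_errors(scores, y, scores, y)
        rate = errors.mean()
    elif method == "loocv_centroid":
        wrong = 0
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            y_tr = y[keep]
            if y_tr.min() == y_tr.max():
                warnings.warn(f"fold {i}: a class is absent in training; counted as error")
                wrong += 1
                continue
            m = fit_plsda(
                X[keep], y_tr, model.n_components, task_names=model.task_names
            )
            t_new = m.project(X[i])
            wrong += int(_centroid_errors(m.scores, y_tr, t_new, y[i : i + 1])[0])
        rate = wrong / n
    else:
        raise ParameterError("method must be 'loocv_centroid' or 'resubstitution'")
    model.error_rate[method] = float(rate)
    return float(rate)


def _centroid_errors(train_scores, train_y, test_scores, test_y) -> np.ndarray:
    c0 = train_scores[train_y == 0].mean(axis=0)
    c1 = train_scores[train_y == 1].mean(axis=0)
    test_scores = np.atleast_2d(test_scores)
    d0 = np.linalg.norm(test_scores - c0, axis=1)
    d1 = np.linalg.norm(test_scores - c1, axis=1)
    pred = (d1 < d0).astype(float)
    return pred != np.asarray(test_y, dtype=float)


def pooled_t_test(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics; returns (t, df, p).

    Pooled-variance by default (df = n1 + n2 - 2); ``welch=True`` uses the
    Welch-Satterthwaite form. Two identical degenerate samples give t = 0 by
    convention.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("both samples need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise DegenerateInputError("zero variance with unequal means: t undefined")
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    t = (mean1 - mean2) / se
    p = 2 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class LogisticFit:
    """Logistic regression of group on Q, a task score and their interaction."""

    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    separation: bool
    n_obs: int
    loglik: float
    coef_names: tuple = ("intercept", "q", "task", "q_x_task")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": list(self.coef_names),
                "estimate": self.coef,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )


def fit_logistic_interaction(
    delta_q,
    task,
    groups,
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit logit P(AE) = b0 + b1 Q + b2 task + b3 (Q x task) by IRLS.

    Q is the per-subject change in median modularity and ``task`` the
    studentized post residual of one discriminant task; both are z-scored
    before the interaction is formed (default) to stabilize the estimates.
    Complete separation is detected (diverging coefficients) and flagged
    rather than silently returned.
    """
    q = np.asarray(delta_q, dtype=float)
    x = np.asarray(task, dtype=float)
    y = _binary_labels(groups)
    ok = np.isfinite(q) & np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("logistic model: dropping %d incomplete case(s)", dropped)
    q, x, y = q[ok], x[ok], y[ok]
    if y.size < 8:
        raise ParameterError("too few complete cases for the logistic model")
    if y.min() == y.max():
        raise ParameterError("outcome has a single class; model undefined")
    if standardize:
        q = (q - q.mean()) / q.std()
        x = (x - x.mean()) / x.std()
    X = np.column_stack([np.ones_like(q), q, x, q * x])
    beta = np.zeros(4)
    separation = False
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = mu * (1 - mu)
        grad = X.T @ (y - mu)
        if np.abs(grad).max() < tol:
            converged = True
            break
        H = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(4), grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving on the log-likelihood
        ll_old = float(y @ eta - np.logaddexp(0.0, eta).sum())
        lam = 1.0
        for _ in range(25):
            cand = beta + lam * step
            eta_c = X @ cand
            ll_new = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_new >= ll_old - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        if np.abs(beta).max() > 15:
            separation = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    wt = np.clip(mu * (1 - mu), 1e-12, None)
    H = (X * wt[:, None]).T @ X
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    if separation:
        warnings.warn(
            "complete or quasi-complete separation detected; coefficients and "
            "standard errors are unreliable"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta / se
    pval = 2 * norm.sf(np.abs(zval))
    return LogisticFit(
        coef=beta,
        se=se,
        z=zval,
        p=pval,
        converged=converged and not separation,
        separation=separation,
        n_obs=y.size,
        loglik=ll,
    )


def complete_cases(df: pd.DataFrame) -> pd.DataFrame:
    """Listwise deletion with a logged count (per-analysis convention)."""
    out = df.dropna()
    if len(out) < len(df):
        logger.info("listwise deletion: %d of %d rows dropped", len(df) - len(out), len(df))
    return out
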
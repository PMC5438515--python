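"""Cox proportional-hazards and Weibull regression fits, with Wald, score
and likelihood-ratio tests.

Cox model: Breslow-ties log partial likelihood

    l(beta) = sum_k [ s_k' beta - d_k * log sum_{j in R(t_k)} exp(x_j' beta) ]

over distinct event times t_k, where d_k events occur with covariate sum s_k
and R(t_k) is the risk set.  Maximised by Newton-Raphson with step-halving;
standard errors from the inverse observed information.

Weibull model: proportional-hazards parameterisation with hazard
h(t | x) = gamma * t^(gamma-1) * exp(alpha + x' beta), giving

    l = sum_i [ d_i (log gamma + (gamma-1) log t_i + alpha + x_i' beta)
                - t_i^gamma * exp(alpha + x_i' beta) ]

fitted over the unconstrained parameters (alpha, log gamma, beta).

Per-coefficient inference: Wald tests for Cox (with 95% hazard-ratio CIs);
Rao score tests for Weibull coefficients, evaluated at the restricted MLE
with the efficient (Schur-complement) information.  The overall model is
summarised by a likelihood-ratio test against the covariate-free null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .errors import FitError

MAX_ITER = 25
MAX_HALVINGS = 10
SCORE_TOL = 1e-6
REL_LL_TOL = 1e-8

#: two-sided 95% normal quantile used for hazard-ratio confidence intervals
Z_95 = 1.959964


@dataclass
class ModelFit:
    """Converged (or flagged) maximum-likelihood fit for either family."""

    family: str  # "cox" | "weibull"
    coefficient_names: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    loglik_full: float
    loglik_null: float
    n_events: int
    n_used: int
    converged: bool
    iterations: int
    # Weibull extras: intercept alpha and shape gamma with their SEs
    intercept: float = np.nan
    intercept_se: float = np.nan
    log_shape: float = np.nan
    log_shape_se: float = np.nan

    @property
    def shape(self) -> float:
        return float(np.exp(self.log_shape))

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficient_names)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    kind: str  # "wald" | "score" | "lrt"
    df: int = 1
    ci_low: float = np.nan
    ci_high: float = np.nan


# ---------------------------------------------------------------------------
# Newton-Raphson driver


def _newton_raphson(objective, theta0: np.ndarray):
    """Maximise ``objective`` (returning ll, grad, hess) with step-halving.

    Returns (theta, ll, grad, hess, converged, iterations).  The observed
    information may be singular; that is raised as :class:`FitError`.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    ll, grad, hess = objective(theta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        try:
            step = linalg.solve(-hess, grad, assume_a="sym")
        except linalg.LinAlgError as exc:
            raise FitError("singular information matrix") from exc
        if not np.isfinite(step).all():
            raise FitError("singular information matrix")
        new_theta = theta + step
        new = objective(new_theta)
        halvings = 0
        # a deterioration within rounding noise of the objective is not a
        # failed step: near the optimum the true improvement underflows
        noise = 1e-10 * (abs(ll) + 1.0)
        while (not np.isfinite(new[0]) or new[0] < ll - noise) and halvings < MAX_HALVINGS:
            step *= 0.5
            new_theta = theta + step
            new = objective(new_theta)
            halvings += 1
        if not np.isfinite(new[0]) or new[0] < ll - noise:
            break  # cannot improve: stop at current theta
        rel_change = abs(new[0] - ll) / (abs(ll) + 1.0)
        theta, (ll, grad, hess) = new_theta, new
        if np.max(np.abs(grad)) < SCORE_TOL or rel_change < REL_LL_TOL:
            converged = True
            break
    return theta, ll, grad, hess, converged, it


def _covariance(hess: np.ndarray) -> np.ndarray:
    try:
        cov = linalg.inv(-hess)
    except linalg.LinAlgError as exc:
        raise FitError("singular information matrix") from exc
    if not np.isfinite(cov).all() or (np.diag(cov) <= 0).any():
        raise FitError("information matrix not positive definite at optimum")
    return cov


# ---------------------------------------------------------------------------
# Cox proportional hazards


def cox_loglik(beta: np.ndarray, times: np.ndarray, events: np.ndarray,
               X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow log partial likelihood with gradient and Hessian at ``beta``.

    O(n p^2) via suffix sums over subjects sorted by ascending time: the risk
    set of an event time is a suffix of the sorted sample.
    """
    order = np.argsort(times, kind="stable")
    t, d, Xs = times[order], events[order], X[order]
    eta = Xs @ beta
    shift = eta.max() if len(eta) else 0.0
    w = np.exp(eta - shift)
    wx = w[:, None] * Xs
    # suffix (reverse cumulative) sums: S0[i] = sum_{j >= i} w_j, etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum((wx[:, :, None] * Xs[:, None, :])[::-1], axis=0)[::-1]

    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    event_times = np.unique(t[d == 1])
    for tk in event_times:
        first = np.searchsorted(t, tk, side="left")
        at_tk = (t == tk) & (d == 1)
        dk = int(at_tk.sum())
        sk = Xs[at_tk].sum(axis=0)
        ll += sk @ beta - dk * (np.log(S0[first]) + shift)
        xbar = S1[first] / S0[first]
        grad += sk - dk * xbar
        hess -= dk * (S2[first] / S0[first] - np.outer(xbar, xbar))
    return ll, grad, hess


def fit_cox(times: np.ndarray, events: np.ndarray, X: np.ndarray,
            names: list[str] | None = None) -> ModelFit:
    """Fit the Cox model by Newton-Raphson from beta = 0.

    Raises :class:`FitError` when there are no events, a design column is
    constant, or the information matrix is singular / the fit does not
    converge within the iteration budget.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"x{j}" for j in range(X.shape[1])]
    n_events = int(events.sum())
    if n_events == 0:
        raise FitError("no events observed: Cox model cannot be fitted")
    if X.shape[1] == 0:
        raise FitError("empty design matrix")
    if (X.std(axis=0) == 0).any():
        raise FitError("constant design column (monomorphic SNP or degenerate covariate)")

    loglik_null = cox_loglik(np.zeros(X.shape[1]), times, events, X)[0]
    theta, ll, grad, hess, converged, it = _newton_raphson(
        lambda b: cox_loglik(b, times, events, X), np.zeros(X.shape[1])
    )
    if not converged:
        raise FitError(f"Cox Newton-Raphson did not converge in {it} iterations")
    cov = _covariance(hess)
    return ModelFit(
        family="cox",
        coefficient_names=list(names),
        estimates=theta,
        standard_errors=np.sqrt(np.diag(cov)),
        covariance=cov,
        loglik_full=ll,
        loglik_null=loglik_null,
        n_events=n_events,
        n_used=len(times),
        converged=converged,
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Weibull proportional-hazards regression


def weibull_loglik(theta: np.ndarray, times: np.ndarray, events: np.ndarray,
                   X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Log likelihood, gradient and Hessian in (alpha, log gamma, beta)."""
    alpha, g = theta[0], theta[1]
    beta = theta[2:]
    gamma = np.exp(g)
    logt = np.log(times)
    u = gamma * logt
    eta = X @ beta if X.shape[1] else np.zeros(len(times))
    lam = np.exp(u + alpha + eta)  # t^gamma * exp(alpha + eta)
    d = events

    ll = float(np.sum(d * (g + (gamma - 1.0) * logt + alpha + eta) - lam))
    p = X.shape[1]
    grad = np.empty(2 + p)
    resid = d - lam
    grad[0] = resid.sum()
    grad[1] = float(np.sum(d * (1.0 + u) - lam * u))
    grad[2:] = X.T @ resid

    hess = np.empty((2 + p, 2 + p))
    hess[0, 0] = -lam.sum()
    hess[0, 1] = hess[1, 0] = -float(np.sum(lam * u))
    hess[1, 1] = float(np.sum(d * u - lam * u * (1.0 + u)))
    if p:
        lam_x = lam[:, None] * X
        hess[0, 2:] = hess[2:, 0] = -lam_x.sum(axis=0)
        hess[1, 2:] = hess[2:, 1] = -(lam * u) @ X
        hess[2:, 2:] = -X.T @ lam_x
    return ll, grad, hess


def _prepare_times(times: np.ndarray) -> np.ndarray:
    """Shift zero survival times to half the smallest positive time."""
    times = np.asarray(times, float)
    if (times == 0).any():
        positive = times[times > 0]
        if len(positive) == 0:
            raise FitError("all survival times are zero")
        shift = positive.min() / 2.0
        import logging
        logging.getLogger(__name__).warning(
            "%d zero survival time(s) shifted to %g for Weibull fitting",
            int((times == 0).sum()), shift,
        )
        times = np.where(times == 0, shift, times)
    return times


def _weibull_start(times: np.ndarray, events: np.ndarray, p: int) -> np.ndarray:
    theta0 = np.zeros(2 + p)
    theta0[0] = np.log(max(events.sum(), 0.5) / times.sum())  # exponential MLE
    return theta0


def fit_weibull(times: np.ndarray, events: np.ndarray, X: np.ndarray,
                names: list[str] | None = None,
                fixed_log_shape: float | None = None) -> ModelFit:
    """Fit the proportional-hazards Weibull model by Newton-Raphson.

    Reports the intercept alpha and shape gamma alongside the regression
    coefficients; ``loglik_null`` comes from the intercept + shape model
    fitted to the same data.  ``fixed_log_shape`` pins log(gamma) instead of
    estimating it (0 gives the exponential sub-model).
    """
    times = _prepare_times(times)
    events = np.asarray(events, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"x{j}" for j in range(X.shape[1])]
    n_events = int(events.sum())
    if n_events == 0:
        raise FitError("no events observed: Weibull model cannot be fitted")
    if X.shape[1] and (X.std(axis=0) == 0).any():
        raise FitError("constant design column (monomorphic SNP or degenerate covariate)")

    p = X.shape[1]
    if fixed_log_shape is None:
        objective = lambda th: weibull_loglik(th, times, events, X)
        theta0 = _weibull_start(times, events, p)
    else:
        free = np.array([0] + list(range(2, 2 + p)))  # drop the log-shape slot

        def objective(th_r):
            th = np.empty(2 + p)
            th[free] = th_r
            th[1] = fixed_log_shape
            ll, g, h = weibull_loglik(th, times, events, X)
            return ll, g[free], h[np.ix_(free, free)]

        theta0 = _weibull_start(times, events, p)[free]
    theta_r, ll, grad, hess, converged, it = _newton_raphson(objective, theta0)
    if not converged:
        raise FitError(f"Weibull Newton-Raphson did not converge in {it} iterations")
    cov_r = _covariance(hess)
    if fixed_log_shape is None:
        theta, cov = theta_r, cov_r
    else:
        theta = np.empty(2 + p)
        theta[free] = theta_r
        theta[1] = fixed_log_shape
        cov = np.zeros((2 + p, 2 + p))
        cov[np.ix_(free, free)] = cov_r
    se = np.sqrt(np.abs(np.diag(cov)))
    if fixed_log_shape is not None:
        se[1] = np.nan

    if p:
        null_fit = fit_weibull(times, events, np.empty((len(times), 0)), [],
                               fixed_log_shape=fixed_log_shape)
        loglik_null = null_fit.loglik_full
    else:
        loglik_null = ll
    return ModelFit(
        family="weibull",
        coefficient_names=list(names),
        estimates=theta[2:],
        standard_errors=se[2:],
        covariance=cov,
        loglik_full=ll,
        loglik_null=loglik_null,
        n_events=n_events,
        n_used=len(times),
        converged=converged,
        iterations=it,
        intercept=float(theta[0]),
        intercept_se=float(se[0]),
        log_shape=float(theta[1]),
        log_shape_se=float(se[1]),
    )


# ---------------------------------------------------------------------------
# tests


def wald_test(estimate: float, se: float, hazard_ratio_ci: bool = False) -> TestResult:
    """Two-sided Wald z test; optional 95% CI on the hazard-ratio scale."""
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    res = TestResult(statistic=float(z), p_value=float(p), kind="wald")
    if hazard_ratio_ci:
        res.ci_low = float(np.exp(estimate - Z_95 * se))
        res.ci_high = float(np.exp(estimate + Z_95 * se))
    return res


def score_test(times: np.ndarray, events: np.ndarray, X_full: np.ndarray,
               tested_columns: list[int],
               names: list[str] | None = None) -> TestResult:
    """Rao score test of Weibull coefficients, nuisance at the restricted MLE.

    The restricted model omits ``tested_columns`` from the design (their
    coefficients pinned at zero); the full-model score and observed
    information are evaluated at that point, and the statistic is
    U_T' S^{-1} U_T with S the Schur complement of the nuisance block (the
    efficient information).  For df = 1 the signed z = sign(U_T) sqrt(stat)
    is stored in ``statistic``; the chi-square statistic is z^2.
    """
    times = _prepare_times(times)
    events = np.asarray(events, float)
    X_full = np.asarray(X_full, float)
    if X_full.ndim == 1:
        X_full = X_full[:, None]
    p = X_full.shape[1]
    tested = sorted(tested_columns)
    if not tested or any(j < 0 or j >= p for j in tested):
        raise ValueError("tested_columns must be a non-empty subset of design columns")
    nuisance_cols = [j for j in range(p) if j not in tested]

    restricted = fit_weibull(
        times, events, X_full[:, nuisance_cols],
        [f"x{j}" for j in nuisance_cols],
    )
    theta0 = np.zeros(2 + p)
    theta0[0] = restricted.intercept
    theta0[1] = restricted.log_shape
    for est, j in zip(restricted.estimates, nuisance_cols):
        theta0[2 + j] = est

    _, grad, hess = weibull_loglik(theta0, times, events, X_full)
    info = -hess
    t_idx = np.array([2 + j for j in tested])
    n_idx = np.array([0, 1] + [2 + j for j in nuisance_cols])
    I_tt = info[np.ix_(t_idx, t_idx)]
    I_tn = info[np.ix_(t_idx, n_idx)]
    I_nn = info[np.ix_(n_idx, n_idx)]
    try:
        schur = I_tt - I_tn @ linalg.solve(I_nn, I_tn.T, assume_a="sym")
        u_t = grad[t_idx]
        stat = float(u_t @ linalg.solve(schur, u_t, assume_a="sym"))
    except linalg.LinAlgError as exc:
        raise FitError("singular information in score test") from exc
    if stat < 0:
        stat = 0.0
    df = len(tested)
    p_value = float(stats.chi2.sf(stat, df))
    if df == 1:
        signed_z = float(np.sign(u_t[0]) * np.sqrt(stat))
        return TestResult(statistic=signed_z, p_value=p_value, kind="score", df=1)
    return TestResult(statistic=stat, p_value=p_value, kind="score", df=df)


def likelihood_ratio_test(fit: ModelFit) -> TestResult:
    """Overall-model LRT: 2(l_full - l_null), df = number of coefficients.

    The Weibull intercept and shape are present in both models and do not
    count toward the degrees of freedom.  The statistic is clamped at zero.
    """
    stat = max(0.0, 2.0 * (fit.loglik_full - fit.loglik_null))
    df = fit.n_coefficients
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(statistic=stat, p_value=p, kind="lrt", df=df)
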
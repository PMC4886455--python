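"""Estimation layer: logistic and random-intercept logistic regression,
odds-ratio tables, trend tests and the minimum-exposed-cases rule.

The study design is a matched case-control study analyzed *unconditionally*
(matching variables may enter as covariates): plain logistic regression for
a single-region analysis, and a random-intercept logistic model — a
normally distributed per-region deviation of the intercept — when several
regions are pooled.  The mixed model's marginal likelihood is maximized
with adaptive Gauss-Hermite quadrature (one quadrature node recovers the
Laplace approximation).  Odds ratios are exponentiated coefficients with
Wald 95% confidence intervals; the trend test is a Wald test of the 0-4
exposure category entered as a numeric score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools import numdiff
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .landcover import InvalidInputError


class EstimationError(RuntimeError):
    """Model estimation failed (separation, rank deficiency, non-convergence)."""


@dataclass
class ModelFit:
    """A fitted (possibly mixed) logistic regression.

    Coefficients are on the log-odds scale; ``cov`` is the (symmetric PSD)
    covariance of the fixed effects; ``random_intercept_sd`` is None for a
    plain model and the estimated between-group SD (possibly 0, at the
    boundary) for a mixed one.
    """

    terms: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    random_intercept_sd: float | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class ORResult:
    """One odds-ratio row: a term of one (diagnostic group, crop type) model.

    ``eligible`` is False when the minimum-exposed-cases rule suppresses
    the estimate; ineligible rows carry no estimates (None), mirroring a
    blank table cell.
    """

    diagnostic_group: str
    crop_type: str
    term: str
    or_estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    trend_p: float | None = None
    eligible: bool = True
    n_exposed_cases: int = 0
    note: str = ""


def _as_design(design, terms=None):
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns) if terms is None else list(terms)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        terms = [f"x{i}" for i in range(X.shape[1])] if terms is None else list(terms)
    return X, terms


def fit_logistic(outcome, design, terms=None, maxiter: int = 100, tol: float = 1e-10) -> ModelFit:
    """Maximum-likelihood logistic regression (Newton scoring).

    ``design`` must include the intercept column if one is wanted.  The
    design must be full rank and the data must not be separated; either
    condition failing raises :class:`EstimationError` rather than
    returning silently unusable estimates.
    """
    y = np.asarray(outcome, dtype=float)
    X, terms = _as_design(design, terms)
    if y.shape[0] != X.shape[0]:
        raise InvalidInputError("outcome and design have different lengths")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise InvalidInputError("non-finite values in outcome or design")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InvalidInputError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("design matrix is rank deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # convergence is checked explicitly below; overflow in expit is benign
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            warnings.filterwarnings("ignore", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise EstimationError(f"perfect separation detected: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular information matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError("logistic regression did not converge")
    if np.abs(res.params).max() > 30:
        raise EstimationError("quasi-separation suspected (|coefficient| > 30)")
    return ModelFit(
        terms=terms,
        coef=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        loglik=float(res.llf),
        converged=True,
        n_used=int(y.shape[0]),
    )


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (adaptive Gauss-Hermite)
# ---------------------------------------------------------------------------


def _group_mode(eta0, y, sigma2, u0=0.0, tol=1e-10, maxiter=50):
    """Newton mode and curvature of the per-group integrand h(u)."""
    u = u0
    for _ in range(maxiter):
        p = special.expit(eta0 + u)
        g = np.sum(y - p) - u / sigma2
        h = -np.sum(p * (1 - p)) - 1.0 / sigma2
        step = g / h
        u_new = u - step
        if abs(step) < tol:
            u = u_new
            break
        u = u_new
    p = special.expit(eta0 + u)
    curv = -np.sum(p * (1 - p)) - 1.0 / sigma2
    return u, curv


def _bernoulli_ll(eta, y):
    # numerically safe sum of y*log(p) + (1-y)*log(1-p)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _mixed_loglik(beta, sigma, Xg, yg, z_nodes, w_nodes, modes):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    For each group the integrand exp(h(u)) with
    h(u) = sum_i loglik_i(x_i beta + u) - u^2/(2 sigma^2)
    is integrated against du / (sqrt(2 pi) sigma): nodes are centered at
    the mode of h and scaled by its curvature, which keeps the quadrature
    accurate even for very peaked group likelihoods.
    """
    total = 0.0
    for k, (X, y) in enumerate(zip(Xg, yg)):
        eta0 = X @ beta
        u_hat, curv = _group_mode(eta0, y, sigma**2, u0=modes[k])
        modes[k] = u_hat
        tau = 1.0 / np.sqrt(-curv)
        u_k = u_hat + np.sqrt(2.0) * tau * z_nodes
        h_hat = _bernoulli_ll(eta0 + u_hat, y) - u_hat**2 / (2 * sigma**2)
        vals = np.empty_like(z_nodes)
        for j, u in enumerate(u_k):
            vals[j] = (
                _bernoulli_ll(eta0 + u, y) - u**2 / (2 * sigma**2) - h_hat + z_nodes[j] ** 2
            )
        # a misconverged mode during a line search could overflow exp
        integral = np.sqrt(2.0) * tau * np.dot(w_nodes, np.exp(np.clip(vals, None, 700.0)))
        total += h_hat + np.log(integral) - 0.5 * np.log(2 * np.pi) - np.log(sigma)
    return total


#: Below this estimated between-group SD the mixed model is numerically the
#: plain model; the variance is reported as exactly 0 (boundary estimate).
_SIGMA_BOUNDARY = 1e-4


def fit_mixed_logistic(
    outcome,
    design,
    groups,
    terms=None,
    n_quad: int = 9,
    sigma_start: float = 0.3,
) -> ModelFit:
    """Random-intercept logistic regression by adaptive Gauss-Hermite ML.

    ``groups`` labels each row with its cluster (e.g. administrative
    region); at least two distinct groups are required — with one group
    the model is unidentified, use :func:`fit_logistic`.  ``n_quad``
    quadrature nodes refine the Laplace approximation (``n_quad=1``
    recovers it exactly).

    A variance estimate on the 0 boundary is reported as
    ``random_intercept_sd = 0`` with the fixed effects of the plain
    model — the maximum-likelihood solution in that limit — never hidden.
    """
    y = np.asarray(outcome, dtype=float)
    X, terms = _as_design(design, terms)
    groups = np.asarray(groups)
    if y.shape[0] != X.shape[0] or groups.shape[0] != X.shape[0]:
        raise InvalidInputError("outcome, design and groups have different lengths")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InvalidInputError(
            "mixed model needs >= 2 groups; use fit_logistic for a single group"
        )
    Xg = [X[groups == g] for g in labels]
    yg = [y[groups == g] for g in labels]
    z_nodes, w_nodes = np.polynomial.hermite.hermgauss(n_quad)

    plain = fit_logistic(y, X, terms)
    modes = np.zeros(len(labels))

    def negll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        return -_mixed_loglik(beta, sigma, Xg, yg, z_nodes, w_nodes, modes)

    x0 = np.concatenate([plain.coef, [np.log(sigma_start)]])
    opt = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(np.log(1e-6), np.log(10.0))],
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    sigma_hat = float(np.exp(opt.x[-1]))
    loglik = -float(opt.fun)

    if sigma_hat < _SIGMA_BOUNDARY or plain.loglik >= loglik - 1e-4:
        # variance at the boundary: the plain MLE maximizes the likelihood
        return ModelFit(
            terms=terms,
            coef=plain.coef,
            cov=plain.cov,
            loglik=plain.loglik,
            converged=True,
            n_used=int(y.shape[0]),
            random_intercept_sd=0.0,
        )
    if not opt.success and abs(loglik - plain.loglik) < 1e-6:
        raise EstimationError(f"mixed logistic regression did not converge: {opt.message}")

    # Wald covariance of the fixed effects conditional on the estimated
    # variance component (the convention of mainstream mixed-model software)
    def negll_beta(beta):
        return -_mixed_loglik(beta, sigma_hat, Xg, yg, z_nodes, w_nodes, modes)

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hess = numdiff.approx_hess1(opt.x[:-1], negll_beta)
    try:
        cov_beta = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular Hessian in mixed model: {exc}") from exc
    cov_beta = (cov_beta + cov_beta.T) / 2
    d = np.diag(cov_beta)
    if not (np.isfinite(d).all() and (d > 0).all()):
        raise EstimationError("mixed-model Hessian is not positive definite")
    return ModelFit(
        terms=terms,
        coef=np.asarray(opt.x[:-1], dtype=float),
        cov=cov_beta,
        loglik=loglik,
        converged=bool(opt.success),
        n_used=int(y.shape[0]),
        random_intercept_sd=sigma_hat,
    )


# ---------------------------------------------------------------------------
# Odds ratios, trend test, eligibility
# ---------------------------------------------------------------------------


def or_table(fit: ModelFit, terms=None, alpha: float = 0.05) -> pd.DataFrame:
    """Wald odds-ratio table: OR = exp(b), CI = exp(b +/- z * SE)."""
    if not fit.converged:
        raise EstimationError("cannot tabulate odds ratios from a non-converged fit")
    wanted = list(fit.terms) if terms is None else list(terms)
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for t in wanted:
        i = fit.terms.index(t)
        b, s = fit.coef[i], fit.se[i]
        rows.append(
            {
                "term": t,
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * s)),
                "ci_high": float(np.exp(b + z * s)),
            }
        )
    return pd.DataFrame(rows, columns=["term", "or", "ci_low", "ci_high"])


def trend_test(outcome, score, adjusters=None, groups=None) -> float:
    """Two-sided Wald p-value for a linear trend across exposure categories.

    The 0-4 category (0 = unexposed) enters the adjusted logistic model as
    a numeric score; the returned p-value tests its slope.  When ``groups``
    is given the score is tested inside the random-intercept model.
    """
    score = np.asarray(score, dtype=float)
    if np.var(score) == 0:
        raise InvalidInputError("trend score has no variance")
    n = score.shape[0]
    cols = {"intercept": np.ones(n), "trend_score": score}
    if adjusters is not None:
        A, names = _as_design(adjusters)
        for j, nm in enumerate(names):
            cols[nm if nm not in cols else f"adj_{j}"] = A[:, j]
    X = pd.DataFrame(cols)
    if groups is not None:
        fit = fit_mixed_logistic(outcome, X, groups)
    else:
        fit = fit_logistic(outcome, X)
    i = fit.terms.index("trend_score")
    z = fit.coef[i] / fit.se[i]
    return float(2 * stats.norm.sf(abs(z)))


def eligibility(n_exposed_cases: int, threshold: int = 3) -> bool:
    """Minimum-exposed-cases rule: estimates are only reported when at
    least ``threshold`` cases fall in the exposure category (0 disables)."""
    if n_exposed_cases < 0:
        raise InvalidInputError("n_exposed_cases must be nonnegative")
    return n_exposed_cases >= threshold
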
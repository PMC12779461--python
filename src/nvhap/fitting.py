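"""Model-fitting primitives shared across the package.

* logistic regression via statsmodels GLM, with a lightly ridge-penalized
  Newton fallback for designs with separated cells (rare-event site
  indicators can be perfectly predictive in small samples);
* a fast maximum-likelihood fit of the zero-truncated negative binomial
  regression (log link, NB2 dispersion) with analytic gradients — the
  count component of the length-of-stay hurdle model;
* :class:`HurdleFit`, the fitted hurdle model with probability-mass and
  mean functions used both for trend description and for counterfactual
  standardization.

Dispersion is optimized on the log scale (``eta = log alpha``,
variance = mu + alpha mu^2); ``theta = 1/alpha`` in the mean/dispersion
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

_MAX_ABS_COEF = 30.0


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def hurdle_los_pmf(p_one, mu, theta, l_max: int) -> np.ndarray:
    """Hurdle LOS mass over l = 1..l_max: P(1) = p_one, and for l >= 2
    (1 - p_one) times the zero-truncated NB mass of l - 1.  Vectorized over
    rows; tail mass beyond ``l_max`` is not redistributed here."""
    p_one = np.atleast_1d(np.asarray(p_one, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    r = float(theta)
    q = r / (r + mu)
    out = np.zeros((len(mu), int(l_max)))
    out[:, 0] = p_one
    pmf_w = q**r                      # NB pmf at w = 0
    zt_norm = 1.0 - pmf_w
    one_minus_q = 1.0 - q
    w = 0
    for l in range(2, int(l_max) + 1):
        pmf_w = pmf_w * (w + r) / (w + 1) * one_minus_q
        w += 1
        out[:, l - 1] = (1.0 - p_one) * pmf_w / zt_norm
    return out


# ----------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    n_obs: int
    ridged: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(X @ self.params)


def _newton_logistic(X, y, maxiter=60, tol=1e-10):
    """Plain Newton-Raphson MLE; returns (params, cov) or None on failure."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-8) / (1 - y.mean() + 1e-8))
    I = None
    for _ in range(maxiter):
        pr = sigmoid(X @ beta)
        W = pr * (1.0 - pr) + 1e-12
        I = X.T @ (W[:, None] * X)
        g = X.T @ (y - pr)
        try:
            step = np.linalg.solve(I, g)
        except np.linalg.LinAlgError:
            return None
        m = np.max(np.abs(step))
        if m > 10.0:
            step *= 10.0 / m
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > _MAX_ABS_COEF:
        return None
    return beta, np.linalg.inv(I)


def _ridge_logistic(X, y, alpha=1e-4, maxiter=200):
    n, p = X.shape
    beta = np.zeros(p)
    I = np.eye(p)
    for _ in range(maxiter):
        pr = sigmoid(X @ beta)
        W = pr * (1.0 - pr) + 1e-12
        H = X.T @ (W[:, None] * X) + 2.0 * alpha * I
        g = X.T @ (y - pr) - 2.0 * alpha * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    pr = sigmoid(X @ beta)
    W = pr * (1.0 - pr) + 1e-12
    H = X.T @ (W[:, None] * X) + 2.0 * alpha * I
    return beta, np.linalg.inv(H)


def _firth_logistic(X, y, maxiter=100, tol=1e-7):
    """Bias-reduced logistic regression (Jeffreys-prior penalty).  Keeps
    coefficients finite under separation — site indicators with zero events
    in rare-event data — and removes the O(1/n) bias of the MLE."""
    n, p = X.shape
    warm = _newton_logistic(X, y, maxiter=30, tol=1e-8)
    if warm is not None:
        beta = warm[0].copy()
    else:
        beta = np.zeros(p)
        beta[0] = np.log((y.mean() + 0.5 / n) / (1 - y.mean() + 0.5 / n))
    I = None
    for _ in range(maxiter):
        pr = sigmoid(X @ beta)
        W = pr * (1.0 - pr) + 1e-12
        XW = X * W[:, None]
        I = X.T @ XW
        try:
            L = np.linalg.cholesky(I)
        except np.linalg.LinAlgError:
            I += 1e-8 * np.eye(p)
            L = np.linalg.cholesky(I)
        # leverages of W^(1/2) X
        A = solve_triangular(L, (X * np.sqrt(W)[:, None]).T, lower=True)
        h = (A**2).sum(axis=0)
        score = X.T @ (y - pr + h * (0.5 - pr))
        step = np.linalg.solve(I, score)
        # damp very large steps for stability
        m = np.max(np.abs(step))
        if m > 5.0:
            step *= 5.0 / m
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    # intercept recalibration: Firth probabilities are pulled toward 1/2,
    # a material relative bias when events are rare; shift the intercept so
    # the in-sample mean prediction matches the observed event rate
    eta = X @ beta - beta[0] * X[:, 0]
    c = beta[0]
    target = y.mean()
    for _ in range(60):
        pr = sigmoid(eta + c * X[:, 0])
        grad = np.mean(pr * (1.0 - pr) * X[:, 0])
        diff = pr.mean() - target
        if abs(diff) < 1e-12 or grad <= 0:
            break
        c -= diff / grad
    beta[0] = c
    return beta, np.linalg.inv(I)


def fit_logistic(X: np.ndarray, y: np.ndarray, columns: list[str] | None = None,
                 method: str = "glm") -> LogisticFit:
    """Logistic regression.

    ``method="glm"``: Binomial GLM (statsmodels) with a ridge-stabilized
    fallback under separation.  ``method="firth"``: bias-reduced fit for
    rare-event models with sparse cells.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    columns = columns or [f"x{j}" for j in range(X.shape[1])]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single level; logistic fit is undefined")
    if method == "firth":
        params, cov = _firth_logistic(X, y)
        return LogisticFit(params=params, cov=cov, columns=list(columns), n_obs=len(y))
    if method == "newton":
        out = _newton_logistic(X, y)
        if out is not None:
            return LogisticFit(params=out[0], cov=out[1], columns=list(columns), n_obs=len(y))
        params, cov = _ridge_logistic(X, y)
        return LogisticFit(params=params, cov=cov, columns=list(columns), n_obs=len(y), ridged=True)
    ridged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        bad = (not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov))
               or np.max(np.abs(params)) > _MAX_ABS_COEF)
    except Exception:
        bad = True
    if bad:
        params, cov = _ridge_logistic(X, y)
        ridged = True
    return LogisticFit(params=params, cov=cov, columns=list(columns), n_obs=len(y), ridged=ridged)


# ----------------------------------------------------------------------
# zero-truncated negative binomial regression

def ztnb_negloglik_grad(params: np.ndarray, X: np.ndarray, w: np.ndarray,
                        unique_w=None):
    """Negative log-likelihood (up to a data-only constant) and gradient of
    the zero-truncated NB regression for counts w >= 1;
    params = (coefficients..., log alpha).

    ``unique_w``: optional (values, inverse) from ``np.unique`` of the
    integer counts — the gamma/digamma terms are then evaluated once per
    distinct count instead of once per row.
    """
    p = X.shape[1]
    delta, eta = params[:p], params[p]
    r = np.exp(-eta)
    mu = np.exp(np.clip(X @ delta, -30.0, 30.0))
    q = r / (r + mu)
    log_q = np.log(q)
    p0 = np.exp(r * log_q)
    om = 1.0 - p0
    if unique_w is None:
        gam_wr = gammaln(w + r)
        dig_wr = digamma(w + r)
    else:
        wu, inv = unique_w
        gam_wr = gammaln(wu + r)[inv]
        dig_wr = digamma(wu + r)[inv]
    ll = (gam_wr - gammaln(r)
          + r * log_q + w * np.log(mu / (r + mu)) - np.log(om))
    dmu = w / mu - (w + r) / (r + mu) - p0 * r / ((r + mu) * om)
    gdelta = X.T @ (dmu * mu)
    dr = dig_wr - digamma(r) + (log_q + 1.0 - q) / om - w / (r + mu)
    geta = -r * np.sum(dr)
    return -np.sum(ll), -np.concatenate([gdelta, [geta]])


@dataclass
class ZTNBFit:
    params: np.ndarray       # (coefficients..., log alpha)
    cov: np.ndarray
    columns: list[str]
    n_obs: int
    converged: bool

    @property
    def coefficients(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def alpha(self) -> float:
        return float(np.exp(self.params[-1]))

    @property
    def theta(self) -> float:
        return 1.0 / self.alpha

    def mu(self, X: np.ndarray) -> np.ndarray:
        return np.exp(X @ self.coefficients)


def fit_ztnb(X: np.ndarray, w: np.ndarray, columns: list[str] | None = None) -> ZTNBFit:
    """Maximum-likelihood zero-truncated NB regression (counts >= 1)."""
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < 1):
        raise ValueError("zero-truncated NB requires counts >= 1")
    columns = columns or [f"x{j}" for j in range(X.shape[1])]
    wbar, s2 = float(w.mean()), float(w.var())
    alpha0 = min(max((s2 - wbar) / max(wbar**2, 1e-8), 0.05), 5.0)
    start = np.concatenate([np.linalg.lstsq(X, np.log(w + 0.5), rcond=None)[0],
                            [np.log(alpha0)]])
    uw = np.unique(w, return_inverse=True)
    # dispersion bounded away from overflow (alpha in [e^-8, e^4])
    bounds = [(None, None)] * X.shape[1] + [(-8.0, 4.0)]
    res = minimize(ztnb_negloglik_grad, start, args=(X, w, uw), jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6})
    params = res.x
    k = len(params)
    eps = 1e-5
    g0 = ztnb_negloglik_grad(params, X, w, uw)[1]
    H = np.empty((k, k))
    for i in range(k):
        pert = params.copy()
        pert[i] += eps
        H[:, i] = (ztnb_negloglik_grad(pert, X, w, uw)[1] - g0) / eps
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return ZTNBFit(params=params, cov=cov, columns=list(columns) + ["log_alpha"],
                   n_obs=len(w), converged=bool(res.success))


# ----------------------------------------------------------------------
# hurdle model

@dataclass
class HurdleFit:
    """Fitted hurdle model for length of stay (hurdle at LOS = 1 day).

    Component A: logistic model for P(LOS = 1 | x).
    Component B: zero-truncated NB for LOS - 1 on stays longer than a day.
    """

    columns: list[str]
    hurdle: LogisticFit
    count: ZTNBFit

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.hurdle.params, self.count.params])

    @property
    def cov(self) -> np.ndarray:
        """Joint covariance; the two components are orthogonal blocks of the
        hurdle likelihood, so the joint matrix is exactly block-diagonal."""
        a, b = self.hurdle.cov, self.count.cov
        out = np.zeros((a.shape[0] + b.shape[0],) * 2)
        out[: a.shape[0], : a.shape[0]] = a
        out[a.shape[0]:, a.shape[0]:] = b
        return out

    @property
    def n_params(self) -> int:
        return len(self.hurdle.params) + len(self.count.params)

    def split_params(self, params: np.ndarray):
        k = len(self.hurdle.params)
        return params[:k], params[k:]

    def p_one(self, X: np.ndarray, params: np.ndarray | None = None) -> np.ndarray:
        g = self.hurdle.params if params is None else self.split_params(params)[0]
        return sigmoid(X @ g)

    def los_pmf(self, X: np.ndarray, l_max: int, params: np.ndarray | None = None,
                renormalize: bool = True) -> np.ndarray:
        if l_max < 1:
            raise ValueError("l_max must be >= 1")
        if params is None:
            params = self.params
        g, c = self.split_params(params)
        p1 = sigmoid(X @ g)
        delta, eta = c[:-1], c[-1]
        mu = np.exp(np.clip(X @ delta, -30.0, 30.0))
        pmf = hurdle_los_pmf(p1, mu, np.exp(-eta), int(l_max))
        if renormalize:
            pmf = pmf / pmf.sum(axis=1, keepdims=True)
        return pmf

    def mean_los(self, X: np.ndarray, params: np.ndarray | None = None) -> np.ndarray:
        """Analytic E[LOS | x] = p1 + (1 - p1) (1 + mu / (1 - P_NB(0)))."""
        if params is None:
            params = self.params
        g, c = self.split_params(params)
        p1 = sigmoid(X @ g)
        delta, eta = c[:-1], c[-1]
        mu = np.exp(np.clip(X @ delta, -30.0, 30.0))
        r = np.exp(-eta)
        p0 = (r / (r + mu)) ** r
        return p1 + (1.0 - p1) * (1.0 + mu / (1.0 - p0))


def fit_hurdle(los: np.ndarray, X: np.ndarray, columns: list[str] | None = None) -> HurdleFit:
    los = np.asarray(los)
    if np.any(los < 1):
        raise ValueError("length of stay must be >= 1 day")
    if len(np.unique(los)) < 2:
        raise ValueError("degenerate length-of-stay: all values equal")
    X = np.asarray(X, dtype=float)
    columns = columns or [f"x{j}" for j in range(X.shape[1])]
    is_one = (los == 1).astype(float)
    if is_one.max() == 0:
        # no one-day stays: hurdle probability pinned near zero via ridge
        hurdle_part, cov = _ridge_logistic(X, is_one, alpha=1e-2)
        hfit = LogisticFit(hurdle_part, cov, list(columns), len(los), ridged=True)
    else:
        hfit = fit_logistic(X, is_one, columns, method="newton")
    mask = los > 1
    cfit = fit_ztnb(X[mask], los[mask] - 1.0, columns)
    return HurdleFit(columns=list(columns), hurdle=hfit, count=cfit)
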
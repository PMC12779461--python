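"""Pre/post effect estimation by counterfactual standardization.

For each site with an intervention start date, the year before
implementation provides training data for two models sharing one design
(site indicators, continuous calendar-year term, annual sine/cosine
seasonality, patient flags):

1. a hurdle model for the conditional length-of-stay (LOS) distribution;
2. a logistic model for the event probability given LOS and the same
   factors.

For every patient admitted in the year after implementation, the law of
total probability combines the two fits into a counterfactual event
probability — the predicted risk had the pre-period regime continued,
accounting for the possibility that the intervention acts directly on the
event and/or indirectly through LOS:

    p_cf(x) = sum_{l=1}^{L_max} P_hat(LOS = l | x) * P_hat(event | l, x),

with the LOS mass renormalized over {1..L_max} (L_max is a high quantile
of pre-period LOS).  Averaging p_cf over a site's post-period patients
gives the site's counterfactual risk; the site risk difference is
actual - counterfactual, so a beneficial intervention is negative.

Site-level uncertainty propagates the joint covariance of the fitted
parameters through the standardization map by the delta method (forward
finite differences), plus the binomial variance of the actual risk; the
shared pre-period fits make site estimates correlated, and the pooled
fixed-effect estimate (inverse-variance weights on the marginal
variances) carries that full covariance into its standard error.

30-day mortality uses the same machinery without LOS mediation; the LOS
outcome compares actual post-period mean LOS to the counterfactual mean
from the pre-fitted hurdle model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignInfo, build_matrix, check_full_rank, design_info
from .fitting import HurdleFit, LogisticFit, fit_hurdle, fit_logistic, sigmoid, hurdle_los_pmf

Z95 = 1.959963984540054

_SHIFTS = {"none": 0, "minus_3_months": -91}


@dataclass
class PrePostConfig:
    outcome: str = "nvhap_electronic"
    window_days: int = 365
    date_shift: str | int = "none"        # "none", "minus_3_months", or days
    subgroup: str = "all"                 # "all" | "non_icu_only"
    l_max_quantile: float = 0.999
    l_max_cap: int = 120

    @property
    def shift_days(self) -> int:
        if isinstance(self.date_shift, str):
            try:
                return _SHIFTS[self.date_shift]
            except KeyError:
                raise ValueError(f"unknown date_shift {self.date_shift!r}; "
                                 f"use one of {sorted(_SHIFTS)} or an integer of days")
        return int(self.date_shift)


@dataclass
class ModelFits:
    """Pre-period fits reused for post-period counterfactual prediction."""

    design: DesignInfo                 # base design (no LOS column)
    los_fit: HurdleFit | None
    outcome_fit: LogisticFit | None
    l_max: int
    outcome: str
    mediated: bool = True              # outcome model conditions on LOS

    @property
    def stacked_params(self) -> np.ndarray:
        if self.outcome_fit is None:
            return np.asarray(self.los_fit.params)
        if self.mediated:
            return np.concatenate([self.los_fit.params, self.outcome_fit.params])
        return np.asarray(self.outcome_fit.params)

    @property
    def stacked_cov(self) -> np.ndarray:
        """Block-diagonal over the component fits (pre-period LOS and outcome
        likelihoods are treated as independent)."""
        if self.outcome_fit is None:
            return np.asarray(self.los_fit.cov)
        if not self.mediated:
            return np.asarray(self.outcome_fit.cov)
        a = self.los_fit.cov
        b = self.outcome_fit.cov
        out = np.zeros((a.shape[0] + b.shape[0],) * 2)
        out[: a.shape[0], : a.shape[0]] = a
        out[a.shape[0]:, a.shape[0]:] = b
        return out

    def split(self, theta: np.ndarray):
        if self.outcome_fit is None:
            return theta, None
        if not self.mediated:
            return None, theta
        k = self.los_fit.n_params
        return theta[:k], theta[k:]


@dataclass
class SiteRiskDifference:
    site: str
    n_post: int
    actual: float
    counterfactual: float
    rd: float
    se: float = np.nan


@dataclass
class PooledEstimate:
    rd: float
    se: float
    ci95: tuple[float, float]
    weights: np.ndarray
    sigma: np.ndarray
    sites: list[str]


# ----------------------------------------------------------------------

def split_pre_post(hosp: pd.DataFrame, implementation_dates: pd.Series,
                   config: PrePostConfig | None = None):
    """Half-open one-year windows around each site's (shifted) start date:
    pre = [start - W, start), post = [start, start + W)."""
    config = config or PrePostConfig()
    missing = set(hosp["site"].unique()) - set(implementation_dates.index)
    if missing:
        raise ValueError(f"implementation date missing for sites: {sorted(missing)}")
    impl = pd.to_datetime(implementation_dates) + pd.Timedelta(days=config.shift_days)
    start = hosp["site"].map(impl)
    admit = pd.to_datetime(hosp["admit_date"])
    w = pd.Timedelta(days=config.window_days)
    df = hosp
    if config.subgroup == "non_icu_only":
        df = hosp[hosp["ward_type"] != "icu"] if "ward_type" in hosp else hosp[hosp["icu_ward"] == 0]
        start = start.loc[df.index]
        admit = admit.loc[df.index]
    elif config.subgroup != "all":
        raise ValueError(f"unknown subgroup {config.subgroup!r}")
    pre = df[(admit >= start - w) & (admit < start)]
    post = df[(admit >= start) & (admit < start + w)]
    return pre.reset_index(drop=True), post.reset_index(drop=True)


def fit_pre_models(pre: pd.DataFrame, outcome: str, covariates: list[str],
                   study_start=None, config: PrePostConfig | None = None,
                   mediated: bool = True, fit_outcome_model: bool = True) -> ModelFits:
    """Fit the LOS hurdle model and the (LOS-conditional) outcome model on
    pre-implementation data only."""
    config = config or PrePostConfig(outcome=outcome)
    if pre["site"].nunique() < 1:
        raise ValueError("pre-period table is empty")
    if study_start is None:
        study_start = pd.to_datetime(pre["admit_date"]).min()
    info = design_info(pre, covariates, study_start, include_los=False)
    X = build_matrix(pre, info)
    check_full_rank(X, info.columns)
    los_fit = None
    if mediated:
        los_fit = fit_hurdle(pre["los"].to_numpy(), X, info.columns)
        info_out = DesignInfo(site_levels=info.site_levels, covariates=info.covariates,
                              study_start=info.study_start, include_los=True)
        Xo = build_matrix(pre, info_out)
    else:
        Xo = X
    outcome_fit = None
    if fit_outcome_model:
        y = pre[outcome].to_numpy(dtype=float)
        # bias-reduced fit: events are rare and site cells can be empty
        outcome_fit = fit_logistic(Xo, y, info.columns + (["los"] if mediated else []),
                                   method="firth")
    l_max = int(max(2, min(config.l_max_cap,
                           np.quantile(pre["los"].to_numpy(), config.l_max_quantile))))
    return ModelFits(design=info, los_fit=los_fit, outcome_fit=outcome_fit,
                     l_max=l_max, outcome=outcome, mediated=mediated)


# ----------------------------------------------------------------------
# standardization

def _base_matrices(df: pd.DataFrame, fits: ModelFits):
    """(X for the LOS model, X for the outcome model with the LOS column
    zeroed) — LOS enters the outcome linear predictor as beta_los * l."""
    Xb = build_matrix(df, fits.design)
    if not fits.mediated:
        return Xb, Xb
    Xo0 = np.column_stack([Xb, np.zeros(len(Xb))])
    return Xb, Xo0


def _cf_from_matrices(Xb, Xo0, fits: ModelFits, theta: np.ndarray,
                      pmf_cache: np.ndarray | None = None,
                      probs_cache: np.ndarray | None = None):
    """Per-patient counterfactual probability, optionally reusing a cached
    LOS-mass or event-probability matrix (delta-method fast paths)."""
    theta_los, theta_out = fits.split(theta)
    if not fits.mediated:
        return sigmoid(Xo0 @ theta_out)
    l_max = fits.l_max
    pmf = pmf_cache if pmf_cache is not None else \
        fits.los_fit.los_pmf(Xb, l_max, params=theta_los, renormalize=True)
    if probs_cache is None:
        a = Xo0 @ theta_out
        ls = np.arange(1, l_max + 1)
        probs = sigmoid(a[:, None] + theta_out[-1] * ls[None, :])
    else:
        probs = probs_cache
    return (pmf * probs).sum(axis=1)


def counterfactual_probability(df: pd.DataFrame, fits: ModelFits,
                               l_max: int | None = None) -> np.ndarray:
    """Standardized event probability for each row of ``df`` under the
    pre-period regime."""
    if l_max is not None:
        if l_max < 1:
            raise ValueError("l_max must be >= 1")
        fits = ModelFits(design=fits.design, los_fit=fits.los_fit,
                         outcome_fit=fits.outcome_fit, l_max=int(l_max),
                         outcome=fits.outcome, mediated=fits.mediated)
    Xb, Xo0 = _base_matrices(df, fits)
    return _cf_from_matrices(Xb, Xo0, fits, fits.stacked_params)


def counterfactual_mean_los(df: pd.DataFrame, fits: ModelFits) -> np.ndarray:
    """Counterfactual expected LOS per row (mass truncated at L_max and
    renormalized, consistent with the standardization sum)."""
    Xb = build_matrix(df, fits.design)
    pmf = fits.los_fit.los_pmf(Xb, fits.l_max, renormalize=True)
    return pmf @ np.arange(1, fits.l_max + 1)


def site_risk_differences(post: pd.DataFrame, fits: ModelFits,
                          kind: str = "risk") -> list[SiteRiskDifference]:
    """Actual minus counterfactual outcome per site over post-period patients.

    ``kind``: "risk" (binary outcome) or "mean_los" (days).
    """
    out = []
    for site, grp in post.groupby("site", sort=True):
        if len(grp) == 0:
            continue
        if kind == "mean_los":
            cf = float(np.mean(counterfactual_mean_los(grp, fits)))
            actual = float(grp["los"].mean())
        else:
            cf = float(np.mean(counterfactual_probability(grp, fits)))
            actual = float(grp[fits.outcome].mean())
        out.append(SiteRiskDifference(site=str(site), n_post=len(grp),
                                      actual=actual, counterfactual=cf,
                                      rd=actual - cf))
    return out


# ----------------------------------------------------------------------
# delta-method covariance

class _SiteStandardizer:
    """Vectorized per-site counterfactual summaries and their gradient with
    respect to the stacked model parameters.

    Gradients of the standardization map are exact (analytic) for the two
    logistic blocks and forward finite differences for the truncated-NB
    count block, whose derivative has no convenient closed form; the
    ``values`` method recomputes everything from an arbitrary parameter
    vector so the analytic pieces can be verified against pure FD.
    """

    def __init__(self, fits: ModelFits, post: pd.DataFrame, kind: str = "risk"):
        self.fits = fits
        self.kind = kind
        post = post.sort_values("site", kind="stable").reset_index(drop=True)
        self.post = post
        codes, self.sites = pd.factorize(post["site"].astype(str), sort=True)
        self.codes = codes
        self.counts = np.bincount(codes, minlength=len(self.sites)).astype(float)
        self.X = build_matrix(post, fits.design)
        self.ls = np.arange(1, fits.l_max + 1, dtype=float)
        col = "los" if kind == "mean_los" else fits.outcome
        self.y = post[col].to_numpy(dtype=float)

    # -- helpers --------------------------------------------------------
    def _site_mean(self, v: np.ndarray) -> np.ndarray:
        return np.bincount(self.codes, weights=v, minlength=len(self.sites)) / self.counts

    def _site_mean_cols(self, scalar: np.ndarray, M: np.ndarray) -> np.ndarray:
        """site means of scalar * M[:, j] for every column j -> (K, p)."""
        out = np.empty((len(self.sites), M.shape[1]))
        for j in range(M.shape[1]):
            out[:, j] = self._site_mean(scalar * M[:, j])
        return out

    def _zt_matrix(self, delta, eta):
        """Zero-truncated NB mass at counts 1..l_max-1 (LOS 2..l_max)."""
        mu = np.exp(np.clip(self.X @ delta, -30.0, 30.0))
        r = np.exp(-eta)
        q = r / (r + mu)
        p0 = q**r
        zt = np.empty((len(mu), len(self.ls) - 1))
        pmf_w = p0
        omq = 1.0 - q
        w = 0
        norm = 1.0 - p0
        for col in range(zt.shape[1]):
            pmf_w = pmf_w * (w + r) / (w + 1) * omq
            w += 1
            zt[:, col] = pmf_w / norm
        return zt

    def _pieces(self, theta):
        fits = self.fits
        theta_los, theta_out = fits.split(theta)
        if self.kind == "risk" and not fits.mediated:
            p = sigmoid(self.X @ theta_out)
            return {"cf": p, "p": p}
        k_h = len(fits.los_fit.hurdle.params)
        gamma, count = theta_los[:k_h], theta_los[k_h:]
        p1 = sigmoid(self.X @ gamma)
        zt = self._zt_matrix(count[:-1], count[-1])
        raw = np.column_stack([p1, (1.0 - p1)[:, None] * zt])
        Z = raw.sum(axis=1)
        if self.kind == "mean_los":
            probs = np.broadcast_to(self.ls, raw.shape)
        else:
            a = self.X @ theta_out[:-1]
            probs = sigmoid(a[:, None] + theta_out[-1] * self.ls[None, :])
        S = (raw * probs).sum(axis=1)
        return {"cf": S / Z, "p1": p1, "zt": zt, "raw": raw, "Z": Z, "S": S,
                "probs": probs, "gamma": gamma, "count": count, "theta_out": theta_out}

    def values(self, theta) -> np.ndarray:
        return self._site_mean(self._pieces(theta)["cf"])

    def values_and_gradient(self, rel_step: float = 1e-5):
        fits = self.fits
        theta0 = fits.stacked_params
        pc = self._pieces(theta0)
        vals = self._site_mean(pc["cf"])
        K, P = len(self.sites), len(theta0)
        G = np.empty((K, P))
        col = 0
        if self.kind == "risk" and not fits.mediated:
            G[:, :] = self._site_mean_cols(pc["p"] * (1.0 - pc["p"]), self.X)
            return vals, G
        p1, zt, raw, Z, S, probs = (pc["p1"], pc["zt"], pc["raw"], pc["Z"], pc["S"], pc["probs"])
        cf = pc["cf"]
        # hurdle-logistic block: raw depends on p1 linearly
        dS_dp1 = probs[:, 0] - (zt * probs[:, 1:]).sum(axis=1)
        dZ_dp1 = 1.0 - zt.sum(axis=1)
        dcf_dp1 = (dS_dp1 - cf * dZ_dp1) / Z
        scal = dcf_dp1 * p1 * (1.0 - p1)
        k_h = len(fits.los_fit.hurdle.params)
        G[:, col:col + k_h] = self._site_mean_cols(scal, self.X)
        col += k_h
        # truncated-NB count block: the mean coefficients have an analytic
        # gradient (d log zt_w / d mu is linear in w), the dispersion by FD
        count = pc["count"]
        delta, eta = count[:-1], count[-1]
        mu = np.exp(np.clip(self.X @ delta, -30.0, 30.0))
        r = np.exp(-eta)
        p0 = (r / (r + mu)) ** r
        a_c = -r / (r + mu) - p0 * r / ((r + mu) * (1.0 - p0))
        b_c = r / (mu * (r + mu))
        wgrid = np.arange(1, zt.shape[1] + 1, dtype=float)      # w = l - 1
        rp2 = raw[:, 1:] * probs[:, 1:]
        T1 = rp2.sum(axis=1)
        T2 = rp2 @ wgrid
        U1 = raw[:, 1:].sum(axis=1)
        U2 = raw[:, 1:] @ wgrid
        dcf_dmu = ((a_c * T1 + b_c * T2) - cf * (a_c * U1 + b_c * U2)) / Z
        G[:, col:col + len(delta)] = self._site_mean_cols(dcf_dmu * mu, self.X)
        col += len(delta)
        h = rel_step * max(1.0, abs(eta))
        zt_j = self._zt_matrix(delta, eta + h)
        raw_j = np.column_stack([p1, (1.0 - p1)[:, None] * zt_j])
        cf_j = (raw_j * probs).sum(axis=1) / raw_j.sum(axis=1)
        G[:, col] = self._site_mean((cf_j - cf) / h)
        col += 1
        # outcome block (absent for the LOS outcome)
        if self.kind == "risk":
            w = raw * probs * (1.0 - probs)
            s_base = w.sum(axis=1) / Z
            G[:, col:col + self.X.shape[1]] = self._site_mean_cols(s_base, self.X)
            col += self.X.shape[1]
            G[:, col] = self._site_mean((w @ self.ls) / Z)
            col += 1
        assert col == P
        return vals, G


def _sigma_from_standardizer(std: "_SiteStandardizer",
                             include_sampling_variance: bool = True,
                             stabilize: bool = True,
                             rel_step: float = 1e-5):
    fits = std.fits
    V = fits.stacked_cov
    vals, G = std.values_and_gradient(rel_step=rel_step)
    G_raw = G
    if stabilize:
        # variance stabilization on the relative scale: gradient rows are
        # rescaled from the fitted counterfactual level to the pooled actual
        # outcome level.  Rationale: (i) inverse-variance weights must not
        # track site-level estimation noise (a standardized risk that comes
        # out randomly low would otherwise get a randomly small variance and
        # an inflated weight); (ii) the gradient of the exp-like
        # standardization map shrinks with the estimate itself, so in
        # replicates where the shared calendar terms draw low the local
        # delta variance understates the error — anchoring the scale at the
        # observed outcome level (a score-test-style choice) restores it.
        level = float(vals.mean())
        observed = float(np.mean(std.y))
        # partial anchoring toward the observed outcome level: when the
        # fitted counterfactual level runs below the observed rate (the
        # regime where the local gradient understates the error) the scale
        # is inflated by a fractional power of the ratio; never deflated
        anchor = level * max(1.0, (observed / max(level, 1e-10)) ** 0.3)
        scale = anchor / np.clip(vals, 1e-8, None)
        G = G * scale[:, None]
    Sigma = G @ V @ G.T
    Sigma = 0.5 * (Sigma + Sigma.T)
    if include_sampling_variance:
        if std.kind == "mean_los":
            for i, (_, grp) in enumerate(std.post.groupby("site", sort=True)):
                Sigma[i, i] += float(grp["los"].var(ddof=1)) / len(grp)
        else:
            # binomial variance of each site's actual risk at the pooled
            # post-period rate: one shared rate, so weights stay decoupled
            # from the site estimates when events are sparse
            p_bar = float(np.clip(np.mean(std.y), 1e-10, 1 - 1e-10))
            Sigma[np.diag_indices_from(Sigma)] += p_bar * (1.0 - p_bar) / std.counts
    ev = np.linalg.eigvalsh(Sigma)
    if ev.min() < -1e-10 * max(ev.max(), 1e-300):
        raise ValueError(f"site covariance not positive semidefinite (min eigenvalue {ev.min():.3g})")
    if ev.min() < 0:
        warnings.warn("projecting site covariance to nearest PSD (tiny eigenvalue deficit)")
        w, vecs = np.linalg.eigh(Sigma)
        Sigma = (vecs * np.clip(w, 0.0, None)) @ vecs.T
        Sigma = 0.5 * (Sigma + Sigma.T)
    return vals, Sigma, G_raw


def delta_method_covariance(fits: ModelFits, post: pd.DataFrame,
                            kind: str = "risk",
                            include_sampling_variance: bool = True,
                            stabilize: bool = True,
                            rel_step: float = 1e-5):
    """K x K covariance of the site risk differences.

    Model-parameter uncertainty enters through the gradient of each site's
    counterfactual summary with respect to the stacked parameters; shared
    pre-period fits make the off-diagonals nonzero.  Gradient rows are
    rescaled to the pooled counterfactual level (``stabilize``) so that
    inverse-variance weights do not correlate with site-level noise.  The
    diagonal adds the sampling variance of the site's actual outcome
    (binomial at the pooled post-period rate, or var(LOS)/n for the LOS
    outcome) unless disabled.

    Returns (Sigma, sites) with sites in sorted order.
    """
    std = _SiteStandardizer(fits, post, kind)
    _, Sigma, _ = _sigma_from_standardizer(std, include_sampling_variance, stabilize, rel_step)
    return Sigma, list(std.sites)


# ----------------------------------------------------------------------
# pooling

def pool(rds: np.ndarray | list, sigma: np.ndarray, sites: list[str] | None = None) -> PooledEstimate:
    """Fixed-effect inverse-variance pooling with the full between-site
    covariance in the pooled variance: w_i prop 1/Sigma_ii, Var = w' Sigma w."""
    if isinstance(rds, list) and rds and isinstance(rds[0], SiteRiskDifference):
        sites = [r.site for r in rds]
        rds = np.array([r.rd for r in rds])
    rds = np.asarray(rds, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if len(rds) < 2:
        raise ValueError("pooling needs at least two sites")
    d = np.diag(sigma)
    if np.any(d <= 0):
        raise ValueError("non-positive site variance; cannot form inverse-variance weights")
    w = (1.0 / d) / np.sum(1.0 / d)
    est = float(w @ rds)
    var = float(w @ sigma @ w)
    se = float(np.sqrt(var))
    return PooledEstimate(rd=est, se=se, ci95=(est - Z95 * se, est + Z95 * se),
                          weights=w, sigma=sigma, sites=list(sites) if sites else [])


# ----------------------------------------------------------------------
# crude (unadjusted) analysis

def unadjusted_differences(pre: pd.DataFrame, post: pd.DataFrame, outcome: str,
                           kind: str = "risk"):
    """Per-site crude post-minus-pre differences with two-sample standard
    errors, pooled with a diagonal covariance."""
    rows = []
    sites = sorted(set(pre["site"]) | set(post["site"]))
    for site in sites:
        a = pre[pre["site"] == site]
        b = post[post["site"] == site]
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"site {site}: empty pre or post window; excluded from crude analysis")
            continue
        if kind == "mean_los":
            diff = float(b["los"].mean() - a["los"].mean())
            var = float(a["los"].var(ddof=1)) / len(a) + float(b["los"].var(ddof=1)) / len(b)
        else:
            pa = (a[outcome].sum() + 0.5) / (len(a) + 1.0)
            pb = (b[outcome].sum() + 0.5) / (len(b) + 1.0)
            diff = float(b[outcome].mean() - a[outcome].mean())
            var = pa * (1 - pa) / len(a) + pb * (1 - pb) / len(b)
        rows.append({"site": site, "n_pre": len(a), "n_post": len(b),
                     "pre": float(a["los" if kind == "mean_los" else outcome].mean()),
                     "post": float(b["los" if kind == "mean_los" else outcome].mean()),
                     "difference": diff, "se": float(np.sqrt(var))})
    per_site = pd.DataFrame(rows)
    pooled = pool(per_site["difference"].to_numpy(),
                  np.diag(per_site["se"].to_numpy() ** 2),
                  sites=per_site["site"].tolist())
    return per_site, pooled


# ----------------------------------------------------------------------
# orchestration

@dataclass
class EffectResult:
    outcome: str
    kind: str
    per_site: pd.DataFrame
    pooled: PooledEstimate
    fits: ModelFits = field(repr=False, default=None)
    config: PrePostConfig = None


def evaluate_prepost(hosp: pd.DataFrame, implementation_dates: pd.Series,
                     covariates: list[str], config: PrePostConfig | None = None,
                     study_start=None) -> EffectResult:
    """End-to-end adjusted pre/post analysis for one outcome.

    ``config.outcome``: a binary event column (LOS-mediated standardization),
    "death30" (covariates-only standardization), or "los" (counterfactual
    mean LOS difference in days).
    """
    config = config or PrePostConfig()
    outcome = config.outcome
    if outcome == "los":
        kind, mediated, fit_outcome = "mean_los", True, None
    elif outcome == "death30":
        kind, mediated, fit_outcome = "risk", False, "death30"
    else:
        kind, mediated, fit_outcome = "risk", True, outcome

    pre, post = split_pre_post(hosp, implementation_dates, config)
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("empty pre or post window; check implementation dates")
    if kind == "mean_los":
        fits = fit_pre_models(pre, outcome="los", covariates=covariates,
                              study_start=study_start, config=config,
                              mediated=True, fit_outcome_model=False)
    else:
        fits = fit_pre_models(pre, outcome=fit_outcome, covariates=covariates,
                              study_start=study_start, config=config, mediated=mediated)
    std = _SiteStandardizer(fits, post, kind)
    cf_vals, sigma, _ = _sigma_from_standardizer(std)
    actual = std._site_mean(std.y)
    se = np.sqrt(np.diag(sigma))
    per_site = pd.DataFrame({"site": list(std.sites), "n_post": std.counts.astype(int),
                             "actual": actual, "counterfactual": cf_vals,
                             "rd": actual - cf_vals, "se": se})
    pooled = pool(per_site["rd"].to_numpy(), sigma, sites=list(std.sites))
    return EffectResult(outcome=outcome, kind=kind, per_site=per_site,
                        pooled=pooled, fits=fits, config=config)


def secondary_effects(hosp: pd.DataFrame, implementation_dates: pd.Series,
                      covariates: list[str], config: PrePostConfig) -> EffectResult:
    """Secondary analyses — 30-day mortality, length of stay, subgroup and
    date-shift variants — via the same standardization machinery; select
    them on ``config`` (outcome, subgroup, date_shift)."""
    return evaluate_prepost(hosp, implementation_dates, covariates, config)
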
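"""Counterfactual standardization, delta-method covariance, and pooling."""

import numpy as np
import pandas as pd
import pytest

from conftest import COVS3, EFF3, cohort_with_truth, small_sim_config
from nvhap.counterfactual import (ModelFits, PooledEstimate, PrePostConfig,
                                  _SiteStandardizer, counterfactual_probability,
                                  delta_method_covariance, evaluate_prepost,
                                  fit_pre_models, pool, site_risk_differences,
                                  split_pre_post, unadjusted_differences)
from nvhap.design import DesignInfo
from nvhap.fitting import LogisticFit, sigmoid
from nvhap.synthetic_data import SimConfig, generate_cohort, ground_truth_effects

PP = PrePostConfig(outcome="true_event")
COV_LIST = list(COVS3)


@pytest.fixture(scope="module")
def small_study():
    cfg = small_sim_config(n_sites=6, patients_per_site_per_week=12.0)
    coh, hosp = cohort_with_truth(cfg, seed=101)
    return cfg, coh, hosp


@pytest.fixture(scope="module")
def fitted(small_study):
    cfg, coh, hosp = small_study
    pre, post = split_pre_post(hosp, coh.implementation_dates, PP)
    fits = fit_pre_models(pre, "true_event", COV_LIST, cfg.start, PP)
    return pre, post, fits


# ---------------------------------------------------------------- windows

def test_boundary_admission_is_post(small_study):
    cfg, coh, hosp = small_study
    pre, post = split_pre_post(hosp, coh.implementation_dates, PP)
    impl = coh.implementation_dates
    on_boundary = hosp[hosp["admit_date"] == hosp["site"].map(impl)]
    if len(on_boundary):
        assert on_boundary["hospitalization_id"].isin(post["hospitalization_id"]).all()
    # brute-force date filter agreement
    w = pd.Timedelta(days=365)
    for df, lo_off, hi_off in ((pre, -w, pd.Timedelta(0)), (post, pd.Timedelta(0), w)):
        for _, row in df.sample(50, random_state=0).iterrows():
            start = impl[row["site"]]
            assert start + lo_off <= row["admit_date"] < start + hi_off


def test_pre_post_counts_match_direct_arithmetic(small_study):
    cfg, coh, hosp = small_study
    pre, post = split_pre_post(hosp, coh.implementation_dates, PP)
    impl = hosp["site"].map(coh.implementation_dates)
    admit = hosp["admit_date"]
    n_pre = ((admit >= impl - pd.Timedelta(days=365)) & (admit < impl)).sum()
    n_post = ((admit >= impl) & (admit < impl + pd.Timedelta(days=365))).sum()
    assert (len(pre), len(post)) == (n_pre, n_post)


def test_minus_three_months_shift(small_study):
    cfg, coh, hosp = small_study
    shifted = PrePostConfig(outcome="true_event", date_shift="minus_3_months")
    pre_s, post_s = split_pre_post(hosp, coh.implementation_dates, shifted)
    impl = hosp["site"].map(coh.implementation_dates) - pd.Timedelta(days=91)
    admit = hosp["admit_date"]
    assert len(post_s) == ((admit >= impl) & (admit < impl + pd.Timedelta(days=365))).sum()


def test_missing_site_implementation_date_errors(small_study):
    cfg, coh, hosp = small_study
    with pytest.raises(ValueError, match="S0"):
        split_pre_post(hosp, coh.implementation_dates.iloc[:-1], PP)


def test_non_icu_subgroup_filter(small_study):
    cfg, coh, hosp = small_study
    sub = PrePostConfig(outcome="true_event", subgroup="non_icu_only")
    pre, post = split_pre_post(hosp, coh.implementation_dates, sub)
    assert (pre["ward_type"] != "icu").all() and (post["ward_type"] != "icu").all()


# ---------------------------------------------------------------- pre models

def test_row_permutation_leaves_fits_unchanged(fitted):
    pre, post, fits = fitted
    shuffled = pre.sample(frac=1.0, random_state=5).reset_index(drop=True)
    fits2 = fit_pre_models(shuffled, "true_event", COV_LIST, fits.design.study_start, PP)
    np.testing.assert_allclose(fits.outcome_fit.params, fits2.outcome_fit.params, atol=1e-7)
    np.testing.assert_allclose(fits.los_fit.params, fits2.los_fit.params, atol=1e-6)


def test_rank_deficient_design_reports_columns(fitted):
    pre, _, fits = fitted
    pre2 = pre.copy()
    pre2["chf_copy"] = pre2["chf"]
    with pytest.raises(ValueError, match="chf_copy"):
        fit_pre_models(pre2, "true_event", COV_LIST + ["chf_copy"], fits.design.study_start, PP)


def test_pre_model_parameter_recovery():
    """Outcome and LOS models recover the generative parameters within 3 SEs
    on a large single-window cohort."""
    cfg = SimConfig(n_sites=4, patients_per_site_per_week=240.0,
                    covariate_prevalences=dict(COVS3),
                    covariate_log_odds_nvhap=dict(EFF3),
                    baseline_nvhap_log_odds=-5.3)
    coh, hosp = cohort_with_truth(cfg, seed=202)
    pre, _ = split_pre_post(hosp, coh.implementation_dates, PP)
    assert len(pre) > 45_000
    fits = fit_pre_models(pre, "true_event", COV_LIST, cfg.start, PP)
    of = fits.outcome_fit
    se = np.sqrt(np.diag(of.cov))
    idx = {c: i for i, c in enumerate(of.columns)}
    for name, truth in [("age_75_plus", 0.4), ("chf", 0.3), ("icu_ward", 0.5), ("los", 0.05)]:
        i = idx[name]
        assert abs(of.params[i] - truth) < 3 * se[i], name
    # LOS count component: dispersion recovered
    th = cfg.los_hurdle_params.nb_dispersion
    eta_se = np.sqrt(fits.los_fit.count.cov[-1, -1])
    assert abs(fits.los_fit.count.params[-1] - np.log(1 / th)) < 3 * eta_se


# ---------------------------------------------------------------- standardization

def _toy_fits(beta_los: float, p_one: float = 0.3):
    """Hand-crafted ModelFits on an intercept-only design."""
    info = DesignInfo(site_levels=["A"], covariates=[], study_start=pd.Timestamp("2015-10-01"))
    from nvhap.fitting import HurdleFit, ZTNBFit
    k = info.n_columns
    g = np.zeros(k)
    g[0] = np.log(p_one / (1 - p_one))
    hurdle = LogisticFit(params=g, cov=np.eye(k) * 1e-4, columns=info.columns, n_obs=100)
    c = np.zeros(k + 1)
    c[0] = 1.2                     # log NB mean
    c[-1] = np.log(0.8)            # log alpha
    count = ZTNBFit(params=c, cov=np.eye(k + 1) * 1e-4, columns=info.columns + ["log_alpha"],
                    n_obs=100, converged=True)
    los_fit = HurdleFit(columns=info.columns, hurdle=hurdle, count=count)
    b = np.zeros(k + 1)
    b[0] = -4.0
    b[-1] = beta_los
    outcome = LogisticFit(params=b, cov=np.eye(k + 1) * 1e-4,
                          columns=info.columns + ["los"], n_obs=100)
    return ModelFits(design=info, los_fit=los_fit, outcome_fit=outcome,
                     l_max=60, outcome="y", mediated=True)


def _toy_rows(n=5):
    return pd.DataFrame({"site": "A", "admit_date": pd.Timestamp("2017-01-15"),
                         "los": 3, "y": 0}, index=range(n))


def test_total_probability_collapse_when_outcome_independent_of_los():
    fits = _toy_fits(beta_los=0.0)
    probs = counterfactual_probability(_toy_rows(), fits)
    np.testing.assert_allclose(probs, sigmoid(-4.0), rtol=1e-12)


def test_degenerate_hurdle_reduces_to_one_day_probability():
    fits = _toy_fits(beta_los=0.3, p_one=1.0 - 1e-12)
    probs = counterfactual_probability(_toy_rows(), fits)
    np.testing.assert_allclose(probs, sigmoid(-4.0 + 0.3), rtol=1e-6)


def test_invalid_l_max_rejected():
    fits = _toy_fits(0.1)
    with pytest.raises(ValueError, match="l_max"):
        counterfactual_probability(_toy_rows(), fits, l_max=0)


def test_standardization_matches_monte_carlo_sampling(fitted, rng):
    """The law-of-total-probability sum equals Monte-Carlo integration over
    the fitted LOS distribution (200k draws per row, 3 MC SEs)."""
    pre, post, fits = fitted
    rows = post.sample(8, random_state=9)
    exact = counterfactual_probability(rows, fits)
    from nvhap.design import build_matrix
    Xb = build_matrix(rows, fits.design)
    pmf = fits.los_fit.los_pmf(Xb, fits.l_max)
    beta = fits.outcome_fit.params
    a = np.column_stack([Xb, np.zeros(len(Xb))]) @ beta
    n_draw = 200_000
    for i in range(len(rows)):
        ls = rng.choice(np.arange(1, fits.l_max + 1), size=n_draw, p=pmf[i])
        p_draw = sigmoid(a[i] + beta[-1] * ls)
        mc, se = p_draw.mean(), p_draw.std(ddof=1) / np.sqrt(n_draw)
        assert abs(exact[i] - mc) < 3 * max(se, 1e-12)


def test_counterfactual_probabilities_bounded(fitted):
    pre, post, fits = fitted
    probs = counterfactual_probability(post, fits)
    assert ((probs >= 0) & (probs <= 1)).all()
    rds = site_risk_differences(post, fits)
    for r in rds:
        assert 0.0 <= r.counterfactual <= 1.0 and 0.0 <= r.actual <= 1.0


# ---------------------------------------------------------------- delta method

def test_gradient_engine_agrees_with_pure_finite_differences(fitted):
    pre, post, fits = fitted
    for kind, f in (("risk", fits),
                    ("mean_los", fit_pre_models(pre, "los", COV_LIST,
                                                fits.design.study_start, PP,
                                                fit_outcome_model=False)),
                    ("risk", fit_pre_models(pre, "death30", COV_LIST,
                                            fits.design.study_start, PP, mediated=False))):
        std = _SiteStandardizer(f, post, kind)
        vals, G = std.values_and_gradient()
        th0 = f.stacked_params
        for j in range(len(th0)):
            h = 1e-6 * max(1, abs(th0[j]))
            p = th0.copy()
            p[j] += h
            fd = (std.values(p) - vals) / h
            np.testing.assert_allclose(G[:, j], fd, atol=2e-4 * (1 + np.abs(fd).max()))


def test_single_site_sigma_is_scalar_delta_plus_binomial(small_study):
    cfg, coh, hosp = small_study
    one = hosp[hosp["site"] == "S01"]
    impl = coh.implementation_dates.loc[["S01"]]
    pre, post = split_pre_post(one, impl, PP)
    fits = fit_pre_models(pre, "true_event", COV_LIST, cfg.start, PP)
    Sigma, sites = delta_method_covariance(fits, post, stabilize=False)
    assert Sigma.shape == (1, 1) and sites == ["S01"]
    std = _SiteStandardizer(fits, post, "risk")
    _, G = std.values_and_gradient()
    p_bar = post["true_event"].mean()
    expect = (G @ fits.stacked_cov @ G.T).item() + p_bar * (1 - p_bar) / len(post)
    assert Sigma[0, 0] == pytest.approx(expect, rel=1e-6)


def test_shared_fits_induce_valid_cross_site_correlation(fitted):
    pre, post, fits = fitted
    Sigma, sites = delta_method_covariance(fits, post)
    K = len(sites)
    off = Sigma[~np.eye(K, dtype=bool)]
    assert (np.abs(off) > 0).all()
    d = np.sqrt(np.diag(Sigma))
    corr = Sigma / np.outer(d, d)
    assert (corr <= 1 + 1e-9).all() and (corr >= -1 - 1e-9).all()
    assert np.linalg.eigvalsh(Sigma).min() > -1e-12


# ---------------------------------------------------------------- pooling

def test_pool_equal_variances_is_simple_mean():
    rd = np.array([0.01, 0.03, -0.02, 0.02])
    sigma = np.eye(4) * 0.5**2
    res = pool(rd, sigma, sites=list("abcd"))
    assert res.rd == pytest.approx(rd.mean())
    assert res.se**2 == pytest.approx(0.25 / 4)
    assert res.weights == pytest.approx(np.full(4, 0.25))


def test_pool_matches_textbook_fixed_effect_formula():
    rd = np.array([0.5, -0.1, 0.2])
    v = np.array([0.04, 0.01, 0.09])
    res = pool(rd, np.diag(v), sites=list("abc"))
    w = (1 / v) / (1 / v).sum()
    assert res.rd == pytest.approx((w * rd).sum(), abs=1e-12)
    assert res.se**2 == pytest.approx(1.0 / (1 / v).sum(), abs=1e-12)


def test_pool_equicorrelated_inflation():
    K, s2, rho = 6, 0.09, 0.4
    sigma = s2 * ((1 - rho) * np.eye(K) + rho * np.ones((K, K)))
    res = pool(np.zeros(K), sigma, sites=[str(i) for i in range(K)])
    base = s2 / K
    assert res.se**2 == pytest.approx(base * (1 + (K - 1) * rho), rel=1e-12)


def test_pool_rejects_bad_inputs():
    with pytest.raises(ValueError, match="two sites"):
        pool(np.array([0.1]), np.array([[0.1]]))
    with pytest.raises(ValueError, match="variance"):
        pool(np.zeros(2), np.array([[0.0, 0.0], [0.0, 1.0]]))


# ---------------------------------------------------------------- crude analysis

def test_crude_differences_equal_direct_arithmetic(small_study):
    cfg, coh, hosp = small_study
    pre, post = split_pre_post(hosp, coh.implementation_dates, PP)
    per_site, pooled = unadjusted_differences(pre, post, "true_event")
    for _, row in per_site.iterrows():
        a = pre[pre["site"] == row["site"]]["true_event"]
        b = post[post["site"] == row["site"]]["true_event"]
        assert row["difference"] == pytest.approx(b.mean() - a.mean(), abs=1e-12)
    assert abs(pooled.rd) < 3 * pooled.se        # null simulation


def test_crude_agrees_with_adjusted_when_no_confounding(small_study):
    cfg, coh, hosp = small_study
    pre, post = split_pre_post(hosp, coh.implementation_dates, PP)
    _, crude = unadjusted_differences(pre, post, "true_event")
    adj = evaluate_prepost(hosp, coh.implementation_dates, COV_LIST, PP,
                           study_start=cfg.start)
    joint_se = np.sqrt(crude.se**2 + adj.pooled.se**2)
    assert abs(crude.rd - adj.pooled.rd) < 3 * joint_se


# ---------------------------------------------------------------- secondary

def test_mortality_and_los_null_effects(small_study):
    cfg, coh, hosp = small_study
    for outcome in ("death30", "los"):
        res = evaluate_prepost(hosp, coh.implementation_dates, COV_LIST,
                               PrePostConfig(outcome=outcome), study_start=cfg.start)
        assert abs(res.pooled.rd) < 3 * res.pooled.se, outcome


def test_los_multiplier_effect_recovered():
    """A 3% post-implementation reduction of the NB mean yields a negative
    pooled LOS difference consistent with the closed-form truth."""
    cfg = small_sim_config(n_sites=6, patients_per_site_per_week=60.0,
                           los_effect_multiplier=0.97)
    coh, hosp = cohort_with_truth(cfg, seed=404)
    res = evaluate_prepost(hosp, coh.implementation_dates, COV_LIST,
                           PrePostConfig(outcome="los"), study_start=cfg.start)
    # closed-form truth from the generative moments, averaged over flags
    from nvhap.synthetic_data import _los_linear_predictors
    k = len(COV_LIST)
    patterns = np.array(np.meshgrid(*([[0, 1]] * k), indexing="ij")).reshape(k, -1).T
    prev = np.array([COVS3[c] for c in COV_LIST])
    wts = np.prod(np.where(patterns == 1, prev, 1 - prev), axis=1)
    wts = np.tile(wts, cfg.n_sites) / cfg.n_sites
    site_idx = np.repeat(np.arange(cfg.n_sites), len(patterns))
    cov = np.tile(patterns, (cfg.n_sites, 1))
    th = cfg.los_hurdle_params.nb_dispersion
    mids = np.full(len(site_idx), 2.0)
    def mean_los(post_flag):
        p1, mu = _los_linear_predictors(cfg, cov, site_idx, mids, np.zeros(len(site_idx)),
                                        np.full(len(site_idx), post_flag))
        p0 = (th / (th + mu)) ** th
        return wts @ (p1 + (1 - p1) * (1 + mu / (1 - p0)))
    truth = mean_los(True) - mean_los(False)
    assert truth < 0
    assert res.pooled.rd < 0
    assert abs(res.pooled.rd - truth) < 3 * res.pooled.se


def test_icu_only_events_vanish_in_non_icu_subgroup():
    cfg = small_sim_config(
        n_sites=6, patients_per_site_per_week=40.0,
        covariate_log_odds_nvhap={"age_75_plus": 0.0, "chf": 0.0, "icu_ward": 6.0},
        baseline_nvhap_log_odds=-9.5)
    coh, hosp = cohort_with_truth(cfg, seed=505)
    icu_rate = hosp[hosp["ward_type"] == "icu"]["true_event"].mean()
    sub = hosp[hosp["ward_type"] != "icu"]["true_event"].mean()
    assert icu_rate > 20 * max(sub, 1e-6)
    res = evaluate_prepost(hosp, coh.implementation_dates, ["age_75_plus", "chf"],
                           PrePostConfig(outcome="true_event", subgroup="non_icu_only"),
                           study_start=cfg.start)
    assert abs(res.pooled.rd) < max(3 * res.pooled.se, 5e-4)


def test_effect_direction_recovered_at_moderate_scale():
    """A protective direct effect produces a negative pooled estimate within
    3 SEs of the generative truth."""
    cfg = small_sim_config(patients_per_site_per_week=30.0, direct_effect_log_odds=-0.5)
    gt = ground_truth_effects(cfg, season_grid=4)
    coh, hosp = cohort_with_truth(cfg, seed=606)
    res = evaluate_prepost(hosp, coh.implementation_dates, COV_LIST, PP,
                           study_start=cfg.start)
    assert res.pooled.rd < 0
    assert abs(res.pooled.rd - gt.risk_difference) < 3 * res.pooled.se
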
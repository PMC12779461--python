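"""Temporal-trend models for NV-HAP, mortality and length of stay.

Binary outcomes (NV-HAP by either definition, 30-day death) are modeled
by logistic regression on a linear term in days since the study start;
length of stay by a hurdle model (logistic hurdle at one day, zero-
truncated negative binomial above it) with the same linear time term in
both components.  The two surveillance definitions are compared on one
long table (two rows per hospitalization) with a definition-by-time
interaction, estimated by GEE with an independence working correlation —
numerically identical to a logistic fit with cluster-robust (sandwich)
standard errors clustered on hospitalization, which is how it is computed
here.

Slopes are estimated per day and reported per year (x 365.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DAYS_PER_YEAR
from .fitting import HurdleFit, fit_hurdle, fit_logistic, sigmoid

Z95 = 1.959963984540054


@dataclass
class TrendFit:
    """A fitted linear-trend model with its endpoint summaries.

    ``value_start``/``value_end`` are risks (binary outcomes) or mean LOS in
    days; ``difference`` is end minus start with a delta-method 95% CI.
    """

    outcome: str
    kind: str                    # "binary" | "los"
    study_start: pd.Timestamp
    study_end: pd.Timestamp
    params: np.ndarray
    cov: np.ndarray
    value_start: float
    value_end: float
    difference: float
    difference_se: float
    difference_ci: tuple[float, float]
    slope_per_year: float | None = None
    slope_per_year_se: float | None = None
    hurdle_fit: HurdleFit | None = field(default=None, repr=False)

    def predict(self, dates) -> np.ndarray:
        t = (pd.to_datetime(pd.Series(dates)) - self.study_start).dt.days.to_numpy(dtype=float)
        if self.kind == "binary":
            return sigmoid(self.params[0] + self.params[1] * t)
        X = np.column_stack([np.ones(len(t)), t])
        return self.hurdle_fit.mean_los(X)


def _time_days(dates, origin) -> np.ndarray:
    return (pd.to_datetime(pd.Series(dates).reset_index(drop=True)) - pd.Timestamp(origin)).dt.days.to_numpy(dtype=float)


def fit_linear_trend_binary(dates, y, study_start=None, study_end=None,
                            outcome: str = "outcome") -> TrendFit:
    """Logistic trend: logit P(y=1) = b0 + b1 * days-since-start."""
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    y = np.asarray(y, dtype=float)
    if dates.nunique() < 2:
        raise ValueError("need at least two distinct admission dates")
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has a single level")
    start = pd.Timestamp(study_start) if study_start is not None else dates.min()
    end = pd.Timestamp(study_end) if study_end is not None else dates.max()
    t = _time_days(dates, start)
    X = np.column_stack([np.ones(len(t)), t])
    fit = fit_logistic(X, y, ["intercept", "per_day"])
    if fit.ridged:
        raise ValueError(f"trend model for {outcome!r} is separated; "
                         "maximum-likelihood slope does not exist")
    b0, b1 = fit.params
    T = float((end - start).days)
    ps, pe = float(sigmoid(b0)), float(sigmoid(b0 + b1 * T))
    # delta method for pe - ps
    g = np.array([pe * (1 - pe) - ps * (1 - ps), pe * (1 - pe) * T])
    var = float(g @ fit.cov @ g)
    se = np.sqrt(max(var, 0.0))
    diff = pe - ps
    return TrendFit(
        outcome=outcome, kind="binary", study_start=start, study_end=end,
        params=fit.params, cov=fit.cov,
        value_start=ps, value_end=pe, difference=diff, difference_se=se,
        difference_ci=(diff - Z95 * se, diff + Z95 * se),
        slope_per_year=float(b1 * DAYS_PER_YEAR),
        slope_per_year_se=float(np.sqrt(fit.cov[1, 1]) * DAYS_PER_YEAR),
    )


def fit_linear_trend_los(dates, los, study_start=None, study_end=None,
                         outcome: str = "los") -> TrendFit:
    """Hurdle-model trend in mean length of stay over calendar time."""
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    los = np.asarray(los)
    if dates.nunique() < 2:
        raise ValueError("need at least two distinct admission dates")
    start = pd.Timestamp(study_start) if study_start is not None else dates.min()
    end = pd.Timestamp(study_end) if study_end is not None else dates.max()
    t = _time_days(dates, start)
    X = np.column_stack([np.ones(len(t)), t])
    hfit = fit_hurdle(los, X, ["intercept", "per_day"])
    T = float((end - start).days)
    Xs = np.array([[1.0, 0.0]])
    Xe = np.array([[1.0, T]])
    ms = float(hfit.mean_los(Xs)[0])
    me = float(hfit.mean_los(Xe)[0])

    def f(theta):
        return float((hfit.mean_los(Xe, theta) - hfit.mean_los(Xs, theta))[0])

    theta0 = hfit.params
    g = np.empty(len(theta0))
    f0 = f(theta0)
    for i in range(len(theta0)):
        step = 1e-5 * max(1.0, abs(theta0[i]))
        pert = theta0.copy()
        pert[i] += step
        g[i] = (f(pert) - f0) / step
    var = float(g @ hfit.cov @ g)
    se = np.sqrt(max(var, 0.0))
    return TrendFit(
        outcome=outcome, kind="los", study_start=start, study_end=end,
        params=hfit.params, cov=hfit.cov,
        value_start=ms, value_end=me, difference=me - ms, difference_se=se,
        difference_ci=(me - ms - Z95 * se, me - ms + Z95 * se),
        hurdle_fit=hfit,
    )


@dataclass
class DefinitionTrendComparison:
    """Definition-by-time interaction from the clustered two-definition model.

    ``interaction_per_year`` is the electronic-definition slope minus the
    coding-definition slope, on the log-odds-per-year scale, with a
    cluster-robust standard error.
    """

    interaction_per_year: float
    interaction_se: float
    interaction_ci: tuple[float, float]
    slope_coding_per_year: float
    slope_electronic_per_year: float
    params: np.ndarray
    cov: np.ndarray
    n_hospitalizations: int


def compare_definitions_gee(long: pd.DataFrame, study_start=None) -> DefinitionTrendComparison:
    """``long`` columns: hospitalization_id, definition in
    {"coding", "electronic"}, indicator (0/1), admit_date.  Exactly two rows
    (one per definition) per hospitalization."""
    counts = long.groupby("hospitalization_id")["definition"].agg(["size", "nunique"])
    if (counts["size"] != 2).any() or (counts["nunique"] != 2).any():
        bad = counts.index[(counts["size"] != 2) | (counts["nunique"] != 2)].tolist()[:10]
        raise ValueError(f"each hospitalization needs exactly one row per definition; "
                         f"offending ids: {bad}")
    defs = set(long["definition"].unique())
    if defs != {"coding", "electronic"}:
        raise ValueError(f"definitions must be 'coding' and 'electronic', got {sorted(defs)}")
    start = pd.Timestamp(study_start) if study_start is not None else pd.to_datetime(long["admit_date"]).min()
    t = _time_days(long["admit_date"], start) / DAYS_PER_YEAR   # years: slope directly per year
    is_elec = (long["definition"] == "electronic").to_numpy(dtype=float)
    y = long["indicator"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(t)), is_elec, t, is_elec * t])
    groups = long["hospitalization_id"].to_numpy()
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
        cov_type="cluster", cov_kwds={"groups": groups})
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    est, se = float(params[3]), float(np.sqrt(cov[3, 3]))
    return DefinitionTrendComparison(
        interaction_per_year=est, interaction_se=se,
        interaction_ci=(est - Z95 * se, est + Z95 * se),
        slope_coding_per_year=float(params[2]),
        slope_electronic_per_year=float(params[2] + params[3]),
        params=params, cov=cov,
        n_hospitalizations=int(long["hospitalization_id"].nunique()),
    )


def fit_hurdle_los(los, X, columns: list[str] | None = None) -> HurdleFit:
    """Hurdle model for LOS >= 1 on an arbitrary design (see fitting.fit_hurdle)."""
    return fit_hurdle(np.asarray(los), np.asarray(X, dtype=float), columns)


def quarterly_summaries(dates, values, fit: TrendFit) -> pd.DataFrame:
    """Observed quarterly proportions/means alongside the model prediction
    at each quarter midpoint."""
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    vals = pd.Series(np.asarray(values, dtype=float))
    quarters = dates.dt.to_period("Q")
    grouped = vals.groupby(quarters)
    obs = grouped.mean()
    n = grouped.size()
    midpoints = [q.start_time + (q.end_time - q.start_time) / 2 for q in obs.index]
    pred = fit.predict(pd.Series(midpoints))
    return pd.DataFrame({
        "quarter": obs.index.astype(str),
        "n": n.to_numpy(),
        "observed": obs.to_numpy(),
        "predicted": np.asarray(pred, dtype=float),
    })
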
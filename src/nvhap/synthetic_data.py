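"""Synthetic multi-site hospitalization cohorts with known ground truth.

This module generates the four tables the surveillance and effect-estimation
machinery consumes — hospitalizations, patient-days, antibiotic
administrations, and discharge diagnoses — together with a truth table
recording, per hospitalization, the true pneumonia-event status and the
closed-form counterfactual (no-intervention) event probability.

The generative model mirrors the structure the downstream analysis assumes:

* admissions arrive as independent weekly Poisson streams per site;
* binary patient flags are independent Bernoulli draws;
* length of stay (LOS) follows a hurdle model — a logistic hurdle at
  LOS = 1 day, with (LOS - 1) drawn from a zero-truncated negative binomial
  whose log mean carries site offsets, patient flags, seasonality and an
  optional secular trend; a post-implementation multiplier on the NB mean
  is the *indirect* (mediated) intervention channel;
* the true hospital-acquired pneumonia event is Bernoulli with a logit that
  is linear in the patient flags, in realized LOS (per-day risk), in a
  post-implementation indicator (the *direct* channel), and in an annual
  sinusoid;
* events are assigned an in-stay onset day and a full clinical signature
  (oxygenation deterioration, fever, chest imaging, a new 3-day antibiotic
  course) only when the stay is long enough to carry one; shorter stays keep
  truth = event with no detectable signature;
* a discharge pneumonia code flagged "not present on admission" is emitted
  with configurable sensitivity/specificity plus an optional secular
  log-odds drift in coding practice, independent of true event rates.

Every random draw flows from a single integer seed through named
sub-streams, one per table, so regenerating with the same (config, seed)
is byte-identical and adding a new table cannot perturb existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DAYS_PER_YEAR, TWO_PI
from .fitting import hurdle_los_pmf

ABX_CLASSES = [
    "penicillin",
    "cephalosporin",
    "carbapenem",
    "fluoroquinolone",
    "macrolide",
    "glycopeptide",
    "aminoglycoside",
    "tetracycline",
]

#: qualifying pneumonia codes emitted for coded events (dotted dialect on
#: purpose: the classifier must normalize)
PNEUMONIA_CODES = [
    "J18.9", "J18.0", "J18.1", "J15.9", "J15.211", "J16.8",
    "J17", "J13", "B95.3", "B96.0", "J84.111", "J84.2", "J85.1",
]

#: background (never pneumonia-qualifying) discharge codes
BACKGROUND_CODES = ["I10", "E11.9", "N17.9", "I50.9", "K21.9", "F32.9", "J44.9", "N39.0"]

_STREAMS = {
    "admissions": 0,
    "covariates": 1,
    "los": 2,
    "events": 3,
    "signatures": 4,
    "daily": 5,
    "antibiotics": 6,
    "diagnoses": 7,
    "mortality": 8,
}


def _default_prevalences() -> dict[str, float]:
    return {
        "age_75_plus": 0.35,
        "male": 0.95,
        "chf": 0.20,
        "copd": 0.25,
        "dysphagia": 0.05,
        "immunocompromised": 0.10,
        "abnormal_wbc_admission": 0.20,
        "abnormal_temp_admission": 0.10,
        "low_spo2_admission": 0.15,
        "icu_ward": 0.16,
    }


def _default_event_log_odds() -> dict[str, float]:
    return {
        "age_75_plus": 0.40,
        "male": 0.10,
        "chf": 0.30,
        "copd": 0.35,
        "dysphagia": 0.60,
        "immunocompromised": 0.30,
        "abnormal_wbc_admission": 0.25,
        "abnormal_temp_admission": 0.20,
        "low_spo2_admission": 0.30,
        "icu_ward": 0.50,
    }


@dataclass
class LosHurdleParams:
    """Generative parameters of the length-of-stay hurdle model.

    ``nb_dispersion`` is theta in the mean/dispersion parameterization
    (variance = mu + mu^2/theta).
    """

    hurdle_intercept: float = -1.45
    hurdle_covariate_log_odds: dict[str, float] = field(default_factory=lambda: {
        "age_75_plus": -0.20, "chf": -0.15, "copd": -0.10,
        "dysphagia": -0.20, "immunocompromised": -0.10, "icu_ward": -0.50,
    })
    nb_log_mean_intercept: float = 1.48
    nb_covariate_log_effects: dict[str, float] = field(default_factory=lambda: {
        "age_75_plus": 0.10, "chf": 0.10, "copd": 0.08, "dysphagia": 0.15,
        "immunocompromised": 0.12, "abnormal_wbc_admission": 0.08,
        "abnormal_temp_admission": 0.05, "low_spo2_admission": 0.10,
        "icu_ward": 0.35,
    })
    nb_site_log_effects: list[float] | None = None  # default: even grid +-0.15
    nb_year_log_trend: float = 0.0
    nb_dispersion: float = 1.3


@dataclass
class MortalityParams:
    intercept: float = -3.60
    per_los_day: float = 0.015
    covariate_log_odds: dict[str, float] = field(default_factory=lambda: {
        "age_75_plus": 0.60, "male": 0.00, "chf": 0.40, "copd": 0.20,
        "dysphagia": 0.30, "immunocompromised": 0.40,
        "abnormal_wbc_admission": 0.20, "abnormal_temp_admission": 0.10,
        "low_spo2_admission": 0.30, "icu_ward": 0.80,
    })


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort generator.

    Defaults emulate a 17-hospital system observed 10/2015-12/2019 with a
    marginal pneumonia-event risk near 0.6% per hospitalization, mean LOS
    near 6 days, 30-day mortality near 5%, and a diagnosis-coding process
    with imperfect sensitivity/specificity.
    """

    n_sites: int = 17
    patients_per_site_per_week: float = 88.0
    study_start: str = "2015-10-01"
    study_end: str = "2019-12-31"
    implementation_dates: list[str] | None = None  # staggered by default
    covariate_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    covariate_log_odds_nvhap: dict[str, float] = field(default_factory=_default_event_log_odds)
    baseline_nvhap_log_odds: float = -6.21
    los_per_day_log_odds_nvhap: float = 0.05
    direct_effect_log_odds: float = 0.0
    los_hurdle_params: LosHurdleParams = field(default_factory=LosHurdleParams)
    los_effect_multiplier: float = 1.0
    coding_sensitivity: float = 0.50
    coding_specificity: float = 0.996
    coding_trend_per_year: float = 0.0
    seasonal_amplitude: float = 0.10
    los_seasonal_amplitude: float = 0.05
    mortality_params: MortalityParams = field(default_factory=MortalityParams)
    background_abx_prob: float = 0.15
    background_imaging_prob: float = 0.02
    cap_code_prob: float = 0.03
    seed: int | None = None

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        if isinstance(self.los_hurdle_params, dict):
            self.los_hurdle_params = LosHurdleParams(**self.los_hurdle_params)
        if isinstance(self.mortality_params, dict):
            self.mortality_params = MortalityParams(**self.mortality_params)

    @property
    def covariates(self) -> list[str]:
        return list(self.covariate_prevalences)

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.study_start)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.study_end)

    @property
    def site_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    def site_impl_dates(self) -> pd.Series:
        if self.implementation_dates is not None:
            dates = pd.to_datetime(pd.Series(list(self.implementation_dates)))
            if len(dates) != self.n_sites:
                raise ValueError("implementation_dates must list one date per site")
        else:
            lo = self.start + pd.Timedelta(days=365)
            hi = self.end - pd.Timedelta(days=365)
            if hi < lo:
                raise ValueError("study window too short for staggered implementation")
            if self.n_sites == 1:
                offsets = [0]
            else:
                span = (hi - lo).days
                offsets = [round(i * span / (self.n_sites - 1)) for i in range(self.n_sites)]
            dates = pd.Series([lo + pd.Timedelta(days=o) for o in offsets])
        dates.index = self.site_names
        return dates

    def nb_site_effects(self) -> np.ndarray:
        eff = self.los_hurdle_params.nb_site_log_effects
        if eff is None:
            if self.n_sites == 1:
                return np.zeros(1)
            return np.linspace(-0.15, 0.15, self.n_sites)
        eff = np.asarray(eff, dtype=float)
        if eff.shape != (self.n_sites,):
            raise ValueError("nb_site_log_effects must have one entry per site")
        return eff

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not self.patients_per_site_per_week > 0:
            raise ValueError("patients_per_site_per_week must be positive")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        for name, p in [("coding_sensitivity", self.coding_sensitivity),
                        ("coding_specificity", self.coding_specificity)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not self.los_hurdle_params.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be > 0")
        if not self.los_effect_multiplier > 0:
            raise ValueError("los_effect_multiplier must be > 0")
        if self.end <= self.start:
            raise ValueError("study_end must fall after study_start")
        impl = self.site_impl_dates()
        if (impl < self.start).any() or (impl > self.end).any():
            raise ValueError("implementation dates must lie within the study window")


@dataclass
class GroundTruthEffects:
    risk_pre: float
    risk_post: float
    risk_difference: float


@dataclass
class CohortTables:
    """The generated cohort: four analysis tables plus per-admission truth."""

    hospitalizations: pd.DataFrame
    patient_days: pd.DataFrame
    antibiotic_days: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame
    implementation_dates: pd.Series
    config: SimConfig | None = None

    _TABLES = ("hospitalizations", "patient_days", "antibiotic_days", "diagnoses", "truth")

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)
        sites = self.implementation_dates.rename("implementation_date").rename_axis("site")
        sites.dt.strftime("%Y-%m-%d").to_csv(directory / "sites.csv")

    @classmethod
    def read(cls, directory) -> "CohortTables":
        directory = Path(directory)
        frames = {}
        for name in cls._TABLES:
            df = pd.read_csv(directory / f"{name}.csv")
            for col in ("admit_date", "discharge_date"):
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            frames[name] = df
        sites = pd.read_csv(directory / "sites.csv", index_col="site")["implementation_date"]
        return cls(implementation_dates=pd.to_datetime(sites), **frames)


# ----------------------------------------------------------------------
# numeric helpers

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


def _los_support(mu_max: float, theta: float) -> int:
    sd = np.sqrt(mu_max + mu_max**2 / theta)
    return int(min(max(50, mu_max + 40 * sd), 1000))


# ----------------------------------------------------------------------
# generative linear predictors

def _event_logit(config: SimConfig, cov: np.ndarray, los, post, angle) -> np.ndarray:
    beta = np.array([config.covariate_log_odds_nvhap.get(c, 0.0) for c in config.covariates])
    return (
        config.baseline_nvhap_log_odds
        + cov @ beta
        + config.los_per_day_log_odds_nvhap * np.asarray(los, dtype=float)
        + config.direct_effect_log_odds * np.asarray(post, dtype=float)
        + config.seasonal_amplitude * np.sin(angle)
    )


def _los_linear_predictors(config: SimConfig, cov: np.ndarray, site_idx, year_c, angle, post):
    hp = config.los_hurdle_params
    g = np.array([hp.hurdle_covariate_log_odds.get(c, 0.0) for c in config.covariates])
    d = np.array([hp.nb_covariate_log_effects.get(c, 0.0) for c in config.covariates])
    p_one = _sigmoid(hp.hurdle_intercept + cov @ g)
    log_mu = (
        hp.nb_log_mean_intercept
        + cov @ d
        + config.nb_site_effects()[site_idx]
        + hp.nb_year_log_trend * year_c
        + config.los_seasonal_amplitude * np.sin(angle)
    )
    mu = np.exp(log_mu) * np.where(np.asarray(post, dtype=bool), config.los_effect_multiplier, 1.0)
    return p_one, mu


# ----------------------------------------------------------------------
# event-signature planting

def _plant_core(spo2, rank, temp, wbc, imaging, vent, los, event_day, abx_days_by_class, rng):
    """Overwrite in-place the day arrays of one stay so that the electronic
    definition fires at exactly ``event_day``; returns the antibiotic rows
    (drug_class, day) to add.  Arrays are 0-indexed by in-stay day - 1.
    """
    d = int(event_day)
    if not (3 <= d <= los - 2):
        raise ValueError(
            f"event_day={d} outside the plantable range [3, LOS-2] for LOS={los}: "
            "the signature needs 2 stable baseline days, 2 worsening days, and a "
            "3-day antibiotic course completed in-stay"
        )
    i = d - 1  # 0-based index of onset day
    base = spo2[i - 3] if d > 3 else 95.0
    if not np.isfinite(base):
        base = 95.0
    stable = max(95.0, base - 2.0)
    spo2[i - 2] = stable
    spo2[i - 1] = stable
    rank[i - 2] = rank[i - 3] if d > 3 else 0
    rank[i - 1] = rank[i - 2]
    rank[i] = rank[i - 1] + 1          # device escalation on onset day
    rank[i + 1] = rank[i]
    spo2[i] = stable - 3.0             # saturation drop, redundant evidence
    spo2[i + 1] = spo2[i] - 3.0
    temp[i] = 38.6                     # fever on the onset day
    imaging[i] = True
    vent[i - 2:i + 2] = False
    # a class with no administration anywhere near the onset
    blocked = {c for c, days in abx_days_by_class.items()
               if any(d - 2 <= t <= d + 2 for t in days)}
    candidates = [c for c in ABX_CLASSES if c not in blocked]
    cls = candidates[rng.integers(len(candidates))]
    return [(cls, d), (cls, d + 1), (cls, d + 2)]


def plant_event_signature(days: pd.DataFrame, abx: pd.DataFrame, event_day: int, seed=None):
    """Insert a full detectable pneumonia signature into one stay's records.

    ``days``/``abx`` hold a single hospitalization (1-based ``day`` column,
    one row per day in ``days``).  Returns modified copies.  ``seed`` may be
    an integer or a ``numpy.random.Generator``; it only picks the antibiotic
    class.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = days.sort_values("day").reset_index(drop=True)
    los = len(days)
    if not (days["day"].to_numpy() == np.arange(1, los + 1)).all():
        raise ValueError("days must cover 1..LOS with no gaps or duplicates")
    spo2 = days["spo2_min"].to_numpy(dtype=float)
    rank = days["o2_device_rank"].to_numpy()
    temp = days["temp_max"].to_numpy(dtype=float)
    wbc = days["wbc_max"].to_numpy(dtype=float)
    imaging = days["chest_imaging"].to_numpy(dtype=bool).copy()
    vent = days["ventilated"].to_numpy(dtype=bool).copy()
    by_class: dict[str, list[int]] = {}
    for cls, day in zip(abx["drug_class"], abx["day"]):
        by_class.setdefault(cls, []).append(int(day))
    new_rows = _plant_core(spo2, rank, temp, wbc, imaging, vent, los, event_day, by_class, rng)
    days = days.assign(spo2_min=spo2, o2_device_rank=rank, temp_max=temp,
                       wbc_max=wbc, chest_imaging=imaging, ventilated=vent)
    hid = days["hospitalization_id"].iloc[0]
    add = pd.DataFrame([{"hospitalization_id": hid, "drug_class": c, "day": t} for c, t in new_rows])
    abx = pd.concat([abx, add], ignore_index=True).sort_values(["drug_class", "day"]).reset_index(drop=True)
    return days, abx


# ----------------------------------------------------------------------
# cohort generation

def generate_cohort(config: SimConfig, seed: int | None = None,
                    include_daily_tables: bool = True,
                    include_truth_probability: bool = True) -> CohortTables:
    """Draw a complete multi-site cohort under ``config``.

    ``include_daily_tables=False`` skips the patient-day and antibiotic
    tables (the expensive part) for hospitalization-level studies;
    ``include_truth_probability=False`` skips the closed-form per-patient
    counterfactual probability column.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required: pass generate_cohort(config, seed=...) "
                         "or set SimConfig.seed")
    seed = int(seed)

    impl = config.site_impl_dates()
    sites = config.site_names
    n_sites = config.n_sites

    # --- admissions -----------------------------------------------------
    rng = _rng(seed, "admissions")
    week_starts = pd.date_range(config.start, config.end, freq="7D")
    n_weeks = len(week_starts)
    counts = rng.poisson(config.patients_per_site_per_week, size=(n_sites, n_weeks))
    site_idx = np.repeat(np.repeat(np.arange(n_sites), n_weeks), counts.ravel())
    week_idx = np.repeat(np.tile(np.arange(n_weeks), n_sites), counts.ravel())
    offsets = rng.integers(0, 7, size=len(site_idx))
    admit = week_starts.to_numpy()[week_idx] + offsets.astype("timedelta64[D]")
    keep = admit <= config.end.to_datetime64()
    site_idx, admit = site_idx[keep], admit[keep]
    order = np.lexsort((admit, site_idx))
    site_idx, admit = site_idx[order], admit[order]
    n = len(site_idx)
    hosp_id = np.arange(1, n + 1)
    admit = pd.DatetimeIndex(admit)
    year_c = (admit - config.start).days.to_numpy() / DAYS_PER_YEAR
    angle = TWO_PI * admit.dayofyear.to_numpy() / DAYS_PER_YEAR
    post = admit.to_numpy() >= impl.to_numpy()[site_idx]

    # --- covariates -----------------------------------------------------
    rng = _rng(seed, "covariates")
    prev = np.array([config.covariate_prevalences[c] for c in config.covariates])
    cov = (rng.random((n, len(prev))) < prev).astype(np.int8)

    # --- length of stay -------------------------------------------------
    rng = _rng(seed, "los")
    theta = config.los_hurdle_params.nb_dispersion
    p_one, mu = _los_linear_predictors(config, cov, site_idx, year_c, angle, post)
    is_one = rng.random(n) < p_one
    los = np.ones(n, dtype=np.int64)
    idx = np.flatnonzero(~is_one)
    if len(idx):
        q = theta / (theta + mu[idx])
        w = rng.negative_binomial(theta, q)
        redo = np.flatnonzero(w == 0)
        while len(redo):                      # zero-truncate by rejection
            w[redo] = rng.negative_binomial(theta, q[redo])
            redo = redo[w[redo] == 0]
        los[idx] = 1 + w

    # --- true events ----------------------------------------------------
    rng = _rng(seed, "events")
    p_event = _sigmoid(_event_logit(config, cov, los, post, angle))
    true_event = rng.random(n) < p_event
    event_day = np.full(n, np.nan)
    plantable = true_event & (los >= 5)
    k = plantable.sum()
    if k:
        lo_k = los[plantable]
        event_day[plantable] = 3 + np.floor(rng.random(k) * (lo_k - 4))  # uniform {3..LOS-2}

    # --- mortality ------------------------------------------------------
    rng = _rng(seed, "mortality")
    mp = config.mortality_params
    m_beta = np.array([mp.covariate_log_odds.get(c, 0.0) for c in config.covariates])
    p_death = _sigmoid(mp.intercept + cov @ m_beta + mp.per_los_day * los)
    death30 = rng.random(n) < p_death

    # --- closed-form counterfactual probability -------------------------
    if include_truth_probability:
        true_cf = _counterfactual_truth(config, cov, site_idx, year_c, angle)
    else:
        true_cf = np.full(n, np.nan)

    hosp = pd.DataFrame({
        "hospitalization_id": hosp_id,
        "site": np.array(sites)[site_idx],
        "admit_date": admit,
        "los": los,
        "death30": death30.astype(np.int8),
        "post_implementation": post.astype(np.int8),
        "ward_type": np.where(cov[:, config.covariates.index("icu_ward")] == 1, "icu", "med_surg")
        if "icu_ward" in config.covariates else "med_surg",
    })
    hosp["discharge_date"] = hosp["admit_date"] + pd.to_timedelta(los - 1, unit="D")
    for j, c in enumerate(config.covariates):
        hosp[c] = cov[:, j]

    truth = pd.DataFrame({
        "hospitalization_id": hosp_id,
        "true_event": true_event.astype(np.int8),
        "true_event_day": event_day,
        "detectable": (~np.isnan(event_day)).astype(np.int8),
        "true_p_event": p_event,
        "true_counterfactual": true_cf,
    })

    # --- diagnoses ------------------------------------------------------
    rng = _rng(seed, "diagnoses")
    t_years = year_c
    logit_pos = _clip_logit(config.coding_sensitivity) + config.coding_trend_per_year * t_years
    logit_neg = _clip_logit(1.0 - config.coding_specificity) + config.coding_trend_per_year * t_years
    p_code = np.where(true_event, _sigmoid(logit_pos), _sigmoid(logit_neg))
    p_code = np.where(true_event & (config.coding_sensitivity == 1.0), 1.0, p_code)
    p_code = np.where(~true_event & (config.coding_specificity == 1.0), 0.0, p_code)
    coded = rng.random(n) < p_code
    diagnoses = _build_diagnoses(config, rng, hosp_id, coded)

    # --- daily tables ---------------------------------------------------
    if include_daily_tables:
        patient_days, abx_days = _build_daily_tables(config, seed, hosp_id, los, true_event, event_day)
    else:
        patient_days = pd.DataFrame(columns=["hospitalization_id", "day", "spo2_min",
                                             "o2_device_rank", "temp_max", "wbc_max",
                                             "chest_imaging", "ventilated"])
        abx_days = pd.DataFrame(columns=["hospitalization_id", "day", "drug_class"])

    return CohortTables(hosp, patient_days, abx_days, diagnoses, truth, impl, config)


def _clip_logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _counterfactual_truth(config, cov, site_idx, year_c, angle, chunk: int = 20000) -> np.ndarray:
    """Per-patient event probability with the intervention switched off,
    integrating over the no-intervention LOS distribution."""
    n = len(site_idx)
    out = np.empty(n)
    theta = config.los_hurdle_params.nb_dispersion
    b_los = config.los_per_day_log_odds_nvhap
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        p_one, mu = _los_linear_predictors(config, cov[sl], site_idx[sl], year_c[sl],
                                           angle[sl], np.zeros(sl.stop - sl.start, dtype=bool))
        l_max = _los_support(float(mu.max()), theta)
        pmf = hurdle_los_pmf(p_one, mu, theta, l_max)
        base = _event_logit(config, cov[sl], 0.0, 0.0, angle[sl])
        ls = np.arange(1, l_max + 1)
        probs = _sigmoid(base[:, None] + b_los * ls[None, :])
        out[sl] = (pmf * probs).sum(axis=1) + (1.0 - pmf.sum(axis=1)) * probs[:, -1]
    return out


def _build_diagnoses(config, rng, hosp_id, coded) -> pd.DataFrame:
    n = len(hosp_id)
    n_bg = rng.integers(1, 5, size=n)
    bg_ids = np.repeat(hosp_id, n_bg)
    m = len(bg_ids)
    bg_codes = np.array(BACKGROUND_CODES)[rng.integers(len(BACKGROUND_CODES), size=m)]
    bg_poa = np.array(["Y", "N", "U", "W"])[rng.choice(4, size=m, p=[0.75, 0.15, 0.05, 0.05])]
    rows = [pd.DataFrame({"hospitalization_id": bg_ids, "icd10_code": bg_codes,
                          "position": "secondary", "poa": bg_poa})]
    cap = rng.random(n) < config.cap_code_prob      # community-acquired: present on admission
    if cap.any():
        ids = hosp_id[cap]
        codes = np.array(PNEUMONIA_CODES)[rng.integers(len(PNEUMONIA_CODES), size=len(ids))]
        rows.append(pd.DataFrame({"hospitalization_id": ids, "icd10_code": codes,
                                  "position": np.where(rng.random(len(ids)) < 0.5, "primary", "secondary"),
                                  "poa": "Y"}))
    if coded.any():
        ids = hosp_id[coded]
        codes = np.array(PNEUMONIA_CODES)[rng.integers(len(PNEUMONIA_CODES), size=len(ids))]
        rows.append(pd.DataFrame({"hospitalization_id": ids, "icd10_code": codes,
                                  "position": np.where(rng.random(len(ids)) < 0.3, "primary", "secondary"),
                                  "poa": "N"}))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["hospitalization_id", "icd10_code"], kind="stable").reset_index(drop=True)


def _build_daily_tables(config, seed, hosp_id, los, true_event, event_day):
    rng = _rng(seed, "daily")
    total = int(los.sum())
    rep_id = np.repeat(hosp_id, los)
    day = np.concatenate([np.arange(1, l + 1) for l in los]) if total else np.array([], dtype=int)
    spo2 = 95.0 + rng.integers(-1, 2, size=total).astype(float)
    rank = np.zeros(total, dtype=np.int64)
    temp = np.clip(36.7 + rng.normal(0.0, 0.25, size=total), 35.5, 37.6)
    wbc = np.clip(7.5 + rng.normal(0.0, 1.3, size=total), 0.5, 11.0)
    imaging = rng.random(total) < config.background_imaging_prob
    vent = np.zeros(total, dtype=bool)

    # background antibiotic courses
    rng_abx = _rng(seed, "antibiotics")
    n = len(hosp_id)
    has_bg = rng_abx.random(n) < config.background_abx_prob
    abx_rows = {"hospitalization_id": [], "day": [], "drug_class": []}
    bg_idx = np.flatnonzero(has_bg)
    bg_cls = rng_abx.integers(len(ABX_CLASSES), size=len(bg_idx))
    bg_start = 1 + np.floor(rng_abx.random(len(bg_idx)) * los[bg_idx]).astype(int)
    bg_dur = 1 + rng_abx.geometric(0.4, size=len(bg_idx))
    for j, i in enumerate(bg_idx):
        end = min(bg_start[j] + min(bg_dur[j], 5) - 1, los[i])
        for t in range(bg_start[j], end + 1):
            abx_rows["hospitalization_id"].append(hosp_id[i])
            abx_rows["day"].append(t)
            abx_rows["drug_class"].append(ABX_CLASSES[bg_cls[j]])
    abx_by_hosp: dict[int, dict[str, list[int]]] = {}
    for hid, t, cls in zip(abx_rows["hospitalization_id"], abx_rows["day"], abx_rows["drug_class"]):
        abx_by_hosp.setdefault(hid, {}).setdefault(cls, []).append(t)

    # plant signatures for detectable events
    rng_sig = _rng(seed, "signatures")
    starts = np.concatenate([[0], np.cumsum(los)[:-1]])
    for i in np.flatnonzero(true_event & ~np.isnan(event_day)):
        s, l = starts[i], int(los[i])
        sl = slice(s, s + l)
        new_rows = _plant_core(spo2[sl], rank[sl], temp[sl], wbc[sl], imaging[sl],
                               vent[sl], l, int(event_day[i]),
                               abx_by_hosp.get(hosp_id[i], {}), rng_sig)
        for cls, t in new_rows:
            abx_rows["hospitalization_id"].append(hosp_id[i])
            abx_rows["day"].append(t)
            abx_rows["drug_class"].append(cls)

    patient_days = pd.DataFrame({
        "hospitalization_id": rep_id, "day": day, "spo2_min": spo2,
        "o2_device_rank": rank, "temp_max": np.round(temp, 1),
        "wbc_max": np.round(wbc, 1), "chest_imaging": imaging, "ventilated": vent,
    })
    abx_days = pd.DataFrame(abx_rows).sort_values(
        ["hospitalization_id", "drug_class", "day"], kind="stable").reset_index(drop=True)
    return patient_days, abx_days


# ----------------------------------------------------------------------
# ground-truth marginal effects

def ground_truth_effects(config: SimConfig, season_grid: int = 12) -> GroundTruthEffects:
    """Marginal event risks with the intervention off (pre) and on (post),
    by exact summation over the covariate, site, season and LOS distributions.

    The secular-year term of the LOS model, if any, is evaluated at
    mid-study.  The returned risk difference is the estimand targeted by
    the counterfactual standardization estimator when case mix is stable.
    """
    config.validate()
    covs = config.covariates
    k = len(covs)
    if k > 16:
        raise ValueError("covariate enumeration limited to 16 binary flags")
    patterns = np.array(np.meshgrid(*([[0, 1]] * k), indexing="ij")).reshape(k, -1).T if k else np.zeros((1, 0))
    prev = np.array([config.covariate_prevalences[c] for c in covs])
    w_pat = np.prod(np.where(patterns == 1, prev, 1 - prev), axis=1)
    n_sites = config.n_sites
    theta = config.los_hurdle_params.nb_dispersion
    b_los = config.los_per_day_log_odds_nvhap
    mid_year = (config.end - config.start).days / (2 * DAYS_PER_YEAR)

    # rows = site x covariate pattern
    site_idx = np.repeat(np.arange(n_sites), len(patterns))
    cov = np.tile(patterns, (n_sites, 1))
    weights = np.tile(w_pat, n_sites) / n_sites

    angles = TWO_PI * (np.arange(season_grid) + 0.5) / season_grid
    risks = {}
    for label, is_post in (("pre", False), ("post", True)):
        acc = 0.0
        post = np.full(len(site_idx), is_post)
        for a in angles:
            ang = np.full(len(site_idx), a)
            p_one, mu = _los_linear_predictors(config, cov, site_idx,
                                               np.full(len(site_idx), mid_year), ang, post)
            l_max = _los_support(float(mu.max()), theta)
            pmf = hurdle_los_pmf(p_one, mu, theta, l_max)
            base = _event_logit(config, cov, 0.0, post, ang)
            ls = np.arange(1, l_max + 1)
            probs = _sigmoid(base[:, None] + b_los * ls[None, :])
            per_row = (pmf * probs).sum(axis=1) + (1.0 - pmf.sum(axis=1)) * probs[:, -1]
            acc += weights @ per_row
        risks[label] = acc / season_grid
    return GroundTruthEffects(risks["pre"], risks["post"], risks["post"] - risks["pre"])
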
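import warnings

import numpy as np
import pandas as pd
import pytest

from nvhap.synthetic_data import SimConfig, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)

#: compact covariate set for replicate-heavy studies
COVS3 = {"age_75_plus": 0.35, "chf": 0.20, "icu_ward": 0.16}
EFF3 = {"age_75_plus": 0.4, "chf": 0.3, "icu_ward": 0.5}


def small_sim_config(**overrides) -> SimConfig:
    """17-site scaled-down study: staggered rollout, 0.6% event risk."""
    base = dict(
        n_sites=17,
        patients_per_site_per_week=22.0,
        covariate_prevalences=dict(COVS3),
        covariate_log_odds_nvhap=dict(EFF3),
        baseline_nvhap_log_odds=-5.78,
    )
    base.update(overrides)
    return SimConfig(**base)


def cohort_with_truth(config: SimConfig, seed: int, **kw) -> pd.DataFrame:
    """Hospitalization table with the true event indicator merged in."""
    kw.setdefault("include_daily_tables", False)
    kw.setdefault("include_truth_probability", False)
    coh = generate_cohort(config, seed=seed, **kw)
    hosp = coh.hospitalizations.merge(
        coh.truth[["hospitalization_id", "true_event"]], on="hospitalization_id")
    return coh, hosp


def quiet_stay(los: int, hosp_id: int = 1) -> pd.DataFrame:
    """A clinically quiet patient-day record: room air, stable saturation,
    afebrile, normal white count, no imaging, not ventilated."""
    return pd.DataFrame({
        "hospitalization_id": hosp_id,
        "day": np.arange(1, los + 1),
        "spo2_min": 95.0,
        "o2_device_rank": 0,
        "temp_max": 36.8,
        "wbc_max": 7.5,
        "chest_imaging": False,
        "ventilated": False,
    })


def empty_abx(hosp_id: int = 1) -> pd.DataFrame:
    return pd.DataFrame(columns=["hospitalization_id", "day", "drug_class"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
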
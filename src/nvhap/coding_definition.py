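"""Diagnosis-coding surveillance definition for NV-HAP.

A hospitalization is coded as NV-HAP when any primary or secondary
discharge diagnosis carries a qualifying pneumonia ICD-10 code with a
present-on-admission flag of "N" (explicitly hospital-onset).  The
qualifying set combines exact codes (B95.3, B96.0, J13, J84.111, J84.116,
J84.117, J84.2, J85.1, J85.2) and whole code families (J15.x, J16.x,
J17.x, J18.x, including the bare 3-character roots).

POA values "U" (unknown), "W" (clinically undetermined) and missing are
treated as not qualifying: surveillance of hospital-onset disease requires
an affirmative "not present on admission".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EXACT_CODES = frozenset({"B953", "B960", "J13", "J84111", "J84116", "J84117",
                         "J842", "J851", "J852"})
FAMILY_PREFIXES = ("J15", "J16", "J17", "J18")

QUALIFYING_POA = frozenset({"N"})


def normalize_code(raw: str) -> str:
    """Canonical ICD-10 form: uppercase, periods and whitespace stripped."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        raise ValueError("empty diagnosis code")
    code = str(raw).replace(".", "").replace(" ", "").strip().upper()
    if not code:
        raise ValueError(f"diagnosis code empty after normalization: {raw!r}")
    return code


def matches_nvhap_code(code: str) -> bool:
    """True iff a *normalized* code belongs to the pneumonia surveillance set."""
    if code in EXACT_CODES:
        return True
    return code.startswith(FAMILY_PREFIXES)


def classify_hospitalization(records: pd.DataFrame) -> bool:
    """One hospitalization's records -> coded NV-HAP status."""
    if len(records) == 0:
        return False
    if records["hospitalization_id"].nunique() > 1:
        raise ValueError("records span multiple hospitalizations")
    for _, row in records.iterrows():
        if str(row.get("poa")) in QUALIFYING_POA and matches_nvhap_code(normalize_code(row["icd10_code"])):
            return True
    return False


def classify_table(diagnoses: pd.DataFrame) -> pd.Series:
    """Vectorized classification of a full diagnosis table.

    Returns a boolean Series indexed by hospitalization_id covering every
    hospitalization present in the table.
    """
    if len(diagnoses) == 0:
        return pd.Series(dtype=bool)
    codes = (diagnoses["icd10_code"].astype(str)
             .str.replace(".", "", regex=False)
             .str.replace(" ", "", regex=False)
             .str.strip().str.upper())
    if (codes == "").any():
        bad = diagnoses.loc[codes == "", "hospitalization_id"].tolist()[:10]
        raise ValueError(f"empty diagnosis codes for hospitalizations {bad}")
    hit = codes.isin(EXACT_CODES) | codes.str.startswith(FAMILY_PREFIXES)
    hit &= diagnoses["poa"].astype(str).isin(QUALIFYING_POA)
    return hit.groupby(diagnoses["hospitalization_id"]).any()
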
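"""Rule-based electronic surveillance definition for non-ventilator
hospital-acquired pneumonia (NV-HAP) over patient-day data.

An event is called at onset day ``d`` when all of the following hold:

1. *Respiratory deterioration*: days ``d`` and ``d+1`` both show worsening
   oxygenation (supplemental-oxygen device escalation, or a drop of at
   least ``spo2_drop`` points in the daily minimum SpO2 at an unchanged
   device rank) after at least two preceding days (``d-2``, ``d-1``) of
   stable or improving oxygenation; hence ``d >= 3``.
2. *Systemic inflammation*: fever (``temp_max >= fever_temp``) or
   leukocytosis (``wbc_max >= leuko_wbc``) on some day in ``[d-1, d+1]``.
3. *Imaging*: chest imaging performed on some day in ``[d-1, d+2]``.
4. *New antibiotics*: some antibiotic class with no administration on days
   ``[d-2, d-1]`` whose first administration on/after ``d-1`` falls in
   ``[d-1, d+1]`` and continues for at least 3 consecutive in-stay days
   (discharge before the third day disqualifies).
5. *Non-ventilated*: no invasive mechanical ventilation on days
   ``[d-2, d]``.

Missing daily values never create evidence: a missing SpO2 with unchanged
device rank counts as stable, and missing temperature/WBC never satisfy
criterion 2.  Only the first adjudicated event per hospitalization is kept.
All thresholds and windows are knobs on :class:`DetectorRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

WORSENING = "worsening"
STABLE = "stable_or_improving"
UNDEFINED = "undefined"

VENT_RANK = 5  # invasive mechanical ventilation on the 0-5 device ladder


@dataclass
class DetectorRules:
    spo2_drop: float = 3.0
    fever_temp: float = 38.0
    leuko_wbc: float = 12.0
    fl_window: tuple[int, int] = (-1, 1)       # fever/leukocytosis, relative to onset
    imaging_window: tuple[int, int] = (-1, 2)
    abx_start_window: tuple[int, int] = (-1, 1)
    abx_lookback: int = 2                      # class must be absent this many days pre-onset
    abx_min_days: int = 3
    baseline_days: int = 2
    worsening_days: int = 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EventCall:
    hospitalization_id: object
    event_day: int
    baseline_days: tuple[int, int]
    worsening_days: tuple[int, int]
    fever_met: bool
    leukocytosis_met: bool
    imaging_met: bool
    new_abx_met: bool
    nonventilated_met: bool
    qualifying_abx_class: str | None = None

    @property
    def all_met(self) -> bool:
        return ((self.fever_met or self.leukocytosis_met) and self.imaging_met
                and self.new_abx_met and self.nonventilated_met)


def daily_oxygenation_status(days: pd.DataFrame, rules: DetectorRules | None = None) -> list[str]:
    """Per-day oxygenation label for one stay: worsening / stable_or_improving
    on days >= 2, undefined on day 1 (no prior day to compare)."""
    rules = rules or DetectorRules()
    days = days.sort_values("day")
    d = days["day"].to_numpy()
    if len(np.unique(d)) != len(d):
        raise ValueError("duplicate day index within hospitalization")
    if not (d == np.arange(1, len(d) + 1)).all():
        raise ValueError("days must run 1..LOS with no gaps")
    rank = days["o2_device_rank"].to_numpy(dtype=float)
    spo2 = days["spo2_min"].to_numpy(dtype=float)
    labels = [UNDEFINED]
    for i in range(1, len(d)):
        esc = rank[i] > rank[i - 1]
        drop = (rank[i] == rank[i - 1] and np.isfinite(spo2[i]) and np.isfinite(spo2[i - 1])
                and spo2[i] <= spo2[i - 1] - rules.spo2_drop)
        labels.append(WORSENING if (esc or drop) else STABLE)
    return labels


def find_candidate_onsets(labels: list[str], rules: DetectorRules | None = None) -> list[int]:
    """Onset candidates: ``worsening_days`` consecutive worsening labels at
    ``d, d+1, ...`` preceded by ``baseline_days`` stable-or-improving labels
    (day 1's undefined label counts toward the baseline requirement)."""
    rules = rules or DetectorRules()
    ok_base = {STABLE, UNDEFINED}
    n = len(labels)
    out = []
    for d in range(1 + rules.baseline_days, n - rules.worsening_days + 2):
        worsen = all(labels[d - 1 + j] == WORSENING for j in range(rules.worsening_days))
        base = all(labels[d - 1 - j] in ok_base for j in range(1, rules.baseline_days + 1))
        if worsen and base:
            out.append(d)
    return out


def _window(d: int, rel: tuple[int, int], los: int) -> range:
    return range(max(1, d + rel[0]), min(los, d + rel[1]) + 1)


def adjudicate_event(candidate_day: int, days: pd.DataFrame, abx: pd.DataFrame,
                     rules: DetectorRules | None = None) -> EventCall | None:
    """Evaluate the fever/leukocytosis, imaging, new-antibiotic and
    non-ventilation criteria at one candidate onset; return the call iff
    all criteria hold."""
    rules = rules or DetectorRules()
    days = days.sort_values("day")
    d = int(candidate_day)
    los = int(days["day"].max())
    temp = days.set_index("day")["temp_max"]
    wbc = days.set_index("day")["wbc_max"]
    imaging = days.set_index("day")["chest_imaging"]
    vent = days.set_index("day")["ventilated"]

    fl_days = _window(d, rules.fl_window, los)
    fever = bool(np.any([temp.get(t, np.nan) >= rules.fever_temp for t in fl_days]))
    leuko = bool(np.any([wbc.get(t, np.nan) >= rules.leuko_wbc for t in fl_days]))
    img = bool(np.any([bool(imaging.get(t, False)) for t in _window(d, rules.imaging_window, los)]))
    nonvent = not any(bool(vent.get(t, False)) for t in range(max(1, d - rules.abx_lookback), d + 1))

    new_abx, qual_class = _qualifying_antibiotic(d, abx, los, rules)

    call = EventCall(
        hospitalization_id=days["hospitalization_id"].iloc[0],
        event_day=d,
        baseline_days=(d - 2, d - 1),
        worsening_days=(d, d + 1),
        fever_met=fever,
        leukocytosis_met=leuko,
        imaging_met=img,
        new_abx_met=new_abx,
        nonventilated_met=nonvent,
        qualifying_abx_class=qual_class,
    )
    return call if call.all_met else None


def _qualifying_antibiotic(d: int, abx: pd.DataFrame, los: int, rules: DetectorRules):
    if len(abx) == 0:
        return False, None
    lookback = set(range(max(1, d - rules.abx_lookback), d))
    start_days = set(_window(d, rules.abx_start_window, los))
    for cls, grp in abx.groupby("drug_class"):
        days_given = set(int(t) for t in grp["day"])
        if days_given & lookback:
            continue                      # not new: given during the washout
        on_after = sorted(t for t in days_given if t >= d + rules.abx_start_window[0])
        if not on_after:
            continue
        s = on_after[0]
        if s not in start_days:
            continue
        course = all((s + j) in days_given and (s + j) <= los for j in range(rules.abx_min_days))
        if course:
            return True, cls
    return False, None


def detect_nvhap(patient_days: pd.DataFrame, antibiotic_days: pd.DataFrame,
                 rules: DetectorRules | None = None,
                 hospitalizations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the full detector; returns at most one event row per
    hospitalization (the first adjudicated onset).

    When ``hospitalizations`` is given, referential integrity of the two
    day-level tables is checked first.
    """
    rules = rules or DetectorRules()
    if hospitalizations is not None:
        known = set(hospitalizations["hospitalization_id"])
        for name, tbl in (("patient_days", patient_days), ("antibiotic_days", antibiotic_days)):
            orphans = set(tbl["hospitalization_id"]) - known
            if orphans:
                raise ValueError(f"{name} references unknown hospitalizations: "
                                 f"{sorted(orphans)[:10]}")

    cols = ["hospitalization_id", "event_day", "baseline_start", "worsening_end",
            "fever_met", "leukocytosis_met", "imaging_met", "new_abx_met",
            "nonventilated_met", "qualifying_abx_class"]
    if len(patient_days) == 0:
        return pd.DataFrame(columns=cols)

    pdays = patient_days.sort_values(["hospitalization_id", "day"], kind="stable")
    dup = pdays.duplicated(["hospitalization_id", "day"])
    if dup.any():
        bad = pdays.loc[dup, "hospitalization_id"].unique()
        raise ValueError(f"duplicate patient-day rows for hospitalizations {bad[:10]}")

    hid = pdays["hospitalization_id"].to_numpy()
    day = pdays["day"].to_numpy()
    rank = pdays["o2_device_rank"].to_numpy(dtype=float)
    spo2 = pdays["spo2_min"].to_numpy(dtype=float)
    same = np.empty(len(hid), dtype=bool)
    same[0] = False
    same[1:] = hid[1:] == hid[:-1]

    esc = np.zeros(len(hid), dtype=bool)
    drop = np.zeros(len(hid), dtype=bool)
    esc[1:] = same[1:] & (rank[1:] > rank[:-1])
    with np.errstate(invalid="ignore"):
        drop[1:] = (same[1:] & (rank[1:] == rank[:-1])
                    & np.isfinite(spo2[1:]) & np.isfinite(spo2[:-1])
                    & (spo2[1:] <= spo2[:-1] - rules.spo2_drop))
    worsen = esc | drop  # day-1 rows are False: undefined counts as stable here

    # candidate mask at position i (day d): worsen[i] & worsen[i+1] within the
    # same stay, previous `baseline_days` positions not worsening, d >= 3
    n = len(hid)
    cand = np.zeros(n, dtype=bool)
    w_next = np.zeros(n, dtype=bool)
    w_next[:-1] = worsen[1:] & same[1:]
    cand = worsen & w_next & (day >= 1 + rules.baseline_days)
    for j in range(1, rules.baseline_days + 1):
        prev_ok = np.zeros(n, dtype=bool)
        prev_ok[j:] = ~worsen[:-j] & (hid[j:] == hid[:-j])
        cand &= prev_ok
    if rules.worsening_days > 2:
        for j in range(2, rules.worsening_days):
            nxt = np.zeros(n, dtype=bool)
            nxt[:-j] = worsen[j:] & (hid[:-j] == hid[j:])
            cand &= nxt

    if not cand.any():
        return pd.DataFrame(columns=cols)

    cand_df = pd.DataFrame({"hospitalization_id": hid[cand], "day": day[cand]})
    abx_by_hosp = dict(tuple(antibiotic_days.groupby("hospitalization_id"))) if len(antibiotic_days) else {}
    empty_abx = antibiotic_days.iloc[0:0]
    rows = []
    for h, grp in cand_df.groupby("hospitalization_id", sort=True):
        days_h = pdays[pdays["hospitalization_id"] == h]
        abx_h = abx_by_hosp.get(h, empty_abx)
        for d in sorted(grp["day"]):
            call = adjudicate_event(int(d), days_h, abx_h, rules)
            if call is not None:
                rows.append({
                    "hospitalization_id": h, "event_day": call.event_day,
                    "baseline_start": call.baseline_days[0],
                    "worsening_end": call.worsening_days[1],
                    "fever_met": call.fever_met, "leukocytosis_met": call.leukocytosis_met,
                    "imaging_met": call.imaging_met, "new_abx_met": call.new_abx_met,
                    "nonventilated_met": call.nonventilated_met,
                    "qualifying_abx_class": call.qualifying_abx_class,
                })
                break  # only the first event per hospitalization is counted
    return pd.DataFrame(rows, columns=cols)
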
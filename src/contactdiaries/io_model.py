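"""Diary data model: read/validate/write the CSV dialect and derive contact rates.

The core record is a *diary panel*: a participant roster, one diary per
participant per survey wave, and the contact events reported in each diary.
A contact event is an encounter with a distinct individual or group of
individuals in one geographical location during the reporting day; a group
event represents ``group_size`` people at once.  From the raw events we
derive, per diary,

* ``K`` — number of contacts: the sum of ``group_size`` over events,
* ``L`` — number of distinct location labels used in the diary,
* setting-stratified counts (home / school-or-work / other),

while total contact duration ``D`` is filled in later by the duration
module (durations are only observed as ordinal categories).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WAVES = ["R1", "R2", "R3", "R4"]

#: Contact-side age groups (reported as a category, never an exact age).
CONTACT_AGE_GROUPS = ["0-5", "6-19", "20-39", "40-64", "65+"]

#: Participant-side age groups used by the mixing matrices.  Participants
#: aged 2-4 are recorded but excluded from mixing analyses (small samples).
PARTICIPANT_AGE_GROUPS = ["5-19", "20-39", "40-64", "65+"]

SETTINGS = ["home", "school", "work", "other"]
SEXES = ["male", "female", "unrecorded"]
TYPICAL_DAY = ["typical", "non_typical", "unknown"]
WEEKDAYS = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]

UNKNOWN = "unknown"

PARTICIPANT_COLUMNS = ["participant_id", "household_id", "age_years", "sex", "household_size"]
DIARY_COLUMNS = ["participant_id", "wave", "reporting_day", "typical_day"]
EVENT_COLUMNS = [
    "participant_id",
    "wave",
    "event_id",
    "group_size",
    "contact_age_group",
    "setting",
    "duration_category",
    "touch",
    "location_label",
    "frequency",
]
CENSUS_COLUMNS = ["age_group", "population_count"]

RATE_COLUMNS = [
    "participant_id",
    "wave",
    "K",
    "L",
    "K_home",
    "K_schoolwork",
    "K_other",
    "K_unknown_setting",
    "D",
    "weekday",
    "typical_day",
    "age_years",
    "age_group",
    "sex",
    "household_size",
]


class SchemaError(ValueError):
    """A mandatory column is missing or a hard invariant is violated."""


def participant_age_group(age_years: float) -> str:
    """Map an exact age in decimal years to the participant-side age group.

    Ages 2-4 get their own label so downstream analyses can exclude them;
    ages below the study minimum of 2 are mapped to ``unknown``.
    """
    if pd.isna(age_years):
        return UNKNOWN
    if age_years < 2:
        return UNKNOWN
    if age_years < 5:
        return "2-4"
    if age_years < 20:
        return "5-19"
    if age_years < 40:
        return "20-39"
    if age_years < 65:
        return "40-64"
    return "65+"


def contact_age_group_of(age_years: float) -> str:
    """Map an exact age to the contact-side age group (five categories)."""
    if pd.isna(age_years) or age_years < 0:
        return UNKNOWN
    if age_years < 6:
        return "0-5"
    if age_years < 20:
        return "6-19"
    if age_years < 40:
        return "20-39"
    if age_years < 65:
        return "40-64"
    return "65+"


@dataclass
class DiaryPanel:
    """Validated long-format panel of participants, diaries and contact events.

    ``rejected`` collects event/diary rows that failed row-level invariants,
    with a ``reason`` column; ``excluded_participants`` flags participants
    lacking core demographic information (age or sex), who are excluded from
    analyses that need the missing field.
    """

    participants: pd.DataFrame
    diaries: pd.DataFrame
    events: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded_participants: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        dup = self.diaries.duplicated(subset=["participant_id", "wave"])
        if dup.any():
            bad = self.diaries.loc[dup, ["participant_id", "wave"]].iloc[0]
            raise SchemaError(
                f"duplicate diary for participant {bad['participant_id']!r} wave {bad['wave']!r}"
            )
        if self.participants["participant_id"].duplicated().any():
            raise SchemaError("participant_id values must be unique")

    def events_of(self, participant_id: str, wave: str) -> pd.DataFrame:
        ev = self.events
        return ev[(ev["participant_id"] == participant_id) & (ev["wave"] == wave)]


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")


def _weekday_of(reporting_day: object) -> str:
    try:
        d = pd.Timestamp(reporting_day)
    except (ValueError, TypeError):
        return UNKNOWN
    if pd.isna(d):
        return UNKNOWN
    return WEEKDAYS[d.weekday()]


def read_census(path: str | Path) -> pd.Series:
    """Read ``census.csv`` and return contact-age-group population proportions.

    Any census with the five contact age groups is accepted; counts are
    normalized to proportions summing to one.
    """
    df = pd.read_csv(path, dtype={"age_group": str})
    _require_columns(df, CENSUS_COLUMNS, "census.csv")
    counts = df.set_index("age_group")["population_count"].astype(float)
    missing = [g for g in CONTACT_AGE_GROUPS if g not in counts.index]
    if missing:
        raise SchemaError(f"census.csv: missing age group(s) {missing}")
    counts = counts.loc[CONTACT_AGE_GROUPS]
    if (counts <= 0).any():
        raise SchemaError("census.csv: population counts must be positive")
    return counts / counts.sum()


def read_diary_panel(directory: str | Path) -> DiaryPanel:
    """Read and validate ``participants.csv``, ``diaries.csv`` and ``events.csv``.

    Rows violating row-level invariants (non-positive group size, unknown
    wave label, events without a matching diary) are removed and collected in
    ``panel.rejected`` with a reason; participants with missing age or sex
    are flagged in ``panel.excluded_participants`` rather than dropped.
    Duplicate (participant, wave) diaries and missing mandatory columns are
    hard errors.
    """
    directory = Path(directory)
    participants = pd.read_csv(
        directory / "participants.csv",
        dtype={"participant_id": str, "household_id": str, "sex": str},
    )
    diaries = pd.read_csv(
        directory / "diaries.csv", dtype={"participant_id": str, "wave": str, "typical_day": str}
    )
    events = pd.read_csv(
        directory / "events.csv",
        dtype={
            "participant_id": str,
            "wave": str,
            "event_id": str,
            "contact_age_group": str,
            "setting": str,
            "location_label": str,
            "frequency": str,
        },
    )
    _require_columns(participants, PARTICIPANT_COLUMNS, "participants.csv")
    _require_columns(diaries, DIARY_COLUMNS, "diaries.csv")
    _require_columns(events, EVENT_COLUMNS, "events.csv")

    rejected_frames = []

    participants = participants.copy()
    participants["age_years"] = pd.to_numeric(participants["age_years"], errors="coerce")
    participants["sex"] = participants["sex"].fillna("unrecorded")
    participants.loc[~participants["sex"].isin(SEXES), "sex"] = "unrecorded"
    participants["age_group"] = participants["age_years"].map(participant_age_group)

    missing_age = participants["age_years"].isna()
    missing_sex = participants["sex"].eq("unrecorded")
    flagged = participants[missing_age | missing_sex].copy()
    flagged["reason"] = np.where(
        missing_age[flagged.index] & missing_sex[flagged.index],
        "missing age and sex",
        np.where(missing_age[flagged.index], "missing age", "missing sex"),
    )
    excluded = flagged[["participant_id", "reason"]].reset_index(drop=True)

    diaries = diaries.copy()
    bad_wave = ~diaries["wave"].isin(WAVES)
    if bad_wave.any():
        rej = diaries[bad_wave].copy()
        rej["reason"] = "unknown wave label"
        rejected_frames.append(rej)
        diaries = diaries[~bad_wave]
    unknown_participant = ~diaries["participant_id"].isin(participants["participant_id"])
    if unknown_participant.any():
        rej = diaries[unknown_participant].copy()
        rej["reason"] = "diary without matching participant"
        rejected_frames.append(rej)
        diaries = diaries[~unknown_participant]
    diaries["typical_day"] = diaries["typical_day"].fillna(UNKNOWN)
    diaries.loc[~diaries["typical_day"].isin(TYPICAL_DAY), "typical_day"] = UNKNOWN
    if "weekday" in diaries.columns:
        derived = diaries["reporting_day"].map(_weekday_of)
        clash = diaries["weekday"].notna() & (derived != UNKNOWN) & (diaries["weekday"] != derived)
        if clash.any():
            rej = diaries[clash].copy()
            rej["reason"] = "weekday inconsistent with reporting_day"
            rejected_frames.append(rej)
            diaries = diaries[~clash]
        diaries["weekday"] = diaries["weekday"].where(diaries["weekday"].notna(), derived)
    else:
        diaries["weekday"] = diaries["reporting_day"].map(_weekday_of)

    events = events.copy()
    events["group_size"] = pd.to_numeric(events["group_size"], errors="coerce")
    bad_size = events["group_size"].isna() | (events["group_size"] < 1)
    if bad_size.any():
        rej = events[bad_size].copy()
        rej["reason"] = "group_size<1"
        rejected_frames.append(rej)
        events = events[~bad_size]
    events["group_size"] = events["group_size"].astype(int)
    diary_keys = set(zip(diaries["participant_id"], diaries["wave"]))
    orphan = [
        (p, w) not in diary_keys for p, w in zip(events["participant_id"], events["wave"])
    ]
    orphan = np.asarray(orphan)
    if orphan.any():
        rej = events[orphan].copy()
        rej["reason"] = "event without matching diary"
        rejected_frames.append(rej)
        events = events[~orphan]
    for col, valid in [("contact_age_group", CONTACT_AGE_GROUPS), ("setting", SETTINGS)]:
        events[col] = events[col].fillna(UNKNOWN)
        events.loc[~events[col].isin(valid + [UNKNOWN]), col] = UNKNOWN
    events["duration_category"] = pd.to_numeric(events["duration_category"], errors="coerce")
    events["touch"] = events["touch"].astype(str).str.lower().isin(["true", "1", "yes"])

    rejected = (
        pd.concat(rejected_frames, ignore_index=True) if rejected_frames else pd.DataFrame()
    )
    return DiaryPanel(
        participants=participants.reset_index(drop=True),
        diaries=diaries.reset_index(drop=True),
        events=events.reset_index(drop=True),
        rejected=rejected,
        excluded_participants=excluded,
    )


def derive_rates(panel: DiaryPanel) -> pd.DataFrame:
    """Derive one rate record per diary from raw contact events.

    K counts every individual a group event represents (group events add
    ``group_size`` contacts); L counts distinct location labels within the
    diary — labels are never matched across diaries or participants.  The
    school and work settings are merged into one stratum.  Events with an
    unrecorded setting still count towards K and L but fall in
    ``K_unknown_setting``, so ``K_home + K_schoolwork + K_other`` partitions
    K exactly when every setting is recorded.  ``D`` is left missing here;
    the duration module fills it from imputed event durations.
    """
    ev = panel.events
    per_diary = ev.groupby(["participant_id", "wave"], sort=False)
    agg = per_diary.agg(
        K=("group_size", "sum"), L=("location_label", "nunique")
    )
    setting_map = {"home": "K_home", "school": "K_schoolwork", "work": "K_schoolwork",
                   "other": "K_other", UNKNOWN: "K_unknown_setting"}
    strata = (
        ev.assign(stratum=ev["setting"].map(setting_map))
        .pivot_table(
            index=["participant_id", "wave"],
            columns="stratum",
            values="group_size",
            aggfunc="sum",
            fill_value=0,
        )
    )
    rates = panel.diaries[["participant_id", "wave", "weekday", "typical_day"]].copy()
    rates = rates.merge(agg, on=["participant_id", "wave"], how="left")
    rates = rates.merge(strata, on=["participant_id", "wave"], how="left")
    for col in ["K", "L", "K_home", "K_schoolwork", "K_other", "K_unknown_setting"]:
        if col not in rates.columns:
            rates[col] = 0
        rates[col] = pd.to_numeric(rates[col], errors="coerce").fillna(0).astype(int)
    rates["D"] = np.nan
    demo = panel.participants[["participant_id", "age_years", "age_group", "sex", "household_size"]]
    rates = rates.merge(demo, on="participant_id", how="left")
    return rates[RATE_COLUMNS]


def write_rate_table(rates: pd.DataFrame, path: str | Path) -> None:
    rates.to_csv(path, index=False)


def read_rate_table(path: str | Path) -> pd.DataFrame:
    rates = pd.read_csv(path, dtype={"participant_id": str, "wave": str})
    _require_columns(rates, RATE_COLUMNS, "rates.csv")
    return rates


def write_panel(panel: DiaryPanel, directory: str | Path) -> None:
    """Write the panel back to the four-file CSV dialect (lossless round trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = PARTICIPANT_COLUMNS + (
        ["age_group"] if "age_group" in panel.participants.columns else []
    )
    panel.participants[cols].to_csv(directory / "participants.csv", index=False)
    diary_cols = DIARY_COLUMNS + (["weekday"] if "weekday" in panel.diaries.columns else [])
    panel.diaries[diary_cols].to_csv(directory / "diaries.csv", index=False)
    panel.events[EVENT_COLUMNS].to_csv(directory / "events.csv", index=False)
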
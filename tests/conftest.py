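import numpy as np
import pandas as pd
import pytest

from contactdiaries.io_model import DiaryPanel
from contactdiaries.synthetic import SyntheticConfig, generate


def make_panel(participants_rows, diaries_rows, events_rows) -> DiaryPanel:
    """Build a DiaryPanel from explicit row dicts (toy fixtures)."""
    participants = pd.DataFrame(
        participants_rows,
        columns=["participant_id", "household_id", "age_years", "sex",
                 "household_size", "age_group"],
    )
    diaries = pd.DataFrame(
        diaries_rows,
        columns=["participant_id", "wave", "reporting_day", "typical_day", "weekday"],
    )
    events = pd.DataFrame(
        events_rows,
        columns=["participant_id", "wave", "event_id", "group_size", "contact_age_group",
                 "setting", "duration_category", "touch", "location_label", "frequency"],
    )
    return DiaryPanel(participants=participants, diaries=diaries, events=events)


def participant(pid, age=35.0, sex="female", hh="h0", hh_size=2):
    from contactdiaries.io_model import participant_age_group

    return {
        "participant_id": pid, "household_id": hh, "age_years": age, "sex": sex,
        "household_size": hh_size, "age_group": participant_age_group(age),
    }


def diary(pid, wave="R1", day="2012-06-04", typical="typical", weekday="Mon"):
    return {"participant_id": pid, "wave": wave, "reporting_day": day,
            "typical_day": typical, "weekday": weekday}


def event(pid, wave="R1", eid="e0", group_size=1, contact_age="20-39", setting="other",
          duration_category=2, touch=False, location="locA", frequency="often"):
    return {"participant_id": pid, "wave": wave, "event_id": eid, "group_size": group_size,
            "contact_age_group": contact_age, "setting": setting,
            "duration_category": duration_category, "touch": touch,
            "location_label": location, "frequency": frequency}


def rates_frame(values: np.ndarray, waves=None, **columns) -> pd.DataFrame:
    """Rate table from a participants × waves value matrix (K by default)."""
    n, k = values.shape
    waves = waves or [f"R{j+1}" for j in range(k)]
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append({
                "participant_id": f"p{i:04d}", "wave": waves[j], "K": values[i, j],
                "L": 1, "K_home": 0, "K_schoolwork": 0, "K_other": int(values[i, j]),
                "K_unknown_setting": 0, "D": np.nan, "weekday": "Mon",
                "typical_day": "typical", "age_years": 35.0, "age_group": "20-39",
                "sex": "female", "household_size": 2,
            })
    df = pd.DataFrame(rows)
    for name, vals in columns.items():
        df[name] = np.asarray(vals).reshape(-1)
    return df


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_households=120)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate(small_config, seed=42)


@pytest.fixture(scope="session")
def small_rates(small_panel):
    from contactdiaries.io_model import derive_rates

    return derive_rates(small_panel)
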
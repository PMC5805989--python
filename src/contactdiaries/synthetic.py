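"""Synthetic contact-diary panels with the structure the analysis assumes.

The generator emulates an open household cohort followed over four survey
waves: ~857 households / ~1450 individuals, 30% per-wave dropout with
re-entry, long-tailed daily contact counts, group-reported contacts
(average group size around 10), durations observed only as ordinal
categories, and within-individual day-to-day variation exceeding
between-individual variation.

The generative model mirrors the analysis model.  For participant i in
wave j, the number of distinct contact locations L_ij is drawn first
(zero-truncated Poisson), then a latent Gaussian sets the log count of
contacts in excess of the structural one-contact-per-location minimum:

    η_ij = μ_age + β_L·log(1 + min(L_ij, 6)) + wave_j + weekday
           + b_i + ε_ij,
    b_i ~ N(0, σ²_between),   ε_ij ~ N(0, σ²_within),
    K_ij = L_ij + round(expm1(η_ij))  (floored at L_ij).

The location effect saturates at the 6+ category so the fitted categorical
location covariate captures it exactly, and the excess parameterization
keeps log(1+K) a smooth function of the latent Gaussian, so the configured
between/within variance *shares* are recovered by the downstream
random-intercept fit (integer rounding adds a small amount of
within-individual variance, so the components themselves are compressed a
little; the share survives because the compression acts on both alike).
Contacts are split into events (a fraction reported as groups), each event
is given a contact age group with an own-age excess controlled by
``assortativity_strength``, a setting, a location label, a touch flag and
a true exponential duration that is then binned to its duration category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .duration import DurationCategories
from .io_model import (
    CONTACT_AGE_GROUPS,
    DiaryPanel,
    SETTINGS,
    WAVES,
    WEEKDAYS,
    contact_age_group_of,
    participant_age_group,
)

#: Contact-age population proportions shaped like the 2011 Hong Kong census.
DEFAULT_CENSUS = {
    "0-5": 0.055,
    "6-19": 0.145,
    "20-39": 0.305,
    "40-64": 0.365,
    "65+": 0.130,
}

#: Sampling windows (inclusive) for the four study waves.
WAVE_WINDOWS = {
    "R1": ("2012-05-01", "2012-10-31"),
    "R2": ("2012-11-01", "2013-03-15"),
    "R3": ("2013-03-16", "2013-05-31"),
    "R4": ("2013-07-01", "2013-09-30"),
}

_AGE_RANGES = {"2-4": (2, 5), "5-19": (5, 20), "20-39": (20, 40), "40-64": (40, 65), "65+": (65, 90)}

# Event-setting propensities by participant age group (home, school, work, other).
_SETTING_WEIGHTS = {
    "2-4": (0.50, 0.25, 0.00, 0.25),
    "5-19": (0.25, 0.45, 0.02, 0.28),
    "20-39": (0.22, 0.04, 0.44, 0.30),
    "40-64": (0.25, 0.02, 0.40, 0.33),
    "65+": (0.40, 0.01, 0.06, 0.53),
}


def _truncated_geometric(p: float, max_size: int) -> dict[int, float]:
    sizes = np.arange(1, max_size + 1)
    w = p * (1 - p) ** (sizes - 1)
    w = w / w.sum()
    return dict(zip(sizes.tolist(), w.tolist()))


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the diary-panel generator.

    Defaults reproduce the cohort's published scale: 857 households
    (≈1450 individuals at mean household size 1.69), four waves with 30%
    per-wave dropout, a daily contact mean near 12.5 in ≈2.9 locations,
    group reports with mean group size ≈10, exponential event durations
    with mean ≈50 min (total daily duration ≈9 h), and a between-share of
    one third of the log-contact variance.
    """

    n_households: int = 857
    household_size_distribution: dict[int, float] = field(
        default_factory=lambda: _truncated_geometric(0.59, 6)
    )
    age_group_weights: dict[str, float] = field(
        default_factory=lambda: {"2-4": 0.002, "5-19": 0.062, "20-39": 0.196, "40-64": 0.580, "65+": 0.160}
    )
    n_waves: int = 4
    dropout_per_wave: float = 0.30
    rejoin_rate: float = 0.25  # chance a lapsed participant returns next wave
    #: household entry-wave distribution (open cohort: recruitment continues
    #: in later waves to balance losses to follow-up)
    entry_wave_weights: tuple[float, ...] = (0.74, 0.12, 0.08, 0.06)
    mean_log_contacts: dict[str, float] = field(
        default_factory=lambda: {"2-4": 1.15, "5-19": 1.65, "20-39": 1.35, "40-64": 1.45, "65+": 0.95}
    )
    weekday_effects: dict[str, float] = field(
        default_factory=lambda: {
            "Mon": 0.05, "Tue": 0.05, "Wed": 0.05, "Thu": 0.05,
            "Fri": 0.0, "Sat": -0.10, "Sun": -0.10,
        }
    )
    wave_effects: dict[str, float] = field(
        default_factory=lambda: {"R1": 0.0, "R2": 0.10, "R3": 0.0, "R4": -0.05}
    )
    sex_effect_male: float = 0.0
    sigma2_between: float = 0.22
    sigma2_within: float = 0.44
    mean_locations: float = 2.65  # zero-truncated Poisson rate; mean L ≈ 2.9
    sigma2_between_locations: float = 0.08  # participant propensity on log L rate
    location_coupling: float = 0.50  # β_L on log1p(min(L, 6))
    group_report_rate: float = 0.40  # expected groups per diary (paper: <1)
    group_size_mean: float = 10.0  # 2 + Poisson(mean-2): average size 9–11
    duration_rate: float = 0.0202  # per minute; mean event duration ≈50 min, total ≈9.1 h/day
    assortativity_strength: float = 0.40
    typical_day_probs: tuple[float, float, float] = (0.734, 0.263, 0.003)
    census: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CENSUS))
    duration_categories: DurationCategories = field(default_factory=DurationCategories)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_per_wave < 1:
            raise ValueError("dropout_per_wave must lie in [0, 1)")
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")
        for name in ("household_size_distribution", "age_group_weights"):
            w = np.array(list(getattr(self, name).values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError(f"{name}: weights must be non-negative and sum > 0")
        if not np.isclose(sum(self.age_group_weights.values()), 1.0, atol=1e-6):
            raise ValueError("age_group_weights must sum to 1")

    @property
    def waves(self) -> list[str]:
        return WAVES[: self.n_waves]


def census_series(config: SyntheticConfig) -> pd.Series:
    s = pd.Series(config.census, dtype=float).loc[CONTACT_AGE_GROUPS]
    return s / s.sum()


def generate_population(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw households and their members; deterministic under the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes_support = np.array(list(config.household_size_distribution.keys()))
    sizes_probs = np.array(list(config.household_size_distribution.values()), dtype=float)
    sizes_probs = sizes_probs / sizes_probs.sum()
    sizes = rng.choice(sizes_support, size=config.n_households, p=sizes_probs)

    groups = list(config.age_group_weights.keys())
    gw = np.array(list(config.age_group_weights.values()), dtype=float)
    gw = gw / gw.sum()

    rows = []
    pid = 0
    for h, size in enumerate(sizes):
        hid = f"h{h:05d}"
        member_groups = rng.choice(len(groups), size=size, p=gw)
        for g in member_groups:
            lo, hi = _AGE_RANGES[groups[g]]
            age = float(np.round(rng.uniform(lo, hi), 1))
            rows.append(
                {
                    "participant_id": f"p{pid:05d}",
                    "household_id": hid,
                    "age_years": age,
                    "sex": "male" if rng.random() < 0.39 else "female",
                    "household_size": int(size),
                }
            )
            pid += 1
    participants = pd.DataFrame(rows)
    participants["age_group"] = participants["age_years"].map(participant_age_group)
    return participants


def _participation(
    n: int, config: SyntheticConfig, rng: np.random.Generator, entry_wave: np.ndarray
) -> np.ndarray:
    """Markov participation per participant × wave after a staggered entry:
    continuing participants drop at ``dropout_per_wave``; lapsed participants
    re-enter at ``rejoin_rate`` (open cohort with ongoing recruitment)."""
    waves = config.waves
    part = np.zeros((n, len(waves)), dtype=bool)
    part[np.arange(n), entry_wave] = True
    for j in range(1, len(waves)):
        stay = rng.random(n) < (1.0 - config.dropout_per_wave)
        rejoin = rng.random(n) < config.rejoin_rate
        after_entry = entry_wave < j
        part[:, j] |= after_entry & np.where(part[:, j - 1], stay, rejoin)
    return part


def _zt_poisson(lam: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson draw by inverse CDF (stable for tiny rates)."""
    from scipy import stats

    p0 = np.exp(-lam)
    u = rng.uniform(p0, 1.0)
    return max(1, int(stats.poisson.ppf(u, lam)))


def _reporting_day(wave: str, rng: np.random.Generator) -> pd.Timestamp:
    lo, hi = WAVE_WINDOWS[wave]
    lo, hi = pd.Timestamp(lo), pd.Timestamp(hi)
    return lo + pd.Timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def generate_panel(
    participants: pd.DataFrame, config: SyntheticConfig, seed: int | None = None
) -> DiaryPanel:
    """Generate diaries and contact events for an existing population."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n = len(participants)
    waves = config.waves
    ew = np.asarray(config.entry_wave_weights[: len(waves)], dtype=float)
    ew = ew / ew.sum()
    # entry is at the household level: all members join together
    households = participants["household_id"].to_numpy()
    uniq, inverse = np.unique(households, return_inverse=True)
    hh_entry = rng.choice(len(waves), size=len(uniq), p=ew)
    part = _participation(n, config, rng, hh_entry[inverse])
    intercepts = rng.normal(0.0, np.sqrt(config.sigma2_between), size=n)
    # participant-level propensity to roam: persistent component of L,
    # independent of the contact-count intercepts
    loc_propensity = rng.normal(
        -config.sigma2_between_locations / 2.0,
        np.sqrt(config.sigma2_between_locations),
        size=n,
    )

    census = census_series(config)
    census_groups = list(census.index)
    census_probs = census.to_numpy()
    cat = config.duration_categories
    tp, tn, tu = config.typical_day_probs

    diary_rows, event_rows = [], []
    for i in range(n):
        p = participants.iloc[i]
        own_contact_group = contact_age_group_of(p["age_years"])
        mu_age = config.mean_log_contacts.get(p["age_group"], 1.5)
        sw = np.array(_SETTING_WEIGHTS.get(p["age_group"], (0.25, 0.05, 0.35, 0.35)))
        sw = sw / sw.sum()
        for j, wave in enumerate(waves):
            if not part[i, j]:
                continue
            day = _reporting_day(wave, rng)
            weekday = WEEKDAYS[day.weekday()]
            loc_rate = config.mean_locations * np.exp(loc_propensity[i])
            L = _zt_poisson(loc_rate, rng)
            eta = (
                mu_age
                + config.location_coupling * np.log1p(min(L, 6))
                + config.wave_effects.get(wave, 0.0)
                + config.weekday_effects.get(weekday, 0.0)
                + (config.sex_effect_male if p["sex"] == "male" else 0.0)
                + intercepts[i]
                + rng.normal(0.0, np.sqrt(config.sigma2_within))
            )
            # η models contacts in excess of the structural one-contact-
            # per-location minimum, keeping the realized log(1+K) a smooth
            # function of the latent Gaussian
            K = L + max(0, int(np.round(np.expm1(eta))))
            u = rng.random()
            typical = "typical" if u < tp else ("non_typical" if u < tp + tn else "unknown")
            diary_rows.append(
                {
                    "participant_id": p["participant_id"],
                    "wave": wave,
                    "reporting_day": day.date().isoformat(),
                    "typical_day": typical,
                    "weekday": weekday,
                }
            )
            if K == 0:
                continue
            # split K contacts into events: possibly group reports, rest
            # individual; group sizes are capped so the diary keeps at least
            # L events (one per location)
            event_sizes: list[int] = []
            remaining = K
            slack = K - L  # contacts available for absorption into groups
            n_groups = rng.poisson(config.group_report_rate)
            for _ in range(n_groups):
                gmax = min(slack + 1, remaining)
                if gmax < 3:
                    break
                g = min(int(2 + rng.poisson(config.group_size_mean - 2)), gmax)
                event_sizes.append(g)
                remaining -= g
                slack -= g - 1
            event_sizes.extend([1] * remaining)
            n_events = len(event_sizes)
            n_loc = min(L, n_events)
            loc_of = np.concatenate(
                [np.arange(n_loc), rng.integers(0, n_loc, size=n_events - n_loc)]
            )
            rng.shuffle(loc_of)
            assort = rng.random(n_events) < config.assortativity_strength
            cages = np.where(
                assort,
                own_contact_group,
                rng.choice(census_groups, size=n_events, p=census_probs),
            )
            settings = rng.choice(SETTINGS, size=n_events, p=sw)
            true_dur = rng.exponential(1.0 / config.duration_rate, size=n_events)
            dur_cat = cat.categorize(true_dur)
            touch_p = np.where(settings == "home", 0.7, 0.35)
            touch = rng.random(n_events) < touch_p
            freq = rng.choice(
                ["daily", "often", "occasional", "rare", "first_time"],
                size=n_events,
                p=[0.35, 0.25, 0.2, 0.1, 0.1],
            )
            for e in range(n_events):
                event_rows.append(
                    {
                        "participant_id": p["participant_id"],
                        "wave": wave,
                        "event_id": f"{p['participant_id']}-{wave}-e{e}",
                        "group_size": int(event_sizes[e]),
                        "contact_age_group": cages[e],
                        "setting": settings[e],
                        "duration_category": int(dur_cat[e]),
                        "touch": bool(touch[e]),
                        "location_label": f"loc{loc_of[e]}",
                        "frequency": freq[e],
                    }
                )

    diaries = pd.DataFrame(diary_rows)
    events = pd.DataFrame(
        event_rows,
        columns=[
            "participant_id", "wave", "event_id", "group_size", "contact_age_group",
            "setting", "duration_category", "touch", "location_label", "frequency",
        ],
    )
    return DiaryPanel(participants=participants.copy(), diaries=diaries, events=events)


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> DiaryPanel:
    """Convenience: population + panel in one call."""
    config = config or SyntheticConfig()
    participants = generate_population(config, seed=seed)
    return generate_panel(participants, config, seed=seed)


def write_census(config: SyntheticConfig, path: str | Path, scale: float = 7_000_000) -> None:
    """Write a census.csv matching the generator's contact-age proportions."""
    s = census_series(config)
    pd.DataFrame(
        {"age_group": s.index, "population_count": np.round(s.to_numpy() * scale).astype(int)}
    ).to_csv(path, index=False)
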
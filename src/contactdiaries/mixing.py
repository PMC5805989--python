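"""Age-mixing matrices relative to proportionate mixing, and NGM growth rates.

For participant age group a and contact age group b, the mixing ratio is

    ratio(a, b) = (share of group-a participants' contacts made with
                   group-b individuals) / (census proportion of group b).

Under proportionate mixing — contacts distributed across ages in
proportion to the census population — every ratio is 1; values above one
indicate age-assortative excess.  Group events contribute ``group_size``
contacts of the event's contact age group.  Confidence intervals come from
bootstrap resampling of participants (each resampled participant brings
all their contacts for the wave).  Participants aged 2–4 are excluded
(small samples), as are contacts of unknown age.

For epidemic-growth comparison across waves, per-capita contact-rate
matrices are collapsed to a common square age grouping and their dominant
eigenvalues — proportional to the epidemic growth factor under uniform
susceptibility and infectivity — are ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import CONTACT_AGE_GROUPS, PARTICIPANT_AGE_GROUPS, DiaryPanel

#: Square age grouping shared by both axes for the next-generation matrix:
#: participant 5–19 is matched with contact 6–19; the 0–5 contact column,
#: absent on the participant side, is dropped.
NGM_GROUPS = ["5-19", "20-39", "40-64", "65+"]
_NGM_CONTACT_OF = {"5-19": "6-19", "20-39": "20-39", "40-64": "40-64", "65+": "65+"}


@dataclass
class MixingMatrix:
    wave: str
    contact_filter: str  # "all" | "touch"
    ratio: pd.DataFrame  # participant groups × contact groups
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format CSV-ready table: wave, groups, ratio and CI columns."""
        rows = []
        for a in self.ratio.index:
            for b in self.ratio.columns:
                rows.append(
                    {
                        "wave": self.wave,
                        "participant_group": a,
                        "contact_group": b,
                        "ratio": self.ratio.loc[a, b],
                        "ci_low": None if self.ci_low is None else self.ci_low.loc[a, b],
                        "ci_high": None if self.ci_high is None else self.ci_high.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _participant_contact_counts(
    panel: DiaryPanel, wave: str, touch_only: bool = False
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-participant contact counts by contact age group for one wave.

    Returns (group index per participant, counts matrix n×5, participant ids)
    for participants with a diary in the wave and a usable age group.
    Contacts with unknown age are excluded from the counts.
    """
    diaries = panel.diaries[panel.diaries["wave"] == wave]
    demo = panel.participants.set_index("participant_id")["age_group"]
    pids = [p for p in diaries["participant_id"] if demo.get(p) in PARTICIPANT_AGE_GROUPS]
    pos = {p: i for i, p in enumerate(pids)}
    counts = np.zeros((len(pids), len(CONTACT_AGE_GROUPS)))
    ev = panel.events
    ev = ev[(ev["wave"] == wave) & ev["contact_age_group"].isin(CONTACT_AGE_GROUPS)]
    if touch_only:
        ev = ev[ev["touch"]]
    cidx = {g: j for j, g in enumerate(CONTACT_AGE_GROUPS)}
    for p, g, s in zip(ev["participant_id"], ev["contact_age_group"], ev["group_size"]):
        i = pos.get(p)
        if i is not None:
            counts[i, cidx[g]] += s
    group_idx = np.array([PARTICIPANT_AGE_GROUPS.index(demo[p]) for p in pids], dtype=int)
    return group_idx, counts, pids


def _ratios_from_counts(
    group_idx: np.ndarray, counts: np.ndarray, census: np.ndarray
) -> np.ndarray:
    """(4×5) ratio matrix from per-participant counts; empty groups → NaN."""
    out = np.full((len(PARTICIPANT_AGE_GROUPS), len(CONTACT_AGE_GROUPS)), np.nan)
    for a in range(len(PARTICIPANT_AGE_GROUPS)):
        tot = counts[group_idx == a].sum(axis=0)
        denom = tot.sum()
        if denom > 0:
            out[a] = (tot / denom) / census
    return out


def mixing_ratio_matrix(
    panel: DiaryPanel, census: pd.Series, wave: str, touch_only: bool = False
) -> MixingMatrix:
    """Point-estimate mixing ratio matrix for one wave.

    ``census`` maps contact age groups to population proportions (must be
    positive and cover all five groups; normalized internally).
    """
    census = census.loc[CONTACT_AGE_GROUPS].astype(float)
    if (census <= 0).any():
        raise ValueError("census proportions must be positive for all contact age groups")
    census = (census / census.sum()).to_numpy()
    group_idx, counts, _ = _participant_contact_counts(panel, wave, touch_only)
    ratios = _ratios_from_counts(group_idx, counts, census)
    return MixingMatrix(
        wave=wave,
        contact_filter="touch" if touch_only else "all",
        ratio=pd.DataFrame(ratios, index=PARTICIPANT_AGE_GROUPS, columns=CONTACT_AGE_GROUPS),
    )


def bootstrap_ci(
    panel: DiaryPanel,
    census: pd.Series,
    wave: str,
    touch_only: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> MixingMatrix:
    """Mixing matrix with percentile bootstrap CIs.

    The resampling unit is the participant: each draw resamples the wave's
    participants with replacement, carrying all of a participant's contacts.
    The point estimate is the plug-in estimate on the original sample.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be ≥ 2")
    census_norm = census.loc[CONTACT_AGE_GROUPS].astype(float)
    census_norm = (census_norm / census_norm.sum()).to_numpy()
    group_idx, counts, _ = _participant_contact_counts(panel, wave, touch_only)
    point = _ratios_from_counts(group_idx, counts, census_norm)
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_percentiles(group_idx, counts, census_norm, n_boot, rng)
    return MixingMatrix(
        wave=wave,
        contact_filter="touch" if touch_only else "all",
        ratio=pd.DataFrame(point, index=PARTICIPANT_AGE_GROUPS, columns=CONTACT_AGE_GROUPS),
        ci_low=pd.DataFrame(lo, index=PARTICIPANT_AGE_GROUPS, columns=CONTACT_AGE_GROUPS),
        ci_high=pd.DataFrame(hi, index=PARTICIPANT_AGE_GROUPS, columns=CONTACT_AGE_GROUPS),
    )


def _bootstrap_percentiles(
    group_idx: np.ndarray,
    counts: np.ndarray,
    census: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized participant bootstrap → 2.5/97.5 percentile ratio bands."""
    n = len(group_idx)
    n_a, n_b = len(PARTICIPANT_AGE_GROUPS), len(CONTACT_AGE_GROUPS)
    onehot = np.zeros((n, n_a))
    onehot[np.arange(n), group_idx] = 1.0
    reps = np.empty((n_boot, n_a, n_b))
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tot = onehot[idx].T @ counts[idx]  # (4, 5) total contacts per group
        denom = tot.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            reps[r] = (tot / denom) / census
    import warnings

    with warnings.catch_warnings():
        # groups empty in every resample yield all-NaN cells by design
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(reps, 2.5, axis=0)
        hi = np.nanpercentile(reps, 97.5, axis=0)
    return lo, hi


def contact_rate_matrix(panel: DiaryPanel, wave: str, touch_only: bool = False) -> pd.DataFrame:
    """Per-capita contact-rate matrix on the common square NGM age grouping.

    Entry (a, b): mean contacts per group-a diary with group-b contacts,
    contact ages collapsed to the participant-side groups (0–5 dropped).
    """
    group_idx, counts, _ = _participant_contact_counts(panel, wave, touch_only)
    out = np.zeros((len(NGM_GROUPS), len(NGM_GROUPS)))
    for ai, a in enumerate(NGM_GROUPS):
        sel = group_idx == PARTICIPANT_AGE_GROUPS.index(a)
        n_a = sel.sum()
        if n_a == 0:
            continue
        for bi, b in enumerate(NGM_GROUPS):
            j = CONTACT_AGE_GROUPS.index(_NGM_CONTACT_OF[b])
            out[ai, bi] = counts[sel, j].sum() / n_a
    return pd.DataFrame(out, index=NGM_GROUPS, columns=NGM_GROUPS)


def dominant_eigenvalue(matrix) -> float:
    """Perron root of a nonnegative square matrix (spectral radius)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if (m < 0).any():
        raise ValueError("matrix entries must be non-negative")
    return float(np.max(np.abs(np.linalg.eigvals(m))))


def ngm_growth_rank(
    matrices: dict[str, pd.DataFrame], susceptibility: np.ndarray | None = None
) -> pd.DataFrame:
    """Rank waves by the dominant eigenvalue of their contact-rate matrices.

    An optional susceptibility profile scales the rows (who gets infected);
    by default susceptibility and infectivity are uniform, so the eigenvalue
    is proportional to the epidemic growth factor.
    """
    rows = []
    for wave, m in matrices.items():
        arr = np.asarray(m, dtype=float)
        if susceptibility is not None:
            arr = np.diag(np.asarray(susceptibility, dtype=float)) @ arr
        rows.append({"wave": wave, "growth_factor": dominant_eigenvalue(arr)})
    out = pd.DataFrame(rows).sort_values("growth_factor", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
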
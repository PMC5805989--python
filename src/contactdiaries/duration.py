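"""Exponential duration model for interval-censored contact durations.

Contact durations are reported only as ordinal categories with known time
boundaries (interval censoring).  We fit a single exponential rate λ (per
minute), pooled over all contacts, by expectation–maximization:

* E-step: the expected duration of a contact known to lie in [a, b) under
  Exponential(λ) is available in closed form,
    E[T | a ≤ T < b] = a + 1/λ − (b−a)·e^{−λ(b−a)} / (1 − e^{−λ(b−a)}),
  reducing to a + 1/λ for the right-open tail (b = ∞).
* M-step: λ ← N / Σ_c n_c · E[T | category c].

The iteration converges to the interval-censored maximum-likelihood
estimate; the censored log-likelihood is monotone non-decreasing across
iterations and is asserted as such.

Given a fitted rate, per-event durations are imputed by inverse-CDF
sampling from Exponential(λ) truncated to each event's category interval,
repeated over replicates so that derived metrics carry imputation
uncertainty.  Total contact duration per diary, D (hours), is the sum of
its events' imputed durations; a group event contributes a single duration
regardless of group size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default category boundaries in minutes: <5, 5–14, 15–59, 60–239, ≥240.
#: The widely used contact-survey convention; configurable everywhere.
DEFAULT_BOUNDARIES = (0.0, 5.0, 15.0, 60.0, 240.0, np.inf)


@dataclass(frozen=True)
class DurationCategories:
    """Ordered duration category boundaries in minutes, last right-open."""

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b[0] != 0:
            raise ValueError("first lower bound must be 0")
        if not np.all(np.diff(b) >= 0) or len(b) < 2:
            raise ValueError("boundaries must be non-decreasing with ≥1 category")

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) - 1

    def interval(self, index: int) -> tuple[float, float]:
        return self.boundaries[index], self.boundaries[index + 1]

    def lowers(self) -> np.ndarray:
        return np.asarray(self.boundaries[:-1], dtype=float)

    def uppers(self) -> np.ndarray:
        return np.asarray(self.boundaries[1:], dtype=float)

    def categorize(self, minutes: np.ndarray) -> np.ndarray:
        """Bin exact durations (minutes) into category indices."""
        return np.clip(
            np.searchsorted(self.boundaries[1:], minutes, side="right"),
            0,
            self.n_categories - 1,
        )


@dataclass
class DurationModel:
    rate_per_minute: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    categories: DurationCategories = field(default_factory=DurationCategories)

    @property
    def mean_minutes(self) -> float:
        return 1.0 / self.rate_per_minute


def censored_loglik(lam: float, counts: np.ndarray, categories: DurationCategories) -> float:
    """Censored-exponential log-likelihood of category counts at rate ``lam``."""
    if lam <= 0:
        return -np.inf
    a, b = categories.lowers(), categories.uppers()
    with np.errstate(over="ignore"):
        prob = np.exp(-lam * a) - np.where(np.isinf(b), 0.0, np.exp(-lam * b))
    # zero-width (point) categories carry the exponential density instead
    point = b == a
    prob = np.where(point, lam * np.exp(-lam * a), prob)
    mask = counts > 0
    if np.any(prob[mask] <= 0):
        return -np.inf
    return float(np.sum(counts[mask] * np.log(prob[mask])))


def _expected_duration(lam: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """E[T | a ≤ T < b] under Exponential(lam); handles b=∞ and point intervals."""
    w = b - a
    out = np.empty_like(a)
    tail = np.isinf(b)
    out[tail] = a[tail] + 1.0 / lam
    fin = ~tail & (w > 0)
    ew = np.exp(-lam * w[fin])
    out[fin] = a[fin] + 1.0 / lam - w[fin] * ew / (1.0 - ew)
    out[~tail & (w == 0)] = a[~tail & (w == 0)]
    return out


def fit_censored_exponential(
    category_counts,
    categories: DurationCategories | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> DurationModel:
    """Fit Exponential(λ) to categorized duration counts by EM.

    Parameters
    ----------
    category_counts
        Count of contact events per duration category, aligned with
        ``categories``.
    categories
        Category boundaries in minutes; defaults to the package convention.
    tol
        Convergence threshold on the relative change of λ between
        iterations.

    Returns
    -------
    DurationModel
        Fitted rate (per minute) with the censored log-likelihood at the
        optimum; equals the interval-censored MLE.

    Raises
    ------
    ValueError
        If no events are observed, or all mass sits in the unbounded tail
        starting at 0 (the rate is then non-identifiable).
    """
    categories = categories or DurationCategories()
    counts = np.asarray(category_counts, dtype=float)
    if counts.shape != (categories.n_categories,):
        raise ValueError("category_counts length must match number of categories")
    n = counts.sum()
    if n <= 0:
        raise ValueError("no observed durations")
    a, b = categories.lowers(), categories.uppers()
    finite_occupied = counts[(~np.isinf(b)) | (a > 0)].sum()
    if finite_occupied == 0 and np.all(a[counts > 0] == 0):
        raise ValueError("all mass in the unbounded tail from 0: rate non-identifiable")
    occupied = np.flatnonzero(counts > 0)
    if len(occupied) == 1 and b[occupied[0]] != a[occupied[0]]:
        # a single occupied non-point interval pushes the MLE to 0 or ∞
        raise ValueError(
            "all mass in a single censoring interval: rate non-identifiable"
        )

    # moment-style initial value from interval midpoints (tail: lower + width guess)
    mid = np.where(np.isinf(b), a + np.max(a[np.isfinite(a)]) + 1.0, (a + b) / 2.0)
    lam = n / float(np.sum(counts * np.maximum(mid, 1e-9)))

    ll_prev = censored_loglik(lam, counts, categories)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = _expected_duration(lam, a, b)
        lam_new = n / float(np.sum(counts * expected))
        ll = censored_loglik(lam_new, counts, categories)
        if ll < ll_prev - 1e-9:  # EM guarantee; numerical slack only
            raise RuntimeError("censored log-likelihood decreased during EM")
        rel = abs(lam_new - lam) / lam
        lam, ll_prev = lam_new, ll
        if rel < tol:
            converged = True
            break
    return DurationModel(
        rate_per_minute=float(lam),
        log_likelihood=float(ll_prev),
        n_iterations=it,
        converged=converged,
        categories=categories,
    )


def truncated_exponential_mean(lam: float, a: float, b: float) -> float:
    """Closed-form E[T | a ≤ T < b] for Exponential(lam)."""
    a_, b_ = np.asarray([a], dtype=float), np.asarray([b], dtype=float)
    return float(_expected_duration(lam, a_, b_)[0])


def sample_truncated_exponential(
    lam: float, a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws from Exponential(lam) truncated to [a, b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = rng.random(a.shape)
    with np.errstate(over="ignore"):
        mass = np.where(np.isinf(b), 1.0, -np.expm1(-lam * (b - a)))
    out = a - np.log1p(-u * mass) / lam
    out = np.where(b == a, a, out)  # point intervals are deterministic
    return out


@dataclass
class ImputationSet:
    """Per-replicate imputed event durations and per-diary totals.

    ``totals`` is a DataFrame indexed by (participant_id, wave) with one
    column per replicate, in hours.  Events whose duration category is
    unrecorded are drawn from the untruncated exponential and flagged.
    """

    n_replicates: int
    seed: int
    totals: pd.DataFrame
    event_durations: np.ndarray  # (n_replicates, n_events) minutes
    event_index: pd.DataFrame  # participant_id, wave per event column
    n_unknown_category: int

    def summarize(self) -> pd.DataFrame:
        """Across-replicate mean and 2.5/97.5 percentiles of D per diary."""
        vals = self.totals.to_numpy()
        return pd.DataFrame(
            {
                "D": vals.mean(axis=1),
                "D_lo": np.percentile(vals, 2.5, axis=1),
                "D_hi": np.percentile(vals, 97.5, axis=1),
            },
            index=self.totals.index,
        )


def impute_durations(
    panel,
    model: DurationModel,
    n_replicates: int = 200,
    seed: int = 0,
) -> ImputationSet:
    """Impute per-event durations and per-diary totals D over replicates.

    Each event's duration is drawn from Exponential(λ) truncated to its
    category interval; a group event contributes one duration regardless of
    its group size.  The RNG is seeded per replicate index so any replicate
    is reproducible in isolation.
    """
    cats = model.categories
    lam = model.rate_per_minute
    ev = panel.events
    diaries = panel.diaries
    cat_idx = ev["duration_category"].to_numpy(dtype=float)
    known = ~np.isnan(cat_idx)
    if known.any() and (
        (cat_idx[known] < 0).any() or (cat_idx[known] >= cats.n_categories).any()
    ):
        raise ValueError("duration_category outside the configured category set")
    a = np.zeros(len(ev))
    b = np.full(len(ev), np.inf)
    ki = cat_idx[known].astype(int)
    a[known] = cats.lowers()[ki]
    b[known] = cats.uppers()[ki]

    draws = np.empty((n_replicates, len(ev)))
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        draws[r] = sample_truncated_exponential(lam, a, b, rng)

    key = pd.MultiIndex.from_frame(diaries[["participant_id", "wave"]])
    ev_key = pd.MultiIndex.from_frame(ev[["participant_id", "wave"]])
    pos = key.get_indexer(ev_key)
    totals = np.zeros((len(key), n_replicates))
    np.add.at(totals, pos, draws.T / 60.0)  # minutes → hours
    totals_df = pd.DataFrame(
        totals, index=key, columns=[f"rep{r}" for r in range(n_replicates)]
    )
    return ImputationSet(
        n_replicates=n_replicates,
        seed=seed,
        totals=totals_df,
        event_durations=draws,
        event_index=ev[["participant_id", "wave"]].copy(),
        n_unknown_category=int((~known).sum()),
    )


def total_duration(imputations: ImputationSet) -> pd.DataFrame:
    """Per-diary D: across-replicate mean with a 95% replicate envelope."""
    return imputations.summarize()


def fill_rate_durations(rates: pd.DataFrame, imputations: ImputationSet) -> pd.DataFrame:
    """Return the rate table with D filled from the imputation means (hours)."""
    summary = imputations.summarize()
    rates = rates.drop(columns=["D"]).merge(
        summary[["D"]],
        left_on=["participant_id", "wave"],
        right_index=True,
        how="left",
    )
    rates["D"] = rates["D"].fillna(0.0)
    from .io_model import RATE_COLUMNS

    return rates[RATE_COLUMNS]
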
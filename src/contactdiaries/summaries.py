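"""Population-level summaries of contact rates across survey waves.

Overall averages use the mean of participants' means so that participants
observed in several waves are not over-weighted.  Wave homogeneity is
assessed with Pearson chi-square tests on binned per-diary values;
between-wave dependence with Pearson (or Spearman) correlations over
participants observed in both waves; and individual stability with
per-participant coefficients of variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VARIABLES = ("K", "D", "L")


def mean_of_participant_means(rates: pd.DataFrame, variable: str = "K") -> float:
    """Unweighted mean over participants of each participant's diary mean."""
    if rates.empty:
        raise ValueError("empty rate table")
    per_participant = rates.groupby("participant_id")[variable].mean()
    return float(per_participant.mean())


def default_bins(values: pd.Series, variable: str, n_bins: int = 10) -> np.ndarray:
    """Histogram bin edges: integer-ish quantile bins for counts (K, L),
    log-spaced bins for durations (D)."""
    v = values.to_numpy(dtype=float)
    if variable == "D":
        pos = v[v > 0]
        lo = pos.min() if len(pos) else 0.1
        edges = np.concatenate([[-0.5], np.geomspace(max(lo, 1e-3), v.max() + 1e-9, n_bins)])
    else:
        qs = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)))
        edges = np.concatenate([[v.min() - 0.5], qs[1:-1] + 0.5, [v.max() + 0.5]])
    return np.unique(edges)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    bin_edges: np.ndarray
    table: pd.DataFrame


def _pool_sparse_bins(table: np.ndarray, min_expected: float = 5.0) -> np.ndarray:
    """Pool tail bins (columns) until every expected count is ≥ min_expected."""
    while table.shape[1] > 2:
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        if expected.min() >= min_expected:
            break
        j = int(np.argmin(expected.min(axis=0)))
        k = j - 1 if j == table.shape[1] - 1 else j + 1
        table[:, min(j, k)] += table[:, max(j, k)]
        table = np.delete(table, max(j, k), axis=1)
    return table


def wave_homogeneity_test(
    rates: pd.DataFrame,
    variable: str = "K",
    bin_edges: np.ndarray | None = None,
    n_bins: int = 10,
) -> ChiSquareResult:
    """Pearson chi-square test of identical per-diary distributions across waves.

    Per-diary values are binned with shared edges (configurable; reported in
    the result); sparse tail bins are pooled so expected counts reach 5.
    No continuity correction is applied.
    """
    waves = sorted(rates["wave"].unique())
    if len(waves) < 2:
        raise ValueError("need at least two waves")
    counts_by_wave = rates.groupby("wave").size()
    if (counts_by_wave == 0).any():
        raise ValueError("a wave has zero diaries")
    if bin_edges is None:
        bin_edges = default_bins(rates[variable], variable, n_bins=n_bins)
    table = np.vstack(
        [
            np.histogram(rates.loc[rates["wave"] == w, variable].to_numpy(dtype=float), bins=bin_edges)[0]
            for w in waves
        ]
    ).astype(float)
    table = table[:, table.sum(axis=0) > 0]
    table = _pool_sparse_bins(table)
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        bin_edges=np.asarray(bin_edges),
        table=pd.DataFrame(table, index=waves),
    )


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float


def between_wave_correlation(
    rates: pd.DataFrame,
    variable: str,
    wave_pair: tuple[str, str],
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation of a rate between two waves over shared participants,
    with a Fisher-z 95% confidence interval."""
    w1, w2 = wave_pair
    wide = rates.pivot_table(index="participant_id", columns="wave", values=variable)
    if w1 not in wide.columns or w2 not in wide.columns:
        raise ValueError(f"wave pair {wave_pair} not present")
    both = wide[[w1, w2]].dropna()
    if len(both) < 3:
        raise ValueError("need ≥3 participants observed in both waves")
    x, y = both[w1].to_numpy(), both[w2].to_numpy()
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    n = len(both)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 or n <= 3:
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), n=n, p_value=float(p))


def participant_cv(rates: pd.DataFrame, variables: tuple[str, ...] = VARIABLES) -> pd.DataFrame:
    """Per-participant coefficient of variation (sample sd / mean) of each rate.

    Restricted to participants with ≥2 diaries; a zero mean leaves the CV
    undefined (NaN).  Use :func:`cv_correlations` for the cross-variable
    CV correlations.
    """
    counts = rates.groupby("participant_id").size()
    keep = counts[counts >= 2].index
    sub = rates[rates["participant_id"].isin(keep)]
    out = {}
    for v in variables:
        g = sub.groupby("participant_id")[v]
        mean, sd = g.mean(), g.std(ddof=1)
        cv = sd / mean.where(mean > 0)
        out[f"cv_{v}"] = cv
    return pd.DataFrame(out)


def cv_correlations(cv_table: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlations between participants' CVs across rate variables."""
    return cv_table.dropna().corr(method=method)


def typical_day_filter(rates: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Restrict to diaries reported as typical days.

    Returns the filtered table and the proportion of classified diaries
    (typical or non-typical) that were typical; 'unknown' responses do not
    enter the denominator.
    """
    classified = rates[rates["typical_day"].isin(["typical", "non_typical"])]
    if classified.empty:
        raise ValueError("no classified typical-day responses")
    proportion = float((classified["typical_day"] == "typical").mean())
    return rates[rates["typical_day"] == "typical"].copy(), proportion


def wave_summary(rates: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-wave n, mean and quantiles of a per-diary rate."""
    g = rates.groupby("wave")[variable]
    out = g.agg(n="size", mean="mean", median="median")
    for q in (0.25, 0.75, 0.95):
        out[f"q{int(q*100)}"] = g.quantile(q)
    return out
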
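"""Random-intercept models and longitudinal variation analyses.

Contact rates are modelled on the log(1+y) scale with Gaussian linear
mixed models: fixed effects for participant age group, sex, weekday, study
wave and (for contact-count and duration responses) the categorized number
of contact locations, plus a participant-specific random intercept.
Fitting is by restricted maximum likelihood, restricted to participants
with at least two observations.  The random-intercept structure yields the
decomposition of contact-rate variance into a between-individual share
σ²_b/(σ²_b+σ²_w) and the complementary within-individual share.

Covariate effects are reported as percentage contributions: the predicted
rate (back-transformed, exp(·)−1, random intercept at zero) for a
covariate profile as a percentage of the prediction for a fixed comparator
— a 50-year-old male reporting on a Monday in the first wave, household
size one, a single contact location.

Two permutation-null analyses probe within-participant dependence using
participants observed in all waves.  Both nulls permute each wave's
observations across participants, which destroys within-participant
linkage while preserving every wave's marginal distribution exactly:

* accumulation: between-participant CV of cumulative rates at horizons
  1..W, against the null envelope (saturation of the effective
  neighbourhood);
* quantile consistency: the percentage of participants remaining in the
  same within-wave quantile across all waves, for an increasing number of
  quantiles; under independent waves this approaches 100·(1/q)^(W−1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.optimize import minimize_scalar

from .io_model import WAVES

RESPONSES = ("K", "D", "L", "K_home", "K_schoolwork", "K_other")

DEFAULT_COMPARATOR = {
    "age_group": "40-64",  # a 50-year-old
    "sex": "male",
    "weekday": "Mon",
    "wave": "R1",
    "loc_cat": "1",
    "household_size_cat": "1",
}

LOCATION_CATEGORIES = ["0", "1", "2", "3", "4", "5", "6+"]


def location_category(L) -> pd.Series:
    """Categorize location counts as 0, 1, ..., 5, 6+."""
    L = pd.Series(L)
    return pd.Series(
        np.where(L >= 6, "6+", L.astype(int).astype(str)), index=L.index, dtype="object"
    )


@dataclass
class ModelSpec:
    """Specification of one mixed-model fit on a log(1+y) response."""

    response: str = "K"
    include_location: bool | None = None  # default: only for K and D
    include_household_size: bool = False  # home-contact model
    min_observations: int = 2

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.include_location is None:
            self.include_location = self.response in ("K", "D")
        if self.response == "L" and self.include_location:
            raise ValueError("location-count covariate is not allowed when the response is L")

    @property
    def fixed_terms(self) -> list[str]:
        terms = ["C(age_group)", "C(sex)", "C(weekday)", "C(wave)"]
        if self.include_location:
            terms.append("C(loc_cat)")
        if self.include_household_size:
            terms.append("C(household_size_cat)")
        return terms

    @property
    def formula(self) -> str:
        return "y ~ " + " + ".join(self.fixed_terms)


@dataclass
class FittedModel:
    spec: ModelSpec
    fixed_effects: pd.Series
    sigma2_between: float
    sigma2_within: float
    reml_criterion: float  # -2 × restricted log-likelihood, up to a constant
    design_info: object  # patsy DesignInfo, for out-of-sample prediction
    data: pd.DataFrame
    n_participants: int

    @property
    def log_likelihood(self) -> float:
        return -0.5 * self.reml_criterion


@dataclass
class VarianceDecomposition:
    sigma2_between: float
    sigma2_within: float

    @property
    def between_share(self) -> float:
        return self.sigma2_between / (self.sigma2_between + self.sigma2_within)

    @property
    def within_share(self) -> float:
        return 1.0 - self.between_share


def prepare_model_frame(rates: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Model frame: log1p response, categorical covariates, ≥2-obs participants."""
    df = rates.copy()
    df = df[df["age_group"].notna() & (df["age_group"] != "unknown")]
    df = df[df["sex"].isin(["male", "female"])]
    if spec.response == "D":
        df = df[df["D"].notna()]
    df["y"] = np.log1p(df[spec.response].astype(float))
    df["loc_cat"] = location_category(df["L"])
    df["household_size_cat"] = np.where(
        df["household_size"] >= 5, "5+", df["household_size"].astype(int).astype(str)
    )
    n_obs = df.groupby("participant_id")["y"].transform("size")
    df = df[n_obs >= spec.min_observations]
    return df.reset_index(drop=True)


def _check_full_rank(formula: str, df: pd.DataFrame) -> None:
    import patsy

    X = patsy.dmatrix(formula.split("~", 1)[1], df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, _, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
        aliased = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _profiled_neg2_reml(
    gamma: float,
    ng: np.ndarray,
    Xg: np.ndarray,
    yg: np.ndarray,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    p: int,
) -> tuple[float, np.ndarray, float]:
    """Exact −2·REML criterion profiled over β and σ²_w at variance ratio γ.

    γ = σ²_b/σ²_w.  With a single random intercept, V = σ²_w(I + γZZᵀ) is
    block diagonal and Woodbury reduces every quantity to per-group sums:
    V*⁻¹ within a group of size m is I − γ/(1+γm)·J.
    """
    w = gamma / (1.0 + gamma * ng)
    XtVX = XtX - (Xg * w[:, None]).T @ Xg
    XtVy = Xty - Xg.T @ (w * yg)
    yVy = yty - float(np.sum(w * yg**2))
    c, low = cho_factor(XtVX)
    beta = cho_solve((c, low), XtVy)
    rss = yVy - float(XtVy @ beta)
    sigma2_w = rss / (n - p)
    logdet_v = float(np.sum(np.log1p(gamma * ng)))
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(c))))
    crit = (n - p) * np.log(sigma2_w) + logdet_v + logdet_xvx
    return crit, beta, sigma2_w


def fit_random_intercept(rates: pd.DataFrame, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the Gaussian random-intercept model by REML.

    The REML criterion is profiled analytically over the fixed effects and
    the residual variance, leaving a one-dimensional optimization over the
    variance ratio γ = σ²_b/σ²_w (solved by Brent to high precision, with
    the γ = 0 boundary checked explicitly).  In the balanced case the
    estimate coincides with the closed-form one-way ANOVA components.
    Deterministic given the data; raises if fewer than two participants
    remain or the fixed-effect design is rank deficient (aliased columns
    are named in the error).
    """
    import patsy

    spec = spec or ModelSpec()
    df = prepare_model_frame(rates, spec)
    if df["participant_id"].nunique() < 2:
        raise ValueError("need ≥2 participants with enough observations")
    _check_full_rank(spec.formula, df)

    X = patsy.dmatrix(spec.formula.split("~", 1)[1], df, return_type="dataframe")
    design_info = X.design_info
    y = df["y"].to_numpy(dtype=float)
    Xm = X.to_numpy(dtype=float)
    codes, _ = pd.factorize(df["participant_id"])
    n, p = Xm.shape
    n_groups = codes.max() + 1
    ng = np.bincount(codes).astype(float)
    Xg = np.zeros((n_groups, p))
    np.add.at(Xg, codes, Xm)
    yg = np.bincount(codes, weights=y)
    XtX, Xty, yty = Xm.T @ Xm, Xm.T @ y, float(y @ y)
    args = (ng, Xg, yg, XtX, Xty, yty, n, p)

    obj = lambda t: _profiled_neg2_reml(np.exp(t), *args)[0]
    res = minimize_scalar(obj, bounds=(-30.0, 8.0), method="bounded",
                          options={"xatol": 1e-12})
    gamma = float(np.exp(res.x))
    crit, beta, sigma2_w = _profiled_neg2_reml(gamma, *args)
    crit0, beta0, sigma2_w0 = _profiled_neg2_reml(0.0, *args)
    if crit0 <= crit:  # boundary solution: no between-participant variance
        gamma, crit, beta, sigma2_w = 0.0, crit0, beta0, sigma2_w0
    return FittedModel(
        spec=spec,
        fixed_effects=pd.Series(beta, index=design_info.column_names),
        sigma2_between=gamma * sigma2_w,
        sigma2_within=sigma2_w,
        reml_criterion=float(crit),
        design_info=design_info,
        data=df,
        n_participants=int(n_groups),
    )


def variance_shares(fitted: FittedModel) -> VarianceDecomposition:
    """Between/within variance components of the fitted random-intercept model."""
    return VarianceDecomposition(
        sigma2_between=max(fitted.sigma2_between, 0.0), sigma2_within=fitted.sigma2_within
    )


def _linear_predictor(fitted: FittedModel, profile: dict) -> float:
    import patsy

    row = pd.DataFrame([profile])
    (X,) = patsy.build_design_matrices([fitted.design_info], row)
    return float((np.asarray(X) @ fitted.fixed_effects.to_numpy()).item())


def percentage_contribution(
    fitted: FittedModel, profile: dict, comparator: dict | None = None
) -> float:
    """Predicted rate for ``profile`` as a percentage of the comparator's.

    Predictions are back-transformed to the response scale (exp(·)−1) with
    the random intercept at zero.  Profile dicts must cover every fixed
    effect in the model; unspecified keys default to the comparator value.
    """
    comparator = dict(DEFAULT_COMPARATOR, **(comparator or {}))
    full_profile = dict(comparator, **profile)
    pred = np.expm1(_linear_predictor(fitted, full_profile))
    base = np.expm1(_linear_predictor(fitted, comparator))
    if base <= 0:
        raise ValueError("comparator prediction is non-positive on the response scale")
    return float(100.0 * pred / base)


def contribution_table(fitted: FittedModel, comparator: dict | None = None) -> pd.DataFrame:
    """Percentage contributions for every level of every fitted covariate."""
    comparator = dict(DEFAULT_COMPARATOR, **(comparator or {}))
    covariates = {
        "age_group": sorted(fitted.data["age_group"].unique()),
        "sex": ["male", "female"],
        "weekday": ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"],
        "wave": sorted(fitted.data["wave"].unique()),
    }
    if fitted.spec.include_location:
        covariates["loc_cat"] = [
            c for c in LOCATION_CATEGORIES if c in set(fitted.data["loc_cat"])
        ]
    if fitted.spec.include_household_size:
        covariates["household_size_cat"] = sorted(fitted.data["household_size_cat"].unique())
    rows = []
    for cov, levels in covariates.items():
        for level in levels:
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "percent_of_comparator": percentage_contribution(
                        fitted, {cov: level}, comparator
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation-null analyses over complete-panel participants


def complete_wave_matrix(
    rates: pd.DataFrame, variable: str, waves: list[str] | None = None
) -> pd.DataFrame:
    """Wide participants × waves matrix restricted to complete participants."""
    waves = waves or [w for w in WAVES if w in set(rates["wave"])]
    wide = rates.pivot_table(index="participant_id", columns="wave", values=variable)
    wide = wide.reindex(columns=waves).dropna()
    return wide


def _cv(values: np.ndarray, axis: int = 0) -> np.ndarray:
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mean > 0, sd / mean, 0.0)


def _permute_within_waves(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each wave's column across participants."""
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = values[rng.permutation(values.shape[0]), j]
    return out


@dataclass
class AccumulationResult:
    horizons: np.ndarray
    observed_cv: np.ndarray
    null_mean: np.ndarray
    null_low: np.ndarray  # 2.5th percentile
    null_high: np.ndarray  # 97.5th percentile
    n_participants: int
    null_reps: int


def accumulation_analysis(
    rates: pd.DataFrame,
    variable: str = "K",
    null_reps: int = 500,
    seed: int = 0,
    waves: list[str] | None = None,
) -> AccumulationResult:
    """Between-participant CV of cumulative rates versus the permutation null.

    Observed: cumulative sums of the rate over waves 1..W for participants
    observed in every wave; CV across participants at each horizon.  The
    null permutes each wave's observations across participants before
    accumulating, so any excess of the observed CV over the null envelope
    reflects within-participant dependence (consistently high or low
    reporters), i.e. slower saturation of contact neighbourhoods.
    """
    wide = complete_wave_matrix(rates, variable, waves)
    if len(wide) < 2:
        raise ValueError("need ≥2 participants observed in all waves")
    values = wide.to_numpy(dtype=float)
    observed = _cv(np.cumsum(values, axis=1))
    rng = np.random.default_rng(seed)
    null = np.empty((null_reps, values.shape[1]))
    for r in range(null_reps):
        null[r] = _cv(np.cumsum(_permute_within_waves(values, rng), axis=1))
    return AccumulationResult(
        horizons=np.arange(1, values.shape[1] + 1),
        observed_cv=observed,
        null_mean=null.mean(axis=0),
        null_low=np.percentile(null, 2.5, axis=0),
        null_high=np.percentile(null, 97.5, axis=0),
        n_participants=len(wide),
        null_reps=null_reps,
    )


def _quantile_membership(values: np.ndarray, q: int, rng: np.random.Generator) -> np.ndarray:
    """Equal-count quantile index per participant; ties broken at random."""
    n = len(values)
    order = np.lexsort((rng.random(n), values))
    member = np.empty(n, dtype=int)
    member[order] = (np.arange(n) * q) // n
    return member


def _consistency(values: np.ndarray, q: int, rng: np.random.Generator) -> float:
    members = np.column_stack(
        [_quantile_membership(values[:, j], q, rng) for j in range(values.shape[1])]
    )
    return float(np.mean(np.all(members == members[:, [0]], axis=1)) * 100.0)


@dataclass
class QuantileConsistencyResult:
    quantiles: np.ndarray
    observed_percent: np.ndarray
    null_mean: np.ndarray
    null_low: np.ndarray
    null_high: np.ndarray
    independence_percent: np.ndarray  # closed form 100·(1/q)^(W−1)
    n_participants: int
    null_reps: int


def quantile_consistency(
    rates: pd.DataFrame,
    variable: str = "K",
    quantile_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 8, 10),
    null_reps: int = 500,
    seed: int = 0,
    waves: list[str] | None = None,
) -> QuantileConsistencyResult:
    """Percentage of participants keeping the same within-wave quantile
    across all waves, against the permutation null.

    Quantile membership is computed within each wave by equal-count
    ranking, ties broken at random (seeded); a participant is consistent
    if their membership is identical across every wave.  With one quantile
    everyone is trivially consistent; for independent waves the null tends
    to 100·(1/q)^(W−1).
    """
    wide = complete_wave_matrix(rates, variable, waves)
    if len(wide) < 2:
        raise ValueError("need ≥2 participants observed in all waves")
    values = wide.to_numpy(dtype=float)
    W = values.shape[1]
    rng = np.random.default_rng(seed)
    observed = np.array([_consistency(values, q, rng) for q in quantile_grid])
    null = np.empty((null_reps, len(quantile_grid)))
    for r in range(null_reps):
        perm = _permute_within_waves(values, rng)
        null[r] = [_consistency(perm, q, rng) for q in quantile_grid]
    return QuantileConsistencyResult(
        quantiles=np.asarray(quantile_grid),
        observed_percent=observed,
        null_mean=null.mean(axis=0),
        null_low=np.percentile(null, 2.5, axis=0),
        null_high=np.percentile(null, 97.5, axis=0),
        independence_percent=100.0 * (1.0 / np.asarray(quantile_grid, dtype=float)) ** (W - 1),
        n_participants=len(wide),
        null_reps=null_reps,
    )
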
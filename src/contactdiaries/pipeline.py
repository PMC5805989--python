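"""End-to-end pipeline: panel → rates → durations → summaries → mixing → models.

Every stage is a pure function of (inputs, config, seed); the run manifest
records the seeds, the configuration hash and package version so a run can
be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .duration import (
    DurationCategories,
    fill_rate_durations,
    fit_censored_exponential,
    impute_durations,
)
from .io_model import WAVES, DiaryPanel, derive_rates, read_census, read_diary_panel, write_rate_table
from .longitudinal import (
    ModelSpec,
    accumulation_analysis,
    contribution_table,
    fit_random_intercept,
    quantile_consistency,
    variance_shares,
)
from .mixing import bootstrap_ci, contact_rate_matrix, ngm_growth_rank
from .summaries import (
    between_wave_correlation,
    mean_of_participant_means,
    typical_day_filter,
    wave_homogeneity_test,
)
from .synthetic import SyntheticConfig, census_series, generate

log = logging.getLogger("contactdiaries")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    If ``input_dir`` is None a synthetic panel is generated from
    ``synthetic``; otherwise the four CSVs are read from ``input_dir`` and
    ``census_path`` must point at a census table.
    """

    input_dir: str | None = None
    census_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    duration_boundaries: tuple[float, ...] | None = None
    n_boot: int = 1000
    n_imputation_replicates: int = 200
    null_reps: int = 500
    responses: tuple[str, ...] = ("K", "D", "L")
    typical_only: bool = False
    seed: int = 0
    out_dir: str | None = None

    def categories(self) -> DurationCategories:
        if self.duration_boundaries is None:
            return DurationCategories()
        return DurationCategories(tuple(self.duration_boundaries))


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_inputs(config: PipelineConfig) -> tuple[DiaryPanel, pd.Series]:
    if config.input_dir is None:
        panel = generate(config.synthetic, seed=config.seed)
        census = census_series(config.synthetic)
    else:
        panel = read_diary_panel(config.input_dir)
        if config.census_path is None:
            raise FileNotFoundError(
                "mixing stage requires a census input: set census_path (census.csv)"
            )
        census = read_census(config.census_path)
    return panel, census


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return (and optionally write) the output bundle."""
    t0 = time.time()
    outputs: dict = {}
    stage = "load"
    try:
        panel, census = load_inputs(config)
        cats = config.categories()

        stage = "rates"
        rates = derive_rates(panel)

        stage = "duration"
        known = panel.events["duration_category"].dropna().astype(int)
        counts = np.bincount(known, minlength=cats.n_categories)[: cats.n_categories]
        model = fit_censored_exponential(counts, cats)
        imputations = impute_durations(
            panel, model, n_replicates=config.n_imputation_replicates, seed=config.seed
        )
        rates = fill_rate_durations(rates, imputations)
        outputs["duration_model"] = {
            "rate_per_minute": model.rate_per_minute,
            "mean_minutes": model.mean_minutes,
            "log_likelihood": model.log_likelihood,
            "n_iterations": model.n_iterations,
            "converged": model.converged,
            "boundaries": list(cats.boundaries),
        }
        outputs["rates"] = rates

        analysis_rates = rates
        if config.typical_only:
            analysis_rates, _ = typical_day_filter(rates)

        stage = "summaries"
        _, typical_prop = typical_day_filter(rates)
        waves = [w for w in WAVES if w in set(rates["wave"])]
        summaries: dict = {
            "mean_of_participant_means": {
                v: mean_of_participant_means(analysis_rates, v) for v in ("K", "D", "L")
            },
            "typical_day_proportion": typical_prop,
            "wave_homogeneity": {},
            "between_wave_correlation": {},
        }
        for v in ("K", "D", "L"):
            res = wave_homogeneity_test(analysis_rates, v)
            summaries["wave_homogeneity"][v] = {
                "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
                "bin_edges": res.bin_edges,
            }
            summaries["between_wave_correlation"][v] = {
                f"{a}-{b}": asdict(between_wave_correlation(analysis_rates, v, (a, b)))
                for i, a in enumerate(waves)
                for b in waves[i + 1:]
            }
        outputs["summaries"] = summaries

        stage = "mixing"
        matrices = {
            w: bootstrap_ci(panel, census, w, n_boot=config.n_boot, seed=config.seed)
            for w in waves
        }
        outputs["mixing"] = matrices
        outputs["mixing_table"] = pd.concat([m.to_frame() for m in matrices.values()])
        rate_matrices = {w: contact_rate_matrix(panel, w) for w in waves}
        outputs["ngm_ranking"] = ngm_growth_rank(rate_matrices)

        stage = "longitudinal"
        decomp, contribs = {}, {}
        for response in config.responses:
            fitted = fit_random_intercept(analysis_rates, ModelSpec(response=response))
            vd = variance_shares(fitted)
            decomp[response] = {
                "sigma2_between": vd.sigma2_between,
                "sigma2_within": vd.sigma2_within,
                "between_share": vd.between_share,
                "within_share": vd.within_share,
            }
            contribs[response] = contribution_table(fitted).assign(response=response)
        outputs["variance_decomposition"] = decomp
        outputs["contributions"] = pd.concat(contribs.values(), ignore_index=True)

        stage = "accumulation"
        acc = accumulation_analysis(
            analysis_rates, "K", null_reps=config.null_reps, seed=config.seed
        )
        outputs["accumulation"] = acc
        stage = "quantile_consistency"
        qc = quantile_consistency(
            analysis_rates, "K", null_reps=config.null_reps, seed=config.seed
        )
        outputs["quantile_consistency"] = qc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    outputs["manifest"] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "elapsed_seconds": round(time.time() - t0, 2),
        "n_participants": int(panel.participants.shape[0]),
        "n_diaries": int(panel.diaries.shape[0]),
        "n_events": int(panel.events.shape[0]),
    }
    if config.out_dir is not None:
        _write_outputs(outputs, Path(config.out_dir))
    return outputs


def _write_outputs(outputs: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_rate_table(outputs["rates"], out_dir / "rates.csv")
    outputs["mixing_table"].to_csv(out_dir / "mixing.csv", index=False)
    outputs["contributions"].to_csv(out_dir / "contributions.csv", index=False)
    outputs["ngm_ranking"].to_csv(out_dir / "ngm_ranking.csv", index=False)
    acc, qc = outputs["accumulation"], outputs["quantile_consistency"]
    blobs = {
        "summaries.json": outputs["summaries"],
        "duration_model.json": outputs["duration_model"],
        "variance.json": outputs["variance_decomposition"],
        "accumulation.json": {
            "horizons": acc.horizons, "observed_cv": acc.observed_cv,
            "null_mean": acc.null_mean, "null_low": acc.null_low, "null_high": acc.null_high,
            "n_participants": acc.n_participants, "null_reps": acc.null_reps,
        },
        "quantile_consistency.json": {
            "quantiles": qc.quantiles, "observed_percent": qc.observed_percent,
            "null_mean": qc.null_mean, "null_low": qc.null_low, "null_high": qc.null_high,
            "independence_percent": qc.independence_percent,
            "n_participants": qc.n_participants, "null_reps": qc.null_reps,
        },
        "manifest.json": outputs["manifest"],
    }
    for name, blob in blobs.items():
        with open(out_dir / name, "w") as fh:
            json.dump(_jsonable(blob), fh, indent=2)
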
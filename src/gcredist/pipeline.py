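"""End-to-end orchestration: map -> stratify -> fit -> redistribute -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cause_map import CauseMap, default_cause_map, load_cause_map
from .model import FitResult, PriorConfig, fit_map, fit_mcmc, format_rrr_table, rrr_table
from .records import DeathRecord, categorize, read_records
from .redistribute import (
    RedistributionResult,
    StratumPrediction,
    counts_by_category,
    fallback_prediction,
    predict_probs,
    redistribute_hard,
    redistribute_proportional,
)
from .strata import DEFAULT_MIN_TRAINING, build_stratum_dataset, fallback_shares, occupied_strata
from .taxonomy import TargetMatrix, default_target_matrix, load_target_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    records_path: str | None = None
    cause_map_path: str | None = None     # None -> shipped default block maps
    target_matrix_path: str | None = None
    output_dir: str = "run"
    engine: str = "map"                   # "map" or "mcmc"
    method: str = "proportional"          # or "hard"
    seed: int = 0
    strict: bool = True
    min_training: int = DEFAULT_MIN_TRAINING
    mcmc_chains: int = 2
    mcmc_warmup: int = 500
    mcmc_samples: int = 500
    garbage_filter: tuple[str, ...] = ()  # restrict to these garbage categories

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineOutput:
    result: RedistributionResult
    fits: dict[str, FitResult] = field(default_factory=dict)
    stratum_summaries: list[dict] = field(default_factory=list)


def run_pipeline_on_records(
    records: list[DeathRecord],
    cfg: RunConfig,
    cause_maps: dict[int, CauseMap] | None = None,
    tm: TargetMatrix | None = None,
    prior: PriorConfig | None = None,
) -> PipelineOutput:
    """Run the full method on in-memory records; no file I/O."""
    cause_maps = cause_maps or {9: default_cause_map(9), 10: default_cause_map(10)}
    tm = tm or default_target_matrix()
    prior = prior or PriorConfig()

    categorized = [
        categorize(r, cause_maps[r.revision], strict=cfg.strict) for r in records
    ]
    counts_before = counts_by_category(categorized)
    strata = occupied_strata(categorized)
    if cfg.garbage_filter:
        strata = [s for s in strata if s.garbage in cfg.garbage_filter]

    predictions: list[StratumPrediction] = []
    fits: dict[str, FitResult] = {}
    summaries: list[dict] = []
    for stratum in strata:
        ds = build_stratum_dataset(
            categorized, stratum, tm, min_training=cfg.min_training
        )
        summary = {
            "stratum": stratum.key,
            "n_train": ds.n_train,
            "n_pred": ds.n_pred,
            "n_targets": ds.n_targets,
            "dropped_targets": list(ds.dropped_targets),
            "fittable": ds.fittable,
        }
        if ds.n_pred == 0:
            summaries.append(summary)
            continue
        if ds.fittable:
            if cfg.engine == "mcmc":
                fit = fit_mcmc(
                    ds, prior, chains=cfg.mcmc_chains, warmup=cfg.mcmc_warmup,
                    samples=cfg.mcmc_samples, seed=cfg.seed,
                )
            else:
                fit = fit_map(ds, prior, seed=cfg.seed)
            fits[stratum.key] = fit
            predictions.append(predict_probs(fit, ds))
            summary["engine"] = cfg.engine
        else:
            targets, shares = fallback_shares(categorized, stratum, tm)
            predictions.append(
                fallback_prediction(stratum, ds.pred_ids, targets, shares)
            )
            summary["engine"] = "fallback"
            summary["fallback_reason"] = ds.unfittable_reason
            logger.warning(
                "stratum %s unfittable (%s); using pooled empirical shares",
                stratum.key, ds.unfittable_reason,
            )
        summaries.append(summary)
        logger.info(
            "stratum %s: n_train=%d n_pred=%d U=%d dropped=%s",
            stratum.key, ds.n_train, ds.n_pred, ds.n_targets, ds.dropped_targets,
        )

    redistributor = (
        redistribute_hard if cfg.method == "hard" else redistribute_proportional
    )
    result = redistributor(predictions, counts_before)
    return PipelineOutput(result=result, fits=fits, stratum_summaries=summaries)


def run_pipeline(cfg: RunConfig) -> Path:
    """File-based pipeline: read inputs, run, write artifacts + manifest.

    Returns the output directory.  Idempotent given identical inputs and
    seed (the MAP engine is fully deterministic).
    """
    if cfg.records_path is None or not Path(cfg.records_path).exists():
        raise FileNotFoundError(f"records file not found: {cfg.records_path}")
    if cfg.cause_map_path is not None and not Path(cfg.cause_map_path).exists():
        raise FileNotFoundError(f"cause-map file not found: {cfg.cause_map_path}")
    if cfg.target_matrix_path is not None and not Path(cfg.target_matrix_path).exists():
        raise FileNotFoundError(f"target-matrix file not found: {cfg.target_matrix_path}")

    if cfg.cause_map_path:
        cause_maps = {
            9: load_cause_map(cfg.cause_map_path, 9),
            10: load_cause_map(cfg.cause_map_path, 10),
        }
    else:
        cause_maps = None
    tm = load_target_matrix(cfg.target_matrix_path) if cfg.target_matrix_path else None

    records, rejects = read_records(cfg.records_path)
    out = run_pipeline_on_records(records, cfg, cause_maps=cause_maps, tm=tm)

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _write_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        artifacts[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]

    res = out.result
    _write_csv("per_death_probs.csv", res.per_death)
    _write_csv("flows.csv", res.flows)
    from .redistribute import flow_table

    _write_csv("flow_table.csv", flow_table(res))
    ledger_df = pd.DataFrame(
        {
            "category": res.counts_before.index,
            "before": res.counts_before.values,
            "after": res.counts_after.reindex(res.counts_before.index).values,
        }
    )
    _write_csv("conservation_ledger.csv", ledger_df)
    for key, fit in out.fits.items():
        fit.save(outdir / f"fit_{key}.json")
        artifacts[f"fit_{key}.json"] = hashlib.sha256(
            (outdir / f"fit_{key}.json").read_bytes()
        ).hexdigest()[:16]
        formatted = format_rrr_table(rrr_table(fit))
        rrr_path = outdir / f"rrr_{key}.csv"
        formatted.to_csv(rrr_path)
        artifacts[f"rrr_{key}.csv"] = hashlib.sha256(rrr_path.read_bytes()).hexdigest()[:16]

    manifest = {
        "tool_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "engine": cfg.engine,
        "method": cfg.method,
        "n_records": len(records),
        "n_rejected_rows": len(rejects),
        "ledger": res.ledger,
        "strata": out.stratum_summaries,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return outdir
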
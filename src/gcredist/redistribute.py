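"""Redistribution of garbage-coded deaths onto target causes.

Fitted stratum models give each garbage-coded death a probability vector
over its target causes.  Deaths are then either attributed *proportionally*
(each death contributes its probability vector as fractional counts — the
population-level convention) or *hard*-assigned to the highest-probability
target.  Every run carries a conservation ledger: total deaths are invariant
and garbage categories end with exactly zero deaths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .causes import CAUSE_IDS, CauseList, DEFAULT_CAUSE_LIST, garbage_id, is_garbage
from .model import FitResult, class_probabilities, linear_predictor
from .records import CategorizedRecord
from .strata import Stratum, StratumDataset

logger = logging.getLogger(__name__)

PROB_SUM_TOL = 1e-9
MAX_MCMC_PREDICT_DRAWS = 200


@dataclass
class StratumPrediction:
    """Per-death target probabilities for one stratum's garbage deaths."""

    stratum: Stratum
    ids: tuple[str, ...]
    targets: tuple[str, ...]       # surviving targets (order = canonical)
    dropped_targets: tuple[str, ...]
    probs: np.ndarray              # (n_pred, len(targets)), rows sum to 1
    source: str = "model"          # "model" or "fallback"


@dataclass
class RedistributionResult:
    method: str                    # "proportional" or "hard"
    per_death: pd.DataFrame        # id, garbage, target, prob (long)
    flows: pd.DataFrame            # revision, sex, age_group, garbage, target, deaths
    counts_before: pd.Series       # deaths per category (valid + garbage)
    counts_after: pd.Series        # deaths per category; garbage rows exactly 0
    ledger: dict


def predict_probs(fit: FitResult, ds: StratumDataset) -> StratumPrediction:
    """Apply a fitted model to a stratum's prediction set.

    For MCMC fits the probability is the posterior mean of the per-draw
    softmax (a proper posterior predictive), not the softmax at the
    posterior-mean parameters; draws are thinned to at most
    ``MAX_MCMC_PREDICT_DRAWS``.
    """
    if fit.stratum_key != ds.stratum.key:
        raise ValueError(
            f"fit is for stratum {fit.stratum_key}, dataset is {ds.stratum.key}"
        )
    if fit.targets != ds.targets:
        raise ValueError("fit and dataset disagree on surviving targets")
    features = (ds.pred_year, ds.pred_M, ds.pred_state_idx,
                ds.pred_place_idx, ds.pred_race_idx)
    if fit.mode == "MCMC" and fit.draws:
        step = max(len(fit.draws) // MAX_MCMC_PREDICT_DRAWS, 1)
        draws = fit.draws[::step]
        probs = np.mean(
            [class_probabilities(linear_predictor(p, *features)) for p in draws],
            axis=0,
        )
    else:
        probs = class_probabilities(linear_predictor(fit.params, *features))
    return StratumPrediction(
        stratum=ds.stratum,
        ids=ds.pred_ids,
        targets=ds.targets,
        dropped_targets=ds.dropped_targets,
        probs=probs,
        source="model",
    )


def counts_by_category(
    records: list[CategorizedRecord], cause_list: CauseList = DEFAULT_CAUSE_LIST
) -> pd.Series:
    """Deaths per underlying category (valid causes first, then garbage)."""
    counts: dict[str, float] = {c: 0.0 for c in cause_list.causes}
    for cr in records:
        counts[cr.underlying_cat] = counts.get(cr.underlying_cat, 0.0) + 1.0
    return pd.Series(counts, dtype=float)


def _check_rows_sum(probs: np.ndarray, stratum_key: str) -> None:
    sums = probs.sum(axis=1)
    if len(sums) and np.max(np.abs(sums - 1.0)) > PROB_SUM_TOL:
        raise ValueError(
            f"probability rows do not sum to 1 in stratum {stratum_key} "
            f"(max deviation {np.max(np.abs(sums - 1.0)):.2e})"
        )


def _assemble(
    predictions: list[StratumPrediction],
    counts_before: pd.Series,
    weights_fn,
    method: str,
) -> RedistributionResult:
    per_death_rows = []
    flow_rows = []
    for pred in predictions:
        unknown = [t for t in pred.targets if t not in CAUSE_IDS]
        if unknown:
            raise ValueError(f"targets outside the cause list: {unknown}")
        _check_rows_sum(pred.probs, pred.stratum.key)
        w = weights_fn(pred)  # (n, T), rows sum to 1
        s = pred.stratum
        for j, target in enumerate(pred.targets):
            flow_rows.append(
                (s.revision, s.sex, s.age_group, s.garbage, target, float(w[:, j].sum()))
            )
        for i, rid in enumerate(pred.ids):
            for j, target in enumerate(pred.targets):
                per_death_rows.append((rid, s.garbage, target, float(pred.probs[i, j])))

    per_death = pd.DataFrame(
        per_death_rows, columns=["id", "garbage", "target", "prob"]
    )
    flows = pd.DataFrame(
        flow_rows,
        columns=["revision", "sex", "age_group", "garbage", "target", "deaths"],
    )

    counts_after = counts_before.astype(float).copy()
    for garbage, sub in flows.groupby("garbage"):
        gid = garbage_id(garbage)
        if gid not in counts_after.index:
            raise ValueError(f"counts_before lacks garbage category {gid}")
        redistributed = float(sub["deaths"].sum())
        available = float(counts_after[gid])
        if redistributed - available > 1e-6:
            raise ValueError(
                f"{garbage}: redistributing {redistributed} deaths but only "
                f"{available} present before redistribution"
            )
    incoming = flows.groupby("target")["deaths"].sum()
    # garbage deaths with predictions move out of their category entirely
    n_by_garbage = flows.groupby("garbage")["deaths"].sum()
    for garbage, moved in n_by_garbage.items():
        counts_after[garbage_id(garbage)] -= moved
    for target, gained in incoming.items():
        counts_after[target] += gained

    garbage_rows = [c for c in counts_after.index if is_garbage(c)]
    residual_garbage = float(counts_after[garbage_rows].abs().sum()) if garbage_rows else 0.0
    ledger = {
        "total_before": float(counts_before.sum()),
        "total_after": float(counts_after.sum()),
        "residual": float(counts_after.sum() - counts_before.sum()),
        "garbage_remaining": residual_garbage,
        "n_redistributed": float(n_by_garbage.sum()) if len(n_by_garbage) else 0.0,
    }
    if abs(ledger["residual"]) > 1e-6:
        raise AssertionError(f"conservation violated: {ledger}")
    if residual_garbage > 1e-6:
        raise AssertionError(
            f"garbage deaths remain after redistribution: "
            f"{counts_after[garbage_rows][counts_after[garbage_rows] != 0]}"
        )
    counts_after[garbage_rows] = 0.0  # clear float dust below tolerance
    return RedistributionResult(
        method=method,
        per_death=per_death,
        flows=flows,
        counts_before=counts_before,
        counts_after=counts_after,
        ledger=ledger,
    )


def redistribute_proportional(
    predictions: list[StratumPrediction], counts_before: pd.Series
) -> RedistributionResult:
    """Attribute each garbage death fractionally by its probability vector."""
    return _assemble(predictions, counts_before, lambda p: p.probs, "proportional")


def redistribute_hard(
    predictions: list[StratumPrediction],
    counts_before: pd.Series,
    tie_rule: str = "lowest_index",
) -> RedistributionResult:
    """Assign each garbage death wholly to its highest-probability target.

    Ties are broken toward the lower canonical cause index (targets are in
    canonical order, so argmax's first-maximum convention implements this);
    ties are counted and logged.
    """
    if tie_rule != "lowest_index":
        raise ValueError(f"unknown tie rule {tie_rule!r}")

    def hard_weights(pred: StratumPrediction) -> np.ndarray:
        probs = pred.probs
        w = np.zeros_like(probs)
        if probs.size:
            best = probs.argmax(axis=1)
            ties = int(((probs == probs.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
            if ties:
                logger.info(
                    "%s: %d tied argmax assignments broken to lowest canonical index",
                    pred.stratum.key, ties,
                )
            w[np.arange(len(best)), best] = 1.0
        return w

    return _assemble(predictions, counts_before, hard_weights, "hard")


def flow_table(result: RedistributionResult, by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Aggregate flows at a requested grouping.

    Returns columns ``by + (garbage, target, deaths, share_of_garbage,
    share_of_all_garbage)``; shares sum to 1 within each garbage category at
    the grouping level, and across all garbage deaths respectively.
    """
    valid_by = {"revision", "sex", "age_group"}
    bad = set(by) - valid_by
    if bad:
        raise ValueError(f"cannot group flows by {sorted(bad)}; options: {sorted(valid_by)}")
    keys = list(by) + ["garbage", "target"]
    agg = result.flows.groupby(keys, as_index=False)["deaths"].sum()
    gkeys = list(by) + ["garbage"]
    per_garbage = agg.groupby(gkeys)["deaths"].transform("sum")
    all_garbage = agg.groupby(list(by))["deaths"].transform("sum") if by else agg["deaths"].sum()
    agg["share_of_garbage"] = agg["deaths"] / per_garbage
    agg["share_of_all_garbage"] = agg["deaths"] / all_garbage
    return agg


def fallback_prediction(
    stratum: Stratum,
    ids: tuple[str, ...],
    targets: tuple[str, ...],
    shares: np.ndarray,
) -> StratumPrediction:
    """Uniform-shares prediction for strata too small to fit a model.

    Every death gets the pooled empirical target proportions; flagged with
    ``source='fallback'`` so reports can distinguish it from model output.
    """
    probs = np.tile(np.asarray(shares, dtype=float), (len(ids), 1))
    return StratumPrediction(
        stratum=stratum, ids=ids, targets=targets, dropped_targets=(),
        probs=probs, source="fallback",
    )


def integerize_counts(counts: pd.Series) -> pd.Series:
    """Largest-remainder rounding preserving the (rounded) grand total."""
    total = int(round(counts.sum()))
    floors = np.floor(counts.values)
    remainder = int(total - floors.sum())
    order = np.argsort(-(counts.values - floors))
    out = floors.copy()
    out[order[:remainder]] += 1
    return pd.Series(out.astype(int), index=counts.index)
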
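"""Stratification and per-stratum training/prediction dataset construction.

Each (ICD revision, sex, age group, garbage category) cell gets its own
model.  Within a cell:

* the *training* set holds certificates that list the garbage code as a
  contributing cause on lines 1-5 but carry a valid underlying cause that is
  one of the garbage code's targets — the outcome is which target was chosen;
* the *prediction* set holds certificates whose underlying cause IS the
  garbage code, to be redistributed.

Age groups follow the vital-statistics convention: under 1, 1-4, then
5-year bins to 85+ (19 bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .causes import CauseList, DEFAULT_CAUSE_LIST, REVISION_ERAS, garbage_id
from .records import CategorizedRecord
from .taxonomy import DEFAULT_TAXONOMY, GarbageTaxonomy, TargetMatrix

#: Lower edges of the 19 age bins; labels derived below.
_AGE_EDGES = [0, 1] + list(range(5, 90, 5))
AGE_GROUPS: tuple[str, ...] = tuple(
    ["<1", "1-4"] + [f"{lo}-{lo + 4}" for lo in range(5, 85, 5)] + ["85+"]
)
assert len(AGE_GROUPS) == 19

DEFAULT_MIN_TRAINING = 50


def age_group(age: int) -> str:
    """Map an age in years to its bin label (closed-open bins, 85+ open-ended)."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    if age < 1:
        return "<1"
    if age < 5:
        return "1-4"
    if age >= 85:
        return "85+"
    lo = (age // 5) * 5
    return f"{lo}-{lo + 4}"


@dataclass(frozen=True)
class Stratum:
    revision: int
    sex: str
    age_group: str
    garbage: str  # garbage name without the ``garbage:`` prefix

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        DEFAULT_TAXONOMY.check_revision(self.garbage, self.revision)

    @property
    def key(self) -> str:
        return f"icd{self.revision}_{self.sex}_{self.age_group}_{self.garbage}"


@dataclass
class StratumDataset:
    """Training and prediction examples for one stratum.

    Features per example: centred year (in decades from the era midpoint),
    the 25-cause indicator vector M, and integer level indices for state,
    place and race.  Targets with zero training deaths are dropped before
    outcome indexing; ``targets[0]`` is the reference category.
    """

    stratum: Stratum
    targets: tuple[str, ...]
    dropped_targets: tuple[str, ...]
    state_levels: tuple[str, ...]
    place_levels: tuple[str, ...]
    race_levels: tuple[str, ...]
    # training arrays
    y: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    year: np.ndarray = field(default_factory=lambda: np.zeros(0))
    M: np.ndarray = field(default_factory=lambda: np.zeros((0, 25), dtype=np.int8))
    state_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    place_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    race_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    # prediction arrays
    pred_ids: tuple[str, ...] = ()
    pred_year: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pred_M: np.ndarray = field(default_factory=lambda: np.zeros((0, 25), dtype=np.int8))
    pred_state_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    pred_place_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    pred_race_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    unfittable_reason: str | None = None

    @property
    def n_train(self) -> int:
        return len(self.y)

    @property
    def n_pred(self) -> int:
        return len(self.pred_ids)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def fittable(self) -> bool:
        return self.unfittable_reason is None

    def training_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_targets)


def center_year(year: np.ndarray, revision: int) -> np.ndarray:
    """Centre calendar year at the revision era midpoint, scaled to decades."""
    lo, hi = REVISION_ERAS[revision]
    return (np.asarray(year, dtype=float) - (lo + hi) / 2.0) / 10.0


def _in_stratum(cr: CategorizedRecord, stratum: Stratum) -> bool:
    r = cr.record
    return (
        r.revision == stratum.revision
        and r.sex == stratum.sex
        and age_group(r.age) == stratum.age_group
    )


def build_stratum_dataset(
    records: list[CategorizedRecord],
    stratum: Stratum,
    tm: TargetMatrix,
    cause_list: CauseList = DEFAULT_CAUSE_LIST,
    min_training: int = DEFAULT_MIN_TRAINING,
    declared_levels: dict[str, tuple[str, ...]] | None = None,
) -> StratumDataset:
    """Assemble the training and prediction sets for one stratum.

    Level sets for state/place/race are discovered from the stratum's records
    (training union prediction) unless ``declared_levels`` pins them.
    """
    gid = garbage_id(stratum.garbage)
    all_targets = tm.targets_of(stratum.garbage)
    target_pos = {t: i for i, t in enumerate(all_targets)}

    train: list[CategorizedRecord] = []
    pred: list[CategorizedRecord] = []
    for cr in records:
        if not _in_stratum(cr, stratum):
            continue
        if cr.underlying_cat == gid:
            pred.append(cr)
        elif stratum.garbage in {g.split(":", 1)[1] for g in cr.garbage_contrib} and (
            cr.underlying_cat in target_pos
        ):
            train.append(cr)

    # drop targets never observed in training (cannot be estimated; they get
    # predicted probability 0 downstream)
    counts = np.zeros(len(all_targets), dtype=np.int64)
    for cr in train:
        counts[target_pos[cr.underlying_cat]] += 1
    surviving = tuple(t for t, c in zip(all_targets, counts) if c > 0)
    dropped = tuple(t for t, c in zip(all_targets, counts) if c == 0)
    surv_pos = {t: i for i, t in enumerate(surviving)}

    levels = declared_levels or {}
    both = train + pred

    def _levels(factor: str, getter) -> tuple[str, ...]:
        if factor in levels:
            return tuple(levels[factor])
        return tuple(sorted({getter(cr.record) for cr in both}))

    state_levels = _levels("state", lambda r: r.state)
    place_levels = _levels("place", lambda r: r.place)
    race_levels = _levels("race", lambda r: r.race)
    s_ix = {v: i for i, v in enumerate(state_levels)}
    p_ix = {v: i for i, v in enumerate(place_levels)}
    r_ix = {v: i for i, v in enumerate(race_levels)}

    def _features(crs: list[CategorizedRecord]):
        year = center_year(np.array([c.record.year for c in crs]), stratum.revision)
        M = (
            np.stack([c.indicator_vector(cause_list) for c in crs])
            if crs
            else np.zeros((0, len(cause_list)), dtype=np.int8)
        )
        sidx = np.array([s_ix[c.record.state] for c in crs], dtype=np.int64)
        pidx = np.array([p_ix[c.record.place] for c in crs], dtype=np.int64)
        ridx = np.array([r_ix[c.record.race] for c in crs], dtype=np.int64)
        return year, M, sidx, pidx, ridx

    year, M, sidx, pidx, ridx = _features(train)
    py, pM, ps, pp, pr = _features(pred)

    unfittable = None
    if len(surviving) < 2:
        unfittable = f"fewer than 2 surviving targets ({len(surviving)})"
    elif len(train) < min_training:
        unfittable = f"training size {len(train)} below threshold {min_training}"

    return StratumDataset(
        stratum=stratum,
        targets=surviving,
        dropped_targets=dropped,
        state_levels=state_levels,
        place_levels=place_levels,
        race_levels=race_levels,
        y=np.array([surv_pos[c.underlying_cat] for c in train], dtype=np.int64),
        year=year,
        M=M,
        state_idx=sidx,
        place_idx=pidx,
        race_idx=ridx,
        pred_ids=tuple(c.record.id for c in pred),
        pred_year=py,
        pred_M=pM,
        pred_state_idx=ps,
        pred_place_idx=pp,
        pred_race_idx=pr,
        unfittable_reason=unfittable,
    )


def occupied_strata(
    records: list[CategorizedRecord],
    taxonomy: GarbageTaxonomy = DEFAULT_TAXONOMY,
) -> list[Stratum]:
    """All strata in which at least one garbage-underlying death occurs."""
    seen: set[Stratum] = set()
    for cr in records:
        cat = cr.underlying_cat
        if not cat.startswith("garbage:"):
            continue
        name = cat.split(":", 1)[1]
        seen.add(
            Stratum(
                revision=cr.record.revision,
                sex=cr.record.sex,
                age_group=age_group(cr.record.age),
                garbage=name,
            )
        )
    return sorted(seen, key=lambda s: (s.revision, s.sex, AGE_GROUPS.index(s.age_group), s.garbage))


def fallback_shares(
    records: list[CategorizedRecord],
    stratum: Stratum,
    tm: TargetMatrix,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Empirical target shares for strata too small to fit.

    Fallback chain: pool adjacent age groups (±1 bin); if still empty, use
    the sex × revision margin over all ages.  Returns (targets, shares) over
    targets with nonzero pooled counts.
    """
    targets = tm.targets_of(stratum.garbage)
    pos = {t: i for i, t in enumerate(targets)}
    band = AGE_GROUPS.index(stratum.age_group)
    pools = [
        {AGE_GROUPS[j] for j in range(max(band - 1, 0), min(band + 2, 19))},
        set(AGE_GROUPS),
    ]
    for pool in pools:
        counts = np.zeros(len(targets))
        for cr in records:
            r = cr.record
            if (
                r.revision == stratum.revision
                and r.sex == stratum.sex
                and age_group(r.age) in pool
                and cr.underlying_cat in pos
                and stratum.garbage in {g.split(":", 1)[1] for g in cr.garbage_contrib}
            ):
                counts[pos[cr.underlying_cat]] += 1
        if counts.sum() > 0:
            keep = counts > 0
            kept = tuple(t for t, k in zip(targets, keep) if k)
            return kept, counts[keep] / counts.sum()
    raise ValueError(
        f"no training deaths anywhere in the fallback chain for {stratum.key}"
    )
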
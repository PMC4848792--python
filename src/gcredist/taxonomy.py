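"""Garbage-code taxonomy and target matrices.

For each garbage category the target matrix lists the valid underlying
causes that could plausibly have produced the death ("target" causes).  The
default matrix encodes the textually unambiguous rules -- heart failure may
redistribute to the eight non-communicable causes excluding cancers and the
mental/neurological group; ill-defined cancers only to cancers; wholly
ill-defined deaths to any valid cause -- and a documented best reading for
the remaining categories.  It is configuration: alternative readings are
loaded from YAML, never patched in code.

Target order is inherited from the canonical cause order; the first target
of a stratum is its multinomial reference category (diabetes, ``B.2``, for
heart failure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .causes import (
    CAUSE_IDS,
    CauseList,
    DEFAULT_CAUSE_LIST,
    GARBAGE_NAMES,
    GARBAGE_REVISIONS,
)


@dataclass(frozen=True)
class GarbageTaxonomy:
    """The nine garbage categories and the ICD revisions they occur in."""

    categories: tuple[str, ...] = GARBAGE_NAMES
    applicable_revisions: dict[str, frozenset[int]] = field(
        default_factory=lambda: dict(GARBAGE_REVISIONS)
    )

    def check_revision(self, garbage: str, revision: int) -> None:
        if garbage not in self.categories:
            raise KeyError(f"unknown garbage category {garbage!r}")
        if revision not in self.applicable_revisions[garbage]:
            raise ValueError(
                f"garbage category {garbage!r} does not occur under ICD{revision}"
            )


DEFAULT_TAXONOMY = GarbageTaxonomy()

_COMMUNICABLE = ("A.1", "A.2", "A.3", "A.4", "A.6")
_CANCERS = ("B.1.1", "B.1.2", "B.1.3", "B.1.4", "B.1.5", "B.1.6")
_NCD_NON_CANCER = ("B.2", "B.3.1", "B.3.2", "B.3.3", "B.4", "B.5", "B.6", "B.7")
_INJURIES = ("C.1.1", "C.1.2", "C.2.1", "C.2.2")

#: Default garbage -> targets configuration.  heart_failure, ill_defined_cancer
#: and ill_defined follow the stated rules exactly; the other six columns are
#: a best reading of the published check-mark layout and are editable config.
DEFAULT_TARGETS: dict[str, tuple[str, ...]] = {
    "septicemia": _COMMUNICABLE + _CANCERS + _NCD_NON_CANCER + _INJURIES,
    "heart_failure": _NCD_NON_CANCER,
    "ill_defined_cancer": _CANCERS,
    "volume_depletion": _COMMUNICABLE + _CANCERS + _NCD_NON_CANCER
    + ("C.1.2", "C.2.1", "C.2.2"),
    "ill_defined": CAUSE_IDS,
    "ill_defined_cvd": _NCD_NON_CANCER,
    "ill_defined_injury": _INJURIES,
    "undetermined_intent": _INJURIES,
    "ill_defined_infectious": _COMMUNICABLE,
}


@dataclass(frozen=True)
class TargetMatrix:
    """Per-garbage-category ordered target cause lists."""

    targets: dict[str, tuple[str, ...]]
    taxonomy: GarbageTaxonomy = DEFAULT_TAXONOMY

    def targets_of(self, garbage: str) -> tuple[str, ...]:
        if garbage not in self.targets:
            raise KeyError(f"unknown garbage category {garbage!r}")
        return self.targets[garbage]


def targets_of(garbage: str, tm: TargetMatrix) -> tuple[str, ...]:
    """Ordered target-cause list for a garbage category.

    The first element is the candidate reference category for any stratum
    model of this garbage code.
    """
    return tm.targets_of(garbage)


def validate_matrix(tm: TargetMatrix, cause_list: CauseList = DEFAULT_CAUSE_LIST) -> list[str]:
    """Check TargetMatrix invariants; returns a list of violations (empty = valid)."""
    violations: list[str] = []
    for garbage in tm.taxonomy.categories:
        if garbage not in tm.targets:
            violations.append(f"missing target list for {garbage}")
    order = {c: i for i, c in enumerate(cause_list.causes)}
    for garbage, targets in tm.targets.items():
        if garbage not in tm.taxonomy.categories:
            violations.append(f"unknown garbage category {garbage}")
            continue
        if not targets:
            violations.append(f"empty target list for {garbage}")
            continue
        unknown = [t for t in targets if t not in order]
        if unknown:
            violations.append(f"invalid targets for {garbage}: {unknown}")
            continue
        if len(set(targets)) != len(targets):
            violations.append(f"duplicate targets for {garbage}")
        if list(targets) != sorted(targets, key=order.__getitem__):
            violations.append(f"targets for {garbage} not in canonical cause order")
        if garbage == "heart_failure":
            cancers = [t for t in targets if t in _CANCERS]
            if cancers:
                violations.append(f"cancer target for heart_failure: {cancers}")
            if "B.8" in targets:
                violations.append("mental/neurological target for heart_failure")
        if garbage == "ill_defined_cancer":
            non_cancer = [t for t in targets if t not in _CANCERS]
            if non_cancer:
                violations.append(f"non-cancer target for ill_defined_cancer: {non_cancer}")
    return violations


def default_target_matrix() -> TargetMatrix:
    tm = TargetMatrix(targets=dict(DEFAULT_TARGETS))
    assert not validate_matrix(tm), "shipped default matrix must be valid"
    return tm


def load_target_matrix(path: str | Path, taxonomy: GarbageTaxonomy = DEFAULT_TAXONOMY) -> TargetMatrix:
    """Load a target matrix from YAML ({garbage: [cause, ...]}) and validate it."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("target-matrix file must be a mapping of garbage -> cause list")
    tm = TargetMatrix(
        targets={g: tuple(causes) for g, causes in raw.items()}, taxonomy=taxonomy
    )
    violations = validate_matrix(tm)
    if violations:
        raise ValueError("invalid target matrix: " + "; ".join(violations))
    return tm


def save_target_matrix(tm: TargetMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({g: list(t) for g, t in tm.targets.items()}, fh, sort_keys=False)
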
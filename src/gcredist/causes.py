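"""Canonical cause list and garbage-code taxonomy.

The analysis condenses ICD9/ICD10 codes into 25 mutually exclusive,
collectively exhaustive causes of death plus nine "garbage" categories --
codes that are unsuitable as an underlying cause (ill-defined conditions,
intermediate causes like heart failure, or pure modes of death) and whose
deaths must be redistributed onto valid causes.

The order of :data:`CAUSE_IDS` is load-bearing: it defines the canonical
cause order used for indicator vectors and for picking the reference
category of each stratum model (the first target present in a stratum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical ordered cause identifiers (A = communicable, B = non-communicable,
#: C = injuries).  Exactly 25 entries; order is stable.
CAUSE_IDS: tuple[str, ...] = (
    "A.1", "A.2", "A.3", "A.4", "A.5", "A.6",
    "B.1.1", "B.1.2", "B.1.3", "B.1.4", "B.1.5", "B.1.6",
    "B.2",
    "B.3.1", "B.3.2", "B.3.3",
    "B.4", "B.5", "B.6", "B.7", "B.8",
    "C.1.1", "C.1.2", "C.2.1", "C.2.2",
)

CAUSE_LABELS: dict[str, str] = {
    "A.1": "HIV/AIDS & Tuberculosis",
    "A.2": "Respiratory infections",
    "A.3": "Maternal",
    "A.4": "Perinatal",
    "A.5": "Intestinal infections",
    "A.6": "Other communicable diseases",
    "B.1.1": "Lung cancer",
    "B.1.2": "Liver cancer",
    "B.1.3": "Breast cancer",
    "B.1.4": "Digestive cancers",
    "B.1.5": "Lymphomas & leukemias",
    "B.1.6": "Other cancers",
    "B.2": "Diabetes",
    "B.3.1": "Ischaemic heart disease",
    "B.3.2": "Stroke",
    "B.3.3": "Other cardiovascular diseases",
    "B.4": "Chronic respiratory diseases",
    "B.5": "Cirrhosis",
    "B.6": "Renal failure",
    "B.7": "Other non-communicable diseases",
    "B.8": "Mental and neurological",
    "C.1.1": "Road traffic injuries",
    "C.1.2": "Other unintentional injuries",
    "C.2.1": "Suicide",
    "C.2.2": "Homicide/War",
}

#: The nine garbage-code categories.  ``ill_defined_injury`` occurs only in
#: ICD9 data (nature-of-injury codes used as underlying cause).
GARBAGE_NAMES: tuple[str, ...] = (
    "septicemia",
    "heart_failure",
    "ill_defined_cancer",
    "volume_depletion",
    "ill_defined",
    "ill_defined_cvd",
    "ill_defined_injury",
    "undetermined_intent",
    "ill_defined_infectious",
)

GARBAGE_PREFIX = "garbage:"

#: ICD revisions in which each garbage category can occur.
GARBAGE_REVISIONS: dict[str, frozenset[int]] = {
    name: (frozenset({9}) if name == "ill_defined_injury" else frozenset({9, 10}))
    for name in GARBAGE_NAMES
}

#: Calendar-year span of each ICD revision era in the US data.
REVISION_ERAS: dict[int, tuple[int, int]] = {9: (1979, 1998), 10: (1999, 2011)}


def garbage_id(name: str) -> str:
    """Return the category identifier ``garbage:<name>`` for a garbage name."""
    if name not in GARBAGE_NAMES:
        raise ValueError(f"unknown garbage category {name!r}; valid: {', '.join(GARBAGE_NAMES)}")
    return GARBAGE_PREFIX + name


def is_garbage(category: str) -> bool:
    return category.startswith(GARBAGE_PREFIX)


def garbage_name(category: str) -> str:
    """Strip the ``garbage:`` prefix; raises for non-garbage categories."""
    if not is_garbage(category):
        raise ValueError(f"{category!r} is not a garbage category")
    return category[len(GARBAGE_PREFIX):]


ALL_CATEGORY_IDS: frozenset[str] = frozenset(CAUSE_IDS) | frozenset(
    GARBAGE_PREFIX + n for n in GARBAGE_NAMES
)


@dataclass(frozen=True)
class CauseList:
    """Ordered list of valid underlying causes.

    The default instance is the canonical 25-cause list; the class exists so
    the mapping machinery can be exercised with smaller lists in tests.
    """

    causes: tuple[str, ...] = CAUSE_IDS
    labels: dict[str, str] = field(default_factory=lambda: dict(CAUSE_LABELS))

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("cause identifiers must be unique")

    def __len__(self) -> int:
        return len(self.causes)

    def __contains__(self, cause: str) -> bool:
        return cause in self.causes

    def index(self, cause: str) -> int:
        return self.causes.index(cause)

    def label(self, cause: str) -> str:
        return self.labels.get(cause, cause)


#: The canonical 25-cause list.
DEFAULT_CAUSE_LIST = CauseList()
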
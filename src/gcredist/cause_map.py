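"""ICD9/ICD10 code normalization and code-to-category mapping.

A :class:`CauseMap` assigns each normalized 3- or 4-character ICD code to
exactly one of the 25 valid causes or nine garbage categories.  Lookups for
4-character codes fall back to their 3-character parent when the detailed
code is absent, mirroring how condensed cause maps are usually published at
block level with occasional code-level overrides.

The default maps shipped here are built from ICD chapter/block ranges and
approximate a GBD2010-style condensed mapping.  They are *configuration*,
not a claim about any particular published supplementary table: every block
assignment can be replaced by loading a user map in the
``code,revision,category`` dialect (:func:`load_cause_map`).
"""

from __future__ import annotations

import csv
import io
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path

from .causes import ALL_CATEGORY_IDS, GARBAGE_PREFIX, garbage_id, is_garbage

logger = logging.getLogger(__name__)

LENIENT_FALLBACK_CATEGORY = "B.7"


class MappingError(ValueError):
    """Raised for malformed ICD codes or unmapped codes in strict mode."""


def normalize_icd(raw: str, revision: int) -> str:
    """Normalize an ICD code string to its canonical uppercase, point-free form.

    Parameters
    ----------
    raw:
        Code as it appears in the data, e.g. ``"i50.0"`` or ``"428 "``.
    revision:
        ICD revision, 9 or 10.  ICD10 codes must start with a letter; ICD9
        codes with a digit or the supplementary-classification letters E/V.

    Returns
    -------
    str
        Canonical form used as a :class:`CauseMap` key, e.g. ``"I500"``.
    """
    if revision not in (9, 10):
        raise MappingError(f"revision must be 9 or 10, got {revision!r}")
    code = raw.strip().upper().replace(".", "")
    if not code:
        raise MappingError("empty ICD code")
    if not code.isalnum():
        raise MappingError(f"malformed ICD code {raw!r}: non-alphanumeric after cleaning")
    if not 3 <= len(code) <= 5:
        raise MappingError(f"malformed ICD code {raw!r}: length {len(code)} outside 3-5")
    first = code[0]
    if revision == 10 and not first.isalpha():
        raise MappingError(f"malformed ICD10 code {raw!r}: must start with a letter")
    if revision == 9 and not (first.isdigit() or first in "EV"):
        raise MappingError(f"malformed ICD9 code {raw!r}: must start with digit, E or V")
    return code


@dataclass
class CauseMap:
    """Mapping from normalized ICD codes to cause/garbage category identifiers."""

    revision: int
    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values() if c not in ALL_CATEGORY_IDS}
        if bad:
            raise MappingError(f"unknown categories in cause map: {sorted(bad)}")
        if self.revision == 10:
            ill_inj = garbage_id("ill_defined_injury")
            if ill_inj in self.entries.values():
                raise MappingError("ill_defined_injury is an ICD9-only category")

    def categories(self) -> set[str]:
        return set(self.entries.values())

    def lookup(self, code: str) -> str | None:
        """Exact lookup, then fall back to progressively shorter parents (>=3 chars)."""
        for k in (code, *(code[:n] for n in range(len(code) - 1, 2, -1))):
            cat = self.entries.get(k)
            if cat is not None:
                return cat
        return None


def map_code(code: str, cause_map: CauseMap, strict: bool = True) -> str:
    """Map one normalized ICD code to its category.

    In strict mode an unmapped code raises :class:`MappingError`; in lenient
    mode it is mapped to the residual non-communicable category
    (``B.7``) with a logged warning -- silent misclassification being worse
    than a loud approximation.
    """
    cat = cause_map.lookup(code)
    if cat is not None:
        return cat
    if strict:
        raise MappingError(f"ICD{cause_map.revision} code {code!r} not in cause map")
    logger.warning(
        "ICD%d code %s unmapped; lenient mode assigns %s",
        cause_map.revision, code, LENIENT_FALLBACK_CATEGORY,
    )
    return LENIENT_FALLBACK_CATEGORY


def _parse_rows(rows, revision: int) -> CauseMap:
    entries: dict[str, str] = {}
    duplicates: list[str] = []
    for row in rows:
        code = normalize_icd(row["code"], revision)
        cat = row["category"].strip()
        if cat not in ALL_CATEGORY_IDS:
            raise MappingError(f"unknown category {cat!r} for code {code}")
        if code in entries and entries[code] != cat:
            duplicates.append(code)
            continue
        entries[code] = cat
    if duplicates:
        raise MappingError(f"duplicate codes with conflicting categories: {sorted(set(duplicates))}")
    return CauseMap(revision=revision, entries=entries)


def load_cause_map(path: str | Path, revision: int) -> CauseMap:
    """Load a cause map from a delimited text file.

    Format: header ``code,revision,category`` (comma or tab delimited); codes
    without decimal points; categories are canonical cause ids (``A.1`` ...
    ``C.2.2``) or ``garbage:<name>``.  Rows for other revisions are ignored
    so ICD9 and ICD10 maps may share one file.
    """
    text = Path(path).read_text(encoding="utf-8")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    required = {"code", "revision", "category"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise MappingError(f"cause-map file must have header columns {sorted(required)}")
    rows = [r for r in reader if int(r["revision"]) == revision]
    return _parse_rows(rows, revision)


def save_cause_map(cause_map: CauseMap, path: str | Path) -> None:
    """Serialize a CauseMap to the ``code,revision,category`` CSV dialect."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "revision", "category"])
        for code in sorted(cause_map.entries):
            writer.writerow([code, cause_map.revision, cause_map.entries[code]])


# ---------------------------------------------------------------------------
# Default block-range maps
# ---------------------------------------------------------------------------
# Each entry is (first_code, last_code, category) over normalized 3-character
# codes, both ends inclusive.  Later entries override earlier ones, so broad
# chapter assignments may be listed first and carved up afterwards.

_G = garbage_id

#: ICD10 block assignments (letter + two digits).
ICD10_BLOCKS: tuple[tuple[str, str, str], ...] = (
    # Chapter I: infectious
    ("A00", "A09", "A.5"),
    ("A15", "A19", "A.1"),
    ("A20", "A39", "A.6"),
    ("A40", "A41", _G("septicemia")),
    ("A42", "A48", "A.6"),
    ("A49", "A49", _G("ill_defined_infectious")),
    ("A50", "B19", "A.6"),
    ("B20", "B24", "A.1"),
    ("B25", "B98", "A.6"),
    ("B99", "B99", _G("ill_defined_infectious")),
    # Chapter II: neoplasms
    ("C00", "C14", "B.1.6"),
    ("C15", "C21", "B.1.4"),
    ("C22", "C22", "B.1.2"),
    ("C23", "C26", "B.1.4"),
    ("C30", "C32", "B.1.6"),
    ("C33", "C34", "B.1.1"),
    ("C37", "C49", "B.1.6"),
    ("C50", "C50", "B.1.3"),
    ("C51", "C75", "B.1.6"),
    ("C76", "C80", _G("ill_defined_cancer")),
    ("C81", "C96", "B.1.5"),
    ("C97", "C97", "B.1.6"),
    ("D00", "D36", "B.1.6"),
    ("D37", "D48", _G("ill_defined_cancer")),
    # Blood / endocrine
    ("D50", "D89", "B.7"),
    ("E00", "E07", "B.7"),
    ("E10", "E14", "B.2"),
    ("E15", "E85", "B.7"),
    ("E86", "E87", _G("volume_depletion")),
    ("E88", "E90", "B.7"),
    # Mental & neurological (meningitis kept with communicable)
    ("F00", "F99", "B.8"),
    ("G00", "G09", "A.6"),
    ("G10", "G99", "B.8"),
    ("H00", "H95", "B.7"),
    # Circulatory
    ("I00", "I45", "B.3.3"),
    ("I10", "I15", "B.3.3"),
    ("I20", "I25", "B.3.1"),
    ("I26", "I45", "B.3.3"),
    ("I46", "I49", _G("ill_defined_cvd")),
    ("I50", "I50", _G("heart_failure")),
    ("I51", "I51", _G("ill_defined_cvd")),
    ("I52", "I59", "B.3.3"),
    ("I60", "I69", "B.3.2"),
    ("I70", "I99", "B.3.3"),
    # Respiratory
    ("J00", "J22", "A.2"),
    ("J30", "J99", "B.4"),
    # Digestive
    ("K00", "K69", "B.7"),
    ("K70", "K76", "B.5"),
    ("K77", "K93", "B.7"),
    ("L00", "M99", "B.7"),
    # Genitourinary
    ("N00", "N19", "B.6"),
    ("N20", "N99", "B.7"),
    # Maternal / perinatal / congenital
    ("O00", "O99", "A.3"),
    ("P00", "P96", "A.4"),
    ("Q00", "Q99", "B.7"),
    # Symptoms, signs, ill-defined
    ("R00", "R99", _G("ill_defined")),
    # Nature-of-injury codes as underlying carry no external-cause information
    ("S00", "T98", _G("ill_defined")),
    # External causes
    ("V01", "V89", "C.1.1"),
    ("V90", "X59", "C.1.2"),
    ("X60", "X84", "C.2.1"),
    ("X85", "Y09", "C.2.2"),
    ("Y10", "Y34", _G("undetermined_intent")),
    ("Y35", "Y36", "C.2.2"),
    ("Y40", "Y89", "C.1.2"),
)

#: ICD9 block assignments (three digits, plus E/V supplementary codes).
ICD9_BLOCKS: tuple[tuple[str, str, str], ...] = (
    ("001", "009", "A.5"),
    ("010", "018", "A.1"),
    ("020", "037", "A.6"),
    ("038", "038", _G("septicemia")),
    ("039", "041", "A.6"),
    ("042", "044", "A.1"),
    ("045", "135", "A.6"),
    ("136", "136", _G("ill_defined_infectious")),
    ("137", "139", "A.6"),
    ("140", "149", "B.1.6"),
    ("150", "154", "B.1.4"),
    ("155", "155", "B.1.2"),
    ("156", "159", "B.1.4"),
    ("160", "161", "B.1.6"),
    ("162", "162", "B.1.1"),
    ("163", "173", "B.1.6"),
    ("174", "175", "B.1.3"),
    ("176", "194", "B.1.6"),
    ("195", "199", _G("ill_defined_cancer")),
    ("200", "208", "B.1.5"),
    ("209", "234", "B.1.6"),
    ("235", "239", _G("ill_defined_cancer")),
    ("240", "249", "B.7"),
    ("250", "250", "B.2"),
    ("251", "275", "B.7"),
    ("276", "276", _G("volume_depletion")),
    ("277", "289", "B.7"),
    ("290", "359", "B.8"),
    ("360", "389", "B.7"),
    ("390", "409", "B.3.3"),
    ("410", "414", "B.3.1"),
    ("415", "426", "B.3.3"),
    ("427", "427", _G("ill_defined_cvd")),
    ("428", "428", _G("heart_failure")),
    ("429", "429", _G("ill_defined_cvd")),
    ("430", "438", "B.3.2"),
    ("440", "459", "B.3.3"),
    ("460", "466", "A.2"),
    ("470", "478", "B.4"),
    ("480", "487", "A.2"),
    ("490", "519", "B.4"),
    ("520", "570", "B.7"),
    ("571", "571", "B.5"),
    ("572", "579", "B.7"),
    ("580", "589", "B.6"),
    ("590", "629", "B.7"),
    ("630", "676", "A.3"),
    ("680", "759", "B.7"),
    ("760", "779", "A.4"),
    ("780", "799", _G("ill_defined")),
    ("800", "999", _G("ill_defined_injury")),
    ("E800", "E809", "C.1.2"),
    ("E810", "E825", "C.1.1"),
    ("E826", "E949", "C.1.2"),
    ("E950", "E959", "C.2.1"),
    ("E960", "E978", "C.2.2"),
    ("E980", "E989", _G("undetermined_intent")),
    ("E990", "E999", "C.2.2"),
    ("V01", "V91", "B.7"),
)


def _expand_range(first: str, last: str) -> list[str]:
    """Enumerate 3-character codes between first and last (inclusive).

    Codes are treated as a letter-prefixed or plain decimal counter in
    lexicographic order, which matches ICD block conventions (``I20``-``I25``,
    ``V90``-``X59``, ``150``-``154``, ``E810``-``E825``).
    """
    if len(first) != len(last):
        raise ValueError(f"range endpoints {first}-{last} differ in length")
    if first[0].isalpha():
        letters = string.ascii_uppercase
        lo = letters.index(first[0]) * 10 ** (len(first) - 1) + int(first[1:])
        hi = letters.index(last[0]) * 10 ** (len(last) - 1) + int(last[1:])
        width = len(first) - 1
        return [
            f"{letters[v // 10**width]}{v % 10**width:0{width}d}"
            for v in range(lo, hi + 1)
        ]
    width = len(first)
    return [f"{v:0{width}d}" for v in range(int(first), int(last) + 1)]


def build_map_from_blocks(blocks, revision: int) -> CauseMap:
    """Expand (first, last, category) block ranges into an explicit CauseMap."""
    entries: dict[str, str] = {}
    for first, last, cat in blocks:
        for code in _expand_range(first, last):
            entries[code] = cat  # later blocks override earlier ones
    return CauseMap(revision=revision, entries=entries)


def default_cause_map(revision: int) -> CauseMap:
    """The shipped block-level default map for a revision (replaceable config)."""
    if revision == 9:
        return build_map_from_blocks(ICD9_BLOCKS, 9)
    if revision == 10:
        return build_map_from_blocks(ICD10_BLOCKS, 10)
    raise MappingError(f"revision must be 9 or 10, got {revision!r}")


def canonical_code(category: str, cause_map: CauseMap) -> str:
    """A representative ICD code for a category (first in sorted order).

    Used by the synthetic generator to emit syntactically valid certificates
    without inventing clinical code sequences.
    """
    for code in sorted(cause_map.entries):
        if cause_map.entries[code] == category:
            return code
    raise MappingError(
        f"category {category!r} has no codes in the ICD{cause_map.revision} map"
    )
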
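"""Charlson comorbidity index from ICD-10 diagnosis codes.

Maps ICD-10 codes to the 17 Charlson condition groups using the Quan et al.
(2005) enhanced ICD-10 coding algorithm, applies the severity hierarchies,
and sums the original Charlson weights (1/2/3/6).  The mapping ships as a
plain CSV (``data/charlson_icd10_quan2005.csv``) so that an alternative
coding dialect can be substituted without touching code.

Matching is prefix-based on 3-4 character stems: codes are upper-cased and
dots stripped before comparison, so ``"i21.4"`` matches the ``I21`` stem.
Unrecognised codes simply do not match (logged at DEBUG level).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import FrozenSet, Iterable, Mapping, Tuple

logger = logging.getLogger(__name__)

#: Severity hierarchies: when both members of a pair are coded, only the more
#: severe one contributes to the index.
HIERARCHIES: Tuple[Tuple[str, str], ...] = (
    ("diabetes_without_complication", "diabetes_with_complication"),
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("any_malignancy", "metastatic_solid_tumour"),
)

_DEFAULT_TABLE = "charlson_icd10_quan2005.csv"


def _normalize(code: str) -> str:
    return code.strip().upper().replace(".", "")


@lru_cache(maxsize=4)
def load_mapping(table: str = _DEFAULT_TABLE) -> Tuple[Mapping[str, Tuple[str, ...]], Mapping[str, int]]:
    """Load a condition-group -> (prefixes, weight) mapping table.

    ``table`` is either the name of a bundled table or a filesystem path to a
    user-supplied CSV with columns ``condition_group, icd10_prefix, weight``.

    Returns ``(prefixes_by_group, weight_by_group)`` with prefixes already
    normalized (uppercase, dots stripped).
    """
    bundled = resources.files("laceroc.data") / table
    if bundled.is_file():
        text = bundled.read_text()
    else:
        with open(table, newline="") as fh:
            text = fh.read()
    prefixes: dict[str, list[str]] = {}
    weights: dict[str, int] = {}
    for row in csv.DictReader(text.splitlines()):
        group = row["condition_group"]
        prefixes.setdefault(group, []).append(_normalize(row["icd10_prefix"]))
        weights[group] = int(row["weight"])
    return ({g: tuple(p) for g, p in prefixes.items()}, weights)


@dataclass(frozen=True)
class CharlsonResult:
    """Condition flags and the weighted Charlson comorbidity index.

    ``condition_flags`` records every condition group with at least one
    matching code, before hierarchy resolution; ``index`` applies the
    hierarchies, so e.g. metastatic disease plus a primary malignancy scores
    6, not 8.
    """

    condition_flags: FrozenSet[str] = field(default_factory=frozenset)
    index: int = 0

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"Charlson index must be >= 0, got {self.index}")


def charlson_flags(codes: Iterable[str], table: str = _DEFAULT_TABLE) -> CharlsonResult:
    """Map a set of ICD-10 codes to Charlson flags and the weighted index.

    Parameters
    ----------
    codes
        ICD-10 code strings in any common format (``"I21"``, ``"i21.4"``).
        Non-string or empty entries raise ``ValueError``; codes that match
        no Charlson stem are ignored.
    table
        Name or path of the mapping CSV (default: bundled Quan-2005 table).
    """
    prefixes_by_group, weight_by_group = load_mapping(table)
    normalized = []
    for code in codes:
        if not isinstance(code, str) or not code.strip():
            raise ValueError(f"ICD-10 codes must be non-empty strings, got {code!r}")
        normalized.append(_normalize(code))

    flagged = set()
    for code in normalized:
        hit = False
        for group, prefixes in prefixes_by_group.items():
            if any(code.startswith(p) for p in prefixes):
                flagged.add(group)
                hit = True
        if not hit:
            logger.debug("ICD-10 code %s matched no Charlson condition", code)

    contributing = set(flagged)
    for mild, severe in HIERARCHIES:
        if severe in contributing:
            contributing.discard(mild)
    index = sum(weight_by_group[g] for g in contributing)
    return CharlsonResult(condition_flags=frozenset(flagged), index=index)


def charlson_lace_subscore(result: "CharlsonResult | int") -> int:
    """LACE comorbidity component (C) from the Charlson index.

    Uses the published LACE binning: index 0-3 map to themselves and any
    index >= 4 scores 5, giving the component range {0, 1, 2, 3, 5}.
    Accepts either a :class:`CharlsonResult` or a bare integer index.
    """
    index = result.index if isinstance(result, CharlsonResult) else int(result)
    if index < 0:
        raise ValueError(f"Charlson index must be >= 0, got {index}")
    return index if index <= 3 else 5
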
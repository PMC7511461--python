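"""LACE index scoring: Length of stay, Acuity, Comorbidity, ED visits.

The LACE index is an additive risk score on a 0-19 scale built from four
components of a hospital discharge episode:

* **L** — length of stay, binned to 0-7 points;
* **A** — acuity of admission, 3 points for an emergent/unplanned admission;
* **C** — Charlson comorbidity, binned to {0, 1, 2, 3, 5} points;
* **E** — emergency-department visits in the prior six months, 0-4 points.

The length-of-stay bins ship as a data table
(``data/lace_los_bins.csv``) rather than hard-coded constants.

Two dialects of the E component are supported (see :func:`lace_score`):
``count_capped`` scores one point per prior visit capped at 4 (the original
algorithm) and ``binary`` scores 0 for no visits versus 4 for any visit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Tuple, TYPE_CHECKING

import numpy as np

from .comorbidity import CharlsonResult, charlson_lace_subscore

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import EpisodeRecord

E_DIALECTS = ("count_capped", "binary")

MAX_TOTAL = 19  # 7 (L) + 3 (A) + 5 (C) + 4 (E)


@lru_cache(maxsize=1)
def load_los_bins() -> Tuple[Tuple[int, float, int], ...]:
    """Length-of-stay bins as (min_days, max_days, points); max may be inf."""
    text = (resources.files("laceroc.data") / "lace_los_bins.csv").read_text()
    bins = []
    for row in csv.DictReader(text.splitlines()):
        hi = float(row["los_max_days"]) if row["los_max_days"] else np.inf
        bins.append((int(row["los_min_days"]), hi, int(row["points"])))
    return tuple(bins)


@dataclass(frozen=True)
class LaceComponents:
    """The four LACE subscores and their 0-19 total."""

    L: int
    A: int
    C: int
    E: int

    def __post_init__(self) -> None:
        if not 0 <= self.L <= 7:
            raise ValueError(f"L component out of range 0-7: {self.L}")
        if self.A not in (0, 3):
            raise ValueError(f"A component must be 0 or 3: {self.A}")
        if self.C not in (0, 1, 2, 3, 5):
            raise ValueError(f"C component must be in {{0,1,2,3,5}}: {self.C}")
        if not 0 <= self.E <= 4:
            raise ValueError(f"E component out of range 0-4: {self.E}")

    @property
    def total(self) -> int:
        return self.L + self.A + self.C + self.E


def los_points(length_of_stay_days: int) -> int:
    """Length-of-stay subscore from the bundled bin table."""
    if length_of_stay_days < 0:
        raise ValueError(f"length of stay must be >= 0, got {length_of_stay_days}")
    for lo, hi, points in load_los_bins():
        if lo <= length_of_stay_days <= hi:
            return points
    raise AssertionError("LOS bin table does not cover all non-negative days")


def ed_points(ed_visits_6mo: int, dialect: str = "count_capped") -> int:
    """Emergency-department subscore under the selected dialect."""
    if ed_visits_6mo < 0:
        raise ValueError(f"ED visit count must be >= 0, got {ed_visits_6mo}")
    if dialect == "count_capped":
        return min(int(ed_visits_6mo), 4)
    if dialect == "binary":
        return 4 if ed_visits_6mo >= 1 else 0
    raise ValueError(f"unknown E-component dialect {dialect!r}; choose from {E_DIALECTS}")


def lace_components(
    length_of_stay_days: int,
    acuity_emergent: bool,
    charlson_index: int,
    ed_visits_6mo: int,
    e_dialect: str = "count_capped",
) -> LaceComponents:
    """Score the four LACE components from raw episode inputs."""
    return LaceComponents(
        L=los_points(length_of_stay_days),
        A=3 if acuity_emergent else 0,
        C=charlson_lace_subscore(charlson_index),
        E=ed_points(ed_visits_6mo, e_dialect),
    )


def lace_score(
    record: "EpisodeRecord",
    charlson: CharlsonResult,
    e_dialect: str = "count_capped",
) -> LaceComponents:
    """Score one discharge episode given its Charlson result."""
    return lace_components(
        record.length_of_stay_days,
        record.acuity_emergent,
        charlson.index,
        record.ed_visits_6mo,
        e_dialect,
    )


def los_points_array(days: np.ndarray) -> np.ndarray:
    """Vectorised length-of-stay subscore."""
    days = np.asarray(days)
    if (days < 0).any():
        raise ValueError("length of stay must be >= 0")
    out = np.zeros(days.shape, dtype=np.int64)
    for lo, hi, points in load_los_bins():
        out[(days >= lo) & (days <= hi)] = points
    return out


def charlson_subscore_array(index: np.ndarray) -> np.ndarray:
    """Vectorised C component: identity below 4, then capped at 5."""
    index = np.asarray(index)
    if (index < 0).any():
        raise ValueError("Charlson index must be >= 0")
    return np.where(index <= 3, index, 5).astype(np.int64)


def lace_total_array(
    days: np.ndarray,
    emergent: np.ndarray,
    charlson_index: np.ndarray,
    ed_visits: np.ndarray,
    e_dialect: str = "count_capped",
) -> np.ndarray:
    """Vectorised LACE totals for parallel component arrays."""
    ed_visits = np.asarray(ed_visits)
    if (ed_visits < 0).any():
        raise ValueError("ED visit count must be >= 0")
    if e_dialect == "count_capped":
        e = np.minimum(ed_visits, 4)
    elif e_dialect == "binary":
        e = np.where(ed_visits >= 1, 4, 0)
    else:
        raise ValueError(f"unknown E-component dialect {e_dialect!r}; choose from {E_DIALECTS}")
    return (
        los_points_array(days)
        + 3 * np.asarray(emergent).astype(np.int64)
        + charlson_subscore_array(charlson_index)
        + e.astype(np.int64)
    )
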
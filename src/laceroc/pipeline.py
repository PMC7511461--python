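"""End-to-end study orchestration.

Reads an episode table, scores the LACE index, defines the three outcomes
(death within 6 months, death within 30 days, frequent readmission), assigns
age bands, and runs the per-stratum ROC / two-graph / likelihood-ratio
analyses plus threshold-impact comparisons.  The report rows mirror the
structure of an age-stratified test-accuracy table: n, AUC (%), 95% CI,
P (vs AUC = 50%), LR+/LR- at the stratum's equal-error threshold theta_0,
and the intermediate range.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import comorbidity
from .lace import E_DIALECTS
from .roc import (
    LikelihoodRatios,
    RocCurve,
    TwoGraphResult,
    UndefinedAucError,
    likelihood_ratios,
    roc_curve,
    two_graph,
)

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = {
    "death_6mo": "died_within_6mo",
    "death_30d": "died_within_30d",
    "frequent_readmit": "frequent_readmit",
}

#: ICD-10 chapter prefixes excluded by the optional cancer/obstetrics filter.
EXCLUSION_PREFIXES = tuple(f"C{i:02d}" for i in range(98)) + tuple(
    f"O{i:02d}" for i in range(100)
)


class OutOfCohortError(ValueError):
    """Age below the adult cohort minimum."""


@dataclass(frozen=True)
class AgeBand:
    """Half-open age interval [lower, upper); the top band is unbounded."""

    label: str
    lower: float
    upper: float  # math.inf for the open-ended top band

    def contains(self, age_years: float) -> bool:
        return self.lower <= age_years < self.upper


DEFAULT_BANDS: Tuple[AgeBand, ...] = (
    AgeBand("18-49.9 years", 18.0, 50.0),
    AgeBand("50-59.9 years", 50.0, 60.0),
    AgeBand("60-69.9 years", 60.0, 70.0),
    AgeBand("70-79.9 years", 70.0, 80.0),
    AgeBand(">=80 years", 80.0, math.inf),
)


def validate_bands(bands: Sequence[AgeBand]) -> None:
    """Bands must partition [18, inf) with no gaps or overlaps."""
    if not bands:
        raise ValueError("at least one age band is required")
    ordered = sorted(bands, key=lambda b: b.lower)
    if ordered[0].lower != 18.0:
        raise ValueError(f"bands must start at 18, got {ordered[0].lower}")
    for a, b in zip(ordered, ordered[1:]):
        if a.upper != b.lower:
            raise ValueError(f"gap or overlap between bands {a.label!r} and {b.label!r}")
    if not math.isinf(ordered[-1].upper):
        raise ValueError("the top band must be unbounded above")


def assign_band(age_years: float, bands: Sequence[AgeBand] = DEFAULT_BANDS) -> AgeBand:
    """The unique band containing an age (lower-inclusive, upper-exclusive)."""
    if age_years < 18:
        raise OutOfCohortError(f"age {age_years} is below the adult cohort minimum of 18")
    for band in bands:
        if band.contains(age_years):
            return band
    raise ValueError(f"no band contains age {age_years}")


def define_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Aligned boolean outcome triple for each episode.

    ``frequent_readmit`` is two or more readmissions within 28 days of the
    index discharge; the two death horizons pass through unchanged.
    """
    return pd.DataFrame(
        {
            "death_6mo": df["died_within_6mo"].astype(bool),
            "death_30d": df["died_within_30d"].astype(bool),
            "frequent_readmit": df["readmissions_28d"].to_numpy() >= 2,
        },
        index=df.index,
    )


@lru_cache(maxsize=100_000)
def _charlson_index_for(codes_field: str) -> int:
    codes = [c for c in codes_field.split(";") if c.strip()]
    return comorbidity.charlson_flags(codes).index


def score_table(df: pd.DataFrame, e_dialect: str = "count_capped") -> pd.DataFrame:
    """Append the LACE component columns (L, A, C, E, lace_total).

    ``icd10_codes`` is parsed as a semicolon-delimited string per episode
    and mapped through the Charlson coding table.
    """
    if e_dialect not in E_DIALECTS:
        raise ValueError(f"unknown E-component dialect {e_dialect!r}")
    out = df.copy()
    charlson = np.array(
        [_charlson_index_for(str(v)) for v in out["icd10_codes"].fillna("")],
        dtype=np.int64,
    )
    out["charlson_index"] = charlson
    los = out["length_of_stay_days"].to_numpy()
    emergent = out["acuity_emergent"].to_numpy(dtype=bool)
    ed = out["ed_visits_6mo"].to_numpy()
    from .lace import charlson_subscore_array, los_points_array

    out["L"] = los_points_array(los)
    out["A"] = 3 * emergent.astype(np.int64)
    out["C"] = charlson_subscore_array(charlson)
    if e_dialect == "count_capped":
        out["E"] = np.minimum(ed, 4).astype(np.int64)
    else:
        out["E"] = np.where(ed >= 1, 4, 0)
    out["lace_total"] = out[["L", "A", "C", "E"]].sum(axis=1)
    return out


def exclusion_filter(df: pd.DataFrame) -> pd.DataFrame:
    """Drop episodes carrying cancer (C00-C97) or obstetric (O00-O99) codes."""
    def has_excluded(codes_field: str) -> bool:
        for code in str(codes_field).split(";"):
            norm = code.strip().upper().replace(".", "")
            if any(norm.startswith(p) for p in EXCLUSION_PREFIXES):
                return True
        return False

    keep = ~df["icd10_codes"].fillna("").map(has_excluded)
    return df.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class ThresholdImpact:
    """Event capture and false-positive cost of two competing thresholds."""

    threshold_a: float
    threshold_b: float
    events_total: int
    events_flagged_a: int
    events_flagged_b: int
    pct_flagged_a: float
    pct_flagged_b: float
    relative_change_pct: Optional[float]
    false_positive_rate_a: float
    false_positive_rate_b: float


def threshold_impact(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    threshold_a: float,
    threshold_b: float,
) -> ThresholdImpact:
    """Compare how many events two thresholds flag, and at what FP cost.

    Flagging uses the ``score >= threshold`` rule; on integer scores a
    half-point threshold such as 11.5 therefore behaves as the next integer.
    Percentages are fractions of the event count; the false-positive rate is
    the fraction of non-events flagged.
    """
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes, dtype=bool)
    n_events = int(outcomes.sum())
    if n_events == 0:
        raise UndefinedAucError("threshold impact undefined with zero events")
    n_non = len(outcomes) - n_events
    flag_a = scores >= threshold_a
    flag_b = scores >= threshold_b
    ev_a = int((flag_a & outcomes).sum())
    ev_b = int((flag_b & outcomes).sum())
    rel = 100.0 * (ev_a - ev_b) / ev_a if ev_a > 0 else None
    return ThresholdImpact(
        threshold_a=float(threshold_a),
        threshold_b=float(threshold_b),
        events_total=n_events,
        events_flagged_a=ev_a,
        events_flagged_b=ev_b,
        pct_flagged_a=100.0 * ev_a / n_events,
        pct_flagged_b=100.0 * ev_b / n_events,
        relative_change_pct=rel,
        false_positive_rate_a=float((flag_a & ~outcomes).sum() / n_non) if n_non else math.nan,
        false_positive_rate_b=float((flag_b & ~outcomes).sum() / n_non) if n_non else math.nan,
    )


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the stratified analysis."""

    bands: Tuple[AgeBand, ...] = DEFAULT_BANDS
    ir_level: float = 0.95
    e_dialect: str = "count_capped"
    reference_threshold: float = 10.0
    extra_top_band_threshold: Optional[float] = 11.5
    apply_exclusions: bool = False

    def __post_init__(self) -> None:
        validate_bands(self.bands)
        if not 0.5 < self.ir_level < 1:
            raise ValueError(f"ir_level must be in (0.5, 1), got {self.ir_level}")


@dataclass(frozen=True)
class AgeBandReport:
    """One stratum x outcome cell of the study report."""

    stratum: str
    outcome: str
    n: int
    n_events: int
    curve: Optional[RocCurve]
    twograph: Optional[TwoGraphResult]
    lr: Optional[LikelihoodRatios]
    capture: Tuple[ThresholdImpact, ...] = ()
    undefined_reason: Optional[str] = None


@dataclass(frozen=True)
class StudyReport:
    rows: Tuple[AgeBandReport, ...]
    config: StudyConfig
    n_total: int

    def to_dataframe(self) -> pd.DataFrame:
        """Rounded, human-readable table (AUC/CI in %, 1 dp; LRs 2 dp;
        theta_0 and IR bounds 1 dp; P reported as '<0.001' below that)."""
        records = []
        for r in self.rows:
            if r.curve is None:
                records.append(
                    {
                        "stratum": r.stratum,
                        "outcome": r.outcome,
                        "n": r.n,
                        "n_events": r.n_events,
                        "auc_pct": None,
                        "auc_ci_pct": None,
                        "p_value": None,
                        "lr_pos": None,
                        "lr_neg": None,
                        "theta0": None,
                        "ir": None,
                        "note": r.undefined_reason,
                    }
                )
                continue
            p = r.curve.p_value
            records.append(
                {
                    "stratum": r.stratum,
                    "outcome": r.outcome,
                    "n": r.n,
                    "n_events": r.n_events,
                    "auc_pct": round(100 * r.curve.auc, 1),
                    "auc_ci_pct": f"{100 * r.curve.auc_ci[0]:.1f}-{100 * r.curve.auc_ci[1]:.1f}",
                    "p_value": "<0.001" if p < 0.001 else f"{p:.3f}",
                    "lr_pos": round(r.lr.lr_pos, 2) if math.isfinite(r.lr.lr_pos) else "inf",
                    "lr_neg": round(r.lr.lr_neg, 2) if math.isfinite(r.lr.lr_neg) else "inf",
                    "theta0": round(r.twograph.theta0, 1),
                    "ir": f"{r.twograph.ir_lower:.1f}-{r.twograph.ir_upper:.1f}",
                    "note": None,
                }
            )
        return pd.DataFrame.from_records(records)

    def to_json(self, **dump_kwargs) -> str:
        payload = {
            "n_total": self.n_total,
            "ir_level": self.config.ir_level,
            "rows": self.to_dataframe().to_dict(orient="records"),
        }
        dump_kwargs.setdefault("indent", 2)
        return json.dumps(payload, **dump_kwargs)


def _analyze_stratum(
    label: str,
    scores: np.ndarray,
    outcome_flags: np.ndarray,
    outcome: str,
    config: StudyConfig,
    is_top_band: bool,
) -> AgeBandReport:
    n = len(scores)
    n_events = int(outcome_flags.sum())
    if n_events == 0 or n_events == n:
        reason = "no events" if n_events == 0 else "no non-events"
        logger.warning("stratum %r, outcome %r: %s; cell left undefined", label, outcome, reason)
        return AgeBandReport(label, outcome, n, n_events, None, None, None, (), reason)
    curve = roc_curve(scores, outcome_flags)
    tg = two_graph(curve, level=config.ir_level)
    lr = likelihood_ratios(curve, tg.theta0)
    pairs: List[Tuple[float, float]] = [(config.reference_threshold, tg.theta0)]
    if is_top_band and config.extra_top_band_threshold is not None:
        pairs.append((config.reference_threshold, config.extra_top_band_threshold))
    capture = tuple(threshold_impact(scores, outcome_flags, a, b) for a, b in pairs)
    return AgeBandReport(label, outcome, n, n_events, curve, tg, lr, capture)


def run_study(episodes: pd.DataFrame, config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the full age-stratified analysis over an episode table.

    For each outcome and for the whole cohort plus every age band, computes
    the ROC curve with AUC and CI, the two-graph threshold theta_0 with its
    intermediate range, likelihood ratios at theta_0, and threshold-impact
    comparisons of the conventional threshold (default 10) against the
    stratum's theta_0 (and, for the oldest band, against a raised
    threshold, default 11.5).  Strata with zero events for an outcome are
    reported as undefined with a warning and the run continues.
    """
    df = episodes
    if config.apply_exclusions:
        df = exclusion_filter(df)
    if "lace_total" not in df.columns:
        df = score_table(df, e_dialect=config.e_dialect)
    outcomes = define_outcomes(df)
    scores = df["lace_total"].to_numpy()
    ages = df["age_years"].to_numpy()

    top_lower = max(b.lower for b in config.bands)
    rows: List[AgeBandReport] = []
    for outcome in OUTCOME_COLUMNS:
        flags = outcomes[outcome].to_numpy()
        rows.append(
            _analyze_stratum("all", scores, flags, outcome, config, is_top_band=False)
        )
        for band in config.bands:
            mask = (ages >= band.lower) & (ages < band.upper)
            rows.append(
                _analyze_stratum(
                    band.label,
                    scores[mask],
                    flags[mask],
                    outcome,
                    config,
                    is_top_band=band.lower == top_lower,
                )
            )
    return StudyReport(rows=tuple(rows), config=config, n_total=len(df))
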
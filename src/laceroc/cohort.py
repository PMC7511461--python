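"""Synthetic discharge-episode cohorts with controllable score discrimination.

The generator emulates the structure of an adult unplanned-admission cohort
stratified into five age bands (18-49.9, 50-59.9, 60-69.9, 70-79.9, >=80
years) with band sizes and band-specific outcome rates configurable; the
defaults reproduce the published cohort: 8,403 / 4,304 / 4,739 / 6,068 /
8,756 episodes per band, six-month mortality of 0.5 / 2.0 / 4.8 / 7.7 /
15.6%, thirty-day mortality of 0.2 / 0.7 / 1.8 / 2.9 / 6.0%, and frequent
(>= 2 within 28 days) readmission of 1.0 / 1.5 / 2.4 / 3.3 / 6.7%.

Episode components (length of stay, acuity, Charlson burden, prior ED
visits) are drawn independently; the LACE total computed from them drives
the outcomes through a per-band logistic model

    logit P(outcome | score s) = intercept_band + slope * (s - mean_band(s)),

where ``slope`` (``discrimination_slope``, log-odds per LACE point) controls
how well the score discriminates the outcome, and each band intercept is
calibrated by root-finding so the band's marginal outcome rate hits its
target exactly (see :func:`calibrate_intercept`).

Thirty-day death is a Bernoulli thinning of six-month death with the band's
rate ratio as conditional probability, which guarantees the subset
invariant.  Readmission counts are drawn from a band-calibrated Poisson
conditioned on the frequent/non-frequent flag from the logistic model, so
that both the marginal frequent-readmission rate and the score-outcome
discrimination are controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import poisson

from .lace import lace_total_array

OUTCOMES = ("death_6mo", "death_30d", "frequent_readmit")

#: Default band sizes and outcome rates (fractions) of the emulated cohort.
DEFAULT_N_PER_BAND = (8403, 4304, 4739, 6068, 8756)
DEFAULT_RATES: Mapping[str, Tuple[float, ...]] = {
    "death_6mo": (0.005, 0.020, 0.048, 0.077, 0.156),
    "death_30d": (0.002, 0.007, 0.018, 0.029, 0.060),
    "frequent_readmit": (0.010, 0.015, 0.024, 0.033, 0.067),
}
DEFAULT_BAND_EDGES = (18.0, 50.0, 60.0, 70.0, 80.0)
MAX_AGE = 107.0

#: Minimal ICD-10 code sets realising each Charlson index 0-10, chosen so no
#: severity hierarchy fires (weights: B20=6, K72.1=3, G81/N18=2, I21/I50=1).
_CODES_FOR_INDEX: Tuple[Tuple[str, ...], ...] = (
    (),
    ("I21",),
    ("G81",),
    ("K72.1",),
    ("G81", "N18"),
    ("K72.1", "G81"),
    ("B20",),
    ("B20", "I21"),
    ("B20", "G81"),
    ("B20", "K72.1"),
    ("B20", "G81", "N18"),
)

CSV_COLUMNS = (
    "episode_id",
    "age_years",
    "acuity_emergent",
    "length_of_stay_days",
    "icd10_codes",
    "ed_visits_6mo",
    "died_within_30d",
    "died_within_6mo",
    "readmissions_28d",
)


class CohortConfigError(ValueError):
    """A cohort configuration field failed validation."""


class CalibrationError(ValueError):
    """No finite intercept reproduces the target rate (rate 0 or 1)."""


@dataclass(frozen=True)
class ComponentParams:
    """Distributions of the episode components feeding the LACE score.

    ``los_mean_days``: mean of the geometric length-of-stay distribution on
    {0, 1, 2, ...}.  ``p_emergent``: probability an admission is emergent
    (1.0 by default: the cohort is unplanned admissions only).
    ``ed_mean_visits``: Poisson mean of prior ED visits, truncated at
    ``ed_max_visits``.  ``charlson_probs``: categorical distribution of the
    Charlson index over 0..10 (default: truncated geometric with ratio
    0.55).  ``emit_icd10``: when true (default), each episode carries a
    minimal ICD-10 code set realising its drawn Charlson index, so the
    comorbidity coding path is exercised end to end.
    """

    los_mean_days: float = 4.0
    p_emergent: float = 1.0
    ed_mean_visits: float = 1.0
    ed_max_visits: int = 10
    charlson_probs: Tuple[float, ...] = tuple(
        (0.55**k * (1 - 0.55) / (1 - 0.55**11)) for k in range(11)
    )
    emit_icd10: bool = True

    def __post_init__(self) -> None:
        if self.los_mean_days <= 0:
            raise CohortConfigError(f"los_mean_days must be > 0, got {self.los_mean_days}")
        if not 0 <= self.p_emergent <= 1:
            raise CohortConfigError(f"p_emergent must be in [0, 1], got {self.p_emergent}")
        if self.ed_mean_visits < 0:
            raise CohortConfigError(f"ed_mean_visits must be >= 0, got {self.ed_mean_visits}")
        probs = np.asarray(self.charlson_probs)
        if len(probs) != 11 or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise CohortConfigError(
                "charlson_probs must be 11 non-negative values summing to 1"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort.

    ``discrimination_slope`` may be a single value applied to every band and
    outcome, or a per-band sequence (one value per band).
    """

    n_per_band: Tuple[int, ...] = DEFAULT_N_PER_BAND
    band_outcome_rates: Mapping[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    discrimination_slope: Union[float, Tuple[float, ...]] = 0.5
    seed: int = 0
    component_params: ComponentParams = field(default_factory=ComponentParams)
    band_edges: Tuple[float, ...] = DEFAULT_BAND_EDGES
    max_age: float = MAX_AGE

    def __post_init__(self) -> None:
        k = len(self.n_per_band)
        if k != len(self.band_edges):
            raise CohortConfigError(
                f"n_per_band has {k} bands but band_edges has {len(self.band_edges)}"
            )
        if any(n < 1 for n in self.n_per_band):
            raise CohortConfigError(f"n_per_band entries must be >= 1, got {self.n_per_band}")
        for outcome in OUTCOMES:
            if outcome not in self.band_outcome_rates:
                raise CohortConfigError(f"band_outcome_rates missing outcome {outcome!r}")
            rates = self.band_outcome_rates[outcome]
            if len(rates) != k:
                raise CohortConfigError(
                    f"band_outcome_rates[{outcome!r}] has {len(rates)} entries, expected {k}"
                )
            if any(not 0 <= r <= 1 for r in rates):
                raise CohortConfigError(
                    f"band_outcome_rates[{outcome!r}] must lie in [0, 1], got {rates}"
                )
        for r30, r6 in zip(
            self.band_outcome_rates["death_30d"], self.band_outcome_rates["death_6mo"]
        ):
            if r30 > r6:
                raise CohortConfigError(
                    f"band_outcome_rates: death_30d rate {r30} exceeds death_6mo rate {r6}"
                )
        slopes = self.slopes_per_band()
        if any(s < 0 for s in slopes):
            raise CohortConfigError(f"discrimination_slope must be >= 0, got {slopes}")

    def slopes_per_band(self) -> Tuple[float, ...]:
        k = len(self.n_per_band)
        if isinstance(self.discrimination_slope, (int, float)):
            return (float(self.discrimination_slope),) * k
        slopes = tuple(float(s) for s in self.discrimination_slope)
        if len(slopes) != k:
            raise CohortConfigError(
                f"discrimination_slope sequence has {len(slopes)} entries, expected {k}"
            )
        return slopes

    def band_intervals(self) -> Tuple[Tuple[float, float], ...]:
        """(lower, upper) age interval per band; the top band ends at max_age."""
        edges = list(self.band_edges) + [self.max_age]
        return tuple((edges[i], edges[i + 1]) for i in range(len(self.band_edges)))


@dataclass(frozen=True)
class EpisodeRecord:
    """One alive-discharge unplanned-admission episode."""

    episode_id: str
    age_years: float
    acuity_emergent: bool
    length_of_stay_days: int
    icd10_codes: Tuple[str, ...]
    ed_visits_6mo: int
    died_within_30d: bool
    died_within_6mo: bool
    readmissions_28d: int

    def __post_init__(self) -> None:
        if not 18 <= self.age_years <= 110:
            raise ValueError(f"age_years must be in [18, 110], got {self.age_years}")
        if self.length_of_stay_days < 0:
            raise ValueError(f"length_of_stay_days must be >= 0, got {self.length_of_stay_days}")
        if self.ed_visits_6mo < 0:
            raise ValueError(f"ed_visits_6mo must be >= 0, got {self.ed_visits_6mo}")
        if self.readmissions_28d < 0:
            raise ValueError(f"readmissions_28d must be >= 0, got {self.readmissions_28d}")
        if self.died_within_30d and not self.died_within_6mo:
            raise ValueError("died_within_30d implies died_within_6mo")


def calibrate_intercept(
    target_rate: float,
    slope: float,
    score_sample: Sequence[float],
    tol: float = 1e-12,
) -> float:
    """Intercept c with mean(expit(c + slope * (s - mean(s)))) = target_rate.

    The mean logistic probability is strictly increasing in c, so the root
    is unique; for slope = 0 the closed form logit(target_rate) is returned.

    Raises :class:`CalibrationError` for target rates of exactly 0 or 1,
    where no finite intercept exists.
    """
    scores = np.asarray(score_sample, dtype=float)
    if scores.size == 0:
        raise CalibrationError("score_sample must be non-empty")
    if not 0 < target_rate < 1:
        raise CalibrationError(
            f"no finite intercept for target rate {target_rate}; handle 0/1 as constant outcome"
        )
    if slope == 0:
        return float(logit(target_rate))
    offsets = slope * (scores - scores.mean())

    def excess(c: float) -> float:
        return float(expit(c + offsets).mean() - target_rate)

    lo, hi = -60.0, 60.0
    return float(optimize.brentq(excess, lo, hi, xtol=tol))


def calibrate_intercepts(
    config: CohortConfig,
    score_samples: Sequence[Sequence[float]],
    outcome: str = "death_6mo",
) -> Tuple[Optional[float], ...]:
    """Per-band intercepts matching each band's target rate for ``outcome``.

    ``score_samples`` holds one non-empty score sample per band.  Bands with
    a target rate of exactly 0 or 1 get ``None`` (constant outcome; no
    finite intercept exists).
    """
    if outcome not in OUTCOMES:
        raise CohortConfigError(f"unknown outcome {outcome!r}")
    rates = config.band_outcome_rates[outcome]
    slopes = config.slopes_per_band()
    if len(score_samples) != len(rates):
        raise CohortConfigError(
            f"expected {len(rates)} score samples, got {len(score_samples)}"
        )
    out = []
    for rate, slope, sample in zip(rates, slopes, score_samples):
        if rate in (0.0, 1.0):
            out.append(None)
        else:
            out.append(calibrate_intercept(rate, slope, sample))
    return tuple(out)


def _readmit_poisson_mean(frequent_rate: float) -> float:
    """Poisson mean lambda with P(count >= 2) = frequent_rate."""
    if frequent_rate <= 0:
        return 0.1  # arbitrary small mean for the 0/1 counts of a zero-rate band
    if frequent_rate >= 1:
        raise CalibrationError("frequent-readmission rate must be < 1")

    def excess(lam: float) -> float:
        return poisson.sf(1, lam) - frequent_rate

    return float(optimize.brentq(excess, 1e-12, 60.0, xtol=1e-12))


def _draw_conditional_counts(
    rng: np.random.Generator, frequent: np.ndarray, lam: float, max_count: int = 30
) -> np.ndarray:
    """Readmission counts from Poisson(lam) conditioned on the frequent flag."""
    counts = np.zeros(frequent.shape, dtype=np.int64)
    pmf = poisson.pmf(np.arange(max_count + 1), lam)
    lo, hi = pmf[:2], pmf[2:]
    n_non, n_freq = int((~frequent).sum()), int(frequent.sum())
    if n_non:
        counts[~frequent] = rng.choice(2, size=n_non, p=lo / lo.sum())
    if n_freq:
        counts[frequent] = 2 + rng.choice(len(hi), size=n_freq, p=hi / hi.sum())
    return counts


def _simulate_band(
    rng: np.random.Generator,
    config: CohortConfig,
    band_index: int,
) -> Dict[str, np.ndarray]:
    n = config.n_per_band[band_index]
    lo, hi = config.band_intervals()[band_index]
    cp = config.component_params
    slope = config.slopes_per_band()[band_index]

    ages = rng.uniform(lo, hi, size=n)
    # geometric on {1,2,...} shifted to {0,1,...} with mean los_mean_days
    los = rng.geometric(1.0 / (1.0 + cp.los_mean_days), size=n) - 1
    emergent = rng.random(n) < cp.p_emergent
    ed = np.minimum(rng.poisson(cp.ed_mean_visits, size=n), cp.ed_max_visits)
    charlson = rng.choice(11, size=n, p=np.asarray(cp.charlson_probs))
    score = lace_total_array(los, emergent, charlson, ed)

    def draw(outcome: str) -> np.ndarray:
        rate = config.band_outcome_rates[outcome][band_index]
        if rate == 0.0:
            return np.zeros(n, dtype=bool)
        if rate == 1.0:
            return np.ones(n, dtype=bool)
        c = calibrate_intercept(rate, slope, score)
        p = expit(c + slope * (score - score.mean()))
        return rng.random(n) < p

    died_6mo = draw("death_6mo")
    r6 = config.band_outcome_rates["death_6mo"][band_index]
    r30 = config.band_outcome_rates["death_30d"][band_index]
    ratio = (r30 / r6) if r6 > 0 else 0.0
    died_30d = died_6mo & (rng.random(n) < ratio)

    frequent = draw("frequent_readmit")
    lam = _readmit_poisson_mean(config.band_outcome_rates["frequent_readmit"][band_index])
    readmits = _draw_conditional_counts(rng, frequent, lam)

    return {
        "age_years": ages,
        "acuity_emergent": emergent,
        "length_of_stay_days": los,
        "charlson_index": charlson,
        "ed_visits_6mo": ed,
        "lace_total": score,
        "died_within_30d": died_30d,
        "died_within_6mo": died_6mo,
        "readmissions_28d": readmits,
    }


def simulate_frame(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort as a DataFrame (vectorised; one row per episode).

    Includes the generation-time ``charlson_index`` and ``lace_total``
    convenience columns alongside the canonical episode fields; the
    downstream scorer recomputes both from the raw fields.
    """
    rng = np.random.default_rng(config.seed)
    parts = [_simulate_band(rng, config, b) for b in range(len(config.n_per_band))]
    df = pd.concat([pd.DataFrame(p) for p in parts], ignore_index=True)
    df.insert(0, "episode_id", [f"E{i:07d}" for i in range(len(df))])
    if config.component_params.emit_icd10:
        codes = [";".join(_CODES_FOR_INDEX[k]) for k in df["charlson_index"]]
    else:
        codes = [""] * len(df)
    df.insert(4, "icd10_codes", codes)
    return df


def generate_cohort(config: CohortConfig) -> Tuple[EpisodeRecord, ...]:
    """Generate a cohort as a tuple of :class:`EpisodeRecord`.

    Deterministic given ``config.seed``; per-band record counts equal
    ``n_per_band`` exactly.
    """
    df = simulate_frame(config)
    return tuple(
        EpisodeRecord(
            episode_id=row.episode_id,
            age_years=float(row.age_years),
            acuity_emergent=bool(row.acuity_emergent),
            length_of_stay_days=int(row.length_of_stay_days),
            icd10_codes=tuple(c for c in row.icd10_codes.split(";") if c),
            ed_visits_6mo=int(row.ed_visits_6mo),
            died_within_30d=bool(row.died_within_30d),
            died_within_6mo=bool(row.died_within_6mo),
            readmissions_28d=int(row.readmissions_28d),
        )
        for row in df.itertuples(index=False)
    )


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV with the documented column set."""
    df.loc[:, list(CSV_COLUMNS)].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate an episode CSV; raises on schema violations.

    Error messages cite the 1-based data line number of the first offending
    row for each failed check.
    """
    df = pd.read_csv(path, dtype={"icd10_codes": str}, keep_default_na=False)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"episode CSV missing required columns: {sorted(missing)}")

    def first_bad(mask: np.ndarray, message: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask)[0]) + 1
            raise ValueError(f"line {line}: {message}")

    for col in ("acuity_emergent", "died_within_30d", "died_within_6mo"):
        df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False,
                                                       "1": True, "0": False})
        first_bad(df[col].isna().to_numpy(), f"{col} is not a boolean")
        df[col] = df[col].astype(bool)
    for col in ("length_of_stay_days", "ed_visits_6mo", "readmissions_28d"):
        vals = pd.to_numeric(df[col], errors="coerce")
        first_bad(vals.isna().to_numpy(), f"{col} is not numeric")
        first_bad((vals < 0).to_numpy(), f"{col} is negative")
        df[col] = vals.astype(np.int64)
    ages = pd.to_numeric(df["age_years"], errors="coerce")
    first_bad(ages.isna().to_numpy(), "age_years is not numeric")
    first_bad((ages < 18).to_numpy(), "age_years below the adult cohort minimum of 18")
    df["age_years"] = ages.astype(float)
    first_bad(
        (df["died_within_30d"] & ~df["died_within_6mo"]).to_numpy(),
        "died_within_30d set without died_within_6mo",
    )
    return df


def cohort_to_frame(records: Sequence[EpisodeRecord]) -> pd.DataFrame:
    """Convert EpisodeRecord objects to the canonical episode table."""
    return pd.DataFrame(
        {
            "episode_id": [r.episode_id for r in records],
            "age_years": [r.age_years for r in records],
            "acuity_emergent": [r.acuity_emergent for r in records],
            "length_of_stay_days": [r.length_of_stay_days for r in records],
            "icd10_codes": [";".join(r.icd10_codes) for r in records],
            "ed_visits_6mo": [r.ed_visits_6mo for r in records],
            "died_within_30d": [r.died_within_30d for r in records],
            "died_within_6mo": [r.died_within_6mo for r in records],
            "readmissions_28d": [r.readmissions_28d for r in records],
        }
    )
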
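"""ROC/AUC estimation, likelihood ratios and two-graph threshold derivation.

The positivity convention throughout is ``score >= t  =>  test-positive``,
so for a threshold grid ``t`` spanning [min score, max score + 1]:

* ``sensitivity(t)`` = fraction of events with score >= t (non-increasing),
* ``specificity(t)`` = fraction of non-events with score < t (non-decreasing).

The AUC is the concordance (Mann-Whitney) probability with ties counted
one-half, and its 95% confidence interval uses the Hanley-McNeil
nonparametric standard error by default (DeLong available for
cross-checking).

The *two-graph* ROC analysis plots sensitivity and specificity against the
threshold itself.  Treating both as piecewise-linear between grid points,
their intersection theta_0 is the equal-error threshold (maximum balanced
accuracy), and the *intermediate range* IR is bounded below by the threshold
where sensitivity falls to a chosen accuracy level (default 95%) and above
by the threshold where specificity reaches it; results between the bounds
are "borderline".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats


class UndefinedAucError(ValueError):
    """ROC analysis needs at least one event and one non-event."""


class NoCrossingError(ValueError):
    """The sensitivity and specificity curves never cross."""


@dataclass(frozen=True)
class RocCurve:
    """Per-threshold sensitivity/specificity step curves with AUC and CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci: Tuple[float, float]
    n_pos: int
    n_neg: int

    def sens_at(self, t: float) -> float:
        """Sensitivity at a (possibly fractional) threshold, linear between grid points."""
        return float(np.interp(t, self.thresholds, self.sensitivity))

    def spec_at(self, t: float) -> float:
        return float(np.interp(t, self.thresholds, self.specificity))

    @property
    def p_value(self) -> float:
        """Two-sided z-test of AUC = 0.5 on the curve's standard error."""
        if self.auc_se == 0:
            return 0.0 if self.auc != 0.5 else 1.0
        z = (self.auc - 0.5) / self.auc_se
        return float(2 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class TwoGraphResult:
    """Equal-error threshold theta_0 and the intermediate range at ``level``."""

    theta0: float
    ir_lower: float
    ir_upper: float
    level: float
    clipped: Tuple[bool, bool] = (False, False)


@dataclass(frozen=True)
class LikelihoodRatios:
    """LR+ and LR- of the test "score >= threshold" for one outcome."""

    threshold: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil (1982) nonparametric standard error of the AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def delong_se(pos_scores: np.ndarray, neg_scores: np.ndarray) -> Tuple[float, float]:
    """AUC and DeLong (1988) standard error from raw class scores."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    m, n = len(pos), len(neg)
    # Placement values: V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i)
    all_scores = np.concatenate([pos, neg])
    mid_all = stats.rankdata(all_scores, method="average")
    mid_pos = stats.rankdata(pos, method="average")
    mid_neg = stats.rankdata(neg, method="average")
    v10 = (mid_all[:m] - mid_pos) / n
    v01 = 1.0 - (mid_all[m:] - mid_neg) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, math.sqrt(s10 / m + s01 / n)


def roc_curve(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    ci_method: str = "hanley-mcneil",
    ci_level: float = 0.95,
) -> RocCurve:
    """Build the ROC step curves and AUC for an ordinal score.

    Parameters
    ----------
    scores
        Episode scores (the LACE index, typically integers 0-19).
    outcomes
        Boolean event indicators, aligned with ``scores``.
    ci_method
        ``"hanley-mcneil"`` (default) or ``"delong"`` for the AUC standard
        error.

    Raises
    ------
    UndefinedAucError
        If the outcomes are all positive or all negative.
    ValueError
        If the two sequences differ in length.
    """
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes, dtype=bool)
    if scores.shape != outcomes.shape:
        raise ValueError(
            f"scores and outcomes lengths differ: {scores.shape} vs {outcomes.shape}"
        )
    n_pos = int(outcomes.sum())
    n_neg = int(len(outcomes) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAucError(
            f"AUC undefined with {n_pos} events and {n_neg} non-events"
        )

    pos = np.sort(scores[outcomes])
    neg = np.sort(scores[~outcomes])

    if np.issubdtype(scores.dtype, np.integer):
        thresholds = np.arange(int(scores.min()), int(scores.max()) + 2)
    else:
        uniq = np.unique(scores)
        thresholds = np.append(uniq, uniq[-1] + 1.0)

    # score >= t positives; searchsorted('left') counts scores < t
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / n_pos
    spec = np.searchsorted(neg, thresholds, side="left") / n_neg

    # Mann-Whitney concordance with ties counted 1/2, via the rank-sum identity
    ranks = stats.rankdata(scores, method="average")
    auc = float((ranks[outcomes].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))

    if ci_method == "hanley-mcneil":
        se = hanley_mcneil_se(auc, n_pos, n_neg)
    elif ci_method == "delong":
        _, se = delong_se(scores[outcomes], scores[~outcomes])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = stats.norm.ppf(0.5 + ci_level / 2)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))

    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _solve_crossing(t: np.ndarray, diff: np.ndarray) -> float:
    """Root of a non-increasing piecewise-linear function sampled at t.

    A flat zero stretch yields its midpoint; otherwise linear interpolation
    within the sign-change segment.
    """
    zero = np.isclose(diff, 0.0, atol=1e-12)
    if zero.any():
        idx = np.flatnonzero(zero)
        return float((t[idx[0]] + t[idx[-1]]) / 2)
    sign_change = np.flatnonzero((diff[:-1] > 0) & (diff[1:] < 0))
    if len(sign_change) == 0:
        raise NoCrossingError(
            "sensitivity and specificity curves do not cross within the score range"
        )
    i = sign_change[0]
    frac = diff[i] / (diff[i] - diff[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def two_graph(curve: RocCurve, level: float = 0.95) -> TwoGraphResult:
    """Derive the equal-error threshold theta_0 and the intermediate range.

    ``theta0`` solves sensitivity(t) = specificity(t) under piecewise-linear
    interpolation; ``ir_lower`` solves sensitivity(t) = level and
    ``ir_upper`` solves specificity(t) = level.  Bounds unattainable within
    the score range are clipped to the range end and flagged in ``clipped``.
    """
    if not 0.5 < level < 1:
        raise ValueError(f"accuracy level must be in (0.5, 1), got {level}")
    t = np.asarray(curve.thresholds, dtype=float)
    sens = curve.sensitivity
    spec = curve.specificity

    diff = sens - spec
    if diff[0] < -1e-12:
        raise NoCrossingError(
            "specificity exceeds sensitivity at the smallest threshold; "
            "the two-graph curves have no crossing"
        )
    theta0 = _solve_crossing(t, diff)

    clipped_lo = clipped_hi = False
    # sensitivity starts near 1 and is non-increasing in t
    if sens[-1] >= level:
        ir_lower, clipped_lo = float(t[-1]), True
    elif sens[0] < level:
        ir_lower, clipped_lo = float(t[0]), True
    else:
        ir_lower = _solve_crossing(t, sens - level)
    # specificity is non-decreasing towards 1; solve on the reversed axis
    if spec[0] >= level:
        ir_upper, clipped_hi = float(t[0]), True
    elif spec[-1] < level:
        ir_upper, clipped_hi = float(t[-1]), True
    else:
        ir_upper = _solve_crossing(-t[::-1], spec[::-1] - level)
        ir_upper = -ir_upper
    return TwoGraphResult(
        theta0=theta0,
        ir_lower=ir_lower,
        ir_upper=ir_upper,
        level=level,
        clipped=(clipped_lo, clipped_hi),
    )


def likelihood_ratios(curve: RocCurve, threshold: float) -> LikelihoodRatios:
    """LR+ and LR- at a threshold, interpolating between grid points.

    A perfect specificity with non-zero sensitivity gives ``lr_pos = inf``
    (a valid, infinitely informative positive result), not an error.
    """
    t = curve.thresholds
    if not t[0] <= threshold <= t[-1]:
        raise ValueError(
            f"threshold {threshold} outside the curve's range [{t[0]}, {t[-1]}]"
        )
    sens = curve.sens_at(threshold)
    spec = curve.spec_at(threshold)
    if spec < 1:
        lr_pos = sens / (1 - spec)
    else:
        lr_pos = math.inf if sens > 0 else math.nan
    if spec > 0:
        lr_neg = (1 - sens) / spec
    else:
        lr_neg = math.inf if sens < 1 else math.nan
    return LikelihoodRatios(
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
    )
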
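import numpy as np
import pytest

from laceroc import CohortConfig, simulate_frame


def auc_brute_force(scores, outcomes):
    """All-pairs concordance with ties counted one half (independent oracle)."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    pos = scores[outcomes]
    neg = scores[~outcomes]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def small_cohort():
    """Down-scaled five-band cohort (~3,200 episodes) with default rates."""
    config = CohortConfig(
        n_per_band=(840, 430, 474, 607, 876),
        discrimination_slope=0.5,
        seed=2026,
    )
    return simulate_frame(config)
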
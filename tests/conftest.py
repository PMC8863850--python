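import numpy as np
import pandas as pd
import pytest

from lnmrisk.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but signal-bearing cohort reused across read-only tests."""
    return generate_cohort(CohortConfig(n_cases=150, seed=42))


@pytest.fixture()
def toy_case_tiles():
    """The four-tile worked example used for hand-checked feature values."""
    return pd.DataFrame(
        {
            "case_id": ["case_x"] * 4,
            "tile_id": ["t0", "t1", "t2", "t3"],
            "p_cancer": [0.9, 0.95, 0.85, 0.99],
            "p_met": [0.95, 0.85, 0.15, 0.55],
        }
    )


def tier_fixture_scores(counts):
    """Scores/labels realised from per-tier (lo, hi, n_neg, n_pos) counts.

    Each case gets a score at its tier midpoint, so stratification must
    recover exactly the given contingency counts.
    """
    scores, labels = [], []
    for lo, hi, n_neg, n_pos in counts:
        mid = (lo + hi) / 2
        scores.extend([mid] * (n_neg + n_pos))
        labels.extend([0] * n_neg + [1] * n_pos)
    return np.asarray(scores), np.asarray(labels)
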
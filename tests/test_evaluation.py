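import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lnmrisk.evaluation import (
    DEFAULT_RISK_TIERS,
    DEFAULT_SCORE_CUTOFF,
    UndefinedAUCError,
    assign_tier,
    balanced_cutoff,
    fisher_or,
    roc_and_auc,
    stratify,
    two_group_t,
)
from conftest import tier_fixture_scores


def mann_whitney_auc(pos, neg):
    """Brute-force concordance: P(pos > neg) + 0.5 P(tie) over all pairs."""
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        if p > n:
            wins += 1
        elif p == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration of the 2x2
    tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_p(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = table_p(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


def test_auc_perfect_and_tied():
    roc = roc_and_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
    assert roc.auc == 1.0
    roc = roc_and_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
    assert roc.auc == 0.5


def test_auc_pair_enumeration_example():
    """Positives {0.9, 0.2}, negative {0.5}: 1 concordant of 2 pairs."""
    roc = roc_and_auc([0.9, 0.2, 0.5], [1, 1, 0])
    assert roc.auc == pytest.approx(mann_whitney_auc([0.9, 0.2], [0.5])) == 0.5


def test_auc_matches_brute_force_on_all_small_score_sets():
    """Tie-corrected AUC equals pair enumeration on every random score set
    with 2..5 positives x 2..5 negatives (scores drawn from a coarse grid
    to force ties)."""
    rng = np.random.default_rng(0)
    for n_pos in range(2, 6):
        for n_neg in range(2, 6):
            for _ in range(20):
                pos = rng.integers(0, 8, n_pos) / 8
                neg = rng.integers(0, 8, n_neg) / 8
                scores = np.concatenate([pos, neg])
                labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
                roc = roc_and_auc(scores, labels)
                assert roc.auc == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-12)


def test_auc_trapezoid_agreement_and_complement():
    rng = np.random.default_rng(3)
    scores = rng.random(80)
    labels = (rng.random(80) < 0.4).astype(int)
    roc = roc_and_auc(scores, labels)
    fpr = 1 - roc.specificity
    order = np.lexsort((roc.sensitivity, fpr))  # staircase order at fpr ties
    trap = np.trapezoid(roc.sensitivity[order], fpr[order])
    assert roc.auc == pytest.approx(trap, abs=1e-9)
    flipped = roc_and_auc(-scores, labels)
    assert roc.auc + flipped.auc == pytest.approx(1.0)  # tie-free scores


def test_roc_monotone_and_single_class_error():
    roc = roc_and_auc([0.1, 0.5, 0.9, 0.7], [0, 1, 1, 0])
    assert (np.diff(roc.sensitivity) <= 1e-12).all()
    with pytest.raises(UndefinedAUCError):
        roc_and_auc([0.1, 0.2], [1, 1])


def test_balanced_cutoff_exhaustive_sweep_oracle():
    scores = np.array([0.1, 0.2, 0.6, 0.5, 0.8, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    roc = roc_and_auc(scores, labels)
    cut = balanced_cutoff(roc)
    assert 0.5 < cut <= 0.6
    sens = (scores[labels == 1] >= cut).mean()
    spec = (scores[labels == 0] < cut).mean()
    assert sens == spec == pytest.approx(2 / 3)
    # independent sweep over all candidate thresholds
    best = min(
        np.concatenate([[scores.min() - 1], np.unique(scores)]),
        key=lambda t: (
            abs((scores[labels == 1] >= t).mean() - (scores[labels == 0] < t).mean()),
            t,
        ),
    )
    assert cut == best


def test_balanced_cutoff_tie_goes_low():
    """With perfect separation every threshold in the gap balances; the
    lowest candidate is returned."""
    roc = roc_and_auc([0.3, 0.4, 0.8, 0.9], [0, 0, 1, 1])
    assert balanced_cutoff(roc) == 0.8


def test_published_operating_point_is_the_default():
    assert DEFAULT_SCORE_CUTOFF == 0.70


def test_stratification_reproduces_training_contingency():
    scores, labels = tier_fixture_scores(
        [(0.0, 0.7, 418, 0), (0.7, 0.8, 43, 5), (0.8, 0.9, 39, 29), (0.9, 1.0, 5, 9)]
    )
    tab = stratify(scores, labels)
    assert list(np.round(tab["lnm_pct"], 1)) == [0.0, 10.4, 42.6, 64.3]
    assert tab["n_negative"].sum() + tab["n_positive"].sum() == 548


def test_stratification_reproduces_validation_contingency():
    scores, labels = tier_fixture_scores(
        [(0.0, 0.7, 162, 4), (0.7, 0.8, 26, 3), (0.8, 0.9, 27, 9), (0.9, 1.0, 2, 2)]
    )
    tab = stratify(scores, labels)
    assert list(np.round(tab["lnm_pct"], 1)) == [2.4, 10.3, 25.0, 50.0]


def test_empty_tier_reports_nan_not_zero():
    tab = stratify([0.05, 0.95], [0, 1])
    low = tab.set_index("tier")
    assert math.isnan(low.loc["low", "lnm_pct"])
    assert low.loc["low", "n_negative"] == 0


def test_tier_partition_and_boundaries():
    assert assign_tier(0.0) == "very-low"
    assert assign_tier(0.7) == "low"  # half-open [0.7, 0.8)
    assert assign_tier(0.9) == "high"
    assert assign_tier(1.0) == "high"  # top tier closed
    grid = np.linspace(0, 1, 1001)
    tab = stratify(grid, np.zeros(1001, int))
    assert tab["n_negative"].sum() == 1001


def test_t_test_summary_matches_raw_and_symmetry():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 25)
    t_raw, p_raw = two_group_t(a, b)
    t_sum, p_sum = two_group_t(
        None, summary1=(a.mean(), a.std(ddof=1), 30), summary2=(b.mean(), b.std(ddof=1), 25)
    )
    assert t_raw == pytest.approx(t_sum) and p_raw == pytest.approx(p_sum)
    t_sw, p_sw = two_group_t(b, a)
    assert t_sw == pytest.approx(-t_raw) and p_sw == pytest.approx(p_raw)
    ref = stats.ttest_ind(a, b)  # pooled-variance reference
    assert t_raw == pytest.approx(ref.statistic) and p_raw == pytest.approx(ref.pvalue)


def test_t_test_on_published_tile_proportion_summaries():
    """Negative-tile proportion, 50.18+-25.95 (n=505) vs 23.49+-15.32
    (n=43): overwhelmingly significant (p < 0.00001)."""
    t, p = two_group_t(
        None, summary1=(50.18, 25.95, 505), summary2=(23.49, 15.32, 43)
    )
    assert t > 0 and p < 1e-5


def test_t_test_degenerate_cases():
    t, p = two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0 and p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        two_group_t([1.0, 1.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        two_group_t([1.0], [1.0, 2.0])


def test_fisher_no_association_and_scale_invariance():
    or1, p1 = fisher_or([[10, 10], [10, 10]])
    assert or1 == 1.0 and p1 == pytest.approx(1.0)
    or2, _ = fisher_or([[20, 20], [20, 20]])
    assert or2 == or1
    or3, _ = fisher_or([[6, 2], [4, 8]])
    or4, _ = fisher_or([[12, 4], [8, 16]])
    assert or3 == pytest.approx(or4) == pytest.approx(6.0)


def test_fisher_on_published_location_table():
    """Rectum vs non-rectum x LNM in the training set: p ~ 0.008."""
    _, p = fisher_or([[24, 19], [174, 331]])
    assert p == pytest.approx(0.008, abs=0.001)


def test_fisher_matches_hypergeometric_enumeration():
    """Library p equals the brute-force enumeration for all 2x2 tables with
    small margins (spot lattice with margins <= 30)."""
    rng = np.random.default_rng(1)
    for _ in range(150):
        a, b, c, d = rng.integers(0, 16, 4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        _, p = fisher_or([[a, b], [c, d]])
        assert p == pytest.approx(fisher_p_enumeration(int(a), int(b), int(c), int(d)), abs=1e-9)


def test_fisher_input_validation():
    with pytest.raises(ValueError):
        fisher_or([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        fisher_or([[0, 0], [3, 4]])  # zero margin
    with pytest.raises(ValueError):
        fisher_or([[1.5, 2], [3, 4]])
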
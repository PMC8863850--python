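"""ROC/AUC, the balanced-error operating point, risk-tier stratification,
and the group-comparison statistics used in the case tables.

AUC is the tie-corrected Mann–Whitney concordance probability (equal to the
trapezoidal area under the ROC curve).  The decision cutoff is chosen at the
balanced error rate — the threshold where sensitivity and specificity are
closest, ties resolved toward the lower threshold; the published operating
point for the case score is 0.70, exposed as ``DEFAULT_SCORE_CUTOFF``.

Risk tiers partition the [0, 1] score range as half-open intervals with the
top tier closed: [0, 0.7) very-low, [0.7, 0.8) low, [0.8, 0.9) moderate,
[0.9, 1.0] high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

#: score threshold at which sensitivity and specificity balanced in the
#: published model; the package default for binary decisions on case scores
DEFAULT_SCORE_CUTOFF = 0.70

#: (lo, hi, name) risk tiers; intervals half-open [lo, hi), top closed at 1
DEFAULT_RISK_TIERS = (
    (0.0, 0.7, "very-low"),
    (0.7, 0.8, "low"),
    (0.8, 0.9, "moderate"),
    (0.9, 1.0, "high"),
)


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one outcome class is present."""


@dataclass
class ROCData:
    """ROC operating points: positive call when score >= threshold."""

    thresholds: np.ndarray  # ascending candidate thresholds
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_and_auc(scores, labels) -> ROCData:
    """ROC operating points over all distinct thresholds plus the AUC.

    ``labels`` are binary (1 = positive).  Thresholds are the distinct
    scores plus one below the minimum, so both all-positive and
    all-negative calls appear.  AUC comes from the rank statistic
    (tie-corrected Mann–Whitney), identical to trapezoidal integration of
    the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise UndefinedAUCError("both outcome classes required for a ROC curve")
    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    sens = np.array([(scores[pos] >= t).mean() for t in thresholds])
    spec = np.array([(scores[neg] < t).mean() for t in thresholds])
    auc = float(roc_auc_score(labels, scores))
    return ROCData(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def balanced_cutoff(roc: ROCData) -> float:
    """Threshold minimising |sensitivity − specificity|; ties → lower value."""
    gap = np.abs(roc.sensitivity - roc.specificity)
    return float(roc.thresholds[int(np.argmin(gap))])  # argmin takes first=lowest


def stratify(
    scores,
    labels,
    tiers: tuple = DEFAULT_RISK_TIERS,
) -> pd.DataFrame:
    """Count outcomes per risk tier and compute the per-tier positive rate.

    Returns a frame with one row per tier: boundaries, tier name, negative
    and positive counts, and ``lnm_pct`` = pos/(pos+neg)·100 (NaN for an
    empty tier, never 0).  Counts are checked to conserve the cohort size.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    rows = []
    total = 0
    top_hi = max(hi for _, hi, _ in tiers)
    for lo, hi, name in tiers:
        in_tier = (scores >= lo) & (scores < hi)
        if hi == top_hi:  # close the top tier so 1.0 belongs somewhere
            in_tier |= scores == hi
        n_neg = int(((labels == 0) & in_tier).sum())
        n_pos = int(((labels == 1) & in_tier).sum())
        n = n_neg + n_pos
        total += n
        rows.append(
            {
                "tier": name,
                "lo": lo,
                "hi": hi,
                "n_negative": n_neg,
                "n_positive": n_pos,
                "lnm_pct": (100.0 * n_pos / n) if n else np.nan,
            }
        )
    if total != scores.size:
        raise ValueError("tier map does not partition the score range")
    return pd.DataFrame(rows)


def assign_tier(score: float, tiers: tuple = DEFAULT_RISK_TIERS) -> str:
    """Risk-tier name for one case score."""
    top_hi = max(hi for _, hi, _ in tiers)
    for lo, hi, name in tiers:
        if lo <= score < hi or (hi == top_hi and score == hi):
            return name
    raise ValueError(f"score {score} outside every tier")


def two_group_t(
    group1,
    group2=None,
    *,
    summary1: tuple[float, float, int] | None = None,
    summary2: tuple[float, float, int] | None = None,
) -> tuple[float, float]:
    """Pooled-variance Student t-test, from raw samples or (mean, sd, n).

    Returns ``(t, p)`` two-sided.  Raises on zero pooled variance (the test
    is degenerate) or groups of fewer than 2 observations.
    """
    if summary1 is not None or summary2 is not None:
        if summary1 is None or summary2 is None:
            raise ValueError("provide both summaries or both raw samples")
        m1, s1, n1 = summary1
        m2, s2, n2 = summary2
    else:
        a = np.asarray(group1, dtype=float)
        b = np.asarray(group2, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs n >= 2")
        m1, s1, n1 = a.mean(), a.std(ddof=1), a.size
        m2, s2, n2 = b.mean(), b.std(ddof=1), b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 == 0 and s2 == 0 and m1 == m2:
        raise ValueError("zero pooled variance: degenerate t-test")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def fisher_or(table) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2×2 table.

    ``table`` is ``[[a, b], [c, d]]``; OR = (a·d)/(b·c), reported as ``inf``
    (or 0) when a zero cell makes it unbounded — no continuity correction is
    folded into the estimate.  The two-sided p sums, over the hypergeometric
    distribution of the top-left cell at fixed margins, all tables with
    probability at most that of the observed table (the common convention).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("a zero margin leaves the test undefined")
    (a, b), (c, d) = t
    if b * c == 0:
        oddsratio = float("inf") if a * d > 0 else 0.0
    else:
        oddsratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(oddsratio), float(p)


def plot_roc(roc: ROCData, path: str, label: str = "model") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr = 1 - roc.specificity
    order = np.argsort(fpr)
    ax.plot(fpr[order], roc.sensitivity[order], label=f"{label} (AUC={roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
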
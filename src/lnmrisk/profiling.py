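"""Cancer-tile selection, probability groups A–E, and probability histograms.

After the binary metastasis classifier has scored every cancer tile, tiles
are binned by metastatic probability ``p`` into five groups:

* **A** — confidently non-metastatic, non-metastatic probability > 0.9
  (``p < 0.1``);
* **B** — non-metastatic probability between 0.8 and 0.9
  (``0.1 <= p <= 0.2``);
* **C** — the unconfident middle, either probability < 0.8
  (``0.2 < p < 0.8``);
* **D** — metastatic probability between 0.8 and 0.9 (``0.8 <= p <= 0.9``);
* **E** — confidently metastatic, metastatic probability > 0.9
  (``p > 0.9``).

Boundary values (0.1, 0.2, 0.8, 0.9) are assigned to the more extreme
informative group (B/D); set ``boundary_to_extreme=False`` to push ties into
the neighbouring less extreme group instead (sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUP_LABELS = ("A", "B", "C", "D", "E")


def assign_group(p_met: float, boundary_to_extreme: bool = True) -> str:
    """Map one metastatic probability to its group label A–E."""
    p = float(p_met)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p_met must lie in [0, 1], got {p}")
    if boundary_to_extreme:
        if p < 0.1:
            return "A"
        if p <= 0.2:
            return "B"
        if p < 0.8:
            return "C"
        if p <= 0.9:
            return "D"
        return "E"
    # ties go to the less extreme neighbour: B = (0.1, 0.2), D = (0.8, 0.9)
    if p <= 0.1:
        return "A"
    if p < 0.2:
        return "B"
    if p <= 0.8:
        return "C"
    if p < 0.9:
        return "D"
    return "E"


def assign_groups(p_met, boundary_to_extreme: bool = True) -> np.ndarray:
    """Vectorised :func:`assign_group` over an array of probabilities."""
    p = np.asarray(p_met, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p_met values must lie in [0, 1]")
    labels = np.asarray(GROUP_LABELS)
    if boundary_to_extreme:
        idx = np.select(
            [p < 0.1, p <= 0.2, p < 0.8, p <= 0.9], [0, 1, 2, 3], default=4
        )
    else:
        idx = np.select(
            [p <= 0.1, p < 0.2, p <= 0.8, p < 0.9], [0, 1, 2, 3], default=4
        )
    return labels[idx]


def select_cancer_tiles(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Keep records with cancer-class probability strictly above ``cutoff``.

    The strict ``>`` matters at the published operating points: a tile with
    ``p_cancer`` exactly 0.8 is excluded from classifier training (cutoff
    0.8) and one at exactly 0.5 is excluded from case scoring (cutoff 0.5).
    Order is preserved; an empty result is allowed.
    """
    return records.loc[records["p_cancer"] > cutoff]


@dataclass
class ProbabilityProfile:
    """Histogram of tile metastatic probabilities, split by case outcome."""

    bin_width: float
    bin_edges: np.ndarray
    counts: dict[int, np.ndarray]  # lnm label -> per-bin tile counts
    modal_bin: dict[int, tuple[float, float]]  # lnm label -> [lo, hi) of modal bin

    @property
    def n_tiles(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = {"bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:]}
        for label, c in sorted(self.counts.items()):
            rows[f"count_lnm{label}"] = c
        return pd.DataFrame(rows)


def build_profile(
    records: pd.DataFrame,
    case_labels: pd.Series | dict | None = None,
    bin_width: float = 0.01,
) -> ProbabilityProfile:
    """Histogram tile ``p_met`` per case outcome class.

    ``records`` needs ``p_met`` plus either an ``lnm_label`` column or a
    ``case_id`` column resolvable through ``case_labels``.  The modal bin is
    reported per class as its ``[lo, hi)`` interval.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    if "lnm_label" in records.columns:
        labels = records["lnm_label"].to_numpy()
    else:
        if case_labels is None:
            raise ValueError("need lnm_label column or case_labels mapping")
        mapping = (
            case_labels if isinstance(case_labels, dict) else dict(case_labels)
        )
        labels = records["case_id"].map(mapping).to_numpy()
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts: dict[int, np.ndarray] = {}
    modal: dict[int, tuple[float, float]] = {}
    p = records["p_met"].to_numpy(dtype=float)
    for label in np.unique(labels):
        c, _ = np.histogram(p[labels == label], bins=edges)
        counts[int(label)] = c
        k = int(np.argmax(c))
        modal[int(label)] = (float(edges[k]), float(edges[k + 1]))
    return ProbabilityProfile(
        bin_width=bin_width, bin_edges=edges, counts=counts, modal_bin=modal
    )


def plot_profile(profile: ProbabilityProfile, path: str) -> None:
    """Bar plot of the per-class tile-probability histograms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(profile.counts), 1, figsize=(7, 2.6 * len(profile.counts)), squeeze=False
    )
    centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
    names = {0: "LNM-negative cases", 1: "LNM-positive cases"}
    for ax, (label, c) in zip(axes.ravel(), sorted(profile.counts.items())):
        ax.bar(centers, c, width=profile.bin_width, color="#356e9f")
        ax.set_title(names.get(label, f"class {label}"))
        ax.set_xlabel("metastatic probability")
        ax.set_ylabel("tiles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
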
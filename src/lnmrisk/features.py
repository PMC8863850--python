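"""Assembly of the 18-parameter per-case feature vector for case scoring.

For each case, the cancer tiles retained at the 0.5 cancer-probability
cutoff are summarised into 18 numbers: the ordinal tumor-location code;
counts of cancer tiles, metastasis-predicted (``p_met > 0.5``) and
non-metastasis-predicted tiles, and the five probability-group counts A–E;
the two percentage splits; the mean cancer probability; the mean metastatic
probability of metastasis-predicted tiles and the mean non-metastatic
probability of non-metastasis-predicted tiles; the three matching sample
standard deviations; and the probability score summary (PSS) — the sum over
tiles of cancer probability times metastatic probability.

The enumeration is data-driven (``FEATURE_NAMES``), so an alternative
18-parameter reading is a one-line change.  Standard deviations use the
sample (n−1) convention with sd = 0 for a single tile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiling import assign_groups, select_cancer_tiles

LOCATION_SITES = {
    "cecum": 1,
    "ascending": 1,
    "transverse": 1,
    "descending": 2,
    "sigmoid": 2,
    "rectum": 3,
}

FEATURE_NAMES = [
    "location_code",
    "n_cancer_tiles",
    "n_met_tiles",
    "n_nonmet_tiles",
    "n_groupA",
    "n_groupB",
    "n_groupC",
    "n_groupD",
    "n_groupE",
    "pct_met",
    "pct_nonmet",
    "mean_p_cancer",
    "mean_p_met_of_met_tiles",
    "mean_p_nonmet_of_nonmet_tiles",
    "sd_p_cancer",
    "sd_p_met",
    "sd_p_nonmet",
    "probability_score_summary",
]

FEATURE_SCHEMA_VERSION = "1"

MET_TILE_CUTOFF = 0.5  # tile counted as metastasis-predicted when p_met > 0.5


class ExcludedCaseError(ValueError):
    """Case has no cancer tile after the cutoff and cannot be scored."""


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    lnm_label: int
    location_group: int
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.location_group not in (1, 2, 3):
            raise ValueError("location_group must be 1, 2 or 3")


def encode_location(site: str) -> int:
    """Map an anatomic site name to its ordinal location group.

    Group 1: cecum, ascending and transverse colon; group 2: descending and
    sigmoid colon; group 3: rectum.
    """
    key = site.strip().lower().replace(" colon", "")
    if key not in LOCATION_SITES:
        raise ValueError(
            f"unknown site {site!r}; expected one of {sorted(LOCATION_SITES)}"
        )
    return LOCATION_SITES[key]


def probability_score_summary(tiles: pd.DataFrame) -> float:
    """Per-case PSS: sum over tiles of ``p_cancer * p_met``.

    An empty tile set yields 0 with a warning (such a case is normally
    excluded upstream).
    """
    if len(tiles) == 0:
        warnings.warn("probability score summary of an empty tile set is 0", stacklevel=2)
        return 0.0
    return float((tiles["p_cancer"] * tiles["p_met"]).sum())


def _sample_sd(x: np.ndarray) -> float:
    if x.size <= 1:
        return 0.0
    return float(np.std(x, ddof=1))


def assemble_features(
    case: CaseRecord | pd.Series | dict,
    tiles: pd.DataFrame,
    boundary_to_extreme: bool = True,
) -> pd.Series:
    """Build the 18-feature vector for one case from its cancer tiles.

    ``tiles`` must already be restricted to the case's cancer tiles (post
    0.5-cutoff) and carry ``p_cancer`` and ``p_met``.  Raises
    :class:`ExcludedCaseError` when no tile is available — such cases are
    flagged, not scored, mirroring the exclusion of cases in which no
    cancer tile is detected.
    """
    if isinstance(case, CaseRecord):
        location = case.location_group
    else:
        location = int(case["location_group"])
    n = len(tiles)
    if n == 0:
        raise ExcludedCaseError("no cancer tile after cutoff; case excluded")

    p_cancer = tiles["p_cancer"].to_numpy(dtype=float)
    p_met = tiles["p_met"].to_numpy(dtype=float)
    met_mask = p_met > MET_TILE_CUTOFF
    n_met = int(met_mask.sum())
    n_nonmet = n - n_met

    groups = assign_groups(p_met, boundary_to_extreme=boundary_to_extreme)
    g_counts = {g: int((groups == g).sum()) for g in "ABCDE"}

    p_met_met = p_met[met_mask]
    p_nonmet_nonmet = 1.0 - p_met[~met_mask]

    values = {
        "location_code": float(location),
        "n_cancer_tiles": float(n),
        "n_met_tiles": float(n_met),
        "n_nonmet_tiles": float(n_nonmet),
        "n_groupA": float(g_counts["A"]),
        "n_groupB": float(g_counts["B"]),
        "n_groupC": float(g_counts["C"]),
        "n_groupD": float(g_counts["D"]),
        "n_groupE": float(g_counts["E"]),
        "pct_met": 100.0 * n_met / n,
        "pct_nonmet": 100.0 * n_nonmet / n,
        "mean_p_cancer": float(p_cancer.mean()),
        "mean_p_met_of_met_tiles": float(p_met_met.mean()) if n_met else 0.0,
        "mean_p_nonmet_of_nonmet_tiles": (
            float(p_nonmet_nonmet.mean()) if n_nonmet else 0.0
        ),
        "sd_p_cancer": _sample_sd(p_cancer),
        "sd_p_met": _sample_sd(p_met_met),
        "sd_p_nonmet": _sample_sd(p_nonmet_nonmet),
        "probability_score_summary": probability_score_summary(tiles),
    }
    return pd.Series([values[k] for k in FEATURE_NAMES], index=FEATURE_NAMES)


def build_feature_table(
    cases: pd.DataFrame,
    tiles: pd.DataFrame,
    cancer_cutoff: float = 0.5,
    boundary_to_extreme: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature vectors for a whole cohort.

    Applies the strict cancer-probability cutoff, assembles one row per
    case, and returns ``(features, excluded_case_ids)`` where the features
    frame is indexed by ``case_id`` and carries the 18 feature columns plus
    ``lnm_label``.  Cases with no surviving cancer tile are excluded and
    listed, never silently dropped.
    """
    kept = select_cancer_tiles(tiles, cancer_cutoff)
    grouped = dict(tuple(kept.groupby("case_id", sort=False)))
    rows, labels, ids, excluded = [], [], [], []
    for _, case in cases.iterrows():
        cid = case["case_id"]
        case_tiles = grouped.get(cid)
        if case_tiles is None or len(case_tiles) == 0:
            excluded.append(cid)
            continue
        rows.append(
            assemble_features(case, case_tiles, boundary_to_extreme=boundary_to_extreme)
        )
        labels.append(int(case["lnm_label"]))
        ids.append(cid)
    if rows:
        features = pd.DataFrame(rows, index=pd.Index(ids, name="case_id"))
    else:
        features = pd.DataFrame(
            columns=FEATURE_NAMES, index=pd.Index([], name="case_id"), dtype=float
        )
    features["lnm_label"] = labels
    return features, excluded
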
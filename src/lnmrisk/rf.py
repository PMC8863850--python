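"""Oversampled random-forest ensemble case scoring.

Case-level class imbalance (~10:1 negative:positive) is handled by randomly
oversampling the minority class with replacement until the counts are
equal.  Many candidate forests (default 500) that differ only in their
random seed are trained on the balanced table; each candidate is scored by
its AUC on the *original, unbalanced* training cases (scoring on the
oversampled table would let duplicated positives inflate the AUC), and the
top ``top_k`` (default 20) by selection AUC are retained.  A case's score is
the **maximum** predicted metastatic probability across the retained
members — a deliberately sensitivity-first aggregation that trades false
positives for fewer missed metastatic cases.  Feature importance is the
impurity-decrease importance averaged over the retained members.

Default hyperparameters (tree depth 6, 60 trees per forest) are the tuned
operating point of the published model; :func:`tune_hyperparameters` sweeps
a (depth, trees) grid and reports the AUC surface for both sets.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import DEFAULT_RISK_TIERS, assign_tier, roc_and_auc

DEFAULT_N_CANDIDATES = 500
DEFAULT_TOP_K = 20
DEFAULT_DEPTH = 6
DEFAULT_N_TREES = 60

#: default (depth, trees) tuning grid
DEFAULT_DEPTH_GRID = tuple(range(3, 11))
DEFAULT_TREES_GRID = (20, 40, 60, 80, 100)


def _schema_hash(feature_names: list[str]) -> str:
    return hashlib.sha256("|".join(feature_names).encode()).hexdigest()[:16]


def _member_seeds(master_seed: int, n: int) -> np.ndarray:
    # SeedSequence gives independent, reproducible per-member streams
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def oversample_balance(
    features: pd.DataFrame, labels: pd.Series, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Equalise class counts by sampling the minority class with replacement.

    The majority class is untouched; extra minority rows are drawn uniformly
    with replacement (so an individual minority case may be absent from the
    *resampled* draw — only the final count is guaranteed).  Already
    balanced input is returned unchanged.
    """
    labels = pd.Series(np.asarray(labels, dtype=int), index=features.index)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both outcome classes required for balancing")
    if counts.iloc[0] == counts.iloc[1]:
        return features, labels
    minority = counts.idxmin()
    n_extra = int(counts.max() - counts.min())
    rng = np.random.default_rng(seed)
    pool = features.index[labels == minority]
    extra_idx = rng.choice(pool, size=n_extra, replace=True)
    bal_feats = pd.concat([features, features.loc[extra_idx]])
    bal_labels = pd.concat([labels, labels.loc[extra_idx]])
    return bal_feats, bal_labels


@dataclass
class RFEnsemble:
    """Top-k forests retained from a seeded candidate sweep."""

    members: list[RandomForestClassifier]
    member_seeds: np.ndarray
    selection_aucs: np.ndarray  # per retained member, non-increasing
    depth: int
    n_trees: int
    feature_names: list[str]
    all_candidate_aucs: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def schema_hash(self) -> str:
        return _schema_hash(self.feature_names)

    def save(self, out_dir: str | os.PathLike) -> None:
        import joblib

        os.makedirs(out_dir, exist_ok=True)
        for i, m in enumerate(self.members):
            joblib.dump(m, os.path.join(out_dir, f"member_{i:02d}.joblib"))
        manifest = {
            "member_seeds": [int(s) for s in self.member_seeds],
            "selection_aucs": [float(a) for a in self.selection_aucs],
            "depth": self.depth,
            "n_trees": self.n_trees,
            "feature_names": self.feature_names,
            "schema_hash": self.schema_hash,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, in_dir: str | os.PathLike) -> "RFEnsemble":
        import joblib

        with open(os.path.join(in_dir, "manifest.json")) as fh:
            manifest = json.load(fh)
        members = [
            joblib.load(os.path.join(in_dir, f"member_{i:02d}.joblib"))
            for i in range(len(manifest["selection_aucs"]))
        ]
        return cls(
            members=members,
            member_seeds=np.asarray(manifest["member_seeds"]),
            selection_aucs=np.asarray(manifest["selection_aucs"]),
            depth=manifest["depth"],
            n_trees=manifest["n_trees"],
            feature_names=manifest["feature_names"],
        )


def train_rf_ensemble(
    balanced_features: pd.DataFrame,
    balanced_labels: pd.Series,
    selection_features: pd.DataFrame | None = None,
    selection_labels: pd.Series | None = None,
    n_candidates: int = DEFAULT_N_CANDIDATES,
    top_k: int = DEFAULT_TOP_K,
    depth: int = DEFAULT_DEPTH,
    n_trees: int = DEFAULT_N_TREES,
    master_seed: int = 0,
) -> RFEnsemble:
    """Train ``n_candidates`` seeded forests and keep the ``top_k`` by AUC.

    Candidates share hyperparameters and differ only in their random seed
    (bootstrap and feature-subsampling streams).  Selection AUC is computed
    on ``selection_features``/``selection_labels`` — normally the original
    unbalanced training cases; when omitted, the balanced table is used.
    Ties in the ranking are broken stably by candidate order.
    """
    if top_k > n_candidates:
        raise ValueError("top_k cannot exceed n_candidates")
    y = np.asarray(balanced_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required")
    if selection_features is None:
        selection_features, selection_labels = balanced_features, balanced_labels
    sel_y = np.asarray(selection_labels, dtype=int)
    X = balanced_features.to_numpy(dtype=float)
    sel_X = selection_features.to_numpy(dtype=float)

    seeds = _member_seeds(master_seed, n_candidates)
    models, aucs = [], np.empty(n_candidates)
    for i, s in enumerate(seeds):
        m = RandomForestClassifier(
            n_estimators=n_trees, max_depth=depth, random_state=int(s)
        )
        m.fit(X, y)
        pos_col = int(np.flatnonzero(m.classes_ == 1)[0])
        aucs[i] = roc_and_auc(m.predict_proba(sel_X)[:, pos_col], sel_y).auc
        models.append(m)
    order = np.argsort(-aucs, kind="stable")[:top_k]
    return RFEnsemble(
        members=[models[i] for i in order],
        member_seeds=seeds[order],
        selection_aucs=aucs[order],
        depth=depth,
        n_trees=n_trees,
        feature_names=list(balanced_features.columns),
        all_candidate_aucs=aucs,
    )


def fit_rf_scorer(
    features: pd.DataFrame,
    labels: pd.Series,
    n_candidates: int = DEFAULT_N_CANDIDATES,
    top_k: int = DEFAULT_TOP_K,
    depth: int = DEFAULT_DEPTH,
    n_trees: int = DEFAULT_N_TREES,
    master_seed: int = 0,
) -> RFEnsemble:
    """Convenience wrapper: oversample, train candidates, select on the
    original unbalanced cases."""
    bal_X, bal_y = oversample_balance(features, labels, seed=master_seed)
    return train_rf_ensemble(
        bal_X,
        bal_y,
        selection_features=features,
        selection_labels=labels,
        n_candidates=n_candidates,
        top_k=top_k,
        depth=depth,
        n_trees=n_trees,
        master_seed=master_seed,
    )


def member_probabilities(ensemble: RFEnsemble, features: pd.DataFrame) -> np.ndarray:
    """(n_cases, n_members) matrix of per-member metastatic probabilities."""
    if list(features.columns) != ensemble.feature_names:
        raise ValueError(
            "feature schema mismatch: expected "
            f"{ensemble.feature_names}, got {list(features.columns)}"
        )
    X = features.to_numpy(dtype=float)
    cols = []
    for m in ensemble.members:
        pos_col = int(np.flatnonzero(m.classes_ == 1)[0])
        cols.append(m.predict_proba(X)[:, pos_col])
    return np.column_stack(cols)


def rf_score(
    ensemble: RFEnsemble,
    features: pd.DataFrame,
    tiers: tuple = DEFAULT_RISK_TIERS,
) -> pd.DataFrame:
    """Score cases: max member probability, plus the risk tier.

    Returns a frame indexed like ``features`` with ``rf_score``, ``tier``
    and one ``member_<i>`` column per ensemble member.
    """
    probs = member_probabilities(ensemble, features)
    score = probs.max(axis=1)
    out = pd.DataFrame(
        {"rf_score": score, "tier": [assign_tier(s, tiers) for s in score]},
        index=features.index,
    )
    for i in range(probs.shape[1]):
        out[f"member_{i:02d}"] = probs[:, i]
    return out


def feature_importance(ensemble: RFEnsemble) -> pd.Series:
    """Impurity-decrease importances averaged over the retained members."""
    imp = np.mean([m.feature_importances_ for m in ensemble.members], axis=0)
    return pd.Series(imp, index=ensemble.feature_names).sort_values(ascending=False)


def tune_hyperparameters(
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    val_features: pd.DataFrame,
    val_labels: pd.Series,
    depth_grid: tuple = DEFAULT_DEPTH_GRID,
    trees_grid: tuple = DEFAULT_TREES_GRID,
    n_candidates: int = 20,
    top_k: int = 5,
    master_seed: int = 0,
) -> tuple[tuple[int, int], pd.DataFrame]:
    """Sweep (depth, trees), recording ensemble AUC on both sets.

    Returns the validation-optimal pair (ties → smaller depth, then fewer
    trees, guaranteed by sweep order) and the full AUC surface.
    """
    if not depth_grid or not trees_grid:
        raise ValueError("grid must be non-empty")
    rows = []
    best, best_auc = None, -np.inf
    for depth in sorted(depth_grid):
        for trees in sorted(trees_grid):
            ens = fit_rf_scorer(
                train_features,
                train_labels,
                n_candidates=n_candidates,
                top_k=top_k,
                depth=depth,
                n_trees=trees,
                master_seed=master_seed,
            )
            auc_tr = roc_and_auc(
                rf_score(ens, train_features)["rf_score"], train_labels
            ).auc
            auc_val = roc_and_auc(
                rf_score(ens, val_features)["rf_score"], val_labels
            ).auc
            rows.append(
                {
                    "depth": depth,
                    "n_trees": trees,
                    "auc_train": auc_tr,
                    "auc_validation": auc_val,
                }
            )
            if auc_val > best_auc:  # strict >: first (smallest) wins ties
                best, best_auc = (depth, trees), auc_val
    return best, pd.DataFrame(rows)
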
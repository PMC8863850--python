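"""End-to-end orchestration: cohort → features → ensemble → scores → tiers.

The pipeline runs its stages in dependency order, writing each stage's
artifacts (CSV/JSON) into the run directory and finishing with a run
manifest that records the configuration, per-stage row counts and a SHA-256
hash of every artifact — re-running with the same config and seed
reproduces the same hashes.  A stage can be disabled, in which case its
outputs must already exist in the run directory (supplied by an earlier run
or externally), so the flow is resumable from any completed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation, mapping, rf
from .features import build_feature_table
from .synthetic import CohortConfig, generate_cohort
from .tiling import Tile, TileManifest


@dataclass
class RunConfig:
    """All pipeline parameters in one place; every published constant is
    configuration here, never hard-coded in stage logic."""

    out_dir: str = "run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    features: bool = True
    train_rf: bool = True
    score: bool = True
    stratify: bool = True
    render_maps: bool = True
    # synthetic cohort
    cohort: dict = field(default_factory=dict)
    # feature stage
    cancer_score_cutoff: float = 0.5
    boundary_to_extreme: bool = True
    # ensemble
    n_candidates: int = rf.DEFAULT_N_CANDIDATES
    top_k: int = rf.DEFAULT_TOP_K
    depth: int = rf.DEFAULT_DEPTH
    n_trees: int = rf.DEFAULT_N_TREES
    validation_fraction: float = 0.3
    # reporting
    n_map_cases: int = 2
    map_cell_size: int = mapping.DEFAULT_CELL_SIZE

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage '{stage}' needs missing artifact {path!r}; run the "
            "producing stage first or supply the file"
        )
    return path


def _grid_manifest_from_case(case_id: str, tiles: pd.DataFrame) -> tuple[TileManifest, pd.DataFrame]:
    """Lay one synthetic case's tiles on a near-square grid for mapping."""
    n = len(tiles)
    n_cols = max(1, int(math.ceil(math.sqrt(n))))
    n_rows = int(math.ceil(n / n_cols))
    ts = 299
    man = TileManifest(
        slide_id=case_id, width=n_cols * ts, height=n_rows * ts, tile_size=ts,
        threshold=110,
    )
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    for i, (r, c) in enumerate(zip(rows, cols)):
        man.tiles.append(
            Tile(
                slide_id=case_id, row=int(r), col=int(c), x0=int(c) * ts,
                y0=int(r) * ts, size_px=ts, min_gray=0 if i < n else 255,
                kept=i < n,
            )
        )
    records = tiles.reset_index(drop=True).copy()
    records["row"] = rows[: len(records)]
    records["col"] = cols[: len(records)]
    return man, records[["row", "col", "p_met"]]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "artifacts": {}}
    paths = {
        "cases": os.path.join(out, "cases.csv"),
        "tiles": os.path.join(out, "tiles.csv"),
        "features": os.path.join(out, "features.csv"),
        "scores": os.path.join(out, "scores.csv"),
        "stratification": os.path.join(out, "stratification.csv"),
    }

    if config.simulate:
        cohort = generate_cohort(CohortConfig(**{"seed": config.seed, **config.cohort}))
        cohort.cases.to_csv(paths["cases"], index=False)
        cohort.tiles.to_csv(paths["tiles"], index=False)
        manifest["stages"]["simulate"] = {
            "n_cases": len(cohort.cases),
            "n_tiles": len(cohort.tiles),
            "n_positive": int(cohort.cases["lnm_label"].sum()),
        }

    if config.features:
        cases = pd.read_csv(_require(paths["cases"], "features"))
        tiles = pd.read_csv(_require(paths["tiles"], "features"))
        feats, excluded = build_feature_table(
            cases,
            tiles,
            cancer_cutoff=config.cancer_score_cutoff,
            boundary_to_extreme=config.boundary_to_extreme,
        )
        feats.to_csv(paths["features"])
        with open(os.path.join(out, "features_schema.json"), "w") as fh:
            json.dump(
                {
                    "version": 1,
                    "feature_names": [c for c in feats.columns if c != "lnm_label"],
                    "excluded_cases": excluded,
                },
                fh,
                indent=2,
            )
        manifest["stages"]["features"] = {
            "n_cases": len(feats),
            "n_excluded": len(excluded),
            "n_cancer_tiles": int(feats["n_cancer_tiles"].sum()),
        }

    feats = None
    train_mask = None
    if config.train_rf or config.score:
        feats = pd.read_csv(_require(paths["features"], "train_rf"), index_col="case_id")
        labels = feats.pop("lnm_label")
        # deterministic case-level split for ensemble training vs held-out
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(feats))
        n_val = int(round(config.validation_fraction * len(feats)))
        val_idx = set(order[:n_val])
        train_mask = np.array([i not in val_idx for i in range(len(feats))])

    ens_dir = os.path.join(out, "ensemble")
    if config.train_rf:
        ensemble = rf.fit_rf_scorer(
            feats[train_mask],
            labels[train_mask],
            n_candidates=config.n_candidates,
            top_k=config.top_k,
            depth=config.depth,
            n_trees=config.n_trees,
            master_seed=config.seed,
        )
        ensemble.save(ens_dir)
        imp = rf.feature_importance(ensemble)
        imp.rename("importance").to_csv(os.path.join(out, "feature_importance.csv"))
        manifest["stages"]["train_rf"] = {
            "n_train_cases": int(train_mask.sum()),
            "top_selection_auc": float(ensemble.selection_aucs[0]),
        }

    if config.score:
        ensemble = rf.RFEnsemble.load(ens_dir)
        scores = rf.rf_score(ensemble, feats)
        scores["lnm_label"] = labels
        scores["split"] = np.where(train_mask, "train", "validation")
        scores.to_csv(paths["scores"])
        manifest["stages"]["score"] = {"n_cases": len(scores)}

    if config.stratify:
        scores = pd.read_csv(_require(paths["scores"], "stratify"), index_col="case_id")
        tables = []
        for split, sub in scores.groupby("split"):
            tab = evaluation.stratify(sub["rf_score"], sub["lnm_label"])
            tab.insert(0, "split", split)
            tables.append(tab)
            roc = evaluation.roc_and_auc(sub["rf_score"], sub["lnm_label"])
            manifest["stages"].setdefault("stratify", {})[f"auc_{split}"] = roc.auc
        pd.concat(tables, ignore_index=True).to_csv(paths["stratification"], index=False)

    if config.render_maps:
        tiles = pd.read_csv(_require(paths["tiles"], "render_maps"))
        case_ids = tiles["case_id"].unique()[: config.n_map_cases]
        map_paths = []
        for cid in case_ids:
            man, records = _grid_manifest_from_case(cid, tiles[tiles["case_id"] == cid])
            p = os.path.join(out, f"map_{cid}.png")
            mapping.save_map(man, records, p, cell_size=config.map_cell_size)
            map_paths.append(p)
        manifest["stages"]["render_maps"] = {"maps": [os.path.basename(p) for p in map_paths]}
        for p in map_paths:
            manifest["artifacts"][os.path.basename(p)] = _sha256(p)

    for name, p in paths.items():
        if os.path.exists(p):
            manifest["artifacts"][os.path.basename(p)] = _sha256(p)
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
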
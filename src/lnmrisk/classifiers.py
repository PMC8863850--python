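"""Tile classifier contracts: tissue typing (#1) and metastasis labeling (#2).

Two tile-level models drive the pipeline:

* **Classifier #1** assigns each tissue tile a probability over ten tissue
  classes (cancer, non-tumoral mucosa, hyperplastic mucosa, adenoma,
  lymphoid tissue, smooth muscle, vessels, fat, nerve, background); its
  cancer-class probability gates everything downstream.
* **Classifier #2** is trained only on high-confidence cancer tiles
  (cancer probability strictly above 0.8), each weakly labeled with its
  *case's* lymph-node status, and emits the per-tile metastatic
  probability ``p_met``.

The reference model here is a lightweight multilayer perceptron over a
compact tile representation — an area-averaged downscale of the tile
(default 8 px) concatenated with translation-invariant intensity and
gradient statistics, standardized before the network.  It trains on one
CPU in seconds while honouring the same contract
(probability simplex outputs, per-epoch accuracy/cross-entropy curves,
seeded reproducibility) that a heavier convolutional backbone would; such a
backbone can be slotted in behind the same interface.

Train/validation splits are stratified **by case, never by tile**: tiles of
one case are correlated, and splitting them across folds leaks outcome
information.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .synthetic import TISSUE_CLASSES

DEFAULT_CANCER_TRAIN_CUTOFF = 0.8


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by both tile classifiers."""

    learning_rate: float = 0.01
    n_iterations: int = 40  # epochs
    batch_size: int = 64
    seed: int = 0
    input_resolution: int = 8  # downscale edge length fed to the model

    def __post_init__(self) -> None:
        for name in ("learning_rate", "n_iterations", "batch_size", "input_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def downscale_tiles(images, resolution: int) -> np.ndarray:
    """Area-average tiles down to ``resolution`` square, flattened to [0,1]."""
    feats = np.empty((len(images), resolution * resolution))
    for i, img in enumerate(images):
        img = np.asarray(img)
        if img.ndim == 3:  # collapse RGB before resizing
            img = (img[..., :3].astype(float) @ [0.299, 0.587, 0.114]).astype(np.uint8)
        small = Image.fromarray(img).resize((resolution, resolution), Image.BOX)
        feats[i] = np.asarray(small, dtype=float).ravel() / 255.0
    return feats


def tile_features(images, resolution: int) -> np.ndarray:
    """Per-tile feature vector: downscaled pixels plus summary statistics.

    The statistics (mean, sd, five intensity quantiles, mean and sd of the
    gradient magnitude) are translation-invariant, so texture identity does
    not hinge on where individual structures happen to sit in the tile.
    """
    pixels = downscale_tiles(images, resolution)
    stats = np.empty((len(images), 9))
    for i, img in enumerate(images):
        img = np.asarray(img)
        if img.ndim == 3:
            img = img[..., :3].astype(float) @ [0.299, 0.587, 0.114]
        a = img.astype(float) / 255.0
        gy, gx = np.gradient(a)
        grad = np.hypot(gx, gy)
        stats[i] = [
            a.mean(),
            a.std(),
            *np.quantile(a, (0.05, 0.25, 0.5, 0.75, 0.95)),
            grad.mean(),
            grad.std(),
        ]
    return np.concatenate([pixels, stats], axis=1)


@dataclass
class TileClassifierModel:
    """A trained tile classifier plus the metadata needed to apply it."""

    mlp: MLPClassifier
    scaler: StandardScaler
    classes: list[str]
    input_resolution: int
    train_tile_size: int
    kind: str  # "tissue" or "lnm"

    def predict_proba(self, images) -> np.ndarray:
        """Class probabilities per tile, rows on the probability simplex."""
        if len(images) == 0:
            return np.empty((0, len(self.classes)))
        sizes = {np.asarray(img).shape[0] for img in images}
        if sizes - {self.train_tile_size}:
            warnings.warn(
                f"tile size {sorted(sizes)} differs from the training size "
                f"{self.train_tile_size}; resizing",
                stacklevel=2,
            )
        feats = self.scaler.transform(tile_features(images, self.input_resolution))
        probs = self.mlp.predict_proba(feats)
        return probs / probs.sum(axis=1, keepdims=True)

    def save(self, path_prefix: str | os.PathLike) -> None:
        import joblib

        joblib.dump({"mlp": self.mlp, "scaler": self.scaler}, f"{path_prefix}.joblib")
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(
                {
                    "format_version": 1,
                    "classes": self.classes,
                    "input_resolution": self.input_resolution,
                    "train_tile_size": self.train_tile_size,
                    "kind": self.kind,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path_prefix: str | os.PathLike) -> "TileClassifierModel":
        import joblib

        with open(f"{path_prefix}.json") as fh:
            meta = json.load(fh)
        payload = joblib.load(f"{path_prefix}.joblib")
        return cls(
            mlp=payload["mlp"],
            scaler=payload["scaler"],
            classes=meta["classes"],
            input_resolution=meta["input_resolution"],
            train_tile_size=meta["train_tile_size"],
            kind=meta["kind"],
        )


def _train_mlp(
    raw_feats: np.ndarray, labels: np.ndarray, classes: np.ndarray, config: TrainConfig
) -> tuple[MLPClassifier, StandardScaler, pd.DataFrame]:
    """Epoch loop with per-epoch accuracy and cross-entropy logging."""
    scaler = StandardScaler().fit(raw_feats)
    feats = scaler.transform(raw_feats)
    mlp = MLPClassifier(
        hidden_layer_sizes=(64,),
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(feats)),
        random_state=config.seed,
        max_iter=1,
    )
    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(config.n_iterations):
        order = rng.permutation(len(feats))
        mlp.partial_fit(feats[order], labels[order], classes=classes)
        probs = mlp.predict_proba(feats)
        history.append(
            {
                "epoch": epoch,
                "loss": log_loss(labels, probs, labels=list(classes)),
                "accuracy": float(
                    (classes[np.argmax(probs, axis=1)] == labels).mean()
                ),
            }
        )
    return mlp, scaler, pd.DataFrame(history)


def train_tissue_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[TileClassifierModel, pd.DataFrame]:
    """Train the ten-class tissue-type classifier (#1).

    Returns the model and its learning curves (per-epoch accuracy and
    cross-entropy on the training tiles).  Labels must come from the ten
    known tissue classes and at least two classes must be present.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels)
    unknown = set(labels) - set(TISSUE_CLASSES)
    if unknown:
        raise ValueError(f"unknown tissue labels: {sorted(unknown)}")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("degenerate training set: only one class present")
    feats = tile_features(images, config.input_resolution)
    mlp, scaler, history = _train_mlp(feats, labels, classes, config)
    model = TileClassifierModel(
        mlp=mlp,
        scaler=scaler,
        classes=list(classes),
        input_resolution=config.input_resolution,
        train_tile_size=int(np.asarray(images[0]).shape[0]),
        kind="tissue",
    )
    return model, history


def train_lnm_tile_classifier(
    images: np.ndarray,
    p_cancer: np.ndarray,
    case_ids: np.ndarray,
    case_lnm: dict | pd.Series,
    cancer_prob_cutoff: float = DEFAULT_CANCER_TRAIN_CUTOFF,
    config: TrainConfig | None = None,
) -> tuple[TileClassifierModel, pd.DataFrame]:
    """Train the binary metastasis tile classifier (#2) on weak labels.

    Only tiles with ``p_cancer`` strictly above the cutoff are used; each
    keeps the lymph-node status of its case as its (weak) label.  Raises if
    no tile survives the cutoff or only one outcome class remains.
    """
    config = config or TrainConfig()
    p_cancer = np.asarray(p_cancer, dtype=float)
    mask = p_cancer > cancer_prob_cutoff
    if not mask.any():
        raise ValueError(
            f"empty training set: no tile has p_cancer > {cancer_prob_cutoff}"
        )
    mapping = case_lnm if isinstance(case_lnm, dict) else dict(case_lnm)
    labels = np.asarray([int(mapping[c]) for c in np.asarray(case_ids)[mask]])
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes required after the cancer cutoff")
    feats = tile_features(np.asarray(images)[mask], config.input_resolution)
    mlp, scaler, history = _train_mlp(feats, labels, np.array([0, 1]), config)
    model = TileClassifierModel(
        mlp=mlp,
        scaler=scaler,
        classes=["0", "1"],
        input_resolution=config.input_resolution,
        train_tile_size=int(np.asarray(images[0]).shape[0]),
        kind="lnm",
    )
    return model, history


def classify_tiles(model: TileClassifierModel, images: np.ndarray) -> pd.DataFrame:
    """Apply a tile classifier; one row per input tile, order preserved.

    Tissue models yield per-class probability columns plus
    ``predicted_label`` and ``p_cancer``; metastasis models yield
    ``p_met``/``p_nonmet``.  Inference is a pure function: the same tile
    always gets the same probabilities regardless of batching.
    """
    probs = model.predict_proba(images)
    if model.kind == "tissue":
        df = pd.DataFrame(probs, columns=model.classes)
        df["predicted_label"] = (
            np.asarray(model.classes)[np.argmax(probs, axis=1)]
            if len(df)
            else pd.Series(dtype=object)
        )
        df["p_cancer"] = df["cancer"] if "cancer" in df.columns else 0.0
        return df
    pos = model.classes.index("1")
    p_met = probs[:, pos] if len(probs) else np.empty(0)
    return pd.DataFrame({"p_met": p_met, "p_nonmet": 1.0 - p_met})


def pool_to_binary(labels: np.ndarray, positive: str = "cancer") -> np.ndarray:
    """Coarsen ten-class labels/predictions to cancer-vs-other."""
    return np.where(np.asarray(labels) == positive, positive, "other")


def flag_cases_without_cancer_tiles(
    case_ids: np.ndarray, predicted_labels: np.ndarray
) -> list[str]:
    """Cases in which classifier #1 found no cancer tile; these are
    excluded from case scoring rather than given a default score."""
    df = pd.DataFrame({"case_id": case_ids, "label": predicted_labels})
    has_cancer = df.groupby("case_id")["label"].apply(lambda s: (s == "cancer").any())
    return sorted(has_cancer.index[~has_cancer])


def split_by_case(
    case_ids: np.ndarray,
    case_labels: dict | pd.Series,
    validation_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean tile masks (train, validation) from a case-stratified split."""
    mapping = case_labels if isinstance(case_labels, dict) else dict(case_labels)
    cases = np.unique(np.asarray(case_ids))
    rng = np.random.default_rng(seed)
    val_cases: set = set()
    for label in sorted({mapping[c] for c in cases}):
        group = np.array([c for c in cases if mapping[c] == label])
        n_val = max(1, int(round(validation_fraction * len(group))))
        val_cases.update(rng.choice(group, size=n_val, replace=False))
    val_mask = np.isin(case_ids, sorted(val_cases))
    return ~val_mask, val_mask
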
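import numpy as np
import pytest

from lnmrisk.classifiers import (
    TrainConfig,
    classify_tiles,
    flag_cases_without_cancer_tiles,
    pool_to_binary,
    split_by_case,
    train_lnm_tile_classifier,
    train_tissue_classifier,
)
from lnmrisk.synthetic import (
    TextureSpec,
    default_texture_specs,
    generate_tissue_tiles,
    render_texture_tile,
)

TILE = 128  # reduced tiles keep unit tests fast; the contract is size-agnostic


@pytest.fixture(scope="module")
def texture_set():
    imgs, labs = generate_tissue_tiles(default_texture_specs(tile_size=TILE), 80, seed=3)
    rng = np.random.default_rng(3)
    idx = rng.permutation(len(imgs))
    n_test = len(imgs) // 3
    return (
        imgs[idx[n_test:]],
        labs[idx[n_test:]],
        imgs[idx[:n_test]],
        labs[idx[:n_test]],
    )


@pytest.fixture(scope="module")
def tissue_model(texture_set):
    imgs_tr, labs_tr, _, _ = texture_set
    return train_tissue_classifier(imgs_tr, labs_tr, TrainConfig(seed=3))


def test_tissue_classifier_learns_separable_textures(tissue_model, texture_set):
    _, _, imgs_te, labs_te = texture_set
    model, history = tissue_model
    pred = classify_tiles(model, imgs_te)
    acc = (pred["predicted_label"].to_numpy() == labs_te).mean()
    assert acc >= 0.90
    assert {"epoch", "loss", "accuracy"} <= set(history.columns)
    assert history["loss"].iloc[-1] < history["loss"].iloc[0]


def test_probability_simplex(tissue_model, texture_set):
    model, _ = tissue_model
    _, _, imgs_te, _ = texture_set
    probs = model.predict_proba(imgs_te[:10])
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert (probs >= 0).all() and (probs <= 1).all()


def test_binary_pooling_never_reduces_accuracy(tissue_model, texture_set):
    """Coarsening 10-class predictions to cancer-vs-other by label pooling
    cannot lower per-tile agreement."""
    model, _ = tissue_model
    _, _, imgs_te, labs_te = texture_set
    pred = classify_tiles(model, imgs_te)["predicted_label"].to_numpy()
    acc10 = (pred == labs_te).mean()
    acc2 = (pool_to_binary(pred) == pool_to_binary(labs_te)).mean()
    assert acc2 >= acc10


def test_inference_is_pure_and_order_preserving(tissue_model, texture_set):
    model, _ = tissue_model
    _, _, imgs_te, _ = texture_set
    once = classify_tiles(model, imgs_te[:8])
    twice = classify_tiles(model, np.concatenate([imgs_te[:8], imgs_te[:8]]))
    np.testing.assert_allclose(
        once["p_cancer"].to_numpy(), twice["p_cancer"].to_numpy()[:8]
    )
    np.testing.assert_allclose(
        twice["p_cancer"].to_numpy()[:8], twice["p_cancer"].to_numpy()[8:]
    )
    assert len(classify_tiles(model, np.empty((0, TILE, TILE), np.uint8))) == 0


def test_label_noise_keeps_loss_positive(texture_set):
    imgs_tr, labs_tr, _, _ = texture_set
    labs_noisy = labs_tr.copy()
    # mislabel one tile of each class with the next class round-robin
    classes = list(dict.fromkeys(labs_tr))
    for i, c in enumerate(classes):
        j = np.flatnonzero(labs_noisy == c)[0]
        labs_noisy[j] = classes[(i + 1) % len(classes)]
    _, history = train_tissue_classifier(imgs_tr, labs_noisy, TrainConfig(seed=1, n_iterations=15))
    assert (history["loss"] > 0).all()


def test_single_class_and_unknown_labels_rejected(texture_set):
    imgs_tr, labs_tr, _, _ = texture_set
    one = labs_tr == labs_tr[0]
    with pytest.raises(ValueError, match="one class"):
        train_tissue_classifier(imgs_tr[one], labs_tr[one])
    with pytest.raises(ValueError, match="unknown tissue"):
        train_tissue_classifier(imgs_tr[:4], np.array(["stroma"] * 4))


def _weakly_labeled_cohort(seed=7, n_cases=24, tiles_per=10, distinct=True):
    """Cases whose positive tiles come from a distinct texture (or not)."""
    pos_spec = TextureSpec("cancer", blob_density=2e-3, blob_radius=5,
                           background_gray=120, noise_sd=6, tile_size=TILE)
    neg_spec = TextureSpec("cancer", blob_density=4e-4, blob_radius=9,
                           background_gray=150 if distinct else 120,
                           noise_sd=6, tile_size=TILE)
    if not distinct:
        neg_spec = pos_spec
    rng = np.random.default_rng(seed)
    images, p_cancer, case_ids, lnm = [], [], [], {}
    for c in range(n_cases):
        pos = c % 3 == 0
        cid = f"c{c:03d}"
        lnm[cid] = int(pos)
        for _ in range(tiles_per):
            images.append(render_texture_tile(pos_spec if pos else neg_spec, rng))
            p_cancer.append(rng.uniform(0.81, 0.99))
            case_ids.append(cid)
    return np.stack(images), np.array(p_cancer), np.array(case_ids), lnm


def test_lnm_classifier_on_distinct_textures():
    images, p_cancer, case_ids, lnm = _weakly_labeled_cohort()
    train_m, val_m = split_by_case(case_ids, lnm, 0.3, seed=1)
    model, _ = train_lnm_tile_classifier(
        images[train_m], p_cancer[train_m], case_ids[train_m], lnm,
        config=TrainConfig(seed=1),
    )
    out = classify_tiles(model, images[val_m])
    truth = np.array([lnm[c] for c in case_ids[val_m]])
    acc = ((out["p_met"] > 0.5).astype(int).to_numpy() == truth).mean()
    assert acc >= 0.85
    assert np.allclose(out["p_met"] + out["p_nonmet"], 1.0)


def test_lnm_classifier_null_when_labels_shuffled():
    images, p_cancer, case_ids, lnm = _weakly_labeled_cohort(seed=8)
    rng = np.random.default_rng(0)
    cids = sorted(lnm)
    shuffled = dict(zip(cids, rng.permutation([lnm[c] for c in cids])))
    train_m, val_m = split_by_case(case_ids, shuffled, 0.3, seed=2)
    model, _ = train_lnm_tile_classifier(
        images[train_m], p_cancer[train_m], case_ids[train_m], shuffled,
        config=TrainConfig(seed=2),
    )
    out = classify_tiles(model, images[val_m])
    truth = np.array([shuffled[c] for c in case_ids[val_m]])
    acc = ((out["p_met"] > 0.5).astype(int).to_numpy() == truth).mean()
    assert abs(acc - 0.5) <= 0.25


def test_impossible_cancer_cutoff_is_empty_training_set():
    images, p_cancer, case_ids, lnm = _weakly_labeled_cohort(n_cases=6, tiles_per=2)
    with pytest.raises(ValueError, match="empty training set"):
        train_lnm_tile_classifier(images, p_cancer, case_ids, lnm, cancer_prob_cutoff=1.01)


def test_cases_without_cancer_tiles_are_flagged_not_scored():
    case_ids = np.array(["a", "a", "b", "b", "c"])
    preds = np.array(["cancer", "fat", "fat", "nerve", "cancer"])
    assert flag_cases_without_cancer_tiles(case_ids, preds) == ["b"]


def test_split_by_case_never_splits_a_case():
    case_ids = np.repeat([f"c{i}" for i in range(20)], 7)
    labels = {f"c{i}": i % 2 for i in range(20)}
    train_m, val_m = split_by_case(case_ids, labels, 0.3, seed=0)
    assert not (train_m & val_m).any() and (train_m | val_m).all()
    for cid in np.unique(case_ids):
        mask = case_ids == cid
        assert train_m[mask].all() or val_m[mask].all()


def test_model_round_trip(tmp_path, tissue_model, texture_set):
    model, _ = tissue_model
    _, _, imgs_te, _ = texture_set
    model.save(tmp_path / "tissue")
    from lnmrisk.classifiers import TileClassifierModel

    loaded = TileClassifierModel.load(tmp_path / "tissue")
    np.testing.assert_allclose(
        loaded.predict_proba(imgs_te[:5]), model.predict_proba(imgs_te[:5])
    )


def test_resolution_mismatch_warns(tissue_model):
    model, _ = tissue_model
    other = np.full((2, 40, 40), 150, dtype=np.uint8)
    with pytest.warns(UserWarning, match="differs from the training size"):
        model.predict_proba(other)


def test_invalid_train_config():
    with pytest.raises(ValueError):
        TrainConfig(n_iterations=0)
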
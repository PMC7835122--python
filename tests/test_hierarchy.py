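"""Hierarchy model: preprocessing, schedule, training, taps, checkpoints."""

import numpy as np
import pytest
from scipy.stats import binom

from conceptbench.hierarchy import (
    HierarchyConfig,
    TrainedHierarchy,
    _ConvNet,
    category_selectivity,
    combine_feature_sets,
    evaluate_topk,
    extract_features,
    learning_rate,
    load_checkpoint,
    preprocess,
    save_checkpoint,
    train_hierarchy,
)


# ---------------------------------------------------------------------------
# preprocessing

def test_preprocess_identity_for_square_target_size():
    img = np.random.default_rng(0).random((32, 32)).astype(np.float32)
    out = preprocess(img, 32, "center")
    assert np.array_equal(out, img)


def test_preprocess_aspect_ratio_arithmetic():
    # 300x200, target 100: shortest edge 200 -> scale 1/2 -> 150x100 -> 100x100 crop
    img = np.random.default_rng(1).random((300, 200)).astype(np.float32)
    out = preprocess(img, 100, "center")
    assert out.shape == (100, 100)


def test_preprocess_center_crop_removes_symmetric_margins():
    img = np.zeros((8, 12), dtype=np.float32)
    img[:, 2:10] = np.arange(8 * 8).reshape(8, 8)
    out = preprocess(img, 8, "center")
    assert np.array_equal(out, img[:, 2:10])


def test_preprocess_rejects_empty_and_unknown_mode():
    with pytest.raises(ValueError, match="empty"):
        preprocess(np.zeros((0, 4)), 4)
    with pytest.raises(ValueError, match="crop_mode"):
        preprocess(np.zeros((8, 8)), 4, "corner")
    with pytest.raises(ValueError, match="rng"):
        preprocess(np.zeros((8, 8)), 4, "random")


# ---------------------------------------------------------------------------
# learning-rate schedule

def test_learning_rate_schedule_closed_form():
    cfg = HierarchyConfig(concept_width=6, lr0=0.01, lr_decay_fraction=0.04,
                          decay_interval=1000)
    assert learning_rate(cfg, 0, 5000) == pytest.approx(0.01)
    assert learning_rate(cfg, 1000, 5000) == pytest.approx(0.0096)
    for k in range(8):
        assert learning_rate(cfg, k * 1000, 5000) == pytest.approx(0.01 * 0.96**k)
    # within an interval the rate is flat
    assert learning_rate(cfg, 999, 5000) == pytest.approx(0.01)


def test_config_validation():
    with pytest.raises(ValueError):
        HierarchyConfig(lr_decay_fraction=0.0)
    with pytest.raises(ValueError):
        HierarchyConfig(momentum=1.0)
    with pytest.raises(ValueError):
        HierarchyConfig(input_size=30)


# ---------------------------------------------------------------------------
# training and evaluation

def test_trained_model_beats_chance(tiny_model, tiny_datasets):
    chance = 1.0 / len(tiny_datasets["base-val"].label_set)
    top1 = evaluate_topk(tiny_model, tiny_datasets["base-val"], 1)
    assert top1 > chance
    for entry in tiny_model.training_log:
        assert entry["top1"] <= entry["top5"]


def test_training_log_matches_schedule(tiny_model, tiny_datasets):
    n = len(tiny_datasets["base-train"])
    cfg = tiny_model.config
    for entry in tiny_model.training_log:
        images_seen = (entry["epoch"] + 1) * n
        assert entry["lr"] == pytest.approx(learning_rate(cfg, images_seen, n))


def test_label_and_width_mismatch_errors(tiny_datasets):
    cfg = HierarchyConfig(input_size=16, concept_width=5, epochs=1)
    with pytest.raises(ValueError, match="concept_width"):
        train_hierarchy(tiny_datasets["base-train"], tiny_datasets["base-val"], cfg)
    with pytest.raises(ValueError, match="label set"):
        train_hierarchy(tiny_datasets["base-train"], tiny_datasets["novel"],
                        HierarchyConfig(input_size=16, concept_width=6, epochs=1))


def test_untrained_model_is_at_chance(tiny_datasets):
    """Random-init network on the balanced validation set: top-1 within the
    binomial 99% band around 1/n_base."""
    cfg = HierarchyConfig(input_size=16, stage_widths=(8, 12, 16), concept_width=6, seed=99)
    model = TrainedHierarchy(net=_ConvNet(cfg), config=cfg,
                             label_order=sorted(tiny_datasets["base-val"].label_set))
    top1 = evaluate_topk(model, tiny_datasets["base-val"], 1)
    n = len(tiny_datasets["base-val"])
    lo, hi = binom.ppf([0.005, 0.995], n, 1 / 6) / n
    assert lo <= top1 <= hi


def test_topk_bounds_and_errors(tiny_model, tiny_datasets):
    val = tiny_datasets["base-val"]
    assert evaluate_topk(tiny_model, val, tiny_model.config.concept_width) == 1.0
    assert evaluate_topk(tiny_model, val, 1) <= evaluate_topk(tiny_model, val, 5)
    with pytest.raises(ValueError, match="base labels"):
        evaluate_topk(tiny_model, tiny_datasets["novel"], 1)
    with pytest.raises(ValueError, match="k must be"):
        evaluate_topk(tiny_model, val, 0)


def test_training_is_seed_reproducible(tiny_datasets):
    cfg = HierarchyConfig(input_size=16, stage_widths=(8, 12, 16), concept_width=6,
                          epochs=2, seed=5)
    m1 = train_hierarchy(tiny_datasets["base-train"], tiny_datasets["base-val"], cfg)
    m2 = train_hierarchy(tiny_datasets["base-train"], tiny_datasets["base-val"], cfg)
    assert m1.training_log == m2.training_log
    assert np.array_equal(m1.net.fc.W, m2.net.fc.W)


# ---------------------------------------------------------------------------
# feature extraction

def test_conceptual_features_are_pre_softmax(tiny_model, tiny_datasets):
    fm = extract_features(tiny_model, tiny_datasets["novel"], "Conceptual")
    assert fm.dim == tiny_model.config.concept_width
    # applying softmax in the test normalizes each row to 1 — i.e. the rows
    # themselves were not softmaxed
    e = np.exp(fm.values - fm.values.max(axis=1, keepdims=True))
    assert np.allclose((e / e.sum(axis=1, keepdims=True)).sum(axis=1), 1.0)
    assert not np.allclose(fm.values.sum(axis=1), 1.0)


def test_extraction_is_deterministic(tiny_model, tiny_datasets):
    a = extract_features(tiny_model, tiny_datasets["novel"], "Generic2")
    b = extract_features(tiny_model, tiny_datasets["novel"], "Generic2")
    assert np.array_equal(a.values, b.values)


def test_unknown_tap_lists_registered(tiny_model, tiny_datasets):
    with pytest.raises(ValueError, match="Generic1"):
        extract_features(tiny_model, tiny_datasets["novel"], "pool5")


def test_tap_dims_decrease_with_depth(tiny_model, tiny_datasets):
    """Earlier taps keep spatial layout, so they are wider; the Conceptual
    tap is the narrowest (one unit per base category)."""
    dims = {t: extract_features(tiny_model, tiny_datasets["novel"], t).dim
            for t in ("Conceptual", "Generic1", "Generic2", "Generic3")}
    assert dims["Conceptual"] == 6
    assert dims["Generic2"] > dims["Generic1"] > dims["Conceptual"]
    assert dims["Generic3"] > dims["Generic1"]


def test_combine_feature_sets(tiny_model, tiny_datasets):
    g1 = extract_features(tiny_model, tiny_datasets["novel"], "Generic1")
    con = extract_features(tiny_model, tiny_datasets["novel"], "Conceptual")
    both = combine_feature_sets(g1, con)
    assert both.dim == g1.dim + con.dim
    assert both.values.shape[0] == g1.values.shape[0]
    assert both.tap == "Generic1+Conceptual"
    doubled = combine_feature_sets(g1, g1)
    assert doubled.dim == 2 * g1.dim
    reordered = extract_features(tiny_model, tiny_datasets["base-val"], "Generic1")
    with pytest.raises(ValueError, match="different images"):
        combine_feature_sets(g1, reordered)


def test_selectivity_gradient(tiny_model, tiny_datasets):
    """Conceptual features are more category-selective than the earliest
    generic tap on held-out base images (between/within variance ratio)."""
    con = extract_features(tiny_model, tiny_datasets["base-val"], "Conceptual")
    g3 = extract_features(tiny_model, tiny_datasets["base-val"], "Generic3")
    assert category_selectivity(con) > category_selectivity(g3)


def test_checkpoint_roundtrip(tmp_path, tiny_model, tiny_datasets):
    path = tmp_path / "model.ckpt.npz"
    save_checkpoint(tiny_model, path)
    back = load_checkpoint(path)
    a = extract_features(tiny_model, tiny_datasets["novel"], "Conceptual")
    b = extract_features(back, tiny_datasets["novel"], "Conceptual")
    assert np.array_equal(a.values, b.values)
    assert back.label_order == tiny_model.label_order
    assert back.training_log == tiny_model.training_log
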
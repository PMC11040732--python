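"""Label preprocessing, fold assignment, metric oracles and the training
loop's reproducibility / no-leak guarantees."""

import numpy as np
import pytest

from aldele.config import ModelConfig
from aldele.synthetic import SyntheticSpec, build_dataset
from aldele.train import (CPIDataset, compute_metrics, kfold_split,
                          preprocess_labels, train_model)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def test_preprocess_schemes():
    assert preprocess_labels([4.0], "log2")[0] == 2.0
    assert preprocess_labels([1000.0], "log10")[0] == 3.0
    assert np.array_equal(preprocess_labels([0.1, 0.05], "cutoff:0.08"), [1.0, 0.0])
    assert np.array_equal(preprocess_labels([5.0, 7.0], "percentage"), [5.0, 7.0])
    with pytest.raises(ValueError, match="positive"):
        preprocess_labels([4.0, -1.0], "log2")
    with pytest.raises(ValueError, match="scheme"):
        preprocess_labels([1.0], "sqrt")


def test_preprocess_multiclass_default_bounds():
    raw = [0.0, 0.0, 1.0, 2.0, 3.0, 10.0, 20.0, 30.0, 40.0]
    classes = preprocess_labels(raw, "multiclass")
    assert classes[0] == 0 and classes[1] == 0
    assert set(classes) == {0, 1, 2, 3}
    explicit = preprocess_labels([0.0, 0.5, 1.5, 9.0], "multiclass", bounds=(1.0, 5.0))
    assert np.array_equal(explicit, [0, 1, 2, 3])


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_kfold_partition_properties():
    folds = kfold_split(10, 5, seed=1)
    assert sorted(np.bincount(folds)) == [2, 2, 2, 2, 2]
    assert np.array_equal(kfold_split(10, 5, seed=1), folds)
    a, b = kfold_split(100, 5, seed=1), kfold_split(100, 5, seed=2)
    assert not np.array_equal(a, b)
    with pytest.raises(ValueError):
        kfold_split(3, 5)
    with pytest.raises(ValueError):
        kfold_split(10, 1)


# ---------------------------------------------------------------------------
# metrics (independent hand computations)
# ---------------------------------------------------------------------------

def test_regression_metrics_hand_oracle():
    pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    truth = np.array([1.5, 2.0, 2.5, 5.0, 4.5, 7.0])
    # hand arithmetic, plain Python
    resid = pred - truth
    rmse = (sum(r * r for r in resid) / 6) ** 0.5
    ybar = sum(truth) / 6
    r2 = 1 - sum(r * r for r in resid) / sum((t - ybar) ** 2 for t in truth)
    pbar = sum(pred) / 6
    cov = sum((p - pbar) * (t - ybar) for p, t in zip(pred, truth)) / 6
    r = cov / ((sum((p - pbar) ** 2 for p in pred) / 6) ** 0.5 *
               (sum((t - ybar) ** 2 for t in truth) / 6) ** 0.5)
    rep = compute_metrics(pred, truth)
    assert abs(rep.rmse - rmse) < 1e-10
    assert abs(rep.r_squared - r2) < 1e-10
    assert abs(rep.pearson_r - r) < 1e-10


def test_regression_metric_edge_cases():
    truth = np.array([1.0, 2.0, 3.0])
    rep = compute_metrics(np.full(3, 2.0), truth)          # null model
    assert abs(rep.r_squared) < 1e-10
    rep = compute_metrics(truth, truth)                     # perfect fit
    assert rep.rmse == 0.0 and rep.r_squared == 1.0
    assert abs(rep.pearson_r - 1.0) < 1e-10
    rep = compute_metrics(np.array([0.0, 2.0]), np.array([0.0, 0.0]))
    assert abs(rep.rmse - np.sqrt(2.0)) < 1e-10
    assert rep.r2_undefined and rep.r_squared is None


def test_classification_metrics_hand_oracle():
    truth = [0, 0, 1, 1, 2, 2]
    pred = [0, 1, 1, 1, 2, 0]
    # per-class precision: 1/2, 2/3, 1; recall: 1/2, 1, 1/2
    precision = (0.5 + 2 / 3 + 1.0) / 3
    recall = (0.5 + 1.0 + 0.5) / 3
    f1 = (0.5 + 0.8 + 2 / 3) / 3
    rep = compute_metrics(np.array(pred), np.array(truth), task="classification")
    assert abs(rep.precision - precision) < 1e-10
    assert abs(rep.recall - recall) < 1e-10
    assert abs(rep.f1 - f1) < 1e-10


# ---------------------------------------------------------------------------
# dataset / training loop
# ---------------------------------------------------------------------------

def test_dataset_rejects_dangling_pairs():
    with pytest.raises(ValueError, match="unknown records"):
        CPIDataset(pairs=[("C0", "P9", 1.0)], compounds={"C0": "CCO"},
                   proteins={"P0": "MKVLAA"})


def test_zero_epochs_returns_initialized_model(small_dataset):
    dataset, _ = small_dataset
    cfg = ModelConfig.from_preset("M1", epochs=0, seed=1)
    ckpt, report = train_model(cfg, dataset)
    preds = ckpt.predict_pairs(dataset, [0, 1])
    assert np.all(np.isfinite(preds))
    assert report.learning_curve == []


def test_constant_labels_predict_the_constant():
    spec = SyntheticSpec(n_pairs=40, n_proteins=8, n_compounds=8,
                         seq_length=(20, 26), beta1=0.0, sigma=0.0, seed=3)
    ds, _ = build_dataset(spec)
    cfg = ModelConfig.from_preset("M1", epochs=4, seed=3)
    ckpt, report = train_model(cfg, ds)
    preds = ckpt.predict_pairs(ds)
    assert np.allclose(preds, spec.beta0, atol=1.0)
    assert report.r2_undefined  # truth variance is zero on the test half


def test_training_is_bit_reproducible(small_dataset):
    dataset, _ = small_dataset
    cfg = ModelConfig.from_preset("M1", epochs=2, seed=9)
    ckpt1, rep1 = train_model(cfg, dataset)
    ckpt2, rep2 = train_model(cfg, dataset)
    assert all(np.array_equal(a, b) for a, b in zip(ckpt1.state, ckpt2.state))
    assert rep1.rmse == rep2.rmse


def test_no_leak_from_heldout_labels(small_dataset):
    """Mangling the test-half labels must not change the trained weights:
    every fitted component sees training (and validation) pairs only."""
    dataset, _ = small_dataset
    n = len(dataset)
    folds = np.zeros(n, dtype=int)
    train_idx = np.arange(0, n - 10)
    val_idx = np.arange(n - 10, n - 5)
    test_idx = np.arange(n - 5, n)
    cfg = ModelConfig.from_preset("M1", epochs=2, seed=5)
    ckpt1, _ = train_model(cfg, dataset, train_idx, val_idx, test_idx)
    mangled = CPIDataset(pairs=[(c, p, (lab if i < n - 5 else 1e9))
                                for i, (c, p, lab) in enumerate(dataset.pairs)],
                         compounds=dataset.compounds, proteins=dataset.proteins,
                         scheme=dataset.scheme)
    ckpt2, _ = train_model(cfg, mangled, train_idx, val_idx, test_idx)
    assert all(np.array_equal(a, b) for a, b in zip(ckpt1.state, ckpt2.state))


def test_checkpoint_roundtrip(tmp_path, trained_small):
    ckpt, report, dataset, _ = trained_small
    path = tmp_path / "model.ckpt"
    ckpt.save(path)
    from aldele.train import Checkpoint
    back = Checkpoint.load(path)
    assert np.allclose(back.predict_pairs(dataset, [0, 1, 2]),
                       ckpt.predict_pairs(dataset, [0, 1, 2]))
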
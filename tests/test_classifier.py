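"""Training, scoring, grouped cross-validation, tuning, floating feature
selection, and confusion-matrix metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef, precision_score, recall_score

from posetriage.classifier import (
    FAST_CONFIG,
    LabeledDataset,
    ModelConfig,
    TrainedModel,
    classify,
    cross_validate,
    make_folds,
    metrics,
    sbfs,
    train,
    tune,
)
from posetriage.errors import ContentError, ContractError
from posetriage.synthetic_fixtures import FixtureSpec, make_feature_table


def _dataset(X, y, clusters=None, names=None):
    n, p = X.shape
    names = names or [f"f{i}" for i in range(p)]
    ids = [f"row{i:04d}" for i in range(n)]
    idx = pd.Index(ids, name="complex_id")
    clusters = clusters if clusters is not None else np.arange(n) % 4
    return LabeledDataset(
        pd.DataFrame(X, index=idx, columns=names),
        pd.Series(y, index=idx),
        pd.Series(clusters, index=idx),
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _expand(tp, fp, tn, fn):
    y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
    return np.array(y_true), np.array(y_pred)


def test_metrics_match_sklearn_on_all_small_matrices():
    """Exhaustive check on all 4^4 confusion matrices with entries in 0..3."""
    for tp, fp, tn, fn in itertools.product(range(4), repeat=4):
        if tp + fp + tn + fn == 0:
            continue
        m = metrics(tp, fp, tn, fn)
        y_true, y_pred = _expand(tp, fp, tn, fn)
        if len(np.unique(y_true)) == 2 and len(np.unique(y_pred)) == 2:
            assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
        assert m.precision == pytest.approx(
            precision_score(y_true, y_pred, zero_division=0), abs=1e-12
        )
        assert m.recall == pytest.approx(
            recall_score(y_true, y_pred, zero_division=0), abs=1e-12
        )


def test_metrics_documented_conventions():
    assert metrics(25, 25, 25, 25).mcc == 0.0
    perfect = metrics(50, 0, 50, 0)
    assert (perfect.mcc, perfect.precision, perfect.recall) == (1.0, 1.0, 1.0)
    # direct formula recomputation for an asymmetric case
    tp, fn, tn, fp = 89, 11, 95, 5
    expected = (tp * tn - fp * fn) / np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    assert metrics(tp, fp, tn, fn).mcc == pytest.approx(expected, abs=1e-12)
    assert metrics(0, 0, 5, 5).mcc == 0.0  # zero denominator -> 0 by convention
    with pytest.raises(ContentError):
        metrics(0, 0, 0, 0)
    with pytest.raises(ContractError):
        metrics(-1, 0, 0, 1)


def test_classification_threshold_ties_go_positive():
    assert classify(np.array([0.7, 0.5, 0.49999])).tolist() == [1, 1, 0]


# ---------------------------------------------------------------------------
# train / score
# ---------------------------------------------------------------------------

def test_separable_data_trains_to_perfect_training_auc(rng):
    X = rng.normal(size=(200, 2))
    y = (X[:, 0] > 0).astype(int)
    ds = _dataset(X, y)
    model = train(ds, ModelConfig(n_estimators=50, max_depth=3, learning_rate=0.3), seed=0)
    s = model.score(ds.features)
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(y, s) == 1.0
    assert np.all((s >= 0) & (s <= 1))


def test_training_is_deterministic(rng):
    X = rng.normal(size=(300, 5))
    y = rng.integers(0, 2, 300)
    ds = _dataset(X, y)
    s1 = train(ds, FAST_CONFIG, seed=11).score(ds.features)
    s2 = train(ds, FAST_CONFIG, seed=11).score(ds.features)
    np.testing.assert_array_equal(s1, s2)


def test_single_class_training_fails(rng):
    ds = _dataset(rng.normal(size=(50, 3)), np.ones(50, dtype=int))
    with pytest.raises(ContentError, match="both classes"):
        train(ds)


def test_score_rejects_mismatched_feature_names(rng):
    X = rng.normal(size=(100, 3))
    y = rng.integers(0, 2, 100)
    model = train(_dataset(X, y), FAST_CONFIG)
    wrong = pd.DataFrame(X, columns=["f0", "f1", "other"])
    with pytest.raises(ContractError, match="missing features"):
        model.score(wrong)


def test_model_json_roundtrip(tmp_path, rng):
    X = rng.normal(size=(150, 4))
    y = (X[:, 1] > 0).astype(int)
    ds = _dataset(X, y)
    model = train(ds, FAST_CONFIG, seed=2)
    path = tmp_path / "model.json"
    model.save(path)
    back = TrainedModel.load(path)
    assert back.feature_names == model.feature_names
    assert back.registry_version == model.registry_version
    np.testing.assert_allclose(back.score(ds.features), model.score(ds.features),
                               atol=1e-6)


def test_model_config_validation():
    with pytest.raises(ContractError):
        ModelConfig(n_estimators=0)
    with pytest.raises(ContractError):
        ModelConfig(learning_rate=1.5)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_perfectly_separable_grouped_cv_reaches_mcc_one(rng):
    X = rng.normal(size=(400, 3))
    y = rng.integers(0, 2, 400)
    X[:, 0] = y.astype(float)  # exactly separable: no ambiguity inside a margin gap
    clusters = rng.integers(0, 2, 400)
    ds = _dataset(X, y, clusters)
    report = cross_validate(ds, make_folds(ds), FAST_CONFIG, seed=0)
    assert report.pooled["mcc"] == 1.0
    assert report.pooled["n"] == 400


def test_every_row_scored_exactly_once(rng):
    ds = make_feature_table(FixtureSpec(seed=4, n_active=100, n_decoy=100, n_clusters=5))
    folds = make_folds(ds)
    report = cross_validate(ds, folds, FAST_CONFIG, seed=0)
    assert sorted(report.oof_scores) == sorted(ds.ids)


def test_pooled_metrics_match_hand_confusion(rng):
    """Pooled MCC/precision/recall equal brute-force confusion counting on
    the out-of-fold predictions of a 20-row fixture."""
    X = rng.normal(size=(20, 2))
    y = rng.integers(0, 2, 20)
    X[:, 0] += 1.2 * y  # some signal, imperfect
    ds = _dataset(X, y, clusters=np.arange(20) % 4)
    report = cross_validate(ds, make_folds(ds), FAST_CONFIG, seed=0)
    y_true = ds.labels.loc[list(report.oof_scores)].to_numpy()
    y_pred = (np.array([report.oof_scores[i] for i in report.oof_scores]) >= 0.5).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    hand = metrics(tp, fp, tn, fn)
    assert report.pooled["mcc"] == pytest.approx(hand.mcc, abs=1e-12)
    assert report.pooled["precision"] == pytest.approx(hand.precision, abs=1e-12)
    assert report.pooled["recall"] == pytest.approx(hand.recall, abs=1e-12)


def test_single_class_fold_is_skipped_with_warning(rng):
    X = rng.normal(size=(30, 2))
    y = np.array([1] * 10 + [0] * 20)
    clusters = np.array([0] * 10 + [1] * 10 + [2] * 10)
    ds = _dataset(X, y, clusters)
    from posetriage.seq_cluster import FoldPlan

    ids = np.array(ds.ids)
    plan = FoldPlan([
        (sorted(ids[:20]), sorted(ids[20:])),  # mixed training: usable
        (sorted(ids[20:]), sorted(ids[:20])),  # all-decoy training: skipped
    ])
    with pytest.warns(UserWarning, match="single-class"):
        report = cross_validate(ds, plan, FAST_CONFIG, seed=0)
    assert report.skipped_folds == 1
    assert len(report.per_fold) == 1


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def test_tune_single_point_space_returns_it(rng):
    ds = make_feature_table(FixtureSpec(seed=5, n_active=100, n_decoy=100, n_clusters=4))
    folds = make_folds(ds)
    space = {"n_estimators": (25, 25), "max_depth": (3, 3), "learning_rate": (0.3, 0.3)}
    result = tune(ds, folds, space, n_trials=3, seed=0)
    assert result.best.n_estimators == 25
    assert result.best.max_depth == 3
    assert result.best.learning_rate == pytest.approx(0.3)
    assert len(result.trials) == 3


def test_tune_prefers_depth_on_xor(rng):
    """XOR labels need interaction depth; stumps cannot express them."""
    X = rng.normal(size=(600, 2))
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
    ds = _dataset(X, y, clusters=rng.integers(0, 3, 600))
    folds = make_folds(ds)
    shallow = cross_validate(ds, folds, ModelConfig(60, 1, 0.3), seed=0).mean_auc
    deep = cross_validate(ds, folds, ModelConfig(60, 3, 0.3), seed=0).mean_auc
    assert deep > shallow + 0.2
    space = {"n_estimators": (60, 60), "max_depth": (1, 3), "learning_rate": (0.3, 0.3)}
    result = tune(ds, folds, space, n_trials=8, seed=1)
    assert result.best.max_depth >= 2


def test_tune_rejects_empty_range(rng):
    ds = make_feature_table(FixtureSpec(seed=5, n_active=60, n_decoy=60, n_clusters=3))
    with pytest.raises(ContractError, match="empty range"):
        tune(ds, make_folds(ds), {"n_estimators": (50, 10), "max_depth": (2, 4),
                                  "learning_rate": (0.1, 0.3)}, n_trials=2)


def test_tune_deterministic(rng):
    ds = make_feature_table(FixtureSpec(seed=6, n_active=80, n_decoy=80, n_clusters=4))
    folds = make_folds(ds)
    a = tune(ds, folds, n_trials=4, seed=9).best
    b = tune(ds, folds, n_trials=4, seed=9).best
    assert a == b


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def test_sbfs_keeps_label_copy_feature(rng):
    """Feature A equals the label; B and C are noise: A must be chosen."""
    n = 300
    y = rng.integers(0, 2, n)
    X = np.column_stack([y.astype(float), rng.normal(size=n), rng.normal(size=n)])
    ds = _dataset(X, y, clusters=rng.integers(0, 3, n), names=["A", "B", "C"])
    trace = sbfs(ds, make_folds(ds), FAST_CONFIG, seed=0)
    assert "A" in trace.chosen
    assert trace.chosen_mcc == pytest.approx(1.0)


def test_sbfs_collapses_identical_copies(rng):
    n = 300
    y = rng.integers(0, 2, n)
    base = y + 0.1 * rng.normal(size=n)
    X = np.column_stack([base, base, base, base])
    ds = _dataset(X, y, clusters=rng.integers(0, 3, n))
    trace = sbfs(ds, make_folds(ds), FAST_CONFIG, seed=0)
    assert len(trace.chosen) == 1


def test_sbfs_chosen_at_least_full_set(rng):
    ds = make_feature_table(FixtureSpec(seed=7, n_active=150, n_decoy=150,
                                        n_clusters=5, n_informative=2, n_noise=6,
                                        effect_size=1.0))
    trace = sbfs(ds, make_folds(ds, n_folds=3), FAST_CONFIG, seed=0)
    full_mcc = trace.steps[0][1]
    assert trace.chosen_mcc >= full_mcc
    sizes = [len(s) for s, _ in trace.steps]
    assert min(sizes) == 1  # backward pass reaches a single feature
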
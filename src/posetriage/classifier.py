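"""The gradient-boosted pose classifier: training, grouped cross-validation,
hyper-parameter search, and sequential backward floating feature selection.

Scores range between 0 (decoy-like) and 1 (active-like); hard labels use a
0.5 threshold with ties going to the positive class.  All stochastic steps
take explicit seeds and default to one thread for bit-stable results.
Sentinel (NaN) feature values are passed to the tree learner as missing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .errors import ContentError, ContractError
from .feature_engine import REGISTRY_VERSION
from .seq_cluster import FoldPlan


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels + cluster ids for grouped splitting."""

    features: pd.DataFrame            # index: complex_id, columns: feature names
    labels: pd.Series                 # 1 = active, 0 = decoy
    cluster_ids: pd.Series

    def __post_init__(self) -> None:
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ContractError("labels must be 0/1")
        if not (self.features.index.equals(self.labels.index)
                and self.features.index.equals(self.cluster_ids.index)):
            raise ContractError("features, labels, and cluster_ids must share an index")
        if self.features.index.has_duplicates:
            raise ContractError("complex ids must be unique")

    @property
    def ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset_rows(self, ids: list[str]) -> "LabeledDataset":
        return LabeledDataset(
            self.features.loc[ids], self.labels.loc[ids], self.cluster_ids.loc[ids]
        )

    def subset_features(self, names: list[str]) -> "LabeledDataset":
        return LabeledDataset(self.features[list(names)], self.labels, self.cluster_ids)

    def to_csv(self, path: str | Path) -> None:
        df = self.features.copy()
        df["label"] = self.labels
        df["cluster_id"] = self.cluster_ids
        df.to_csv(path, index_label="complex_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        df = pd.read_csv(path, index_col="complex_id")
        for col in ("label", "cluster_id"):
            if col not in df.columns:
                raise ContentError(f"dataset CSV lacks required column {col!r}")
        labels = df.pop("label").astype(int)
        clusters = df.pop("cluster_id")
        return cls(df, labels, clusters)


@dataclass
class ModelConfig:
    """The three tuned XGB hyper-parameters."""

    n_estimators: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ContractError("n_estimators and max_depth must be positive")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ContractError("learning_rate must lie in (0, 1]")


#: Light configuration for the inner loops of feature selection.
FAST_CONFIG = ModelConfig(n_estimators=20, max_depth=3, learning_rate=0.5)


@dataclass
class Metrics:
    mcc: float
    precision: float
    recall: float


def metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """MCC / precision / recall from confusion counts.

    Zero denominators are defined as 0 (documented convention), so the
    function is total on any non-empty confusion matrix.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ContractError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ContentError("empty confusion matrix")
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return Metrics(mcc, precision, recall)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels from scores; a score exactly at threshold goes positive."""
    return (np.asarray(scores) >= threshold).astype(int)


@dataclass
class TrainedModel:
    """A fitted boosted-tree ensemble plus the contract needed to apply it."""

    booster: XGBClassifier
    feature_names: list[str]
    registry_version: str = REGISTRY_VERSION
    seed: int = 0
    config: ModelConfig = field(default_factory=ModelConfig)

    def score(self, features) -> np.ndarray:
        """Scores in [0, 1] for a feature row / matrix with matching names."""
        X = self._validate(features)
        return self.booster.predict_proba(X)[:, 1]

    def _validate(self, features) -> pd.DataFrame:
        if hasattr(features, "as_dict"):  # FeatureVector
            features = pd.DataFrame([features.as_dict()])
        elif isinstance(features, dict):
            features = pd.DataFrame([features])
        if not isinstance(features, pd.DataFrame):
            raise ContractError("score() expects a FeatureVector, dict, or DataFrame")
        missing = [n for n in self.feature_names if n not in features.columns]
        extra = [n for n in features.columns if n not in self.feature_names]
        if missing:
            raise ContractError(f"missing features: {missing[:5]}; extra: {extra[:5]}")
        return features[self.feature_names]

    def save(self, path: str | Path) -> None:
        bundle = {
            "model": json.loads(self.booster.get_booster().save_raw("json").decode()),
            "feature_names": self.feature_names,
            "registry_version": self.registry_version,
            "seed": self.seed,
            "config": vars(self.config),
        }
        Path(path).write_text(json.dumps(bundle))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        bundle = json.loads(Path(path).read_text())
        config = ModelConfig(**bundle["config"])
        booster = _make_xgb(config, bundle["seed"])
        booster.load_model(bytearray(json.dumps(bundle["model"]).encode()))
        return cls(booster, bundle["feature_names"], bundle["registry_version"],
                   bundle["seed"], config)


def _make_xgb(config: ModelConfig, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        objective="binary:logistic",
        tree_method="hist",
        max_bin=64,  # coarse histograms: deterministic and fast, ample for these features
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


def train(data: LabeledDataset, config: ModelConfig | None = None, seed: int = 0) -> TrainedModel:
    """Fit the logistic-output boosted-tree classifier (deterministic per seed)."""
    config = config or ModelConfig()
    y = data.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ContentError("training requires both classes")
    model = _make_xgb(config, seed)
    model.fit(data.features, y)
    return TrainedModel(model, data.feature_names, seed=seed, config=config)


@dataclass
class CVReport:
    """Per-fold and pooled out-of-fold performance."""

    per_fold: list[dict]
    pooled: dict
    fold_weights: list[int]
    skipped_folds: int = 0
    oof_scores: dict[str, float] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        aucs = [f["auc"] for f in self.per_fold if not math.isnan(f["auc"])]
        return float(np.mean(aucs)) if aucs else float("nan")


def cross_validate(
    data: LabeledDataset,
    folds: FoldPlan,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> CVReport:
    """Out-of-fold evaluation over a fold plan.

    Every row is scored exactly once.  Folds whose training half lacks a
    class are skipped with a warning (their rows are excluded from pooling).
    Pooled metrics come from the concatenated out-of-fold predictions;
    per-fold metrics are also reported with fold sizes as weights.
    """
    config = config or ModelConfig()
    oof_scores: dict[str, float] = {}
    per_fold: list[dict] = []
    weights: list[int] = []
    skipped = 0
    for train_ids, test_ids in folds:
        train_ids = [i for i in train_ids if i in data.features.index]
        test_ids = [i for i in test_ids if i in data.features.index]
        if not train_ids or not test_ids:
            continue
        tr = data.subset_rows(train_ids)
        if len(np.unique(tr.labels)) < 2:
            warnings.warn("fold skipped: single-class training split", stacklevel=2)
            skipped += 1
            continue
        model = train(tr, config, seed)
        te = data.subset_rows(test_ids)
        s = model.score(te.features)
        for cid, sc in zip(test_ids, s):
            if cid in oof_scores:
                raise ContractError(f"row {cid} scored twice across folds")
            oof_scores[cid] = float(sc)
        y_true = te.labels.to_numpy()
        y_pred = classify(s)
        m = metrics(*_confusion(y_true, y_pred))
        auc = (
            float(roc_auc_score(y_true, s)) if len(np.unique(y_true)) == 2 else float("nan")
        )
        per_fold.append(
            {"mcc": m.mcc, "precision": m.precision, "recall": m.recall,
             "auc": auc, "n_test": len(test_ids)}
        )
        weights.append(len(test_ids))

    if not oof_scores:
        raise ContentError("no usable folds")
    ids = list(oof_scores)
    y_true = data.labels.loc[ids].to_numpy()
    s = np.array([oof_scores[i] for i in ids])
    y_pred = classify(s)
    m = metrics(*_confusion(y_true, y_pred))
    pooled = {
        "mcc": m.mcc,
        "precision": m.precision,
        "recall": m.recall,
        "auc": float(roc_auc_score(y_true, s)) if len(np.unique(y_true)) == 2 else float("nan"),
        "n": len(ids),
    }
    return CVReport(per_fold, pooled, weights, skipped, oof_scores)


def make_folds(
    data: LabeledDataset, n_folds: int | None = None, grouped: bool = True, seed: int = 0
) -> FoldPlan:
    """Folds over dataset rows.

    Grouped (default): whole clusters per fold — leave-one-cluster-out when
    ``n_folds`` is None, else clusters dealt into ``n_folds`` groups.
    Row-random folds (``grouped=False``) are available for comparison and
    are exactly the leakage-prone design grouped CV exists to avoid.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(data.ids)
    if grouped:
        clusters = data.cluster_ids.astype(str)
        uniq = sorted(clusters.unique())
        if n_folds is None:
            groups = [[c] for c in uniq]
        else:
            if n_folds < 2 or n_folds > len(uniq):
                raise ContractError("n_folds must lie in [2, n_clusters]")
            perm = rng.permutation(len(uniq))
            groups = [[uniq[j] for j in perm[i::n_folds]] for i in range(n_folds)]
        folds = []
        for g in groups:
            mask = clusters.isin(g).to_numpy()
            folds.append((sorted(ids[~mask]), sorted(ids[mask])))
    else:
        if n_folds is None or n_folds < 2:
            raise ContractError("row-random folds require n_folds >= 2")
        perm = rng.permutation(len(ids))
        folds = []
        for i in range(n_folds):
            test_idx = perm[i::n_folds]
            mask = np.zeros(len(ids), dtype=bool)
            mask[test_idx] = True
            folds.append((sorted(ids[~mask]), sorted(ids[mask])))
    return FoldPlan(folds)


@dataclass
class TuneResult:
    best: ModelConfig
    trials: list[dict]


def tune(
    data: LabeledDataset,
    folds: FoldPlan,
    space: dict[str, tuple[float, float]] | None = None,
    n_trials: int = 20,
    seed: int = 0,
) -> TuneResult:
    """Seeded random search over the three hyper-parameters.

    Samples ``n_trials`` configurations (learning rate log-uniform, the two
    integer parameters uniform) and returns the one with the best mean
    cross-validated AUC; the full trial log is retained.
    """
    if n_trials < 1:
        raise ContractError("n_trials must be >= 1")
    space = space or {
        "n_estimators": (50, 500),
        "max_depth": (2, 8),
        "learning_rate": (0.01, 0.5),
    }
    for key in ("n_estimators", "max_depth", "learning_rate"):
        lo, hi = space[key]
        if hi < lo:
            raise ContractError(f"empty range for {key}")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    best: tuple[float, int] | None = None
    for t in range(n_trials):
        cfg = ModelConfig(
            n_estimators=int(rng.integers(space["n_estimators"][0],
                                          space["n_estimators"][1] + 1)),
            max_depth=int(rng.integers(space["max_depth"][0], space["max_depth"][1] + 1)),
            learning_rate=float(np.exp(rng.uniform(np.log(space["learning_rate"][0]),
                                                   np.log(space["learning_rate"][1])))),
        )
        report = cross_validate(data, folds, cfg, seed)
        auc = report.mean_auc
        trials.append({"config": vars(cfg), "mean_auc": auc})
        if best is None or auc > best[0]:
            best = (auc, t)
    assert best is not None
    return TuneResult(ModelConfig(**trials[best[1]]["config"]), trials)


@dataclass
class SelectionTrace:
    """Every subset visited by floating selection with its cross-validated MCC."""

    steps: list[tuple[tuple[str, ...], float]]
    chosen: tuple[str, ...]

    @property
    def chosen_mcc(self) -> float:
        for subset, mcc in self.steps:
            if subset == self.chosen:
                return mcc
        raise ContractError("chosen subset missing from trace")


def sbfs(
    data: LabeledDataset,
    folds: FoldPlan,
    config: ModelConfig | None = None,
    seed: int = 0,
    min_features: int = 1,
    floating: bool = True,
) -> SelectionTrace:
    """Sequential backward floating selection maximizing cross-validated MCC.

    Backward step: drop the feature whose removal gives the best pooled MCC.
    Floating step: after each removal, conditionally re-include a removed
    feature when doing so beats the best MCC yet seen at that subset size.
    The chosen subset is the argmax of MCC over the trace; ties prefer the
    smaller subset (parsimony), then the earlier visit.
    """
    config = config or FAST_CONFIG
    names = list(data.feature_names)
    if len(names) < 2:
        raise ContractError("feature selection needs >= 2 features")
    cache: dict[frozenset, float] = {}

    def evaluate(subset: tuple[str, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            report = cross_validate(data.subset_features(list(subset)), folds, config, seed)
            cache[key] = report.pooled["mcc"]
        return cache[key]

    current = tuple(names)
    steps: list[tuple[tuple[str, ...], float]] = [(current, evaluate(current))]
    best_at_size: dict[int, float] = {len(current): steps[0][1]}
    removed: list[str] = []

    while len(current) > max(1, min_features):
        # backward step
        candidates = []
        for f in current:
            subset = tuple(x for x in current if x != f)
            candidates.append((evaluate(subset), f, subset))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        mcc, dropped, current = candidates[0]
        removed.append(dropped)
        steps.append((current, mcc))
        size = len(current)
        best_at_size[size] = max(best_at_size.get(size, -np.inf), mcc)

        # floating step: conditional re-inclusion
        while floating and removed:
            readd = []
            for g in removed:
                if g == dropped:
                    continue
                subset = tuple(sorted(current + (g,), key=names.index))
                readd.append((evaluate(subset), g, subset))
            if not readd:
                break
            readd.sort(key=lambda t: (-t[0], t[1]))
            best_mcc, g, subset = readd[0]
            size_up = len(subset)
            if best_mcc > best_at_size.get(size_up, -np.inf):
                current = subset
                removed.remove(g)
                steps.append((current, best_mcc))
                best_at_size[size_up] = best_mcc
                dropped = ""  # allow further re-inclusions of anything
            else:
                break

    chosen = max(steps, key=lambda s: (s[1], -len(s[0]), -steps.index(s)))[0]
    return SelectionTrace(steps, chosen)
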
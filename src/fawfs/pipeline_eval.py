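"""End-to-end orchestration and cross-validated evaluation.

Feature subsets are scored by stratified 5-fold cross-validated accuracy:
the samples are split into five folds, a classifier is trained on four
and validated on the held-out fold, rotating until every fold has served
as the validation set once. Five classical classifier families are
supported (logistic regression, decision tree, k-nearest neighbours,
RBF support-vector machine, random forest); features are standardized on
each training fold and the transform applied to its validation fold so no
statistics leak across the split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datatypes import FeatureMask, LabeledDataset

__all__ = [
    "CLASSIFIER_NAMES",
    "EvalProtocol",
    "EvaluationResult",
    "accuracy",
    "make_classifier",
    "cross_validate",
    "run_pipeline",
    "compare_selectors",
]

CLASSIFIER_NAMES: tuple[str, ...] = ("lr", "dt", "knn", "svm", "rf")


@dataclass(frozen=True)
class EvalProtocol:
    """Cross-validation protocol: fold count, stratification, seed."""

    n_folds: int = 5
    stratified: bool = True
    seed: int = 0
    classifier_names: tuple[str, ...] = CLASSIFIER_NAMES
    classifier_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        unknown = set(self.classifier_names) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


@dataclass(frozen=True)
class EvaluationResult:
    """Per-fold and mean accuracy of one classifier on one feature mask."""

    classifier: str
    mask: FeatureMask
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    n_samples: int
    n_features_selected: int


def accuracy(y_true, y_pred) -> float:
    """Fraction of predictions equal to the truth."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.mean(y_true == y_pred))


def make_classifier(name: str, seed: int = 0, params: dict | None = None):
    """Standardization + classifier pipeline for one of the five families.

    Defaults: LR with L2 penalty (C=1), unrestricted decision tree,
    5-nearest neighbours, RBF SVM with C=1, random forest of 100 trees.
    """
    params = dict(params or {})
    if name == "lr":
        clf = LogisticRegression(C=1.0, max_iter=1000, random_state=seed, **params)
    elif name == "dt":
        clf = DecisionTreeClassifier(random_state=seed, **params)
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=5, **params)
    elif name == "svm":
        clf = SVC(kernel="rbf", C=1.0, random_state=seed, **params)
    elif name == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return make_pipeline(StandardScaler(), clf)


def fold_indices(y: np.ndarray, protocol: EvalProtocol) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (stratified) fold assignment; folds partition the index set."""
    protocol.validate()
    splitter = StratifiedKFold(
        n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed
    )
    splits = list(splitter.split(np.zeros(y.size), y))
    all_val = np.concatenate([val for _, val in splits])
    assert np.array_equal(np.sort(all_val), np.arange(y.size)), "folds must partition"
    return splits


def cross_validate(
    dataset: LabeledDataset,
    mask: FeatureMask | None,
    protocol: EvalProtocol,
    classifier: str,
) -> EvaluationResult:
    """Stratified k-fold accuracy of one classifier on the masked features."""
    if mask is None:
        mask = np.ones(dataset.n_features, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask must select at least one feature")
    X = dataset.X[:, mask]
    y = dataset.y
    accs = []
    for train, val in fold_indices(y, protocol):
        if np.unique(y[train]).size < 2:
            raise ValueError("a training fold contains a single class")
        model = make_classifier(
            classifier, protocol.seed, protocol.classifier_params.get(classifier)
        )
        model.fit(X[train], y[train])
        accs.append(accuracy(y[val], model.predict(X[val])))
    accs = tuple(float(a) for a in accs)
    return EvaluationResult(
        classifier=classifier,
        mask=mask,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        n_samples=dataset.n_samples,
        n_features_selected=int(mask.sum()),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything run_pipeline needs; hashable for provenance."""

    protocol: EvalProtocol = EvalProtocol()
    filter_cfg: "object" = None  # FilterConfig; resolved lazily
    ga_cfg: "object" = None  # GAConfig
    ga_classifier: str = "svm"
    epoch_length_s: float = 2.0
    epoch_overlap_s: float = 0.0
    target_fs: float | None = None

    def config_hash(self) -> str:
        blob = json.dumps(repr(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(dataset: LabeledDataset, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Filter union -> GA wrapper -> cross-validate each classifier.

    Returns one row per requested classifier with the mean CV accuracy of
    the FAW-FS-selected mask, annotated with the config hash and seed so a
    rerun with the same configuration reproduces the table bit for bit.
    """
    from .filter_select import FilterConfig, filter_union
    from .wrapper_select import GAConfig, run_ga

    if config is None:
        config = PipelineConfig()
    protocol = config.protocol
    protocol.validate()
    if np.all(np.ptp(dataset.X, axis=0) == 0):
        raise RuntimeError("pipeline stage filter_union: all feature columns constant")

    filter_cfg = config.filter_cfg if config.filter_cfg is not None else FilterConfig()
    union = filter_union(dataset, filter_cfg)
    ga_cfg = config.ga_cfg if config.ga_cfg is not None else GAConfig(seed=protocol.seed)
    best_mask, _history = run_ga(dataset, union, ga_cfg, config.ga_classifier)

    rows = []
    for name in protocol.classifier_names:
        res = cross_validate(dataset, best_mask, protocol, name)
        rows.append(
            {
                "selector": "faw_fs",
                "classifier": name,
                "mean_accuracy": res.mean_accuracy,
                "n_selected": res.n_features_selected,
                "seed": protocol.seed,
                "config_hash": config.config_hash(),
            }
        )
    return pd.DataFrame(rows)


def compare_selectors(
    dataset: LabeledDataset, protocol: EvalProtocol | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Mean CV accuracy of no selection vs filter-only vs full FAW-FS.

    Rows are selectors, columns classifiers; every cell is a mean
    cross-validated accuracy computed under the same protocol, so the
    comparison is paired within the run.
    """
    from .filter_select import FilterConfig, filter_union
    from .wrapper_select import GAConfig, run_ga

    if protocol is None:
        protocol = EvalProtocol()
    if config is None:
        config = PipelineConfig(protocol=protocol)

    filter_cfg = config.filter_cfg if config.filter_cfg is not None else FilterConfig()
    union = filter_union(dataset, filter_cfg)
    ga_cfg = config.ga_cfg if config.ga_cfg is not None else GAConfig(seed=protocol.seed)
    best_mask, _ = run_ga(dataset, union, ga_cfg, config.ga_classifier)

    all_mask = np.ones(dataset.n_features, dtype=bool)
    masks = {"none": all_mask, "filter_only": union, "faw_fs": best_mask}
    table = {}
    for name in protocol.classifier_names:
        table[name] = {
            sel: cross_validate(dataset, m, protocol, name).mean_accuracy
            for sel, m in masks.items()
        }
    df = pd.DataFrame(table)
    df.index.name = "selector"
    return df.loc[["none", "filter_only", "faw_fs"]]
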
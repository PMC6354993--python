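"""Disease-stage classification under repeated k-fold cross-validation.

Feature tables (per-image projections onto r retained eigenmodes) are
classified with a random forest (1,000 trees, majority vote) or a
radial-kernel support vector machine (cost 1, kernel width 1/n_features,
one-vs-one multiclass, features z-scored with training-fold statistics only).
Ten-fold cross-validation is re-randomized ``repeats`` times; accuracy is
1 − misclassified/total, and pairwise misclassification rates over unordered
class pairs sum exactly to 1 − accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .airway import STAGE_LABELS
from .decomposition import FeatureTable, build_feature_table, dmd, dmdc, pca, pod
from .io import (
    AerosolDataset,
    assemble_snapshots,
    build_control_matrix,
    split_transitions,
)

__all__ = [
    "CVConfig",
    "CVResult",
    "accuracy",
    "pairwise_misclassification",
    "kfold_partition",
    "train_classifier",
    "predict",
    "run_cv",
    "extract_features",
    "sweep_feature_tables",
    "mode_sweep",
    "one_way_anova",
    "DEFAULT_R_LIST",
    "METHODS",
    "CLASSIFIERS",
]

logger = logging.getLogger(__name__)

DEFAULT_R_LIST = (3, 5, 10, 25, 50, 75, 100)
METHODS = ("POD", "PCA", "DMD", "DMDC")
CLASSIFIERS = ("RF", "SVM")


@dataclass
class CVConfig:
    """Cross-validation and classifier settings.

    ``classifier`` is ``"RF"`` (random forest, ``rf_trees`` trees,
    sqrt-of-features subset per split, no depth limit) or ``"SVM"``
    (RBF kernel, cost ``svm_cost``, gamma 1/n_features on z-scored
    features).  One master ``seed`` fans out per-repeat streams so any
    repeat is independently reproducible.
    """

    classifier: str = "RF"
    n_folds: int = 10
    repeats: int = 100
    seed: int = 0
    rf_trees: int = 1000
    svm_cost: float = 1.0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be at least 1")


@dataclass
class CVResult:
    """Per-repeat accuracies plus confusion counts pooled over all repeats."""

    accuracies: np.ndarray  # (repeats,)
    confusion: pd.DataFrame  # pooled counts, rows = truth, cols = prediction
    config: CVConfig
    labels: tuple[str, ...] = STAGE_LABELS

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0

    def pooled_accuracy(self) -> float:
        return accuracy(self.confusion.to_numpy())

    def pairwise_rates(self) -> dict[tuple[str, str], float]:
        return pairwise_misclassification(self.confusion.to_numpy(), self.labels)

    def box_stats(self) -> dict[str, float]:
        """Box-plot statistics of the per-repeat accuracies (outliers beyond 1.5 IQR)."""
        q1, med, q3 = np.percentile(self.accuracies, [25, 50, 75])
        iqr = q3 - q1
        out = self.accuracies[
            (self.accuracies < q1 - 1.5 * iqr) | (self.accuracies > q3 + 1.5 * iqr)
        ]
        return {
            "mean": self.mean_accuracy,
            "sd": self.sd_accuracy,
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "n_outliers": int(len(out)),
        }


def accuracy(confusion: np.ndarray) -> float:
    """Classification accuracy 1 − misclassified/total from confusion counts."""
    c = np.asarray(confusion)
    if c.size == 0:
        raise ValueError("empty confusion matrix")
    if (c < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix has no counts")
    off = total - np.trace(c)
    return float((total - off) / total)


def pairwise_misclassification(
    confusion: np.ndarray, labels: tuple[str, ...] = STAGE_LABELS
) -> dict[tuple[str, str], float]:
    """Misclassification rate per unordered class pair.

    ``rate(i, j) = (count(i→j) + count(j→i)) / total``; the rates sum to
    1 − accuracy exactly (same integer bookkeeping).
    """
    c = np.asarray(confusion)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("empty confusion matrix")
    total = c.sum()
    return {
        (labels[i], labels[j]): float((c[i, j] + c[j, i]) / total)
        for i, j in combinations(range(c.shape[0]), 2)
    }


def kfold_partition(
    n: int,
    k: int,
    seed: int,
    stratify: bool = False,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic partition of n samples into k folds (sizes differ by ≤ 1).

    Returns an array of fold indices in 0..k−1.  The stratified variant
    preserves per-class proportions to within one sample per fold.
    """
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if stratify:
        if labels is None:
            raise ValueError("stratified partitioning requires labels")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_arg = np.asarray(labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_arg = None
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), split_arg)):
        assignment[test_idx] = fold
    return assignment


def _make_classifier(config: CVConfig, random_state: int):
    if config.classifier == "RF":
        return RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features="sqrt",
            random_state=random_state,
            n_jobs=1,
        )
    # e1071-style defaults: z-scored inputs, RBF, cost 1, gamma = 1/n_features;
    # SVC trains one-vs-one binary machines internally.
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(C=config.svm_cost, kernel="rbf", gamma="auto",
                        random_state=random_state)),
        ]
    )


def train_classifier(features: np.ndarray, labels: np.ndarray, config: CVConfig,
                     random_state: int | None = None):
    """Fit the configured classifier on a training split."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("training features contain non-finite values")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain fewer than two classes")
    model = _make_classifier(config, config.seed if random_state is None else random_state)
    return model.fit(features, labels)


def predict(model, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features, dtype=float))


def run_cv(features: FeatureTable | np.ndarray, config: CVConfig,
           labels: np.ndarray | None = None) -> CVResult:
    """Repeated k-fold cross-validation of one feature table.

    Every sample is tested exactly once per repeat; per-repeat accuracies are
    retained and confusion counts pooled over all repeats × folds.
    """
    if isinstance(features, FeatureTable):
        X, y = features.features, np.asarray(features.labels)
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a plain feature array")
        y = np.asarray(labels)
    class_names = tuple(sorted(np.unique(y)))
    pooled = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    accs = np.empty(config.repeats)
    repeat_seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.repeats)
    for rep in range(config.repeats):
        fold_seed = int(repeat_seeds[2 * rep] % (2**31 - 1))
        clf_seed = int(repeat_seeds[2 * rep + 1] % (2**31 - 1))
        assignment = kfold_partition(
            len(y), config.n_folds, fold_seed, stratify=config.stratified, labels=y
        )
        rep_conf = np.zeros_like(pooled)
        for fold in range(config.n_folds):
            test = assignment == fold
            model = train_classifier(X[~test], y[~test], config, random_state=clf_seed + fold)
            pred = predict(model, X[test])
            rep_conf += confusion_matrix(y[test], pred, labels=class_names)
        accs[rep] = accuracy(rep_conf)
        pooled += rep_conf
    confusion = pd.DataFrame(pooled, index=class_names, columns=class_names)
    return CVResult(accuracies=accs, confusion=confusion, config=config,
                    labels=class_names)


def one_way_anova(*groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value across accuracy groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least two observations")
    F, p = stats.f_oneway(*arrays)
    return float(F), float(p)


def extract_features(
    dataset: AerosolDataset, method: str, r: int, input_rank: int | None = None
) -> FeatureTable:
    """Assemble snapshots, fit one extraction method, and project the dataset."""
    method = method.upper()
    snap = assemble_snapshots(dataset)
    if method == "POD":
        basis = pod(snap, r)
    elif method == "PCA":
        basis = pca(snap, r)
    elif method in ("DMD", "DMDC"):
        Xp, Xdp = split_transitions(snap)
        if method == "DMD":
            basis = dmd(Xp, Xdp, r)
        else:
            Y = build_control_matrix(Xp.columns, standardize=True)
            basis, _ = dmdc(Xp, Xdp, Y, p=input_rank, r=r)
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    return build_feature_table(basis, dataset, min(r, basis.rank_used))


def sweep_feature_tables(
    tables: dict[str, FeatureTable],
    classifiers: tuple[str, ...] = CLASSIFIERS,
    r_list: tuple[int, ...] = DEFAULT_R_LIST,
    config: CVConfig | None = None,
) -> pd.DataFrame:
    """CV sweep over (method, classifier, retained modes) on prepared tables.

    Each table holds the maximal-rank features of one method; cell features
    are its leading-r columns.  One master seed fans out one stream per cell
    (in deterministic method × r × classifier order, skipped cells included),
    so any cell is independently reproducible.  Cells whose r exceeds the
    available rank are skipped and logged.
    """
    config = config or CVConfig()
    cell_seeds = np.random.SeedSequence(config.seed).generate_state(
        len(tables) * len(classifiers) * len(r_list)
    )
    rows = []
    i = 0
    for method, table_full in tables.items():
        for r in r_list:
            for clf in classifiers:
                seed = int(cell_seeds[i] % (2**31 - 1))
                i += 1
                if r > table_full.r:
                    logger.warning(
                        "skipping %s/%s r=%d: only %d modes available",
                        method, clf, r, table_full.r,
                    )
                    continue
                sub = FeatureTable(
                    features=table_full.features[:, :r],
                    labels=table_full.labels,
                    conditions=table_full.conditions,
                    method=method,
                    r=r,
                )
                result = run_cv(sub, replace(config, classifier=clf, seed=seed))
                stats_ = result.box_stats()
                rows.append(
                    {
                        "method": method,
                        "classifier": clf,
                        "r": r,
                        "mean_acc": stats_["mean"],
                        "sd": stats_["sd"],
                        "q1": stats_["q1"],
                        "median": stats_["median"],
                        "q3": stats_["q3"],
                        "n_outliers": stats_["n_outliers"],
                        "repeats": config.repeats,
                    }
                )
    return pd.DataFrame(rows)


def mode_sweep(
    dataset: AerosolDataset,
    methods: tuple[str, ...] = METHODS,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    r_list: tuple[int, ...] = DEFAULT_R_LIST,
    config: CVConfig | None = None,
) -> pd.DataFrame:
    """Full factorial sweep: extract features per method, then CV every cell."""
    r_max = max(r_list)
    tables = {m: extract_features(dataset, m, r_max) for m in methods}
    return sweep_feature_tables(tables, classifiers, r_list, config)
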
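"""Subject-wise sleep-stage classification with gradient-boosted trees.

The cohort is divided into 30 distinct 80/20 subject splits (11 train / 3
test of 14); for each split a gradient-boosting classifier is tuned by
grid search under subject-grouped 5-fold cross-validation (no subject ever
spans train and validation of a fold), refit on the full training set, and
evaluated per epoch on the held-out subjects.  Accuracies, confusion
matrices and normalised feature importances are aggregated over splits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GroupKFold

from .recording import STAGES

__all__ = [
    "SplitScheme",
    "ClassifierConfig",
    "ClassifierRun",
    "AggregateResult",
    "make_splits",
    "grid_search",
    "fit_evaluate",
    "run_classification",
    "aggregate",
    "compare_metrics",
]

#: (learning_rate, n_estimators, max_depth)
HyperParams = tuple[float, int, int]

#: Full hyperparameter grid of the reference analysis (150 combinations).
FULL_LEARNING_RATES = (0.005, 0.01, 0.05, 0.1, 0.15)
FULL_N_ESTIMATORS = (250, 500, 750, 1000, 1250, 1500)
FULL_MAX_DEPTHS = (3, 4, 5, 6, 7)

#: Cheap 3-combination grid for routine runs and CI; adequate shallow
#: models — the full grid is opt-in because of its compute cost.
REDUCED_GRID: tuple[HyperParams, ...] = (
    (0.1, 100, 3),
    (0.05, 100, 3),
    (0.1, 200, 3),
)


@dataclass
class SplitScheme:
    """A list of subject-disjoint (train, test) partitions."""

    splits: list[tuple[tuple[str, ...], tuple[str, ...]]]
    seed: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for train, test in self.splits:
            if set(train) & set(test):
                raise ValueError("train and test subjects overlap")
            key = tuple(sorted(test))
            if key in seen:
                raise ValueError("duplicate test set in split scheme")
            seen.add(key)

    @property
    def n_splits(self) -> int:
        return len(self.splits)


@dataclass
class ClassifierConfig:
    """Hyperparameter search space and CV layout.

    ``grid_mode='full'`` spans the reference 5 x 6 x 5 = 150 combinations;
    ``'reduced'`` uses :data:`REDUCED_GRID` (or ``reduced_grid`` if given).
    """

    learning_rates: tuple[float, ...] = FULL_LEARNING_RATES
    n_estimators: tuple[int, ...] = FULL_N_ESTIMATORS
    max_depths: tuple[int, ...] = FULL_MAX_DEPTHS
    cv_folds: int = 5
    grid_mode: str = "full"
    reduced_grid: tuple[HyperParams, ...] = REDUCED_GRID

    def __post_init__(self) -> None:
        if self.grid_mode not in ("full", "reduced"):
            raise ValueError("grid_mode must be 'full' or 'reduced'")

    @property
    def grid(self) -> tuple[HyperParams, ...]:
        if self.grid_mode == "reduced":
            return tuple(self.reduced_grid)
        return tuple(
            (lr, ne, md)
            for lr in self.learning_rates
            for ne in self.n_estimators
            for md in self.max_depths
        )


@dataclass
class ClassifierRun:
    """One train/test split's result for one feature set."""

    metric: str
    split_index: int
    best_hyperparams: HyperParams
    accuracy: float
    confusion: np.ndarray  # 4 x 4, rows = true stage, cols = predicted
    importances: np.ndarray  # normalised, sums to 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy outside [0, 1]")


@dataclass
class AggregateResult:
    """Aggregation of many runs of the same metric."""

    metric: str
    accuracies: np.ndarray
    mean_accuracy: float
    mean_confusion: np.ndarray
    mean_importances: np.ndarray
    band_shares: dict[str, float] = field(default_factory=dict)


def make_splits(
    subject_ids: list[str],
    n_splits: int = 30,
    test_n: int = 3,
    seed: int = 0,
) -> SplitScheme:
    """Sample distinct test sets uniformly without replacement.

    All C(n_subjects, test_n) candidate test sets are enumerated and
    ``n_splits`` of them drawn without replacement, so every scheme is a
    set of distinct subject-disjoint 80/20 partitions.
    """
    subject_ids = list(subject_ids)
    candidates = list(itertools.combinations(sorted(subject_ids), test_n))
    if n_splits > len(candidates):
        raise ValueError(
            f"requested {n_splits} splits but only {len(candidates)} distinct "
            f"test sets of size {test_n} exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_splits, replace=False)
    splits = []
    for idx in chosen:
        test = candidates[idx]
        train = tuple(s for s in sorted(subject_ids) if s not in test)
        splits.append((train, test))
    return SplitScheme(splits=splits, seed=seed)


def _split_xy(features: pd.DataFrame):
    feat_cols = [c for c in features.columns if c not in ("subject", "stage", "epoch")]
    X = features[feat_cols].to_numpy(dtype=float)
    y = features["stage"].to_numpy()
    groups = features["subject"].to_numpy()
    return X, y, groups


def grid_search(
    train_features: pd.DataFrame,
    config: ClassifierConfig,
    seed: int = 0,
) -> HyperParams:
    """Pick the grid point maximising mean subject-grouped CV accuracy.

    Ties (exact equality of mean CV accuracy) are broken toward the
    cheapest adequate model: smallest n_estimators, then smallest depth,
    then smallest learning rate.
    """
    X, y, groups = _split_xy(train_features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ValueError("grid search needs at least 2 training subjects")
    folds = min(config.cv_folds, n_groups)
    cv = GroupKFold(n_splits=folds)
    results: list[tuple[float, HyperParams]] = []
    for lr, ne, md in config.grid:
        accs = []
        for tr_idx, va_idx in cv.split(X, y, groups):
            clf = GradientBoostingClassifier(
                learning_rate=lr, n_estimators=ne, max_depth=md, random_state=seed
            )
            clf.fit(X[tr_idx], y[tr_idx])
            accs.append(accuracy_score(y[va_idx], clf.predict(X[va_idx])))
        results.append((float(np.mean(accs)), (lr, ne, md)))
    # max accuracy; tie-break (n_estimators, depth, learning rate) ascending
    results.sort(key=lambda r: (-r[0], r[1][1], r[1][2], r[1][0]))
    return results[0][1]


def fit_evaluate(
    split: tuple[tuple[str, ...], tuple[str, ...]],
    features: pd.DataFrame,
    hyperparams: HyperParams,
    metric: str = "COH",
    split_index: int = 0,
    seed: int = 0,
    expected_n_features: int | None = None,
    stages: tuple[str, ...] = STAGES,
) -> ClassifierRun:
    """Fit on all training epochs, evaluate per epoch on held-out subjects."""
    train_subjects, test_subjects = split
    if set(train_subjects) & set(test_subjects):
        raise ValueError("train and test subjects overlap")
    feat_cols = [c for c in features.columns if c not in ("subject", "stage", "epoch")]
    if expected_n_features is not None and len(feat_cols) != expected_n_features:
        raise ValueError(
            f"feature length {len(feat_cols)} does not match schema "
            f"({expected_n_features})"
        )
    train = features[features["subject"].isin(train_subjects)]
    test = features[features["subject"].isin(test_subjects)]
    if train.empty or test.empty:
        raise ValueError("empty train or test set for this split")
    missing_stages = set(stages) - set(train["stage"])
    if missing_stages:
        raise ValueError(f"training data missing stages {sorted(missing_stages)}")

    lr, ne, md = hyperparams
    clf = GradientBoostingClassifier(
        learning_rate=lr, n_estimators=ne, max_depth=md, random_state=seed
    )
    X_tr, y_tr, _ = _split_xy(train)
    X_te, y_te, _ = _split_xy(test)
    clf.fit(X_tr, y_tr)
    y_pred = clf.predict(X_te)
    acc = float(accuracy_score(y_te, y_pred))
    conf = confusion_matrix(y_te, y_pred, labels=list(stages))
    imp = np.asarray(clf.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)
    return ClassifierRun(
        metric=metric,
        split_index=split_index,
        best_hyperparams=hyperparams,
        accuracy=acc,
        confusion=conf,
        importances=imp,
    )


def run_classification(
    features: pd.DataFrame,
    scheme: SplitScheme,
    config: ClassifierConfig | None = None,
    metric: str = "COH",
    seed: int = 0,
    expected_n_features: int | None = None,
) -> list[ClassifierRun]:
    """Grid search + fit/evaluate for every split of the scheme."""
    if config is None:
        config = ClassifierConfig(grid_mode="reduced")
    runs = []
    for k, split in enumerate(scheme.splits):
        train = features[features["subject"].isin(split[0])]
        best = grid_search(train, config, seed=seed)
        runs.append(
            fit_evaluate(
                split, features, best, metric=metric, split_index=k, seed=seed,
                expected_n_features=expected_n_features,
            )
        )
    return runs


def aggregate(
    runs: list[ClassifierRun],
    band_order: tuple[str, ...] = ("delta", "theta", "alpha", "beta"),
) -> AggregateResult:
    """Mean accuracy, element-wise mean confusion, renormalised importances.

    Per-band importance shares assume the canonical band-major feature
    ordering (equal block length per band).
    """
    if not runs:
        raise ValueError("no classifier runs to aggregate")
    metrics = {r.metric for r in runs}
    if len(metrics) != 1:
        raise ValueError(f"mixed metrics in aggregation: {sorted(metrics)}")
    sizes = {r.importances.size for r in runs}
    if len(sizes) != 1:
        raise ValueError("runs have inconsistent feature schemas")
    accs = np.array([r.accuracy for r in runs])
    mean_conf = np.mean([r.confusion for r in runs], axis=0)
    mean_imp = np.mean([r.importances for r in runs], axis=0)
    mean_imp = mean_imp / mean_imp.sum()
    n_feat = mean_imp.size
    shares = {}
    if n_feat % len(band_order) == 0:
        block = n_feat // len(band_order)
        for k, band in enumerate(band_order):
            shares[band] = float(mean_imp[k * block : (k + 1) * block].sum())
    return AggregateResult(
        metric=runs[0].metric,
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        mean_confusion=mean_conf,
        mean_importances=mean_imp,
        band_shares=shares,
    )


def compare_metrics(accuracy_table: pd.DataFrame):
    """One-way ANOVA across metrics plus Tukey HSD pairwise comparisons.

    ``accuracy_table`` has one column per metric, one row per split.
    Returns ``(F, p, tukey)`` where ``tukey`` is a symmetric DataFrame of
    pairwise p-values.
    """
    if accuracy_table.isna().any().any():
        raise ValueError("accuracy table has missing cells")
    cols = list(accuracy_table.columns)
    samples = [accuracy_table[c].to_numpy(dtype=float) for c in cols]
    f_stat, p = sps.f_oneway(*samples)
    res = sps.tukey_hsd(*samples)
    pmat = pd.DataFrame(res.pvalue, index=cols, columns=cols)
    return float(f_stat), float(p), pmat
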
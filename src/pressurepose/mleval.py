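"""Classifier training, feature ranking/selection and LOSO evaluation.

Five classifier configurations are supported (random forest, RBF-kernel SVM
on standardized inputs, a one-hidden-layer 512-unit MLP, 3-nearest-neighbors
and naive Bayes).  Performance is measured by per-class precision, recall
and F1 (harmonic mean of the two) from a pooled confusion matrix, with the
macro (unweighted) mean F1 as the summary score — the right choice when the
classes are unevenly distributed.

Generalization across drivers is estimated by leave-one-subject-out (LOSO)
cross-validation: one fold per subject, so no subject ever contributes to
both the training and the test split of a fold.

Feature importance uses the classic random-forest out-of-bag permutation
method: for every tree, the increase in its out-of-bag classification error
after permuting one feature's values, averaged over trees.  The best feature
subset is then the smallest prefix of the importance ranking whose
cross-validated macro F1 comes within a tolerance of the curve maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

ALGORITHMS = ("RF", "SVM", "MLP", "kNN", "NB")


@dataclass
class ClassifierConfig:
    """Algorithm name plus its hyperparameters.

    Defaults mirror the evaluated configurations: the RF samples 10 candidate
    variables per split and allows at most 200 splits per tree (100 trees);
    the SVM uses an RBF kernel with automatic scale on standardized inputs;
    the MLP has one hidden layer of 512 units, mini-batches of 300, the adam
    optimizer and 40 epochs; kNN uses 3 neighbors.  Naive Bayes is Gaussian
    per feature (the features are continuous signed reals).
    """

    algorithm: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        self.params = {**_DEFAULT_PARAMS[self.algorithm], **self.params}

    @classmethod
    def default(cls, algorithm: str = "RF", **overrides) -> "ClassifierConfig":
        return cls(algorithm, overrides)


_DEFAULT_PARAMS: dict[str, dict] = {
    "RF": {"n_estimators": 100, "max_features": 10, "max_splits": 200},
    "SVM": {"kernel": "rbf", "gamma": "scale", "standardize": True},
    "MLP": {"hidden_width": 512, "batch_size": 300, "solver": "adam", "max_epochs": 40},
    "kNN": {"n_neighbors": 3},
    "NB": {},
}


def make_estimator(config: ClassifierConfig, n_features: int, seed: int = 0):
    """Instantiate the scikit-learn estimator for a configuration."""
    p = config.params
    if config.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"],
            max_features=min(p["max_features"], n_features),
            max_leaf_nodes=p["max_splits"] + 1,  # k splits -> k+1 leaves
            random_state=seed,
        )
    if config.algorithm == "SVM":
        svc = SVC(kernel=p["kernel"], gamma=p["gamma"], random_state=seed)
        if p["standardize"]:
            return Pipeline([("scale", StandardScaler()), ("svc", svc)])
        return svc
    if config.algorithm == "MLP":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(p["hidden_width"],),
                        batch_size=p["batch_size"],
                        solver=p["solver"],
                        max_iter=p["max_epochs"],
                        random_state=seed,
                    ),
                ),
            ]
        )
    if config.algorithm == "kNN":
        return KNeighborsClassifier(n_neighbors=p["n_neighbors"])
    return GaussianNB()


def train(config: ClassifierConfig, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit the configured classifier; deterministic given the seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    est = make_estimator(config, X.shape[1], seed)
    with warnings.catch_warnings():
        # the MLP's fixed epoch budget routinely stops before convergence
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        est.fit(X, y)
    return est


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the class list")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        classes = tuple(classes) if classes is not None else tuple(
            sorted(set(y_true) | set(y_pred))
        )
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(classes=classes, counts=counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class ClassificationReport:
    """Per-class precision / recall / F1 plus the macro-average F1."""

    classes: tuple
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.f1))

    def f1_for(self, cls) -> float:
        return float(self.f1[self.classes.index(cls)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"precision": self.precision, "recall": self.recall, "f1": self.f1},
            index=list(self.classes),
        )


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassificationReport:
    """Per-class one-vs-rest PREC = TP/(TP+FP), REC = TP/(TP+FN) and
    F1 = 2*PREC*REC/(PREC+REC) (zero when PREC+REC is zero)."""
    counts = cm.counts.astype(float)
    if counts.size == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return ClassificationReport(cm.classes, prec, rec, f1)


# ---------------------------------------------------------------------------
# OOB permutation importance


def oob_importance(
    config: ClassifierConfig,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation importance on out-of-bag samples, per tree.

    For each bootstrap tree: fit on the in-bag rows, measure the OOB
    classification error, then for every feature permute its OOB column and
    record the error increase; importances average the increases over trees.
    Returns a DataFrame (feature, importance) sorted by descending
    importance, ties broken by feature order.  Only defined for the RF
    configuration.
    """
    if config.algorithm != "RF":
        raise ValueError("OOB importance is defined for the RF configuration only")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    n_trees = config.params["n_estimators"]
    rng = np.random.default_rng(seed)
    totals = np.zeros(p)
    used = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=min(config.params["max_features"], p),
            max_leaf_nodes=config.params["max_splits"] + 1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        X_oob = X[oob]
        base_err = float(np.mean(tree.predict(X_oob) != y[oob]))
        X_perm = X_oob.copy()
        for j in range(p):
            saved = X_perm[:, j].copy()
            X_perm[:, j] = saved[rng.permutation(len(oob))]
            err = float(np.mean(tree.predict(X_perm) != y[oob]))
            totals[j] += err - base_err
            X_perm[:, j] = saved
        used += 1
    if used == 0:
        raise ValueError("no usable bootstrap tree (too few samples or classes)")
    importance = totals / used
    names = feature_names or [f"f{j}" for j in range(p)]
    df = pd.DataFrame({"feature": names, "importance": importance})
    df["_order"] = np.arange(p)
    df = df.sort_values(["importance", "_order"], ascending=[False, True])
    return df.drop(columns="_order").reset_index(drop=True)


# ---------------------------------------------------------------------------
# LOSO cross-validation and feature selection


@dataclass
class LosoResult:
    confusion: ConfusionMatrix
    report: ClassificationReport
    fold_subjects: list
    fold_reports: list[ClassificationReport]

    def fold_f1_matrix(self) -> pd.DataFrame:
        """Per-fold per-class F1 (rows = held-out subject)."""
        return pd.DataFrame(
            [r.f1 for r in self.fold_reports],
            index=self.fold_subjects,
            columns=list(self.report.classes),
        )


def loso_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: ClassifierConfig,
    seed: int = 0,
    feature_idx: np.ndarray | None = None,
) -> LosoResult:
    """Leave-one-subject-out cross-validation: one fold per subject; test
    predictions pooled into a single confusion matrix; per-fold reports kept
    for paired significance tests."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    if feature_idx is not None:
        X = X[:, np.asarray(feature_idx)]
    subjects = list(pd.unique(groups))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    classes = tuple(sorted(np.unique(y)))
    y_pred = np.empty(len(y), dtype=y.dtype)
    fold_reports: list[ClassificationReport] = []
    for subj in subjects:
        test = groups == subj
        if len(np.unique(y[~test])) < 2:
            warnings.warn(f"training split for held-out {subj!r} has a single class")
        est = train(config, X[~test], y[~test], seed=seed)
        y_pred[test] = est.predict(X[test])
        fold_cm = ConfusionMatrix.from_predictions(y[test], y_pred[test], classes)
        fold_reports.append(metrics_from_confusion(fold_cm))
    pooled = ConfusionMatrix.from_predictions(y, y_pred, classes)
    return LosoResult(pooled, metrics_from_confusion(pooled), subjects, fold_reports)


@dataclass
class SelectionCurve:
    """Macro F1 as a function of the number of top-ranked features used."""

    ranked_features: list
    points: list[tuple[int, float]]
    best_n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["n_features", "macro_f1"])


def _default_grid(p: int) -> list[int]:
    grid = list(range(1, min(p, 15) + 1))
    grid += list(range(20, min(p, 60) + 1, 10))
    grid += list(range(80, p + 1, 40))
    if p not in grid:
        grid.append(p)
    return sorted(set(g for g in grid if 1 <= g <= p))


def select_features(
    ranked: pd.DataFrame | list,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    tolerance: float = 0.01,
    grid: list[int] | None = None,
    feature_names: list[str] | None = None,
) -> SelectionCurve:
    """Macro-F1-vs-feature-count curve over prefixes of an importance ranking.

    ``ranked`` is the output of :func:`oob_importance` (or any list of
    feature names / column indices, most important first).  ``best_n`` is the
    smallest prefix whose score comes within ``tolerance`` of the curve
    maximum — more features do not necessarily improve recognition.
    """
    config = config or ClassifierConfig.default("RF")
    names = feature_names or [f"f{j}" for j in range(np.asarray(X).shape[1])]
    if isinstance(ranked, pd.DataFrame):
        ranked_names = list(ranked["feature"])
    else:
        ranked_names = [names[r] if isinstance(r, (int, np.integer)) else r for r in ranked]
    if not ranked_names:
        raise ValueError("empty feature ranking")
    order = [names.index(r) for r in ranked_names]
    grid = grid or _default_grid(len(order))
    points: list[tuple[int, float]] = []
    for n_feat in grid:
        res = loso_cv(X, y, groups, config, seed=seed, feature_idx=np.array(order[:n_feat]))
        points.append((n_feat, res.report.macro_f1))
    best_f1 = max(f for _, f in points)
    best_n = next(n for n, f in points if f >= best_f1 - tolerance)
    return SelectionCurve(ranked_features=ranked_names, points=points, best_n=best_n)


# ---------------------------------------------------------------------------
# paired comparison against the full-resolution benchmark


def paired_fold_ttest(
    benchmark: LosoResult, candidate: LosoResult
) -> pd.DataFrame:
    """Two-sided paired t-test per class on the per-fold F1 vectors.

    Folds pair by held-out subject.  Identical score vectors give t = 0,
    p = 1 by convention.  Flags mark p < 0.05 and p < 0.01.
    """
    if benchmark.fold_subjects != candidate.fold_subjects:
        raise ValueError("fold subjects differ between the two results")
    a = benchmark.fold_f1_matrix()
    b = candidate.fold_f1_matrix()
    rows = []
    for cls in a.columns:
        diff = b[cls].to_numpy() - a[cls].to_numpy()
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(b[cls], a[cls])
        rows.append({"class": cls, "t": float(t), "p": float(p),
                     "sig_05": p < 0.05, "sig_01": p < 0.01})
    return pd.DataFrame(rows).set_index("class")


def benchmark_layouts(dataset, levels, config=None, feature_subset=None, **kwargs):
    """Compare reduced layouts to the full-resolution benchmark; see
    :func:`pressurepose.pipeline.benchmark_layouts` for the full contract."""
    from .pipeline import benchmark_layouts as _impl

    return _impl(dataset, levels, config=config, feature_subset=feature_subset, **kwargs)
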
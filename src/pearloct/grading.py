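"""Luster grade prediction and feature analysis.

The 237-feature table feeds two classifier families — an SVM (rbf /
poly / sigmoid kernels) and a random forest — tuned by randomized
search under stratified 5-fold cross-validation.  Experiments follow a
repeated-holdout protocol: a stratified 80/20 split, tuning on the
train split, evaluation on the test split, repeated with independent
seeds, and the per-run macro precision / recall / F1 / accuracy
aggregated as max / min / avg.  PCA to 6 components (fit on the train
split only, after z-scoring) and backward sequential feature selection
provide the two feature-analysis views.

:class:`LusterGrader` wraps the protocol in a model object whose
``fit()`` returns a :class:`GradingResults` carrying per-run metrics,
confusion matrices, tuned hyperparameters and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import (
    RandomizedSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FAMILY_BLOCKS, N_FEATURES, feature_names

__all__ = [
    "GRADES",
    "FeatureTable",
    "SplitSpec",
    "SearchSpace",
    "GradeReport",
    "PcaModel",
    "SelectionMask",
    "GradingError",
    "split",
    "tune_and_train",
    "evaluate",
    "repeated_experiment",
    "pca_reduce",
    "sequential_select",
    "LusterGrader",
    "GradingResults",
]

GRADES = ("A", "B", "C", "D")
METRICS = ("precision", "recall", "f1", "accuracy")


class GradingError(ValueError):
    """Invalid input to a grading operation."""


@dataclass
class FeatureTable:
    """n_samples x n_features numeric matrix with A-D luster labels."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=feature_names)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.labels.size:
            raise GradingError("matrix and labels are inconsistent")
        if self.matrix.shape[1] != len(self.feature_names):
            raise GradingError("feature_names length does not match the matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise GradingError("feature table contains non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label") -> "FeatureTable":
        cols = [c for c in df.columns if c not in (label_col, "source_id")]
        return cls(
            matrix=df[cols].to_numpy(float),
            labels=df[label_col].to_numpy(),
            feature_names=list(cols),
        )

    def to_dataframe(self, label_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df[label_col] = self.labels
        return df

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.matrix[idx], self.labels[idx], self.feature_names)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified holdout specification (default 80/20)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise GradingError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SearchSpace:
    """Randomized-search space for both classifier families.

    SVM: kernel in {rbf, poly, sigmoid}, C log-uniform [1e-2, 1e2],
    gamma log-uniform [1e-4, 1].  RFC: 5-200 trees, 1-20 max features,
    gini/entropy.  ``iterations`` counts sampled configurations
    (desk-scale default 200; raise for exhaustive searches); scoring is
    mean accuracy under stratified ``cv_folds``-fold CV.
    """

    svm_kernels: tuple[str, ...] = ("rbf", "poly", "sigmoid")
    svm_c_range: tuple[float, float] = (1e-2, 1e2)
    svm_gamma_range: tuple[float, float] = (1e-4, 1.0)
    rfc_trees_range: tuple[int, int] = (5, 200)
    rfc_max_features_range: tuple[int, int] = (1, 20)
    rfc_criteria: tuple[str, ...] = ("gini", "entropy")
    iterations: int = 200
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise GradingError("iterations must be >= 1")
        if self.cv_folds < 2:
            raise GradingError("cv_folds must be >= 2")


@dataclass
class GradeReport:
    """Per-run metrics plus max/min/avg aggregates (the repeated-holdout shape)."""

    per_run: list[dict[str, Any]]

    @property
    def aggregate(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for split_name in ("train", "test"):
            for m in METRICS:
                vals = [r[split_name][m] for r in self.per_run]
                out[f"{split_name}_{m}"] = {
                    "max": float(np.max(vals)),
                    "min": float(np.min(vals)),
                    "avg": float(np.mean(vals)),
                }
        return out

    def to_dict(self) -> dict[str, Any]:
        return {"per_run": self.per_run, "aggregate": self.aggregate}


@dataclass
class PcaModel:
    """Train-fit PCA (after z-scoring) to k components."""

    scaler: StandardScaler
    pca: PCA

    @property
    def component_loadings(self) -> np.ndarray:
        return self.pca.components_.T

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(X))


@dataclass
class SelectionMask:
    """Backward-SFS result: retained-feature mask and per-family counts."""

    fraction: float
    selected: np.ndarray
    feature_names: list[str]

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def family_counts(self) -> dict[str, int]:
        return {
            fam: int(self.selected[a:b].sum())
            for fam, (a, b) in FAMILY_BLOCKS.items()
            if b <= self.selected.size
        }

    def to_dict(self) -> dict[str, Any]:
        return {
            "fraction": self.fraction,
            "n_selected": self.n_selected,
            "selected": self.selected.astype(bool).tolist(),
            "family_counts": self.family_counts,
        }


# ---------------------------------------------------------------------------
# operations

def split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Stratified, seeded train/test partition (116 samples -> 92/24)."""
    classes, counts = np.unique(table.labels, return_counts=True)
    if np.any(counts < 2):
        raise GradingError("every class needs at least 2 samples to split")
    idx = np.arange(len(table))
    tr, te = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=table.labels if spec.stratified else None,
        random_state=spec.seed,
    )
    return table.subset(np.sort(tr)), table.subset(np.sort(te))


def _build_estimator_and_space(
    model_kind: str, space: SearchSpace
) -> tuple[Any, dict[str, Any]]:
    def _loguniform(lo: float, hi: float) -> Any:
        return [lo] if lo == hi else loguniform(lo, hi)  # allow degenerate ranges

    def _randint(lo: int, hi: int) -> Any:
        return [lo] if lo == hi else randint(lo, hi + 1)

    if model_kind == "svm":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", SVC())]
        )
        dist = {
            "clf__kernel": list(space.svm_kernels),
            "clf__C": _loguniform(*space.svm_c_range),
            "clf__gamma": _loguniform(*space.svm_gamma_range),
        }
    elif model_kind == "rfc":
        est = RandomForestClassifier()
        dist = {
            "n_estimators": _randint(*space.rfc_trees_range),
            "max_features": _randint(*space.rfc_max_features_range),
            "criterion": list(space.rfc_criteria),
        }
    else:
        raise GradingError(f"unknown model kind {model_kind!r}; expected 'svm' or 'rfc'")
    return est, dist


def tune_and_train(
    train: FeatureTable,
    space: SearchSpace,
    model_kind: str,
    seed: int = 0,
) -> tuple[Any, dict[str, Any]]:
    """Randomized hyperparameter search (stratified k-fold CV accuracy),
    refit on the full train split.  Returns (fitted model, best params).

    Features are z-scored inside the SVM pipeline; the forest consumes
    raw features.  Deterministic for a given seed.
    """
    if len(train) == 0:
        raise GradingError("empty training table")
    _, counts = np.unique(train.labels, return_counts=True)
    if np.any(counts < space.cv_folds):
        raise GradingError(
            f"every class needs >= {space.cv_folds} train samples for "
            f"{space.cv_folds}-fold stratified CV"
        )
    est, dist = _build_estimator_and_space(model_kind, space)
    if model_kind == "rfc":
        est.set_params(random_state=seed)
        dist = dict(dist)
        dist["max_features"] = randint(
            space.rfc_max_features_range[0],
            min(space.rfc_max_features_range[1], train.matrix.shape[1]) + 1,
        )
    n_unique = None
    if all(not hasattr(v, "rvs") for v in dist.values()):
        n_unique = int(np.prod([len(v) for v in dist.values()]))
    search = RandomizedSearchCV(
        est,
        dist,
        n_iter=space.iterations if n_unique is None else min(space.iterations, n_unique),
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=space.cv_folds, shuffle=True, random_state=seed),
        random_state=seed,
        n_jobs=1,
        refit=True,
    )
    search.fit(train.matrix, train.labels)
    return search.best_estimator_, dict(search.best_params_)


def evaluate(model: Any, test: FeatureTable) -> dict[str, Any]:
    """Confusion matrix plus macro precision/recall/F1 and accuracy."""
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and n_expected != test.matrix.shape[1]:
        raise GradingError(
            f"model expects {n_expected} features, table has {test.matrix.shape[1]}"
        )
    pred = model.predict(test.matrix)
    labels = [g for g in GRADES if g in set(test.labels) | set(pred)] or list(GRADES)
    cm = confusion_matrix(test.labels, pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        test.labels, pred, labels=labels, average="macro", zero_division=0
    )
    acc = float(np.trace(cm) / cm.sum())
    return {
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "accuracy": acc,
        "confusion_matrix": cm.tolist(),
        "confusion_labels": labels,
    }


def repeated_experiment(
    table: FeatureTable,
    spec: SplitSpec,
    space: SearchSpace,
    model_kind: str,
    n_runs: int = 10,
    seeds: Sequence[int] | None = None,
    use_pca: bool = False,
    n_components: int = 6,
) -> GradeReport:
    """``n_runs`` independent split / tune / evaluate cycles.

    Each run uses its own seed for the split, the CV folds and the
    search.  With ``use_pca`` the train-fit z-score + PCA projection to
    ``n_components`` scores replaces the raw features (the
    dimension-reduction arm of the protocol).
    """
    if n_runs < 1:
        raise GradingError("n_runs must be >= 1")
    if seeds is None:
        rng = np.random.SeedSequence(spec.seed)
        seeds = [int(s) for s in rng.generate_state(n_runs) % (2**31)]
    elif len(seeds) != n_runs:
        raise GradingError("need one seed per run")
    runs = []
    for run_seed in seeds:
        run_spec = SplitSpec(spec.train_fraction, spec.stratified, int(run_seed))
        train, test = split(table, run_spec)
        pca_info = None
        if use_pca:
            pca_model, train, test = pca_reduce(train, test, k=n_components)
            pca_info = {
                "explained_variance_ratio": pca_model.explained_variance_ratio.tolist(),
                "total_explained_variance": float(
                    pca_model.explained_variance_ratio.sum()
                ),
            }
        model, best = tune_and_train(train, space, model_kind, seed=int(run_seed))
        rec = {
            "seed": int(run_seed),
            "model_kind": model_kind,
            "best_params": {k: (v if isinstance(v, str) else float(v)) for k, v in best.items()},
            "train": evaluate(model, train),
            "test": evaluate(model, test),
        }
        if pca_info is not None:
            rec["pca"] = pca_info
        runs.append(rec)
    return GradeReport(per_run=runs)


def pca_reduce(
    train: FeatureTable, test: FeatureTable, k: int = 6
) -> tuple[PcaModel, FeatureTable, FeatureTable]:
    """Project both splits onto the first k principal components.

    The z-scoring and the components are fit on the train split only,
    so no test information leaks into the projection.
    """
    if k > min(len(train), train.matrix.shape[1]):
        raise GradingError(f"k={k} exceeds min(n_train, n_features)")
    scaler = StandardScaler().fit(train.matrix)
    pca = PCA(n_components=k).fit(scaler.transform(train.matrix))
    model = PcaModel(scaler=scaler, pca=pca)
    names = [f"pc{i + 1}" for i in range(k)]
    return (
        model,
        FeatureTable(model.transform(train.matrix), train.labels, names),
        FeatureTable(model.transform(test.matrix), test.labels, names),
    )


def _cv_accuracy(
    estimator: Any,
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    correct = 0
    for tr, te in folds:
        m = clone(estimator)
        m.fit(X[tr], y[tr])
        correct += int((m.predict(X[te]) == y[te]).sum())
    return correct / X.shape[0]


def sequential_select(
    table: FeatureTable,
    model_kind: str = "rfc",
    fraction: float = 0.2,
    seed: int = 0,
    cv_folds: int = 5,
    estimator: Any | None = None,
) -> SelectionMask:
    """Backward sequential feature selection to ``round(fraction * p)`` features.

    Starting from the full set, each step drops the feature whose
    removal gives the highest stratified-CV accuracy (ties broken by
    the lowest feature index, for determinism).  Hyperparameters are
    frozen: pass a configured *estimator* (e.g. the tuned model) or let
    the default modest SVM/forest stand in.
    """
    p = table.matrix.shape[1]
    n_keep = int(np.floor(fraction * p + 0.5))  # round half up
    if not 0 < n_keep <= p:
        raise GradingError("fraction leaves no features (or more than exist)")
    if estimator is None:
        if model_kind == "svm":
            estimator = Pipeline(
                [("scale", StandardScaler()), ("clf", SVC(kernel="rbf", C=1.0, gamma="scale"))]
            )
        elif model_kind == "rfc":
            estimator = RandomForestClassifier(
                n_estimators=25, max_features="sqrt", random_state=seed
            )
        else:
            raise GradingError(f"unknown model kind {model_kind!r}")
    X, y = table.matrix, table.labels
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]
    selected = np.ones(p, dtype=bool)
    while selected.sum() > n_keep:
        active = np.flatnonzero(selected)
        best_score, best_feature = -np.inf, None
        for f in active:
            trial = selected.copy()
            trial[f] = False
            score = _cv_accuracy(estimator, X[:, trial], y, folds)
            if score > best_score:  # strict: ties keep the lowest index
                best_score, best_feature = score, f
        selected[best_feature] = False
    return SelectionMask(
        fraction=fraction, selected=selected, feature_names=table.feature_names
    )


# ---------------------------------------------------------------------------
# model/results objects

class LusterGrader:
    """Repeated-holdout luster grading model over a texture feature table.

    Parameters
    ----------
    table
        The n x 237 feature table with A-D labels.
    model_kind
        ``"svm"`` or ``"rfc"``.
    use_pca, n_components
        Replace raw features by train-fit PCA scores (default 6
        components) in every run.
    split_spec, search_space
        Holdout and randomized-search settings.
    """

    def __init__(
        self,
        table: FeatureTable,
        model_kind: str = "rfc",
        use_pca: bool = False,
        n_components: int = 6,
        split_spec: SplitSpec | None = None,
        search_space: SearchSpace | None = None,
    ) -> None:
        if model_kind not in ("svm", "rfc"):
            raise GradingError(f"unknown model kind {model_kind!r}")
        self.table = table
        self.model_kind = model_kind
        self.use_pca = use_pca
        self.n_components = n_components
        self.split_spec = split_spec or SplitSpec()
        self.search_space = search_space or SearchSpace()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs: Any) -> "LusterGrader":
        return cls(FeatureTable.from_dataframe(df, label_col), **kwargs)

    def fit(self, n_runs: int = 10, seed: int | None = None) -> "GradingResults":
        """Run the repeated experiment and return the results object."""
        spec = self.split_spec
        if seed is not None:
            spec = SplitSpec(spec.train_fraction, spec.stratified, seed)
        report = repeated_experiment(
            self.table,
            spec,
            self.search_space,
            self.model_kind,
            n_runs=n_runs,
            use_pca=self.use_pca,
            n_components=self.n_components,
        )
        return GradingResults(model=self, report=report)


class GradingResults:
    """Results of a repeated luster-grading experiment."""

    def __init__(self, model: LusterGrader, report: GradeReport) -> None:
        self.model = model
        self.report = report
        self.per_run = report.per_run
        self.aggregate = report.aggregate

    @property
    def test_accuracy(self) -> float:
        return self.aggregate["test_accuracy"]["avg"]

    def mean_confusion(self) -> np.ndarray:
        return np.mean([np.array(r["test"]["confusion_matrix"]) for r in self.per_run], axis=0)

    def summary(self) -> str:
        """Max/min/avg of the four metrics on train and test splits."""
        kind = self.model.model_kind.upper()
        arm = "PCA" if self.model.use_pca else "all"
        lines = [
            f"Luster grading: {kind} ({arm} features), "
            f"{len(self.per_run)} runs of stratified "
            f"{self.model.split_spec.train_fraction:.0%} holdout",
            "",
            f"{'metric':<18}{'max':>8}{'min':>8}{'avg':>8}",
        ]
        for split_name in ("train", "test"):
            for m in METRICS:
                agg = self.aggregate[f"{split_name}_{m}"]
                lines.append(
                    f"{split_name + '_' + m:<18}"
                    f"{agg['max']:>8.3f}{agg['min']:>8.3f}{agg['avg']:>8.3f}"
                )
        return "\n".join(lines)

    def plot_confusion(self, ax: Any = None) -> Any:
        """Heatmap of the mean test confusion matrix across runs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cm = self.mean_confusion()
        labels = self.per_run[0]["test"]["confusion_labels"]
        im = ax.imshow(cm, cmap="Blues")
        ax.set_xticks(range(len(labels)), labels)
        ax.set_yticks(range(len(labels)), labels)
        ax.set_xlabel("predicted grade")
        ax.set_ylabel("true grade")
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                ax.text(j, i, f"{cm[i, j]:.1f}", ha="center", va="center")
        ax.figure.colorbar(im, ax=ax)
        return ax
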
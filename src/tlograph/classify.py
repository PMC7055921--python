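"""SVM classification of infiltrates and class-level statistics.

Infiltrates fall into four organization classes ranked by B-cell
organization: pure T-cell areas, mixed unstructured infiltrates,
intermediately organized structures, and TLO-like structures.  A
radial-kernel SVM over five graph features (|E|, |Eα^B|/|E|, |V_B|/|V|,
κ(2), κ(5)) is evaluated in stratified 5-fold cross-validation; per-class
one-vs-rest confusion metrics are measured on each test fold and averaged
over folds, and the overall row is the unweighted macro-average across the
four classes.  PCA and Kruskal–Wallis / Mann–Whitney comparisons probe
whether the features separate the classes at all.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


class ClassLabel(str, enum.Enum):
    T_CELL_AREA = "T_CELL_AREA"
    MIXED_UNSTRUCTURED = "MIXED_UNSTRUCTURED"
    INTERMEDIATE = "INTERMEDIATE"
    TLO_LIKE = "TLO_LIKE"


#: Features used by the SVM.
SVM_FEATURES = ("n_edges", "frac_alpha_B", "frac_B", "kappa_2", "kappa_5")
#: Features used in the PCA overview.
PCA_FEATURES = (
    "n_nodes",
    "n_edges",
    "frac_alpha_B",
    "frac_B",
    "kappa_2",
    "kappa_5",
    "homogeneity",
    "clustering_C",
    "avg_degree",
    "mean_pairwise_dist_um",
)

METRIC_NAMES = ("TPR", "TNR", "PPV", "NPV", "ACC", "F1")


class InsufficientClassSupportError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMetrics:
    """One-vs-rest confusion counts with derived rates.

    Any rate with a zero denominator is None ("undefined"), never silently
    zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion count")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("empty confusion")

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def tpr(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def tnr(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def acc(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def f1(self) -> float | None:
        return self._ratio(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "TPR": self.tpr,
            "TNR": self.tnr,
            "PPV": self.ppv,
            "NPV": self.npv,
            "ACC": self.acc,
            "F1": self.f1,
        }


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def assemble_feature_matrix(
    feature_table: pd.DataFrame,
    labels: list | None = None,
    feature_subset: tuple[str, ...] = SVM_FEATURES,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Dense numeric matrix from a feature table (rows = infiltrates).

    Raises on missing columns, missing values, or label/row mismatch.
    """
    missing = [f for f in feature_subset if f not in feature_table.columns]
    if missing:
        raise KeyError(f"unknown feature(s): {missing}")
    x = feature_table.loc[:, list(feature_subset)].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = feature_table.index[np.isnan(x).any(axis=1)].tolist()
        raise ValueError(f"incomplete record(s): rows {bad}")
    y = None
    if labels is not None:
        if len(labels) != len(feature_table):
            raise ValueError("incomplete record: labels do not align with rows")
        y = np.array([str(getattr(l, "value", l)) for l in labels])
    return x, y


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


@dataclass
class CvResult:
    """Fold-averaged one-vs-rest metrics per class, plus the macro row."""

    per_class: dict[str, dict[str, float | None]]
    overall: dict[str, float | None]
    multiclass_accuracy: float
    k_folds: int
    seed: int
    fold_metrics: dict[str, list[dict[str, float | None]]] = field(default_factory=dict)

    def as_table(self) -> pd.DataFrame:
        rows = {cls: m for cls, m in self.per_class.items()}
        rows["overall"] = self.overall
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]


def macro_average(per_class: dict[str, dict[str, float | None]]) -> dict[str, float | None]:
    """Unweighted mean of each metric across classes (the overall row)."""
    return {
        m: _mean_defined([metrics.get(m) for metrics in per_class.values()])
        for m in METRIC_NAMES
    }


def cross_validate_svm(
    x: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    c: float = 1.0,
) -> CvResult:
    """Stratified k-fold CV of a radial-kernel SVM.

    Features are z-scored with statistics from the training folds only (no
    leakage into the test fold).  Multiclass prediction uses the SVM's
    one-vs-one voting; per-class metrics are one-vs-rest confusions on each
    test fold, averaged over folds.  Kernel width is 1/(p · Var(X_train)).
    """
    classes, counts = np.unique(y, return_counts=True)
    lacking = classes[counts < k_folds]
    if len(lacking):
        raise InsufficientClassSupportError(
            f"insufficient class support: {lacking.tolist()} (< {k_folds} members)"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_metrics: dict[str, list[dict[str, float | None]]] = {c_: [] for c_ in classes}
    fold_acc: list[float] = []
    for train_idx, test_idx in skf.split(x, y):
        scaler = StandardScaler().fit(x[train_idx])
        clf = SVC(kernel="rbf", C=c, gamma="scale", decision_function_shape="ovo")
        clf.fit(scaler.transform(x[train_idx]), y[train_idx])
        pred = clf.predict(scaler.transform(x[test_idx]))
        truth = y[test_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        for cls in classes:
            tp = int(np.sum((pred == cls) & (truth == cls)))
            tn = int(np.sum((pred != cls) & (truth != cls)))
            fp = int(np.sum((pred == cls) & (truth != cls)))
            fn = int(np.sum((pred != cls) & (truth == cls)))
            fold_metrics[cls].append(confusion_metrics(tp, tn, fp, fn).as_dict())
    per_class = {
        cls: {m: _mean_defined([f[m] for f in folds]) for m in METRIC_NAMES}
        for cls, folds in fold_metrics.items()
    }
    return CvResult(
        per_class=per_class,
        overall=macro_average(per_class),
        multiclass_accuracy=float(np.mean(fold_acc)),
        k_folds=k_folds,
        seed=seed,
        fold_metrics=fold_metrics,
    )


def pca_projection(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardized PCA: (explained-variance proportions, projected coords).

    Constant features are dropped (their z-score is undefined) before
    projection; proportions are sorted descending and sum to 1.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    keep = x.std(axis=0) > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) before PCA")
    x = x[:, keep]
    z = StandardScaler().fit_transform(x)
    pca = PCA()
    coords = pca.fit_transform(z)
    return pca.explained_variance_ratio_, coords


def class_feature_tests(
    feature_table: pd.DataFrame,
    labels: list,
    alpha: float = 0.001,
    features: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Nonparametric class comparisons per feature.

    Kruskal–Wallis across all classes, plus per class a Mann–Whitney U of
    that class against the pooled remainder.  Raw p-values (no multiplicity
    correction) with a boolean significance flag at ``alpha``; an all-tied
    feature gets p = 1 with a degenerate flag.
    """
    y = np.array([str(getattr(l, "value", l)) for l in labels])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or (counts < 2).any():
        raise InsufficientClassSupportError(
            "insufficient class support: need >= 2 classes with >= 2 members"
        )
    if features is None:
        features = tuple(feature_table.columns)
    rows = []
    for feat in features:
        vals = feature_table[feat].to_numpy(dtype=float)
        groups = [vals[y == cls] for cls in classes]
        degenerate = len(np.unique(vals)) == 1
        if degenerate:
            kw_p = 1.0
        else:
            kw_p = float(stats.kruskal(*groups).pvalue)
        row = {
            "feature": feat,
            "kruskal_p": kw_p,
            "kruskal_significant": bool(kw_p < alpha),
            "degenerate": degenerate,
        }
        for cls, grp in zip(classes, groups):
            rest = vals[y != cls]
            if degenerate:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(grp, rest, alternative="two-sided").pvalue)
            row[f"mwu_p_{cls}"] = p
            row[f"mwu_significant_{cls}"] = bool(p < alpha)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
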
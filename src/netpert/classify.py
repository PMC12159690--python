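"""Linear-SVM evaluation of deviation features.

Features are either the vectorized strict lower triangle of each
subject's deviation z-matrix (m(m-1)/2 edge features) or the per-region
RED vector (m features).  Evaluation uses stratified 5-fold
cross-validation — each fold holds out 20% for testing and trains on
80% — with an optional in-fold SMOTE step for class imbalance, a linear
SVM (C = 1), and a label-permutation null for the balanced accuracy.
Three-class problems use a one-vs-one strategy with macro-averaged
pairwise AUC.

Per-fold feature standardization is available but off by default:
deviation z-scores (and the RED values derived from them) already share
a calibrated scale, and re-estimating thousands of per-edge scale
factors from a few dozen training subjects only injects noise.  Turn it
on for heterogeneous feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import REDMatrix, threshold_extreme
from .network import DeviationMatrix

__all__ = [
    "FeatureSet",
    "SVMConfig",
    "ClassificationReport",
    "PermutationTestResult",
    "vectorize_lower_triangle",
    "matrix_from_lower_triangle",
    "features_from_deviations",
    "features_from_red",
    "train_eval_svm",
    "permutation_test",
    "smote_balance",
]


def vectorize_lower_triangle(dev: DeviationMatrix | np.ndarray) -> np.ndarray:
    """Strict lower triangle in row-major order: (1,0), (2,0), (2,1), ...

    Length m(m-1)/2.
    """
    z = dev.z if isinstance(dev, DeviationMatrix) else np.asarray(dev, dtype=float)
    i, j = np.tril_indices(z.shape[0], k=-1)
    return z[i, j]


def matrix_from_lower_triangle(vec: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from its strict lower
    triangle (inverse of :func:`vectorize_lower_triangle`)."""
    vec = np.asarray(vec, dtype=float)
    m = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if m * (m - 1) // 2 != vec.size:
        raise ValueError(f"length {vec.size} is not m(m-1)/2 for any integer m")
    out = np.zeros((m, m))
    i, j = np.tril_indices(m, k=-1)
    out[i, j] = vec
    out[j, i] = vec
    return out


@dataclass
class FeatureSet:
    """Subjects x features design matrix with class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_kind: str = "edges"
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        n_classes = np.unique(self.y).size
        if n_classes not in (2, 3):
            raise ValueError(f"expected 2 or 3 classes, found {n_classes}")
        if self.feature_kind not in ("edges", "red"):
            raise ValueError("feature_kind must be 'edges' or 'red'")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)


def features_from_deviations(
    devs: Sequence[DeviationMatrix],
    labels: Sequence,
    *,
    thresholded: bool = False,
    tau: float = 4.13,
) -> FeatureSet:
    """Edge features: vectorized lower triangles of the raw z-matrices
    (or of the thresholded matrices if requested)."""
    rows = []
    for d in devs:
        mat = threshold_extreme(d, tau=tau).zt if thresholded else d.z
        rows.append(vectorize_lower_triangle(mat))
    return FeatureSet(
        X=np.vstack(rows),
        y=np.asarray(list(labels)),
        feature_kind="edges",
        subject_ids=[d.subject_id for d in devs],
    )


def features_from_red(red: REDMatrix, labels: Sequence) -> FeatureSet:
    return FeatureSet(
        X=red.red.copy(),
        y=np.asarray(list(labels)),
        feature_kind="red",
        subject_ids=list(red.subject_ids),
    )


@dataclass
class SVMConfig:
    """Settings for the linear-SVM evaluation pipeline."""

    n_folds: int = 5
    C: float = 1.0
    standardize: bool = False  # deviation features are already z-scaled
    smote: bool = False
    smote_k: int = 5
    single_split: bool = False  # one fixed stratified 80/20 split instead of CV
    test_fraction: float = 0.2
    seed: int = 0


@dataclass
class ClassificationReport:
    balanced_accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    per_fold: list[dict] = field(default_factory=list)
    permutation_p: float | None = None

    def summary(self) -> str:
        lines = [
            "Linear SVM evaluation",
            f"  balanced accuracy : {self.balanced_accuracy:.3f}",
            f"  AUC               : {self.auc:.3f}",
            f"  sensitivity       : {self.sensitivity:.3f}",
            f"  specificity       : {self.specificity:.3f}",
            f"  folds             : {len(self.per_fold)}",
        ]
        if self.permutation_p is not None:
            lines.append(f"  permutation p     : {self.permutation_p:.4g}")
        return "\n".join(lines)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)


def _splits(fs: FeatureSet, cfg: SVMConfig):
    _, counts = np.unique(fs.y, return_counts=True)
    if counts.min() < 4:
        raise ValueError("need at least 4 subjects per class")
    if cfg.single_split:
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=cfg.test_fraction, random_state=cfg.seed
        )
    else:
        if counts.min() < cfg.n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} subjects, fewer than "
                f"{cfg.n_folds} folds; use fewer folds"
            )
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        )
    return splitter.split(fs.X, fs.y)


def _fit_fold(X_tr, y_tr, cfg: SVMConfig, rng: np.random.Generator):
    scaler = None
    if cfg.standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr = scaler.transform(X_tr)
    if cfg.smote:
        bal = smote_balance(
            FeatureSet(X_tr, y_tr), k=cfg.smote_k, seed=int(rng.integers(2**31 - 1))
        )
        X_tr, y_tr = bal.X, bal.y
    clf = SVC(kernel="linear", C=cfg.C)
    clf.fit(X_tr, y_tr)
    return scaler, clf, X_tr, y_tr


def _binary_fold_metrics(clf, scaler, X_te, y_te, classes) -> dict:
    if scaler is not None:
        X_te = scaler.transform(X_te)
    pred = clf.predict(X_te)
    neg, pos = classes
    sens = np.mean(pred[y_te == pos] == pos) if np.any(y_te == pos) else np.nan
    spec = np.mean(pred[y_te == neg] == neg) if np.any(y_te == neg) else np.nan
    scores = clf.decision_function(X_te)
    auc = roc_auc_score((y_te == pos).astype(int), scores)
    return {
        "balanced_accuracy": balanced_accuracy_score(y_te, pred),
        "auc": float(auc),
        "sensitivity": float(sens),
        "specificity": float(spec),
    }


def _multiclass_fold_metrics(
    clf, scaler, X_tr_raw, y_tr_raw, X_te, y_te, classes, cfg, rng
) -> dict:
    X_te_s = scaler.transform(X_te) if scaler is not None else X_te
    pred = clf.predict(X_te_s)
    recalls, specs = [], []
    for c in classes:
        mask = y_te == c
        if mask.any():
            recalls.append(np.mean(pred[mask] == c))
        rest = ~mask
        if rest.any():
            specs.append(np.mean(pred[rest] != c))
    # one-vs-one pairwise AUCs, each pair fitted on its own training subset
    aucs = []
    for a_idx in range(len(classes)):
        for b_idx in range(a_idx + 1, len(classes)):
            ca, cb = classes[a_idx], classes[b_idx]
            tr_mask = np.isin(y_tr_raw, [ca, cb])
            te_mask = np.isin(y_te, [ca, cb])
            if np.unique(y_te[te_mask]).size < 2:
                continue
            sc, pair_clf, _, _ = _fit_fold(X_tr_raw[tr_mask], y_tr_raw[tr_mask], cfg, rng)
            X_pair = sc.transform(X_te[te_mask]) if sc is not None else X_te[te_mask]
            scores = pair_clf.decision_function(X_pair)
            aucs.append(roc_auc_score((y_te[te_mask] == cb).astype(int), scores))
    return {
        "balanced_accuracy": balanced_accuracy_score(y_te, pred),
        "auc": float(np.mean(aucs)) if aucs else np.nan,
        "sensitivity": float(np.mean(recalls)),
        "specificity": float(np.mean(specs)),
    }


def train_eval_svm(
    fs: FeatureSet, config: SVMConfig | None = None, *, compute_auc: bool = True
) -> ClassificationReport:
    """Cross-validated linear-SVM evaluation.

    Standardization (and SMOTE, if enabled) are fitted inside each
    training fold only; test folds are transformed with the training
    statistics, so no information leaks from the held-out data.
    """
    cfg = config or SVMConfig()
    classes = fs.classes
    rng = np.random.default_rng(cfg.seed)
    per_fold = []
    for train_idx, test_idx in _splits(fs, cfg):
        X_tr_raw, y_tr_raw = fs.X[train_idx], fs.y[train_idx]
        X_te, y_te = fs.X[test_idx], fs.y[test_idx]
        if np.unique(y_te).size < classes.size:
            raise ValueError(
                "a class is absent from a test fold; use fewer folds"
            )
        scaler, clf, _, _ = _fit_fold(X_tr_raw, y_tr_raw, cfg, rng)
        if classes.size == 2:
            metrics = _binary_fold_metrics(clf, scaler, X_te, y_te, classes)
        else:
            metrics = _multiclass_fold_metrics(
                clf, scaler, X_tr_raw, y_tr_raw, X_te, y_te, classes, cfg, rng
            )
        if not compute_auc:
            metrics["auc"] = np.nan
        per_fold.append(metrics)

    def _mean(key):
        vals = np.array([f[key] for f in per_fold])
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")

    mean = {k: _mean(k) for k in per_fold[0]}
    return ClassificationReport(
        balanced_accuracy=mean["balanced_accuracy"],
        auc=mean["auc"],
        sensitivity=mean["sensitivity"],
        specificity=mean["specificity"],
        per_fold=per_fold,
    )


@dataclass
class PermutationTestResult:
    p_value: float
    observed: float
    null_scores: np.ndarray

    @property
    def n_permutations(self) -> int:
        return self.null_scores.size


def permutation_test(
    fs: FeatureSet,
    config: SVMConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Label-permutation null for the cross-validated balanced accuracy.

    The pipeline is re-run on ``n_perm`` random label shufflings and the
    empirical p-value uses the add-one rule
    p = (1 + #{null >= observed}) / (1 + n_perm), which is never zero.
    """
    cfg = config or SVMConfig()
    observed = train_eval_svm(fs, cfg, compute_auc=False).balanced_accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        fs_perm = FeatureSet(
            fs.X, rng.permutation(fs.y), feature_kind=fs.feature_kind
        )
        null[b] = train_eval_svm(fs_perm, cfg, compute_auc=False).balanced_accuracy
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationTestResult(p_value=float(p), observed=float(observed), null_scores=null)


def smote_balance(fs: FeatureSet, k: int = 5, seed: int = 0) -> FeatureSet:
    """Oversample minority classes to the majority size by SMOTE.

    Each synthetic point lies uniformly on the segment between a random
    minority point and one of its k nearest minority-class neighbors.
    Intended for use inside training folds only; applying it before
    splitting leaks synthetic copies of test subjects into training.
    """
    classes, counts = np.unique(fs.y, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return fs
    rng = np.random.default_rng(seed)
    X_new = [fs.X]
    y_new = [fs.y]
    for c, cnt in zip(classes, counts):
        n_syn = target - cnt
        if n_syn == 0:
            continue
        Xc = fs.X[fs.y == c]
        if cnt <= k:
            raise ValueError(
                f"class {c!r} has {cnt} samples, not more than k={k}; use a smaller k"
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)  # +1: self is its own neighbor
        _, idx = nn.kneighbors(Xc)
        parents = rng.integers(0, cnt, size=n_syn)
        neighbor_pick = rng.integers(1, k + 1, size=n_syn)  # skip self at position 0
        gaps = rng.random(n_syn)
        Xp = Xc[parents]
        Xq = Xc[idx[parents, neighbor_pick]]
        X_new.append(Xp + gaps[:, None] * (Xq - Xp))
        y_new.append(np.full(n_syn, c, dtype=fs.y.dtype))
    return FeatureSet(
        X=np.vstack(X_new), y=np.concatenate(y_new), feature_kind=fs.feature_kind
    )
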
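"""Classifier-based evaluation: cross-validation, balancing, robustness.

The evaluation treats each candidate labeling of the sample (from the
clustering constructor or from a norm criterion) as ground truth for a
supervised problem — 13 item scores in, 4 severity levels out — and asks
how learnable it is. The classifier is a shared-covariance linear
discriminant (LDA, SVD solver with tolerance 1e-4, which also handles
rank-deficient pooled covariance); metrics are fold-mean accuracy,
macro one-vs-rest AUC on the class posteriors, and per-class sensitivity
(recall). Folds are stratified by label: the smallest severity class is a
few percent of the sample, and unstratified folds could lose it entirely.

The resampling-robustness protocol re-derives the classification on a
random 70% of the sample (max-min + k-means), extends it to the held-out
30% with an LDA classifier trained on the 70%, and scores the resulting
full-sample labeling against the reference full-sample clustering with
the adjusted Rand index; the ARI distribution over many replicates
summarizes stability under sampling variation.

Every stochastic routine takes a seed and is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .agreement import adjusted_rand
from .cluster import kmeans_fit, maxmin_init, severity_labels
from .dataio import ResponseMatrix

__all__ = [
    "LinearClassifier",
    "CVReport",
    "RobustnessReport",
    "lda_fit",
    "lda_predict",
    "crossval",
    "undersample",
    "robustness",
    "learning_curve",
]


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, ResponseMatrix):
        return matrix.values.astype(float)
    return np.asarray(matrix, dtype=float)


@dataclass
class LinearClassifier:
    """Shared-covariance Gaussian linear discriminant classifier.

    Thin, contract-enforcing wrapper around scikit-learn's
    ``LinearDiscriminantAnalysis(solver="svd", tol=1e-4)``; the SVD route
    drops near-null directions of the pooled covariance below the
    tolerance, which is the documented regularization for degenerate
    feature directions.
    """

    _lda: LinearDiscriminantAnalysis | None = None
    classes_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self._lda is not None


def lda_fit(matrix, labels) -> LinearClassifier:
    """Fit the linear discriminant on item vectors and severity labels."""
    X = _as_array(matrix)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a discriminant")
    if X.shape[0] < len(classes) + 1:
        raise ValueError("need more samples than classes")
    lda = LinearDiscriminantAnalysis(solver="svd", tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear-feature warnings on toys
        lda.fit(X, y)
    return LinearClassifier(_lda=lda, classes_=lda.classes_)


def lda_predict(clf: LinearClassifier, matrix) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class posterior probabilities (rows sum to 1)."""
    if not clf.fitted:
        raise ValueError("classifier is not fitted")
    X = _as_array(matrix)
    if X.shape[1] != clf._lda.n_features_in_:
        raise ValueError(
            f"item count mismatch: classifier expects {clf._lda.n_features_in_}, "
            f"got {X.shape[1]}"
        )
    proba = clf._lda.predict_proba(X)
    labels = clf.classes_[np.argmax(proba, axis=1)]
    return labels, proba


@dataclass
class CVReport:
    """Fold-mean cross-validation metrics for one labeling."""

    n_folds: int
    accuracy: float
    auc_macro: float
    sensitivity: dict          # level -> mean recall over folds
    per_fold: list = field(repr=False, default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "accuracy": self.accuracy,
            "auc_macro": self.auc_macro,
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "seed": self.seed,
            "per_fold": self.per_fold,
        }


def crossval(matrix, labels, folds: int = 10, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation of the linear discriminant."""
    X = _as_array(matrix)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {folds} "
            "folds; reduce the number of folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    per_fold = []
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        clf = lda_fit(X[tr], y[tr])
        pred, proba = lda_predict(clf, X[te])
        acc = float(np.mean(pred == y[te]))
        sens = {}
        for ci, c in enumerate(classes):
            in_class = y[te] == c
            sens[c.item() if hasattr(c, "item") else c] = (
                float(np.mean(pred[in_class] == c)) if in_class.any() else np.nan
            )
        auc = float(roc_auc_score(y[te], proba, multi_class="ovr",
                                  average="macro", labels=clf.classes_))
        per_fold.append({"fold": fold_idx, "accuracy": acc, "auc_macro": auc,
                         "sensitivity": {str(k): v for k, v in sens.items()}})
    sens_mean = {}
    for c in classes:
        key = c.item() if hasattr(c, "item") else c
        vals = [f["sensitivity"][str(key)] for f in per_fold]
        sens_mean[key] = float(np.nanmean(vals))
    return CVReport(
        n_folds=folds,
        accuracy=float(np.mean([f["accuracy"] for f in per_fold])),
        auc_macro=float(np.mean([f["auc_macro"] for f in per_fold])),
        sensitivity=sens_mean,
        per_fold=per_fold,
        seed=int(seed),
    )


def undersample(matrix, labels, seed: int = 0):
    """Random under-sampling of every class to the smallest class size.

    Selected rows keep their original relative order, so the result is
    deterministic given the seed and independent of class numbering.
    """
    X = _as_array(matrix)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.min()
    rng = np.random.default_rng(int(seed))
    chosen = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        chosen.append(rng.choice(idx, size=target, replace=False))
    idx = np.sort(np.concatenate(chosen))
    if isinstance(matrix, ResponseMatrix):
        sub = ResponseMatrix(matrix.values[idx], matrix.item_max)
    else:
        sub = X[idx]
    return sub, y[idx], idx


@dataclass
class RobustnessReport:
    """ARI distribution of the resampling-robustness protocol."""

    reps: int
    train_fraction: float
    ari_values: np.ndarray
    ari_mean: float
    ari_sd: float
    n_failed: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "reps": self.reps,
            "train_fraction": self.train_fraction,
            "ari_mean": self.ari_mean,
            "ari_sd": self.ari_sd,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "ari_values": np.asarray(self.ari_values).tolist(),
        }


def robustness(
    matrix,
    k: int = 4,
    train_fraction: float = 0.7,
    reps: int = 200,
    seed: int = 0,
) -> RobustnessReport:
    """Resampling stability of the max-min k-means classification.

    Reference labeling: max-min + k-means on the full sample, mapped to
    severity levels. Each replicate re-derives the classification on a
    random ``train_fraction`` subsample, labels the complement with an LDA
    classifier fitted on the subsample, reassembles a full-sample labeling
    in original respondent order, and scores it against the reference with
    the ARI. The report carries all replicate ARIs, their mean, and the
    sample SD (denominator reps-1). Subsample indices are kept sorted, so
    ``train_fraction=1.0`` reproduces the reference exactly (ARI 1).
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    X = _as_array(matrix)
    n = X.shape[0]
    reference = severity_labels(kmeans_fit(X, maxmin_init(X, k)))

    rng = np.random.default_rng(int(seed))
    n_train = int(round(train_fraction * n))
    aris, n_failed = [], 0
    for _ in range(reps):
        train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
        try:
            Xtr = X[train_idx]
            model = kmeans_fit(Xtr, maxmin_init(Xtr, k))
            train_sev = severity_labels(model)
            full = np.empty(n, dtype=int)
            full[train_idx] = train_sev
            test_mask = np.ones(n, dtype=bool)
            test_mask[train_idx] = False
            if test_mask.any():
                clf = lda_fit(Xtr, train_sev)
                pred, _ = lda_predict(clf, X[test_mask])
                full[test_mask] = pred
            aris.append(adjusted_rand(reference, full))
        except ValueError:
            n_failed += 1
    aris = np.asarray(aris)
    return RobustnessReport(
        reps=reps,
        train_fraction=train_fraction,
        ari_values=aris,
        ari_mean=float(aris.mean()) if aris.size else float("nan"),
        ari_sd=float(aris.std(ddof=1)) if aris.size > 1 else float("nan"),
        n_failed=n_failed,
        seed=int(seed),
    )


def learning_curve(
    matrix,
    labels,
    train_sizes=(0.1, 0.25, 0.5, 0.75, 1.0),
    folds: int = 5,
    seed: int = 0,
    holdout_fraction: float = 0.3,
) -> pd.DataFrame:
    """Train/test accuracy of the discriminant vs. training-set size.

    Per replicate: a stratified ``holdout_fraction`` test split, then for
    each requested size a stratified subsample of the remaining training
    pool. Sizes too small to keep at least one member per class are
    skipped with a warning. Returns one record per retained size with
    mean train and test accuracy.
    """
    X = _as_array(matrix)
    y = np.asarray(labels)
    classes = np.unique(y)
    rng = np.random.default_rng(int(seed))
    records = {float(s): {"train": [], "test": []} for s in train_sizes}
    if any(not 0 < s <= 1 for s in train_sizes):
        raise ValueError("train sizes must lie in (0, 1]")

    for _ in range(folds):
        # stratified holdout
        test_idx = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            n_test = max(1, int(round(holdout_fraction * idx.size)))
            test_idx.append(rng.choice(idx, size=n_test, replace=False))
        test_idx = np.sort(np.concatenate(test_idx))
        pool = np.setdiff1d(np.arange(y.size), test_idx)
        for s in train_sizes:
            sub = []
            ok = True
            for c in classes:
                idx = pool[y[pool] == c]
                n_sub = int(round(s * idx.size))
                if n_sub < 1:
                    ok = False
                    break
                sub.append(rng.choice(idx, size=n_sub, replace=False))
            if not ok:
                continue
            sub = np.sort(np.concatenate(sub))
            if len(np.unique(y[sub])) < 2:
                continue
            clf = lda_fit(X[sub], y[sub])
            records[float(s)]["train"].append(
                float(np.mean(lda_predict(clf, X[sub])[0] == y[sub]))
            )
            records[float(s)]["test"].append(
                float(np.mean(lda_predict(clf, X[test_idx])[0] == y[test_idx]))
            )

    rows = []
    for s in train_sizes:
        rec = records[float(s)]
        if not rec["train"]:
            warnings.warn(
                f"training size {s} leaves fewer than one sample per class; skipped"
            )
            continue
        rows.append({
            "train_size": float(s),
            "n_splits": len(rec["train"]),
            "train_accuracy": float(np.mean(rec["train"])),
            "test_accuracy": float(np.mean(rec["test"])),
        })
    return pd.DataFrame(rows)
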
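"""Frame-level wheeze classification: native Gaussian naive Bayes, a linear
SVM, the confusion-matrix metrics, and recording-level evaluation protocols.

The Gaussian naive Bayes classifier is fitted in closed form from per-class
sufficient statistics (mean, variance and prior per feature dimension) with
a variance floor for numerically degenerate dimensions.  The SVM contract
(linear kernel, C=1, features standardised with training-set statistics) is
delegated to scikit-learn.

Splits are always at the *recording* level -- all frames of a recording
stay on one side -- so that test frames are never drawn from a recording
seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GNBModel",
    "ConfusionCounts",
    "EvalReport",
    "fit_gnb",
    "predict_gnb",
    "fit_predict_svm",
    "evaluate",
    "holdout_split",
    "kfold_split",
    "kfold_evaluate",
]


@dataclass(frozen=True)
class GNBModel:
    """Per-class Gaussian parameters of a naive Bayes classifier."""

    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray  # (n_classes, n_dims)
    variances: np.ndarray  # (n_classes, n_dims)
    var_floor: float

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts with the derived metrics."""

    t_p: int
    f_p: int
    t_n: int
    f_n: int

    @property
    def total(self) -> int:
        return self.t_p + self.f_p + self.t_n + self.f_n

    @property
    def accuracy(self) -> float:
        return (self.t_p + self.t_n) / self.total

    @property
    def precision(self) -> float:
        return self.t_p / (self.t_p + self.f_p) if self.t_p + self.f_p else 0.0

    @property
    def recall(self) -> float:
        return self.t_p / (self.t_p + self.f_n) if self.t_p + self.f_n else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class EvalReport:
    """Evaluation metrics, optionally with a per-fold breakdown."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts | None = None
    per_fold: list["EvalReport"] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def fit_gnb(features, labels) -> GNBModel:
    """Maximum-likelihood Gaussian naive Bayes fit.

    Per class and dimension: sample mean and (biased, ML) variance; priors
    from class frequencies; variances floored at ``1e-9 * max`` pooled
    variance to keep degenerate dimensions finite.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    variances = np.stack([x[y == c].var(axis=0) for c in classes])
    var_floor = 1e-9 * max(float(x.var(axis=0).max()), np.finfo(float).tiny)
    variances = np.maximum(variances, var_floor)
    priors = np.array([(y == c).mean() for c in classes])
    return GNBModel(
        classes=classes, priors=priors, means=means, variances=variances,
        var_floor=var_floor,
    )


def predict_gnb(model: GNBModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and return the per-class log posteriors (unnormalised).

    Ties are broken toward the class with the larger prior, then toward the
    lexicographically first class id.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.n_dims:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model ({model.n_dims})"
        )
    log_post = np.empty((len(x), len(model.classes)))
    for k in range(len(model.classes)):
        mu, var = model.means[k], model.variances[k]
        ll = -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var).sum(axis=1)
        log_post[:, k] = np.log(model.priors[k]) + ll
    # stable argmax with prior-then-lexicographic tie-break: visit classes in
    # (descending prior, ascending id) order and keep the first maximum
    order = np.lexsort((model.classes, -model.priors))
    best = order[np.argmax(log_post[:, order], axis=1)]
    return model.classes[best], log_post


def fit_predict_svm(features, labels, test_features) -> np.ndarray:
    """Linear-kernel SVM (C=1) on standardised features.

    Standardisation statistics come from the training set only.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    clf.fit(np.asarray(features, dtype=float), y)
    return clf.predict(np.asarray(test_features, dtype=float))


def evaluate(pred_labels, true_labels) -> tuple[ConfusionCounts, EvalReport]:
    """Confusion counts and the derived accuracy/precision/recall/F1.

    Label 1 is the positive (wheeze) class.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    counts = ConfusionCounts(
        t_p=int(np.sum((pred == 1) & (true == 1))),
        f_p=int(np.sum((pred == 1) & (true == 0))),
        t_n=int(np.sum((pred == 0) & (true == 0))),
        f_n=int(np.sum((pred == 0) & (true == 1))),
    )
    report = EvalReport(
        accuracy=counts.accuracy, precision=counts.precision,
        recall=counts.recall, f1=counts.f1, counts=counts,
    )
    return counts, report


def holdout_split(
    ids, labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Stratified recording-level train/test split.

    The total train size is ``round(train_fraction * n)``, apportioned to
    the classes by largest remainder so that both sides retain both
    classes.  Deterministic for a fixed seed.
    """
    ids = list(ids)
    labels = np.asarray(labels)
    if len(ids) != len(labels) or len(ids) < 2:
        raise ValueError("need matching ids/labels for at least two recordings")
    classes = np.unique(labels)
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c} has fewer than two recordings")
    n_train_total = int(round(train_fraction * len(ids)))
    quotas = {c: train_fraction * np.sum(labels == c) for c in classes}
    n_train = {c: int(np.floor(q)) for c, q in quotas.items()}
    leftover = n_train_total - sum(n_train.values())
    for c in sorted(classes, key=lambda c: (-(quotas[c] - np.floor(quotas[c])), c)):
        if leftover <= 0:
            break
        n_train[c] += 1
        leftover -= 1
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for c in classes:
        members = [ids[i] for i in np.flatnonzero(labels == c)]
        perm = rng.permutation(len(members))
        take = min(max(n_train[c], 1), len(members) - 1)  # both sides non-empty
        train_ids += [members[i] for i in perm[:take]]
        test_ids += [members[i] for i in perm[take:]]
    return train_ids, test_ids


def kfold_split(ids, k: int = 5, seed: int = 0) -> list[list]:
    """Random recording-level K folds: disjoint, exhaustive, near-equal size."""
    ids = list(ids)
    if k < 2:
        raise ValueError("need K >= 2")
    if k > len(ids):
        raise ValueError("K exceeds the number of recordings")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = [sorted(perm[i::k]) for i in range(k)]
    return [[ids[i] for i in fold] for fold in folds]


def kfold_evaluate(ids, labels, pipeline, k: int = 5, seed: int = 0) -> EvalReport:
    """K-fold cross-validation at the recording level.

    ``pipeline(train_ids, test_ids)`` must return ``(pred, true)`` frame
    labels for the held-out recordings.  Every recording is tested exactly
    once; the reported metrics are means over folds.
    """
    folds = kfold_split(ids, k=k, seed=seed)
    id_list = list(ids)
    reports = []
    for fold in folds:
        train = [i for i in id_list if i not in fold]
        pred, true = pipeline(train, list(fold))
        _, rep = evaluate(pred, true)
        reports.append(rep)
    return EvalReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        per_fold=reports,
        meta={"k": k, "seed": seed},
    )
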
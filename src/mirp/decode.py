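"""MI decoding: one-vs-rest CSP, log-variance features, RBF-SVM, 10-fold CV.

CSP solves the generalized eigenproblem ``C_target w = lambda (C_target +
C_rest) w``; eigenvalues lie in [0, 1] and the extreme eigenvectors give
spatial filters whose output variance is maximally discriminative between
the target class and the rest.  Features are the log of each filter's
variance share within its model; an RBF-SVM (C = 0.8) classifies them.

Cross-validation is stratified 10-fold.  By default the CSP filters and
feature standardisation are re-fitted inside every training fold
(leakage-free); the optimistic variant that fits CSP on all epochs first
is available via ``csp_within_folds=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import EpochSet

#: Headline task sets: three-class MI and dominant-hand-vs-idle binary.
THREE_CLASS = ("left", "right", "feet")
BINARY = ("right", "idle")


@dataclass
class CSPModel:
    """Spatial filters for one binary (target-vs-rest) problem."""

    filters: np.ndarray        # (n_filters, n_channels)
    eigenvalues: np.ndarray    # descending, in [0, 1], one per kept filter
    target: str
    channels: list[str]

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    def apply(self, epochs: np.ndarray) -> np.ndarray:
        """Filter (epoch, channel, sample) data -> (epoch, filter, sample)."""
        return np.einsum("fc,ecs->efs", self.filters, epochs)


@dataclass
class ClassificationResult:
    y_true: np.ndarray
    y_pred: np.ndarray
    classes: tuple[str, ...]
    confusion: np.ndarray      # rows true, columns predicted
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f: float
    fold_seed: int | None = None
    per_class: dict = field(default_factory=dict)


def class_covariance(epochs: EpochSet, label: str,
                     ridge: float = 1e-8) -> np.ndarray:
    """Average trace-normalized spatial covariance of one class.

    Each epoch's covariance is normalized to unit trace before averaging,
    and a small ridge (``ridge * mean diagonal``) is added for stability.
    """
    mask = epochs.labels == label
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 epochs with label {label!r}, found {mask.sum()}")
    return _mean_covariance(epochs.data[mask], ridge)


def _mean_covariance(data: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    X = data - data.mean(axis=-1, keepdims=True)
    covs = np.einsum("ecs,eds->ecd", X, X) / (X.shape[-1] - 1)
    traces = np.trace(covs, axis1=1, axis2=2)
    covs = covs / traces[:, None, None]
    C = covs.mean(axis=0)
    C = (C + C.T) / 2.0
    return C + ridge * np.mean(np.diag(C)) * np.eye(C.shape[0])


def fit_csp_binary(cov_target: np.ndarray, cov_rest: np.ndarray,
                   n_filters: int = 4, target: str = "",
                   channels: list[str] | None = None) -> CSPModel:
    """CSP filters from a pair of class covariances.

    Keeps the ``n_filters/2`` eigenvectors with the largest and smallest
    generalized eigenvalues of ``C_t w = lambda (C_t + C_rest) w``; the
    returned filters have unit norm in the composite-covariance metric.
    """
    if n_filters % 2:
        raise ValueError("n_filters must be even (half top, half bottom)")
    for C in (cov_target, cov_rest):
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("covariance matrices must be symmetric")
    if n_filters > cov_target.shape[0]:
        raise ValueError("more filters requested than channels")
    composite = cov_target + cov_rest
    evals, evecs = scipy.linalg.eigh(cov_target, composite)  # ascending
    evals = np.clip(evals, 0.0, 1.0)
    k = n_filters // 2
    idx = np.concatenate([np.arange(len(evals) - 1, len(evals) - 1 - k, -1),
                          np.arange(k - 1, -1, -1)])
    return CSPModel(
        filters=evecs[:, idx].T,
        eigenvalues=evals[idx],
        target=target,
        channels=list(channels) if channels is not None else [],
    )


def fit_csp_ovr(epochs: EpochSet, n_filters_per_class: int = 4,
                ridge: float = 1e-8) -> list[CSPModel]:
    """One CSP model per class: target class vs all others pooled."""
    classes = sorted(set(epochs.labels))
    if len(classes) < 2:
        raise ValueError("OVR CSP needs at least 2 classes")
    models = []
    for cls in classes:
        cov_t = class_covariance(epochs, cls, ridge)
        rest_mask = epochs.labels != cls
        if rest_mask.sum() < 2:
            raise ValueError(f"fewer than 2 epochs outside class {cls!r}")
        cov_r = _mean_covariance(epochs.data[rest_mask], ridge)
        models.append(fit_csp_binary(cov_t, cov_r, n_filters_per_class,
                                     target=cls, channels=epochs.channels))
    return models


def csp_features(models: list[CSPModel], epochs: EpochSet) -> np.ndarray:
    """Concatenated log variance-share features, one row per epoch.

    Per model: ``log(var(w_j^T x) / sum_j var(w_j^T x))`` for each filter.
    Invariant to global scaling of an epoch.
    """
    feats = []
    for model in models:
        if model.channels and model.channels != epochs.channels:
            raise ValueError("epoch channel order differs from CSP training order")
        filtered = model.apply(epochs.data)
        var = filtered.var(axis=-1, ddof=1)
        total = var.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("zero-variance epoch encountered")
        feats.append(np.log(var / total))
    out = np.concatenate(feats, axis=1)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite CSP features")
    return out


def confusion_metrics(y_true, y_pred,
                      class_set: tuple[str, ...] | None = None) -> ClassificationResult:
    """Accuracy and macro precision/recall/F from pooled predictions.

    Per-class one-vs-rest counts feed ``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``
    and ``F = 2PR/(P+R)``; macro scores are unweighted class means, with
    zero-denominator cases defined as 0 (conservative convention).
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    if class_set is None:
        class_set = tuple(sorted(set(y_true) | set(y_pred)))
    index = {c: i for i, c in enumerate(class_set)}
    conf = np.zeros((len(class_set), len(class_set)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    precisions, recalls, fscores, per_class = [], [], [], {}
    for i, cls in enumerate(class_set):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        f = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        precisions.append(prec)
        recalls.append(rec)
        fscores.append(f)
        per_class[cls] = {"precision": prec, "recall": rec, "f": f}
    return ClassificationResult(
        y_true=y_true, y_pred=y_pred, classes=tuple(class_set),
        confusion=conf,
        accuracy=float(np.trace(conf) / conf.sum()),
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f=float(np.mean(fscores)),
        per_class=per_class,
    )


def crossval_classify(epochs: EpochSet, classes: tuple[str, ...],
                      n_folds: int = 10, svm_c: float = 0.8, seed: int = 0,
                      n_filters_per_class: int = 4,
                      csp_within_folds: bool = True) -> ClassificationResult:
    """Stratified k-fold CV of the OVR-CSP + RBF-SVM decoder.

    CSP, feature standardisation and the SVM (RBF kernel, width
    ``gamma = 1/(n_features * feature variance)``) are fitted on each
    training fold only; predictions are pooled over folds.
    """
    mask = np.isin(epochs.labels, classes)
    data = epochs.data[mask]
    labels = epochs.labels[mask]
    counts = {c: int((labels == c).sum()) for c in classes}
    if any(v < n_folds for v in counts.values()):
        raise ValueError(f"every class needs >= {n_folds} epochs, got {counts}")
    sub = EpochSet(data=data, labels=labels,
                   provenance=epochs.provenance[mask].reset_index(drop=True),
                   channels=epochs.channels, fs=epochs.fs, window=epochs.window)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    global_models = None
    if not csp_within_folds:
        global_models = fit_csp_ovr(sub, n_filters_per_class)
    y_true = np.empty(len(labels), dtype=object)
    y_pred = np.empty(len(labels), dtype=object)
    for train, test in skf.split(np.zeros(len(labels)), labels.astype(str)):
        tr = EpochSet(data=data[train], labels=labels[train],
                      provenance=sub.provenance.iloc[train].reset_index(drop=True),
                      channels=sub.channels, fs=sub.fs, window=sub.window)
        te = EpochSet(data=data[test], labels=labels[test],
                      provenance=sub.provenance.iloc[test].reset_index(drop=True),
                      channels=sub.channels, fs=sub.fs, window=sub.window)
        models = global_models if global_models is not None else fit_csp_ovr(
            tr, n_filters_per_class)
        X_tr = csp_features(models, tr)
        X_te = csp_features(models, te)
        scaler = StandardScaler().fit(X_tr)
        clf = SVC(C=svm_c, kernel="rbf", gamma="scale")
        clf.fit(scaler.transform(X_tr), labels[train].astype(str))
        y_true[test] = labels[test]
        y_pred[test] = clf.predict(scaler.transform(X_te))
    result = confusion_metrics(y_true, y_pred, tuple(sorted(classes)))
    result.fold_seed = seed
    return result
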
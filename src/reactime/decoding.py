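"""Time-point-specific shrinkage-LDA decoding and cross-validated evidence.

A "perception model" is a linear discriminant trained on the sensor pattern at
a single time sample. Its signed distance to the hyperplane, evaluated at every
test sample with the sign flipped for one class, yields a per-trial evidence
trace in which positive values always mean evidence for the trial's correct
class. Stacking these traces over training time points gives the
:class:`EvidenceTensor`, the input to all reactivation-timing analyses; the
trial-averaged :class:`AccuracyMatrix` is the classical temporal
generalization view of the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .epochs import Epochs, window_indices

__all__ = [
    "DiscriminantModel",
    "EvidenceTensor",
    "AccuracyMatrix",
    "balance_classes",
    "demean",
    "train_lda",
    "evidence",
    "crossval_evidence",
    "decode_by_subject",
    "accuracy_matrix",
    "write_evidence",
    "read_evidence",
    "accuracy_to_tsv",
]

DEFAULT_GAMMA = 0.05


@dataclass
class DiscriminantModel:
    """Linear discriminant at one training time point.

    ``weights @ x + bias`` is positive for class 0. The boundary sits midway
    between the projected class means; ``gamma`` is the shrinkage weight
    blending the pooled covariance toward the identity scaled by the average
    sensor variance.
    """

    weights: np.ndarray
    bias: float
    train_time: float
    gamma: float = DEFAULT_GAMMA
    fold: int | None = None


@dataclass
class EvidenceTensor:
    """Signed correct-class evidence, trials x train times x test times."""

    values: np.ndarray
    train_times: np.ndarray
    test_times: np.ndarray
    fs: float
    subjects: np.ndarray
    labels: np.ndarray
    folds: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_trials, n_train, n_test = self.values.shape
        if self.train_times.shape != (n_train,) or self.test_times.shape != (n_test,):
            raise ValueError("time axes inconsistent with the evidence array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("evidence must be finite")


@dataclass
class AccuracyMatrix:
    """Proportion of correctly classified trials per (train, test) time."""

    values: np.ndarray
    train_times: np.ndarray
    test_times: np.ndarray
    n_trials: int


def balance_classes(epochs: Epochs, seed: int = 0) -> Epochs:
    """Equalise class counts by randomly dropping majority-class trials."""
    labels = epochs.labels
    n0 = int(np.sum(labels == 0))
    n1 = int(np.sum(labels == 1))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    if n0 == n1:
        return epochs
    rng = np.random.default_rng(seed)
    majority = 0 if n0 > n1 else 1
    excess = abs(n0 - n1)
    maj_idx = np.nonzero(labels == majority)[0]
    drop = rng.choice(maj_idx, size=excess, replace=False)
    keep = np.setdiff1d(np.arange(labels.size), drop)
    return epochs.select_trials(keep)


def demean(epochs: Epochs) -> Epochs:
    """Subtract the mean over trials per sensor and time point.

    Removes global amplitude differences between conditions while leaving the
    class-difference pattern (what the classifier uses) untouched.
    """
    out = epochs.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    return out


def _lda_weights(x: np.ndarray, labels: np.ndarray, gamma: float) -> tuple[np.ndarray, float]:
    """Closed-form shrinkage LDA on one time sample, x: (n_trials, n_sensors)."""
    m0 = x[labels == 0].mean(axis=0)
    m1 = x[labels == 1].mean(axis=0)
    n0 = int(np.sum(labels == 0))
    n1 = int(np.sum(labels == 1))
    c0 = x[labels == 0] - m0
    c1 = x[labels == 1] - m1
    pooled = (c0.T @ c0 + c1.T @ c1) / max(n0 + n1 - 2, 1)
    p = x.shape[1]
    nu = np.trace(pooled) / p
    reg = (1.0 - gamma) * pooled + gamma * nu * np.eye(p)
    try:
        w = np.linalg.solve(reg, m0 - m1)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularised covariance is singular; increase gamma or sensors < trials"
        ) from exc
    bias = -0.5 * float(w @ (m0 + m1))
    return w, bias


def train_lda(epochs: Epochs, train_time: float, gamma: float = DEFAULT_GAMMA) -> DiscriminantModel:
    """Train a shrinkage-LDA perception model at one training time point.

    The time point is the nearest sample on the grid. Weights solve
    ``((1-gamma)*S + gamma*nu*I) w = mu0 - mu1`` with ``S`` the pooled
    within-class covariance and ``nu`` its average diagonal variance; the bias
    places the boundary midway between the projected class means.
    """
    if np.sum(epochs.labels == 0) == 0 or np.sum(epochs.labels == 1) == 0:
        raise ValueError("both classes must be present")
    idx = int(np.argmin(np.abs(epochs.times - train_time)))
    w, b = _lda_weights(epochs.data[:, :, idx], epochs.labels, gamma)
    return DiscriminantModel(w, b, float(epochs.times[idx]), gamma)


def evidence(model: DiscriminantModel, epochs: Epochs,
             test_window: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Signed correct-class evidence per trial over the test window.

    Returns ``(values, times)`` with ``values`` of shape (n_trials, n_window):
    the signed distance to the hyperplane, sign-flipped for class-1 trials so
    positive always means evidence for the trial's correct class.
    """
    if test_window is None:
        idx = np.arange(epochs.n_times)
    else:
        idx = window_indices(epochs.times, *test_window)
    proj = np.einsum("s,nst->nt", model.weights, epochs.data[:, :, idx]) + model.bias
    signs = 1.0 - 2.0 * epochs.labels
    return proj * signs[:, None], epochs.times[idx]


def crossval_evidence(epochs: Epochs, train_times, test_window=None,
                      k_folds: int = 5, gamma: float = DEFAULT_GAMMA,
                      seed: int = 0, test_epochs: Epochs | None = None,
                      apply_demean: bool = True) -> EvidenceTensor:
    """Cross-validated evidence tensor over all (train time, test time) pairs.

    Folds stratified by class partition the trial indices; each trial's
    evidence comes from a model never trained on that trial. When
    ``test_epochs`` is given (paired cross-decoding, e.g. perception-trained
    models tested on imagery epochs of the same trials), the folds partition
    the shared trial indices, so a model is never evaluated on the test epoch
    paired with one of its training trials. Class balancing is applied per
    fold within the training split; demeaning is applied to each epoch set
    before classification.
    """
    if test_epochs is None:
        test_src = epochs
    else:
        if test_epochs.n_trials != epochs.n_trials or not np.array_equal(
                test_epochs.labels, epochs.labels):
            raise ValueError("paired test epochs must match trials and labels")
        test_src = test_epochs
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if epochs.n_trials < k_folds:
        raise ValueError("fewer trials than folds")
    train_times = np.atleast_1d(np.asarray(train_times, dtype=float))
    train_idx_grid = np.unique([int(np.argmin(np.abs(epochs.times - t))) for t in train_times])
    grid_times = epochs.times[train_idx_grid]
    if apply_demean:
        epochs = demean(epochs)
        test_src = epochs if test_epochs is None else demean(test_src)
    if test_window is None:
        test_idx = np.arange(test_src.n_times)
    else:
        test_idx = window_indices(test_src.times, *test_window)
    test_times = test_src.times[test_idx]
    signs = 1.0 - 2.0 * test_src.labels

    values = np.empty((epochs.n_trials, train_idx_grid.size, test_idx.size))
    folds = np.full(epochs.n_trials, -1, dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(k_folds) % (2**31)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(epochs.n_trials), epochs.labels)):
        fit_ep = balance_classes(epochs.select_trials(tr), seed=int(fold_seeds[fold]))
        test_data = test_src.data[te][:, :, test_idx]
        for j, ti in enumerate(train_idx_grid):
            w, b = _lda_weights(fit_ep.data[:, :, ti], fit_ep.labels, gamma)
            proj = np.einsum("s,nst->nt", w, test_data) + b
            values[te, j, :] = proj * signs[te, None]
        folds[te] = fold
    return EvidenceTensor(values, grid_times, test_times, epochs.fs,
                          epochs.subjects.copy(), epochs.labels.copy(), folds)


def decode_by_subject(epochs: Epochs, train_times, test_window=None,
                      k_folds: int = 5, gamma: float = DEFAULT_GAMMA,
                      seed: int = 0, test_epochs: Epochs | None = None) -> EvidenceTensor:
    """Run :func:`crossval_evidence` separately within each subject.

    Classifiers never mix subjects; the per-subject tensors are reassembled
    in the original trial order. With a single subject this reduces to a
    plain call to :func:`crossval_evidence`.
    """
    subjects = np.unique(epochs.subjects)
    if subjects.size == 1:
        return crossval_evidence(epochs, train_times, test_window, k_folds,
                                 gamma, seed, test_epochs)
    seeds = np.random.SeedSequence(seed).generate_state(subjects.size) % (2**31)
    values = None
    folds = np.full(epochs.n_trials, -1, dtype=int)
    out_train = out_test = None
    for s, subj in enumerate(subjects):
        idx = np.nonzero(epochs.subjects == subj)[0]
        sub_test = test_epochs.select_trials(idx) if test_epochs is not None else None
        ev = crossval_evidence(epochs.select_trials(idx), train_times, test_window,
                               k_folds, gamma, int(seeds[s]), sub_test)
        if values is None:
            values = np.empty((epochs.n_trials,) + ev.values.shape[1:])
            out_train, out_test = ev.train_times, ev.test_times
        values[idx] = ev.values
        folds[idx] = ev.folds
    return EvidenceTensor(values, out_train, out_test, epochs.fs,
                          epochs.subjects.copy(), epochs.labels.copy(), folds)


def accuracy_matrix(ev: EvidenceTensor) -> AccuracyMatrix:
    """Proportion of trials with positive correct-class evidence per cell."""
    if ev.values.size == 0:
        raise ValueError("empty evidence tensor")
    vals = np.mean(ev.values > 0, axis=0)
    return AccuracyMatrix(vals, ev.train_times, ev.test_times, ev.values.shape[0])


def write_evidence(ev: EvidenceTensor, path) -> None:
    """Write an evidence tensor to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("values", "train_times", "test_times", "subjects", "labels"):
            f.create_dataset(name, data=getattr(ev, name))
        if ev.folds is not None:
            f.create_dataset("folds", data=ev.folds)
        f.attrs["fs"] = ev.fs


def read_evidence(path) -> EvidenceTensor:
    import h5py

    with h5py.File(path, "r") as f:
        return EvidenceTensor(
            f["values"][()], f["train_times"][()], f["test_times"][()],
            float(f.attrs["fs"]), f["subjects"][()], f["labels"][()],
            f["folds"][()] if "folds" in f else None)


def accuracy_to_tsv(acc: AccuracyMatrix, path) -> None:
    """Export an accuracy matrix as TSV (rows: train times; cols: test times)."""
    import pandas as pd

    df = pd.DataFrame(acc.values, index=acc.train_times, columns=acc.test_times)
    df.index.name = "train_time_s"
    df.to_csv(path, sep="\t")
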
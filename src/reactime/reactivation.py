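"""Per-trial reactivation times and peak-based realignment.

The reactivation time of a perception model in a given trial is the testing
time at which that model's signed correct-class evidence peaks. Collecting it
per trial and per training time gives the :class:`ReactivationTable`, the
pipeline's central derived object: unlike trial-averaged accuracy it is
insensitive to between-trial onset jitter, which is what makes order
inference possible under large temporal uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .decoding import EvidenceTensor
from .epochs import Epochs, window_indices

__all__ = ["ReactivationTable", "RealignedEpochs", "lowpass", "peak_time",
           "build_table", "realign", "table_to_tsv", "table_from_tsv"]

DEFAULT_LOWPASS_HZ = 30.0


@dataclass
class ReactivationTable:
    """Peak evidence times, trials x training time points, in seconds."""

    peak_times: np.ndarray
    train_times: np.ndarray
    subjects: np.ndarray
    window: tuple[float, float]
    lowpass_hz: float | None = None

    def __post_init__(self) -> None:
        n_trials, n_train = self.peak_times.shape
        if self.train_times.shape != (n_train,):
            raise ValueError("train_times inconsistent with peak_times")
        if self.subjects.shape != (n_trials,):
            raise ValueError("subjects inconsistent with peak_times")


@dataclass
class RealignedEpochs:
    """Sensor vectors sampled at each trial's peak, plus the inferred axis.

    ``data`` has shape (n_trials, n_sensors, n_train_times); the time axis of
    the realigned data is inferred from the linear relationship between
    training time and reactivation time: ``inferred_times = beta0 + beta1*t``.
    """

    data: np.ndarray
    train_times: np.ndarray
    inferred_times: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray


def lowpass(trace: np.ndarray, cutoff: float, fs: float, order: int = 4,
            axis: int = -1) -> np.ndarray:
    """Zero-phase low-pass filter (4th-order Butterworth, filtered twice).

    Forward-backward application cancels the group delay; edges are handled
    by reflection padding. ``cutoff`` must be below the Nyquist frequency.
    """
    if cutoff >= fs / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, trace, axis=axis, padtype="even")


def peak_time(trace: np.ndarray, times: np.ndarray,
              window: tuple[float, float] | None = None) -> float:
    """Time of the maximum signed evidence within the window.

    Ties break toward the earliest sample. Invariant under any strictly
    increasing transform of the evidence values.
    """
    trace = np.asarray(trace, dtype=float)
    if window is not None:
        idx = window_indices(times, *window)
        trace = trace[idx]
        times = times[idx]
    if np.all(np.isnan(trace)):
        raise ValueError("trace is all-NaN")
    return float(times[int(np.argmax(trace))])


def build_table(ev: EvidenceTensor, window: tuple[float, float] | None = None,
                lowpass_hz: float | None = DEFAULT_LOWPASS_HZ) -> ReactivationTable:
    """Per-trial, per-training-time peak evidence times.

    The optional low-pass filter (30 Hz by default, matching the setting used
    for long test windows; pass ``None`` for short within-stimulus windows) is
    applied to each signed evidence trace over the full test axis before the
    peak search is restricted to ``window``.
    """
    vals = ev.values
    if lowpass_hz is not None:
        vals = lowpass(vals, lowpass_hz, ev.fs, axis=-1)
    if window is None:
        window = (float(ev.test_times[0]), float(ev.test_times[-1]))
    idx = window_indices(ev.test_times, *window)
    sub = vals[:, :, idx]
    peaks = ev.test_times[idx][np.argmax(sub, axis=-1)]
    return ReactivationTable(peaks, ev.train_times.copy(), ev.subjects.copy(),
                             (float(window[0]), float(window[1])), lowpass_hz)


def realign(epochs: Epochs, table: ReactivationTable, fit) -> RealignedEpochs:
    """Extract each trial's sensor vector at its per-model peak time.

    ``fit`` supplies the linear mapping (``beta0``, ``beta1``) from training
    time to reactivation time used to infer the realigned time axis.
    """
    if epochs.n_trials != table.peak_times.shape[0]:
        raise ValueError("table trials do not match epochs trials")
    beta0 = getattr(fit, "beta0", None)
    beta1 = getattr(fit, "beta1", None)
    if beta0 is None or beta1 is None:
        raise ValueError("fit must provide beta0 and beta1")
    sample_idx = np.rint((table.peak_times - epochs.times[0]) * epochs.fs).astype(int)
    sample_idx = np.clip(sample_idx, 0, epochs.n_times - 1)
    n_trials, _ = table.peak_times.shape
    rows = np.arange(n_trials)[:, None]
    data = epochs.data[rows, :, sample_idx].transpose(0, 2, 1)
    inferred = beta0 + beta1 * table.train_times
    return RealignedEpochs(data, table.train_times.copy(), inferred,
                           epochs.labels.copy(), epochs.subjects.copy())


def table_to_tsv(table: ReactivationTable, path) -> None:
    """Serialise a table as TSV: subject, trial, train_time_s, peak_time_s."""
    n_trials, n_train = table.peak_times.shape
    df = pd.DataFrame({
        "subject": np.repeat(table.subjects, n_train),
        "trial": np.repeat(np.arange(n_trials), n_train),
        "train_time_s": np.tile(table.train_times, n_trials),
        "peak_time_s": table.peak_times.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def table_from_tsv(path) -> ReactivationTable:
    df = pd.read_csv(path, sep="\t")
    train_times = np.unique(df["train_time_s"].to_numpy())
    trials = np.unique(df["trial"].to_numpy())
    pivot = df.pivot(index="trial", columns="train_time_s", values="peak_time_s")
    peaks = pivot.loc[trials, train_times].to_numpy()
    subjects = df.drop_duplicates("trial").set_index("trial").loc[trials, "subject"].to_numpy()
    lo = float(np.min(peaks))
    hi = float(np.max(peaks))
    return ReactivationTable(peaks, train_times, subjects.astype(int), (lo, hi))
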
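"""Epoched multichannel data container and HDF5/TSV round-trip.

The :class:`Epochs` object is the exchange format between every stage of the
pipeline: a ``(n_trials, n_sensors, n_times)`` array with binary class labels,
per-trial subject identifiers, a uniform time axis in seconds and its sampling
rate. Non-finite sensor values are rejected at construction time rather than
imputed, so downstream stages can assume clean input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

__all__ = ["Epochs", "read_epochs", "write_epochs", "window_indices"]


@dataclass
class Epochs:
    """Trials x sensors x time array with labels, subjects and a time axis.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_sensors, n_times)
        Sensor activations in arbitrary units.
    labels : ndarray of int, shape (n_trials,)
        Binary class labels in {0, 1}.
    times : ndarray, shape (n_times,)
        Sample times in seconds, strictly increasing and uniform at ``fs``.
    fs : float
        Sampling rate in Hz.
    subjects : ndarray of int, shape (n_trials,), optional
        Subject identifier per trial; defaults to a single subject (zeros).
    attrs : dict
        Free-form metadata (seed, generating config, ...), preserved on I/O.
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    fs: float
    subjects: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.subjects is None:
            self.subjects = np.zeros(self.data.shape[0], dtype=int)
        self.subjects = np.asarray(self.subjects, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_times)")
        n_trials, _, n_times = self.data.shape
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length must match the trial dimension")
        if self.subjects.shape != (n_trials,):
            raise ValueError("subjects length must match the trial dimension")
        if self.times.shape != (n_times,):
            raise ValueError("times length must match the time dimension")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite sensor values are not accepted")
        if n_times > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-9):
                raise ValueError(
                    "fs/time-axis mismatch: spacing deviates from 1/fs by more than 1e-9"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select_trials(self, idx) -> "Epochs":
        idx = np.asarray(idx)
        return Epochs(
            self.data[idx],
            self.labels[idx],
            self.times,
            self.fs,
            self.subjects[idx],
            dict(self.attrs),
        )

    def copy(self) -> "Epochs":
        return Epochs(
            self.data.copy(),
            self.labels.copy(),
            self.times.copy(),
            self.fs,
            self.subjects.copy(),
            dict(self.attrs),
        )


def window_indices(times: np.ndarray, lo: float, hi: float, tol: float = 1e-9) -> np.ndarray:
    """Indices of samples falling in the closed interval ``[lo, hi]``.

    The interval is snapped inclusively onto the sample grid: samples within
    ``tol`` of an endpoint are included, so a 70-130 ms window at 300 Hz
    contains exactly 19 points.
    """
    times = np.asarray(times)
    idx = np.nonzero((times >= lo - tol) & (times <= hi + tol))[0]
    if idx.size == 0:
        raise ValueError(f"window [{lo}, {hi}] contains no samples")
    return idx


def write_epochs(epochs: Epochs, path, events_path=None) -> None:
    """Write epochs to an HDF5 container (and optionally a TSV event table).

    Layout: datasets ``data`` (trial, sensor, time), ``times``, ``labels``,
    ``subjects``; attributes ``fs``, ``schema_version`` and a JSON-encoded
    ``attrs`` blob. The event table has one row per trial with columns
    ``trial``, ``class``, ``subject`` and, when present in ``attrs``,
    ``onset``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("subjects", data=epochs.subjects)
        f.attrs["fs"] = epochs.fs
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["attrs_json"] = json.dumps(epochs.attrs, default=_json_default)
    if events_path is not None:
        table = {
            "trial": np.arange(epochs.n_trials),
            "class": epochs.labels,
            "subject": epochs.subjects,
        }
        onsets = epochs.attrs.get("onsets")
        if onsets is not None:
            table["onset"] = np.asarray(onsets)
        pd.DataFrame(table).to_csv(events_path, sep="\t", index=False)


def read_epochs(path) -> Epochs:
    """Read an :class:`Epochs` container written by :func:`write_epochs`."""
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "labels", "subjects"):
            if name not in f:
                raise ValueError(f"schema error: missing dataset '{name}'")
        if "fs" not in f.attrs:
            raise ValueError("schema error: missing attribute 'fs'")
        attrs = {}
        if "attrs_json" in f.attrs:
            attrs = json.loads(f.attrs["attrs_json"])
        return Epochs(
            f["data"][()],
            f["labels"][()],
            f["times"][()],
            float(f.attrs["fs"]),
            f["subjects"][()],
            attrs,
        )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
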
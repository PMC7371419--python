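"""Synthetic two-class sensor data with a known activation order.

This module generates ground-truth datasets for validating the reactivation
timing pipeline without real recordings. The generative model: five neural
representations ("patterns"), each a pseudo-random activation over 20 abstract
sensors for two stimulus classes, are activated in a partially overlapping
sequence over 60 ms at 300 Hz (the training set, 100 trials per class). Test
trials contain the same sequence slowed down by a factor of 10, in the same or
reversed order, with a per-trial Gaussian onset (mean 0.8 s, SD 0.1 or 0.5)
inside a 2 s trial. Ongoing activity is sampled trial-by-trial from a
multivariate AR(1) model, giving 1/f-like background noise. Ten subjects are
simulated by default, each with independent patterns and noise.

A second generator, :func:`simulate_recurrent_dataset`, produces data whose
activation order sweeps back and forth at a fixed frequency (10 Hz by
default), the regime used to exercise the phase-segmentation and
recurrence-index analyses.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

from .epochs import Epochs

__all__ = [
    "SimConfig",
    "PatternSet",
    "ARModel",
    "GroundTruth",
    "make_patterns",
    "fit_ar1",
    "sample_noise",
    "simulate_dataset",
    "simulate_recurrent_dataset",
    "informative_train_window",
    "load_default_ar_model",
]

_AR_FIXTURE = "ar1_synthetic_background.json"


@dataclass
class SimConfig:
    """Parameters of the validation simulation.

    Defaults reproduce the study conditions: 5 patterns over 20 sensors, a
    60 ms training sequence at 300 Hz, 100 trials per class, test trials of
    2 s containing the sequence slowed by a factor of 10 with onsets drawn
    from N(0.8 s, onset_sd), and 10 subjects.
    """

    n_patterns: int = 5
    n_sensors: int = 20
    fs: float = 300.0
    train_seq_duration: float = 0.060
    n_trials_per_class: int = 100
    onset_mean: float = 0.8
    onset_sd: float = 0.1
    slowdown: float = 10.0
    trial_length: float = 2.0
    order: str = "same"
    n_subjects: int = 10
    noise_scale: float = 2.0
    train_margin: float = 0.020
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patterns, self.n_sensors, self.n_trials_per_class, self.n_subjects) < 1:
            raise ValueError("all counts must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.onset_sd < 0:
            raise ValueError("onset_sd must be non-negative")
        if self.slowdown < 1:
            raise ValueError("slowdown must be >= 1")
        if self.order not in ("same", "reversed"):
            raise ValueError("order must be 'same' or 'reversed'")

    @classmethod
    def from_toml(cls, path) -> "SimConfig":
        with open(path, "rb") as f:
            return cls(**tomllib.load(f))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatternSet:
    """Per-pattern sensor activations for the two classes.

    ``patterns`` has shape (n_patterns, n_sensors, 2); ``stimulus_information``
    is the class-A minus class-B activation per pattern — the quantity a
    linear classifier picks up.
    """

    patterns: np.ndarray

    @property
    def stimulus_information(self) -> np.ndarray:
        return self.patterns[:, :, 0] - self.patterns[:, :, 1]


@dataclass
class ARModel:
    """Multivariate lag-1 autoregressive model of ongoing activity."""

    coefficients: np.ndarray
    innovation_cov: np.ndarray
    mean: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if not np.allclose(self.innovation_cov, self.innovation_cov.T, atol=1e-10):
            raise ValueError("innovation covariance must be symmetric")

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coefficients))))


@dataclass
class GroundTruth:
    """Injected truth for recovery tests: onsets, order, pattern schedule."""

    onsets: np.ndarray
    order: str
    pattern_times: list
    subjects: np.ndarray
    patterns: list = field(default_factory=list)


def make_patterns(config: SimConfig, rng: np.random.Generator | None = None) -> PatternSet:
    """Draw pseudo-random class activation patterns.

    Entries are i.i.d. standard normal, drawn independently per class so the
    expected stimulus information is nonzero; each (pattern, class) sensor
    vector is scaled to unit norm so ``noise_scale`` is interpretable as the
    noise amplitude relative to the signal.
    """
    if config.n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = rng.standard_normal((config.n_patterns, config.n_sensors, 2))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    return PatternSet(p)


def fit_ar1(epochs: Epochs) -> ARModel:
    """Least-squares fit of a multivariate AR(1) model, pooled across trials.

    Regresses x_t on x_{t-1} after removing the pooled per-sensor mean; the
    innovation covariance comes from the regression residuals.
    """
    if epochs.n_times < 2:
        raise ValueError("need at least 2 time samples")
    mean = epochs.data.mean(axis=(0, 2))
    x = epochs.data - mean[None, :, None]
    # stack (sensor, obs) with obs pooled over trials and time
    xp = np.concatenate([tr[:, :-1] for tr in x], axis=1)  # predictors x_{t-1}
    xn = np.concatenate([tr[:, 1:] for tr in x], axis=1)   # responses  x_t
    gram = xp @ xp.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "regressor covariance is singular; consider adding a ridge penalty "
            "to the lag-1 regression or supplying more data"
        )
    coef = np.linalg.solve(gram, xp @ xn.T).T
    resid = xn - coef @ xp
    innov = resid @ resid.T / max(resid.shape[1] - 1, 1)
    innov = (innov + innov.T) / 2.0
    return ARModel(coef, innov, mean)


def sample_noise(model: ARModel, n_trials: int, n_samples: int, seed: int,
                 burn_in: int = 200) -> np.ndarray:
    """Sample independent AR(1) trials, shape (n_trials, n_sensors, n_samples).

    A burn-in of ``burn_in`` steps is discarded so the process is
    approximately stationary from the first retained sample.
    """
    if model.spectral_radius >= 1.0:
        raise ValueError("AR(1) model is not stationary (spectral radius >= 1)")
    rng = np.random.default_rng(seed)
    p = model.coefficients.shape[0]
    try:
        chol = np.linalg.cholesky(model.innovation_cov)
    except np.linalg.LinAlgError:
        # PSD but rank-deficient innovation covariance
        w, v = np.linalg.eigh(model.innovation_cov)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    total = n_samples + burn_in
    out = np.empty((n_trials, p, n_samples))
    a_t = model.coefficients.T
    x = np.zeros((n_trials, p))
    innov = rng.standard_normal((total, n_trials, p)) @ chol.T
    for t in range(total):
        x = x @ a_t + innov[t]
        if t >= burn_in:
            out[:, :, t - burn_in] = x
    return out + model.mean[None, :, None]


def load_default_ar_model() -> ARModel:
    """Load the packaged background-noise AR(1) model.

    The file is a synthetic stand-in constructed to mimic ongoing
    electrophysiological activity: strongly positive lag-1 diagonal (0.95)
    for 1/f-like spectral decay, weak off-diagonal coupling, and spatially
    correlated innovations. It is not fitted to any real recording; use
    :func:`fit_ar1` to refit on your own epochs.
    """
    text = resources.files("reactime").joinpath("data", _AR_FIXTURE).read_text()
    d = json.loads(text)
    return ARModel(np.array(d["coefficients"]), np.array(d["innovation_cov"]),
                   np.array(d["mean"]))


def _sequence_envelopes(config: SimConfig, times: np.ndarray, onset: float,
                        stretch: float, order: str) -> np.ndarray:
    """Raised-cosine activation envelopes, shape (n_patterns, n_times).

    Pattern windows are equal length with 50% overlap between neighbours:
    window length L = 2*D/(n+1), step L/2, Hann-shaped ramps. ``stretch``
    slows the schedule (1 for the training sequence, ``slowdown`` for test
    trials); ``order='reversed'`` reverses which pattern occupies which slot.
    """
    n = config.n_patterns
    width = 2.0 * config.train_seq_duration / (n + 1) * stretch
    step = width / 2.0
    env = np.zeros((n, times.size))
    for slot in range(n):
        k = n - 1 - slot if order == "reversed" else slot
        t0 = onset + slot * step
        local = (times - t0) / width
        mask = (local >= 0.0) & (local <= 1.0)
        env[k, mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * local[mask]))
    return env


def _slot_times(config: SimConfig, stretch: float) -> list:
    """Onset-relative (start, end) of each schedule slot, in slot order."""
    n = config.n_patterns
    width = 2.0 * config.train_seq_duration / (n + 1) * stretch
    step = width / 2.0
    return [(slot * step, slot * step + width) for slot in range(n)]


def informative_train_window(config: SimConfig) -> tuple[float, float]:
    """Training-time interval carrying order information.

    Samples at the very edges of the sequence fall where every activation
    envelope is (near) zero, so their classifiers see only noise and their
    peak times dilute the order regression. The informative window spans the
    first to the last pattern-window centre.
    """
    width = 2.0 * config.train_seq_duration / (config.n_patterns + 1)
    return (width / 2.0, config.train_seq_duration - width / 2.0)


def _time_axis(fs: float, t_start: float, t_stop: float) -> np.ndarray:
    i0 = int(round(t_start * fs))
    i1 = int(round(t_stop * fs))
    return np.arange(i0, i1 + 1) / fs


def simulate_dataset(config: SimConfig,
                     ar_model: ARModel | None = None) -> tuple[Epochs, Epochs, GroundTruth]:
    """Generate paired training and testing epochs with known order.

    Training epochs hold the fast (60 ms) sequence with a noise-only margin on
    both sides; testing epochs hold the same sequence slowed by
    ``config.slowdown``, in ``config.order``, placed at a per-trial onset
    drawn from N(onset_mean, onset_sd); sequence activity extending beyond
    the recorded trial is truncated. Both get AR(1) noise scaled by
    ``noise_scale``.
    Subjects are simulated independently (fresh patterns and noise) and
    concatenated, with per-trial subject ids.
    """
    slowed = config.slowdown * config.train_seq_duration
    if slowed > config.trial_length:
        raise ValueError("slowed sequence does not fit inside the trial")
    if ar_model is None:
        ar_model = load_default_ar_model()
    if ar_model.coefficients.shape[0] != config.n_sensors:
        raise ValueError("AR model sensor count does not match the config")
    root = np.random.SeedSequence(config.seed)
    n_per = 2 * config.n_trials_per_class
    labels = np.repeat([0, 1], config.n_trials_per_class)

    t_train = _time_axis(config.fs, -config.train_margin,
                         config.train_seq_duration + config.train_margin)
    t_test = _time_axis(config.fs, 0.0, config.trial_length - 1.0 / config.fs)

    train_chunks, test_chunks, onset_chunks, subj_chunks, pattern_sets = [], [], [], [], []
    for s, child in enumerate(root.spawn(config.n_subjects)):
        s_pat, s_onset, s_ntr, s_nte = child.spawn(4)
        rng = np.random.default_rng(s_pat)
        pats = make_patterns(config, rng)
        pattern_sets.append(pats)

        env_train = _sequence_envelopes(config, t_train, 0.0, 1.0, "same")
        # onsets keep their exact Gaussian distribution; any activity falling
        # outside the recorded trial is simply not observed (truncating the
        # signal, not the onset, avoids a time-locked pile-up at the edges)
        onsets = np.random.default_rng(s_onset).normal(
            config.onset_mean, config.onset_sd, size=n_per)

        train = np.empty((n_per, config.n_sensors, t_train.size))
        test = np.empty((n_per, config.n_sensors, t_test.size))
        for i, lab in enumerate(labels):
            sig = np.einsum("ps,pt->st", pats.patterns[:, :, lab], env_train)
            train[i] = sig
            env = _sequence_envelopes(config, t_test, onsets[i],
                                      config.slowdown, config.order)
            test[i] = np.einsum("ps,pt->st", pats.patterns[:, :, lab], env)
        if config.noise_scale > 0:
            seed_tr = int(s_ntr.generate_state(1)[0] % (2**31))
            seed_te = int(s_nte.generate_state(1)[0] % (2**31))
            train += config.noise_scale * sample_noise(ar_model, n_per, t_train.size, seed_tr)
            test += config.noise_scale * sample_noise(ar_model, n_per, t_test.size, seed_te)
        train_chunks.append(train)
        test_chunks.append(test)
        onset_chunks.append(onsets)
        subj_chunks.append(np.full(n_per, s))

    subjects = np.concatenate(subj_chunks)
    all_labels = np.tile(labels, config.n_subjects)
    onsets = np.concatenate(onset_chunks)
    attrs = {"seed": config.seed, "config": config.to_dict()}
    train_ep = Epochs(np.concatenate(train_chunks), all_labels, t_train, config.fs,
                      subjects, dict(attrs))
    test_attrs = dict(attrs)
    test_attrs["onsets"] = onsets.tolist()
    test_ep = Epochs(np.concatenate(test_chunks), all_labels, t_test, config.fs,
                     subjects, test_attrs)
    truth = GroundTruth(onsets, config.order, _slot_times(config, config.slowdown),
                        subjects, pattern_sets)
    return train_ep, test_ep, truth


def simulate_recurrent_dataset(config: SimConfig, alternation_hz: float = 10.0,
                               mode: str = "alternating",
                               window: float = 0.4,
                               ar_model: ARModel | None = None,
                               include_imagery: bool = False):
    """Generate epochs whose activation order reverses at a fixed frequency.

    The pattern index sweeps across the ``n_patterns`` representations once
    per half-period of ``alternation_hz``: in ``mode='alternating'`` the
    sweep direction reverses every half-period (a triangle wave — the
    recurrent regime); ``mode='forward'`` repeats the same forward sweep
    (a sawtooth — order information without reversals); ``mode='static'``
    holds the position constant at the middle pattern (decodable stimulus
    information but no sequential order at all — the negative control for
    the Recurrence Index). Activation at a fractional position is a linear
    blend of the two neighbouring patterns. Epochs are time-locked (no onset
    jitter) over ``[0, window]`` seconds plus a noise margin, with AR(1)
    background noise.

    With ``include_imagery=True`` also returns slow reversed-sweep test
    trials (2 s, jittered onsets) whose reactivation times against the
    recurrent training epochs oscillate at ``alternation_hz``.
    """
    if mode not in ("alternating", "forward", "static"):
        raise ValueError("mode must be 'alternating', 'forward' or 'static'")
    if ar_model is None:
        ar_model = load_default_ar_model()
    root = np.random.SeedSequence(config.seed)
    n_per = 2 * config.n_trials_per_class
    labels = np.repeat([0, 1], config.n_trials_per_class)
    margin = config.train_margin
    t = _time_axis(config.fs, -margin, window + margin)
    half = 1.0 / (2.0 * alternation_hz)

    # fractional pattern position over time; NaN outside the stimulus window
    pos = np.full(t.size, np.nan)
    inside = (t >= 0.0) & (t <= window)
    frac = (t[inside] / half) % 2.0
    if mode == "alternating":
        tri = np.where(frac <= 1.0, frac, 2.0 - frac)
    elif mode == "forward":
        tri = frac % 1.0
    else:  # static: sustained middle-pattern activation, no order
        tri = np.full(frac.shape, 0.5)
    pos[inside] = tri * (config.n_patterns - 1)

    def blend_weights(position):
        """(n_times, n_patterns) linear-interpolation weights; 0 outside."""
        w = np.zeros((position.size, config.n_patterns))
        ok = np.isfinite(position)
        idx = np.arange(config.n_patterns)
        w[ok] = np.clip(1.0 - np.abs(position[ok, None] - idx[None, :]), 0.0, None)
        return w

    chunks, subj_chunks, pattern_sets = [], [], []
    imag_chunks, onset_chunks = [], []
    t_imag = _time_axis(config.fs, 0.0, config.trial_length - 1.0 / config.fs)
    slowed = config.slowdown * config.train_seq_duration
    for s, child in enumerate(root.spawn(config.n_subjects)):
        s_pat, s_onset, s_n1, s_n2 = child.spawn(4)
        pats = make_patterns(config, np.random.default_rng(s_pat))
        pattern_sets.append(pats)
        w = blend_weights(pos)  # (n_times, n_patterns)
        data = np.empty((n_per, config.n_sensors, t.size))
        for i, lab in enumerate(labels):
            data[i] = (w @ pats.patterns[:, :, lab]).T
        if config.noise_scale > 0:
            seed1 = int(s_n1.generate_state(1)[0] % (2**31))
            data += config.noise_scale * sample_noise(ar_model, n_per, t.size, seed1)
        chunks.append(data)
        subj_chunks.append(np.full(n_per, s))
        if include_imagery:
            onsets = np.random.default_rng(s_onset).normal(
                config.onset_mean, config.onset_sd, size=n_per)
            imag = np.empty((n_per, config.n_sensors, t_imag.size))
            for i, lab in enumerate(labels):
                # single slow reversed sweep: position n-1 -> 0 over the
                # slowed duration, placed at the trial onset
                rel = (t_imag - onsets[i]) / slowed
                ipos = np.full(t_imag.size, np.nan)
                ok = (rel >= 0.0) & (rel <= 1.0)
                ipos[ok] = (1.0 - rel[ok]) * (config.n_patterns - 1)
                imag[i] = (blend_weights(ipos) @ pats.patterns[:, :, lab]).T
            if config.noise_scale > 0:
                seed2 = int(s_n2.generate_state(1)[0] % (2**31))
                imag += config.noise_scale * sample_noise(ar_model, n_per, t_imag.size, seed2)
            imag_chunks.append(imag)
            onset_chunks.append(onsets)

    subjects = np.concatenate(subj_chunks)
    all_labels = np.tile(labels, config.n_subjects)
    attrs = {"seed": config.seed, "config": config.to_dict(),
             "alternation_hz": alternation_hz, "mode": mode}
    percept = Epochs(np.concatenate(chunks), all_labels, t, config.fs, subjects, dict(attrs))
    truth = GroundTruth(np.concatenate(onset_chunks) if include_imagery else np.zeros(0),
                        mode, _slot_times(config, config.slowdown), subjects, pattern_sets)
    if not include_imagery:
        return percept, truth
    imagery = Epochs(np.concatenate(imag_chunks), all_labels, t_imag, config.fs,
                     subjects, dict(attrs))
    return percept, imagery, truth
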
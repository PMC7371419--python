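"""Spectral characterisation of reactivation traces and raw signals.

Covers the rhythm analyses: a single-frequency complex Morlet wavelet for
power over time, a Hanning-tapered FFT amplitude spectrum, trial-averaged
magnitude-squared coherence between a reactivation trace and raw sensor
signals (with a permutation test against the shuffled-classifier trace), and
normalised cross-correlation lag estimation between two time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import Epochs, window_indices
from .resampling import fdr_correct

__all__ = ["MorletParams", "Spectrum", "morlet_wavelet", "morlet_power",
           "fft_spectrum", "coherence_at", "coherence_permutation_test", "xcorr_lag"]


@dataclass
class MorletParams:
    """Complex Morlet wavelet parameters.

    The wavelet is ``exp(-t^2 / (2 s^2) + i w t)`` on a time vector from
    -0.5 to 0.5 s in steps of 1/fs, with ``w = 2*pi*f0``. Only ``support``
    samples at the centre are retained before convolution. The Gaussian
    width follows ``s = c * 2*pi / w = c / f0`` (0.1 s at 10 Hz for one
    cycle); set ``width_convention='angular'`` for the ``c / (2*pi*f0)``
    reading instead.
    """

    f0: float = 10.0
    c: float = 1.0
    fs: float = 300.0
    support: int = 200
    width_convention: str = "cycles"

    @property
    def w(self) -> float:
        return 2.0 * np.pi * self.f0

    @property
    def s(self) -> float:
        if self.width_convention == "cycles":
            return self.c / self.f0
        if self.width_convention == "angular":
            return self.c / (2.0 * np.pi * self.f0)
        raise ValueError("width_convention must be 'cycles' or 'angular'")

    @property
    def t(self) -> np.ndarray:
        n = int(round(0.5 * self.fs))
        return np.arange(-n, n + 1) / self.fs


@dataclass
class Spectrum:
    """One-sided amplitude spectrum, normalised by signal length."""

    freqs: np.ndarray
    amplitude: np.ndarray
    bin_spacing_hz: float = field(default=np.nan)


def morlet_wavelet(params: MorletParams) -> np.ndarray:
    """The truncated complex Morlet wavelet (central ``support`` samples)."""
    t = params.t
    if params.support > t.size:
        raise ValueError("support exceeds the wavelet time vector")
    mw = np.exp(-(t**2) / (2.0 * params.s**2) + 1j * params.w * t)
    start = (t.size - params.support) // 2
    return mw[start:start + params.support]


def morlet_power(trace: np.ndarray, params: MorletParams) -> np.ndarray:
    """Power over time: squared magnitude of the wavelet convolution.

    The full convolution is cropped to the input length with centre
    alignment (zero phase); values within half the wavelet support of either
    edge are boundary-contaminated.
    """
    trace = np.asarray(trace, dtype=float)
    mw = morlet_wavelet(params)
    if trace.size <= mw.size:
        raise ValueError("trace must be longer than the wavelet support")
    conv = np.convolve(trace, mw, mode="same")
    return np.abs(conv) ** 2


def fft_spectrum(trace: np.ndarray, times: np.ndarray,
                 taper_window: tuple[float, float] | None = None) -> Spectrum:
    """Hanning-tapered amplitude spectrum of a trace segment.

    The segment in ``taper_window`` is multiplied by a Hanning taper, Fourier
    transformed, and the magnitude divided by the segment length.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if taper_window is not None:
        idx = window_indices(times, *taper_window)
        seg = trace[idx]
        t = times[idx]
    else:
        seg, t = trace, times
    n = seg.size
    if n < 2:
        raise ValueError("taper window must contain at least 2 samples")
    fs = 1.0 / (t[1] - t[0])
    tapered = seg * np.hanning(n)
    amp = np.abs(np.fft.rfft(tapered)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Spectrum(freqs, amp, float(freqs[1] - freqs[0]))


def _trial_dft_bin(x: np.ndarray, f0: float, fs: float) -> np.ndarray:
    """Per-trial DFT coefficient at the bin nearest f0. x: (n_trials, n_times)."""
    n = x.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    k = int(np.argmin(np.abs(freqs - f0)))
    return np.fft.rfft(x, axis=1)[:, k]


def coherence_at(x: np.ndarray, y: np.ndarray, f0: float, fs: float) -> float:
    """Magnitude-squared coherence at the frequency bin nearest ``f0``.

    ``x`` and ``y`` are (n_trials, n_times) with matched trials; each trial is
    a single DFT window and cross-spectra are averaged over trials.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shapes")
    if x.shape[0] < 2:
        raise ValueError("coherence is degenerate with a single trial")
    cx = _trial_dft_bin(x, f0, fs)
    cy = _trial_dft_bin(y, f0, fs)
    sxy = np.mean(cx * np.conj(cy))
    sxx = np.mean(np.abs(cx) ** 2)
    syy = np.mean(np.abs(cy) ** 2)
    return float(np.abs(sxy) ** 2 / (sxx * syy))


def coherence_permutation_test(trace_true: np.ndarray, trace_null: np.ndarray,
                               raw: Epochs, f0: float, n_perm: int = 10_000,
                               seed: int = 0, q: float = 0.05):
    """Per-sensor permutation test of the coherence difference.

    For each sensor the statistic is coherence(raw, true trace) minus
    coherence(raw, shuffled-classifier trace); the null exchanges the two
    traces independently per trial. Returns ``(pvals, adjusted, reject,
    diffs)`` with BH-FDR applied at level ``q``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    trace_true = np.atleast_2d(np.asarray(trace_true, dtype=float))
    trace_null = np.atleast_2d(np.asarray(trace_null, dtype=float))
    n_trials = trace_true.shape[0]
    if trace_null.shape != trace_true.shape or raw.n_trials != n_trials:
        raise ValueError("traces and raw epochs must share the trial dimension")
    fs = raw.fs
    ct = _trial_dft_bin(trace_true, f0, fs)
    cn = _trial_dft_bin(trace_null, f0, fs)
    pt = np.abs(ct) ** 2
    pn = np.abs(cn) ** 2
    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm, n_trials)) < 0.5
    keep = ~swap
    pvals = np.empty(raw.n_sensors)
    diffs = np.empty(raw.n_sensors)

    def coh(num_sum, pow_trace, pow_sensor):
        return np.abs(num_sum / n_trials) ** 2 / (
            (pow_trace / n_trials) * (pow_sensor / n_trials))

    for s in range(raw.n_sensors):
        cs = _trial_dft_bin(raw.data[:, s, :], f0, fs)
        ps_sum = np.sum(np.abs(cs) ** 2)
        a = ct * np.conj(cs)
        b = cn * np.conj(cs)
        obs = coh(a.sum(), pt.sum(), ps_sum) - coh(b.sum(), pn.sum(), ps_sum)
        num_t = keep @ a + swap @ b
        num_n = keep @ b + swap @ a
        pow_t = keep @ pt + swap @ pn
        pow_n = keep @ pn + swap @ pt
        null = coh(num_t, pow_t, ps_sum) - coh(num_n, pow_n, ps_sum)
        pvals[s] = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
        diffs[s] = obs
    adjusted, reject = fdr_correct(pvals, q)
    return pvals, adjusted, reject, diffs


def xcorr_lag(x: np.ndarray, y: np.ndarray, fs: float, max_lag: float,
              n_boot: int = 0, seed: int = 0, level: float = 0.95):
    """Lag maximising the normalised cross-correlation within ±``max_lag``.

    A positive lag means ``x`` leads ``y`` (``y(t) ~ x(t - lag)``). Signals
    are mean-removed and variance-normalised so the lag is amplitude
    invariant; per-shift sums are scaled by the overlap length. When the
    inputs are trial-resolved (2-D, trials x time) the lag of the
    trial-averaged traces is returned together with a percentile bootstrap
    CI over trials, as ``(lag, (lo, hi))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal shapes")
    if x.ndim == 2:
        lag = xcorr_lag(x.mean(axis=0), y.mean(axis=0), fs, max_lag)
        if n_boot <= 0:
            return lag, (np.nan, np.nan)
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        samples = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            samples[i] = xcorr_lag(x[idx].mean(axis=0), y[idx].mean(axis=0), fs, max_lag)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
        return lag, (float(lo), float(hi))
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("cross-correlation is undefined for flat signals")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    n = xs.size
    full = np.correlate(ys, xs, mode="full")
    shifts = np.arange(-(n - 1), n)
    overlap = n - np.abs(shifts)
    r = full / overlap
    max_shift = int(round(max_lag * fs))
    ok = np.abs(shifts) <= max_shift
    best = np.argmax(r[ok])
    return float(shifts[ok][best] / fs)
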
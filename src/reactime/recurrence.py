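"""Phase segmentation of reactivation traces and the Recurrence Index.

The mean reactivation trace (reactivation time as a function of training
time) alternates between increasing and decreasing segments when information
flow reverses periodically. Empirical mode decomposition extracts the
oscillatory component without assuming sinusoidality; the intrinsic mode
function whose extrema count is closest to the expected number (eight for
10 Hz over 400 ms) defines the phase boundaries. Alternatively phases can be
tiled at a fixed frequency. For every (test phase, train phase) pair the
slope of reactivation time on training time is computed with the peak search
restricted to the test phase; the Recurrence Index is the dot product of the
vectorised ±1 hypothesis matrix (same phase direction -> +1) with the
empirical slope matrix, positive when the data show the hypothesised
alternation of feed-forward and feedback flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .decoding import EvidenceTensor
from .reactivation import build_table

__all__ = ["IMFSet", "Phase", "PhaseSet", "SlopeMatrix", "RecurrenceResult",
           "emd", "select_imf", "segment_phases", "fixed_freq_phases",
           "phase_slopes", "hypothesis_matrix", "recurrence_index", "neighbor_ri",
           "phases_to_tsv", "slopes_to_tsv", "recurrence_to_json"]


@dataclass
class IMFSet:
    """Intrinsic mode functions plus the monotone residual."""

    imfs: list
    residual: np.ndarray
    times: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


@dataclass
class Phase:
    t_start: float
    t_end: float
    direction: str  # 'increasing' or 'decreasing'


@dataclass
class PhaseSet:
    phases: list

    def __post_init__(self) -> None:
        for a, b in zip(self.phases, self.phases[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError("phases must be non-overlapping and time ordered")

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def directions(self) -> list:
        return [p.direction for p in self.phases]


@dataclass
class SlopeMatrix:
    """Regression slopes per (test phase, train phase) cell.

    ``trial_contrib`` holds the exact per-trial decomposition of each pooled
    slope (the cell slope is the mean over trials of its contributions),
    which makes trial-level bootstrap of any slope functional cheap.
    """

    slopes: np.ndarray
    n_points: np.ndarray
    train_phases: PhaseSet
    test_phases: PhaseSet
    trial_contrib: np.ndarray | None = None  # (n_trials, n_test, n_train)


@dataclass
class RecurrenceResult:
    ri: float
    bootstrap_ci: tuple
    permutation_p: float | None
    hypothesis: np.ndarray
    boot_samples: np.ndarray | None = None
    boot_slopes: np.ndarray | None = None


def phases_to_tsv(phases: PhaseSet, path) -> None:
    import pandas as pd

    pd.DataFrame([{"t_start": p.t_start, "t_end": p.t_end,
                   "direction": p.direction} for p in phases]
                 ).to_csv(path, sep="\t", index=False)


def slopes_to_tsv(slopes: SlopeMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(slopes.slopes).to_csv(path, sep="\t", index=False, header=False)


def recurrence_to_json(result: RecurrenceResult, path) -> None:
    import json

    with open(path, "w") as f:
        json.dump({"ri": result.ri, "bootstrap_ci": list(result.bootstrap_ci),
                   "permutation_p": result.permutation_p,
                   "hypothesis": result.hypothesis.tolist()}, f, indent=2)


def _interior_extrema(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima and minima, sorted."""
    sign = np.sign(np.diff(y))
    idx = []
    last_sign = 0
    for i, s in enumerate(sign):
        if s == 0:
            continue  # plateaus: the turning point is the plateau's last sample
        if last_sign != 0 and s != last_sign:
            idx.append(i)
        last_sign = s
    return np.array(idx, dtype=int)


def _extrema_split(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ext = _interior_extrema(y)
    maxima = np.array([i for i in ext if y[i] >= y[i - 1] and y[i] >= y[i + 1]], dtype=int)
    minima = np.array([i for i in ext if y[i] <= y[i - 1] and y[i] <= y[i + 1]], dtype=int)
    return maxima, minima


def _is_imf_like(y: np.ndarray) -> bool:
    """Mode condition: interior extrema and zero crossings differ by <= 1."""
    ext = _interior_extrema(y).size
    zc = int(np.sum(np.diff(np.signbit(y)) != 0))
    return abs(ext - zc) <= 1


def _envelope(x: np.ndarray, idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema with mirror boundary extension."""
    if idx.size == 0:
        return np.full(n, vals.mean() if vals.size else 0.0)
    pos = idx.astype(float)
    v = vals
    # mirror up to two extrema about each end so the spline is anchored
    k = min(2, idx.size)
    left_pos = -pos[:k][::-1]
    left_val = v[:k][::-1]
    right_pos = 2 * (n - 1) - pos[-k:][::-1]
    right_val = v[-k:][::-1]
    pos_ext = np.concatenate([left_pos, pos, right_pos])
    val_ext = np.concatenate([left_val, v, right_val])
    pos_ext, uniq = np.unique(pos_ext, return_index=True)
    val_ext = val_ext[uniq]
    if pos_ext.size < 2:
        return np.full(n, val_ext[0])
    if pos_ext.size < 4:
        return np.interp(np.arange(n), pos_ext, val_ext)
    return CubicSpline(pos_ext, val_ext)(np.arange(n))


def emd(trace: np.ndarray, times: np.ndarray | None = None,
        sd_thresh: float = 0.2, max_sifts: int = 50, max_imfs: int = 12) -> IMFSet:
    """Empirical mode decomposition by standard sifting.

    Upper and lower cubic-spline envelopes are fitted through the maxima and
    minima (mirror-extended at the boundaries); the envelope mean is
    subtracted and the sift repeats until the normalised squared change
    between sifts falls below ``sd_thresh``. Modes are extracted until the
    residual has fewer than two interior extrema. The residual is defined as
    input minus the sum of modes, so reconstruction is exact.
    """
    x = np.asarray(trace, dtype=float)
    if times is None:
        times = np.arange(x.size, dtype=float)
    times = np.asarray(times, dtype=float)
    imfs = []
    r = x.copy()
    for _ in range(max_imfs):
        mx, mn = _extrema_split(r)
        if mx.size + mn.size < 2 or mx.size == 0 or mn.size == 0:
            break
        h = r.copy()
        for _ in range(max_sifts):
            hmx, hmn = _extrema_split(h)
            if hmx.size == 0 or hmn.size == 0:
                break
            upper = _envelope(h, hmx, h[hmx], h.size)
            lower = _envelope(h, hmn, h[hmn], h.size)
            m = 0.5 * (upper + lower)
            h_new = h - m
            denom = np.sum(h**2)
            if denom == 0.0:
                h = h_new
                break
            sd = np.sum((h - h_new) ** 2) / denom
            h = h_new
            if sd < sd_thresh and _is_imf_like(h):
                break
        imfs.append(h)
        r = r - h
    residual = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return IMFSet(imfs, residual, times)


def select_imf(imfset: IMFSet, expected_extrema: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Pick the IMF whose interior extrema count is closest to the target.

    Ties break toward the lower-index (faster) mode. Returns the mode and the
    times of its interior extrema.
    """
    if not imfset.imfs:
        raise ValueError("empty IMF list")
    counts = [(_interior_extrema(imf)).size for imf in imfset.imfs]
    best = int(np.argmin([abs(c - expected_extrema) for c in counts]))
    imf = imfset.imfs[best]
    ext_idx = _interior_extrema(imf)
    return imf, imfset.times[ext_idx]


def segment_phases(imf: np.ndarray, extrema_times: np.ndarray,
                   times: np.ndarray) -> PhaseSet:
    """One phase per consecutive extrema pair, direction from the IMF change."""
    extrema_times = np.asarray(extrema_times, dtype=float)
    if extrema_times.size < 2:
        raise ValueError("need at least 2 extrema to form a phase")
    phases = []
    for t0, t1 in zip(extrema_times, extrema_times[1:]):
        i0 = int(np.argmin(np.abs(times - t0)))
        i1 = int(np.argmin(np.abs(times - t1)))
        direction = "increasing" if imf[i1] > imf[i0] else "decreasing"
        phases.append(Phase(float(t0), float(t1), direction))
    return PhaseSet(phases)


def fixed_freq_phases(f: float, window: tuple[float, float],
                      phase0: str = "decreasing") -> PhaseSet:
    """Alternating half-period phases tiling the window at frequency ``f``.

    Each phase lasts ``1/(2f)``; directions alternate starting with
    ``phase0``. Only full half-periods are kept, so a 400 ms window at 10 Hz
    yields exactly 8 phases of 50 ms.
    """
    lo, hi = window
    half = 1.0 / (2.0 * f)
    n = int(np.floor((hi - lo) / half + 1e-9))
    if n < 1:
        n = 1
    other = "increasing" if phase0 == "decreasing" else "decreasing"
    phases = [Phase(lo + k * half, min(lo + (k + 1) * half, hi),
                    phase0 if k % 2 == 0 else other) for k in range(n)]
    return PhaseSet(phases)


def _train_phase_masks(train_times: np.ndarray, train_phases: PhaseSet,
                       tol: float = 1e-9) -> list:
    return [np.nonzero((train_times >= p.t_start - tol) &
                       (train_times <= p.t_end + tol))[0] for p in train_phases]


def phase_slopes(ev: EvidenceTensor, train_phases: PhaseSet, test_phases: PhaseSet,
                 lowpass_hz: float | None = None) -> SlopeMatrix:
    """Phase-pair slope matrix (test phases x train phases).

    For test phase i the peak search is restricted to that phase's window
    (re-run from the evidence tensor — a single global peak cannot be reused);
    for train phase j the regression of peak time on training time uses only
    training points inside that phase, pooled over all trials. Cells with
    fewer than two distinct training times are NaN.
    """
    n_test = len(test_phases)
    n_train = len(train_phases)
    masks = _train_phase_masks(ev.train_times, train_phases)
    n_trials = ev.values.shape[0]
    slopes = np.full((n_test, n_train), np.nan)
    n_points = np.zeros((n_test, n_train), dtype=int)
    contrib = np.full((n_trials, n_test, n_train), np.nan)
    for i, tp in enumerate(test_phases):
        table = build_table(ev, window=(tp.t_start, tp.t_end), lowpass_hz=lowpass_hz)
        for j, mask in enumerate(masks):
            x = ev.train_times[mask]
            if np.unique(x).size < 2:
                continue
            y = table.peak_times[:, mask]  # (n_trials, len(mask))
            xc = x - x.mean()
            sxx = float(np.sum(xc**2))
            # pooled OLS slope decomposes exactly into a per-trial mean
            c = (y @ xc) / sxx
            contrib[:, i, j] = c
            slopes[i, j] = float(c.mean())
            n_points[i, j] = y.size
    return SlopeMatrix(slopes, n_points, train_phases, test_phases, contrib)


def hypothesis_matrix(train_phases: PhaseSet, test_phases: PhaseSet) -> np.ndarray:
    """±1 matrix: +1 where test and train phase share direction, -1 otherwise."""
    td = test_phases.directions()
    rd = train_phases.directions()
    return np.array([[1.0 if a == b else -1.0 for b in rd] for a in td])


def recurrence_index(slopes: SlopeMatrix, hypothesis: np.ndarray,
                     n_boot: int = 0, seed: int = 0, level: float = 0.95) -> RecurrenceResult:
    """Dot product of the vectorised hypothesis and slope matrices.

    Missing cells are excluded pairwise. With ``n_boot > 0`` and a slope
    matrix carrying per-trial contributions, a percentile bootstrap CI over
    trials is computed (each resample's RI is the mean of per-trial RI
    contributions, which equals recomputing every pooled cell slope on the
    resampled trials).
    """
    h = np.asarray(hypothesis, dtype=float)
    if h.shape != slopes.slopes.shape:
        raise ValueError("hypothesis and slope matrices must have equal shapes")
    valid = np.isfinite(slopes.slopes)
    ri = float(np.sum(h[valid] * slopes.slopes[valid]))
    ci = (np.nan, np.nan)
    boot = None
    boot_slopes = None
    if n_boot > 0 and slopes.trial_contrib is not None:
        per_trial = np.nansum((h[None] * slopes.trial_contrib)[:, valid], axis=1)
        rng = np.random.default_rng(seed)
        n = per_trial.size
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = per_trial[idx].mean(axis=1)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
        ci = (float(lo), float(hi))
        # bootstrap slope matrices for downstream contrasts (e.g. neighbor RI)
        flat = np.where(np.isfinite(slopes.trial_contrib), slopes.trial_contrib,
                        np.nan).reshape(n, -1)
        boot_slopes = np.nanmean(flat[idx], axis=1).reshape(n_boot, *slopes.slopes.shape)
    return RecurrenceResult(ri, ci, None, h, boot, boot_slopes)


def neighbor_ri(slopes: SlopeMatrix, hypothesis: np.ndarray,
                boot_slopes: np.ndarray | None = None) -> tuple[float, float, float]:
    """Mean hypothesis-weighted slope near the diagonal vs elsewhere.

    "Near" is the diagonal plus the first off-diagonals. The per-cell
    contribution is ``hypothesis * slope`` averaged within each group
    (normalised by the group's cell count). The p-value for near > far is the
    two-sided bootstrap tail probability when trial-resampled slope matrices
    (from :func:`recurrence_index`) are supplied, otherwise NaN.
    """
    s = slopes.slopes
    h = np.asarray(hypothesis, dtype=float)
    if s.shape[0] < 3 or s.shape[1] < 3:
        raise ValueError("slope matrix must be at least 3x3")
    i, j = np.indices(s.shape)
    near_mask = (np.abs(i - j) <= 1) & np.isfinite(s)
    far_mask = (np.abs(i - j) > 1) & np.isfinite(s)
    near = float(np.mean((h * s)[near_mask]))
    far = float(np.mean((h * s)[far_mask]))
    p = np.nan
    if boot_slopes is not None:
        contrib = h[None] * boot_slopes
        near_b = contrib[:, near_mask].mean(axis=1)
        far_b = contrib[:, far_mask].mean(axis=1)
        diff = near_b - far_b
        n_boot = diff.size
        tail = min(np.mean(diff <= 0.0), np.mean(diff >= 0.0))
        p = float(np.clip(2.0 * tail, 1.0 / n_boot, 1.0))
    return near, far, p
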
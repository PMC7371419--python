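"""Shared resampling inference: bootstrap CIs, label permutation, BH-FDR.

All randomness is seed-deterministic; every result records its seed and the
number of resamples so analyses can be replayed bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["BootstrapResult", "bootstrap_ci", "paired_bootstrap_p", "permute_labels", "fdr_correct"]

DEFAULT_N_BOOT = 10_000


@dataclass
class BootstrapResult:
    """Point estimate with a percentile bootstrap confidence interval."""

    estimate: float
    ci: tuple[float, float]
    n_boot: int
    seed: int
    level: float = 0.95
    samples: np.ndarray | None = None


def bootstrap_ci(data, statistic, n_boot: int = DEFAULT_N_BOOT, level: float = 0.95,
                 seed: int = 0, keep_samples: bool = False) -> BootstrapResult:
    """Percentile bootstrap CI for ``statistic`` resampling the first axis.

    ``data`` is an array (or tuple of equally long arrays resampled jointly)
    whose first axis indexes the exchangeable units — trials by default.
    """
    joint = isinstance(data, (tuple, list))
    arrays = [np.asarray(a) for a in (data if joint else (data,))]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all resampling arrays must share the first-axis length")
    if n < 2:
        raise ValueError("need at least 2 resampling units")
    rng = np.random.default_rng(seed)
    est = float(statistic(*arrays) if joint else statistic(arrays[0]))
    samples = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = [a[idx] for a in arrays]
        samples[b] = statistic(*resampled) if joint else statistic(resampled[0])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return BootstrapResult(est, (float(lo), float(hi)), n_boot, seed, level,
                           samples if keep_samples else None)


def paired_bootstrap_p(a, b, statistic=np.mean, n_boot: int = DEFAULT_N_BOOT,
                       seed: int = 0) -> float:
    """Two-sided bootstrap p for a paired difference.

    The matched differences ``a - b`` are resampled with replacement; the p
    value is twice the fraction of bootstrap statistics on the opposite side
    of zero from the observed one, clipped to ``[1/n_boot, 1]``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("paired inputs must have matching lengths")
    d = a - b
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    stats = np.empty(n_boot)
    for i in range(n_boot):
        stats[i] = statistic(d[rng.integers(0, n, size=n)])
    p_lo = np.mean(stats <= 0.0)
    p_hi = np.mean(stats >= 0.0)
    p = 2.0 * min(p_lo, p_hi)
    return float(np.clip(p, 1.0 / n_boot, 1.0))


def permute_labels(labels, seed: int) -> np.ndarray:
    """Uniform random permutation of the label vector (multiset preserved)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(labels.shape[0])]


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(adjusted p-values, reject flags)`` at level ``q``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, reject
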
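"""End-to-end orchestration of the two headline analyses.

``run_reversal_analysis`` chains decoding, per-trial peak timing, pooled and
mixed-effects order regression and a shuffled-label control on a paired
train/test epoch set — the analysis that decides whether representations
reactivate in the same or reversed order. ``run_recurrence_analysis`` runs
the within-stimulus variant: decode at every time point, segment the mean
reactivation trace into phases (EMD-based or fixed-frequency), compute the
phase-pair slope matrix, and quantify alternation with the Recurrence Index
and its bootstrap/shuffled-label inference.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .decoding import accuracy_matrix, decode_by_subject
from .epochs import Epochs, window_indices
from .order import (default_cluster, fit_order_lm, fit_order_lmm,
                    shuffled_control, RANDOM_STRUCTURES)
from .reactivation import build_table
from .recurrence import (emd, fixed_freq_phases, hypothesis_matrix, neighbor_ri,
                         phase_slopes, recurrence_index, segment_phases, select_imf)
from .resampling import permute_labels

__all__ = ["PipelineConfig", "RunManifest", "run_reversal_analysis",
           "run_recurrence_analysis"]


@dataclass
class PipelineConfig:
    """Analysis settings; the defaults are the study's stated choices.

    ``train_window`` spans the perceptual feed-forward sweep (70-130 ms,
    which holds 19 grid points at 300 Hz); decoding uses 5 folds and LDA
    shrinkage 0.05; long test windows are low-passed at 30 Hz before the
    peak search while within-stimulus tests use no filter.
    """

    train_window: tuple = (0.070, 0.130)
    test_window: tuple | None = None
    folds: int = 5
    gamma: float = 0.05
    lowpass: float | None = 30.0
    phases: str = "freq:10"
    phase_window: tuple = (0.0, 0.4)
    expected_extrema: int = 8
    n_boot: int = 10_000
    seed: int = 0
    lmm_candidates: tuple = RANDOM_STRUCTURES


@dataclass
class RunManifest:
    """Snapshot sufficient to replay a run bit-identically."""

    config: dict
    seed: int
    stage_seeds: dict
    versions: dict = field(default_factory=lambda: {
        "reactime": __version__, "python": platform.python_version(),
        "numpy": np.__version__,
    })

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, default=str)


def _stage_seeds(seed: int, names) -> dict:
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return {name: int(s) for name, s in zip(names, state)}


def _fit_dict(fit) -> dict:
    return {"beta0": fit.beta0, "beta1": fit.beta1, "se0": fit.se0, "se1": fit.se1,
            "t": fit.t_stat, "dof": fit.dof, "p": fit.p_value,
            "random_structure": fit.random_structure, "bic": fit.bic,
            "n_obs": fit.n_obs, "converged": fit.converged}


def run_reversal_analysis(train_epochs: Epochs, test_epochs: Epochs,
                          config: PipelineConfig | None = None,
                          fit_lmm: bool = False, n_shuffles: int = 1) -> dict:
    """Decode, time the peaks, and infer the order of reactivation.

    Returns a report with the trained window, pooled OLS fit, optionally the
    BIC-selected mixed-model fit, the mean accuracy matrix, the reactivation
    table, and ``n_shuffles`` shuffled-label control fits.
    """
    if config is None:
        config = PipelineConfig()
    seeds = _stage_seeds(config.seed, ["decode", "shuffle"])
    train_times = train_epochs.times[window_indices(train_epochs.times,
                                                    *config.train_window)]
    ev = decode_by_subject(train_epochs, train_times, config.test_window,
                           k_folds=config.folds, gamma=config.gamma,
                           seed=seeds["decode"], test_epochs=test_epochs)
    table = build_table(ev, lowpass_hz=config.lowpass)
    lm = fit_order_lm(table)
    lm_clustered = fit_order_lm(table, cluster=default_cluster(table))
    report = {
        "n_perception_models": int(train_times.size),
        "lm": _fit_dict(lm),
        "lm_clustered": _fit_dict(lm_clustered),
        "accuracy": accuracy_matrix(ev),
        "table": table,
        "evidence": ev,
        "manifest": RunManifest(asdict(config), config.seed, seeds),
    }
    if fit_lmm:
        sel = fit_order_lmm(table, config.lmm_candidates)
        report["lmm"] = {
            "winner": _fit_dict(sel.best),
            "candidates": [_fit_dict(f) for f in sel.candidates],
        }
    nulls = []
    shuffle_seeds = np.random.SeedSequence(seeds["shuffle"]).generate_state(
        n_shuffles) % (2**31)
    for s in shuffle_seeds:
        nulls.append(_fit_dict(shuffled_control(
            train_epochs, train_times, config.test_window,
            test_epochs=test_epochs, k_folds=config.folds, gamma=config.gamma,
            lowpass_hz=config.lowpass, seed=int(s))))
    report["shuffled"] = nulls
    return report


def _make_phases(ev, config: PipelineConfig):
    spec = config.phases
    if spec.startswith("freq:"):
        f = float(spec.split(":", 1)[1])
        return fixed_freq_phases(f, config.phase_window)
    if spec == "emd":
        table = build_table(ev, window=config.phase_window, lowpass_hz=None)
        trace = table.peak_times.mean(axis=0)
        imfset = emd(trace, times=table.train_times)
        imf, ext_times = select_imf(imfset, config.expected_extrema)
        return segment_phases(imf, ext_times, table.train_times)
    raise ValueError(f"unknown phase spec: {spec}")


def run_recurrence_analysis(epochs: Epochs, config: PipelineConfig | None = None,
                            shuffled: bool = True) -> dict:
    """Within-stimulus recurrence analysis on a single epoch set.

    Classifiers are trained (cross-validated) on every time point of the
    phase window and tested on the same epochs; the same phase set is used
    on both axes, as in the within-perception analysis. The shuffled-label
    run repeats the whole pipeline with permuted classes to provide the
    negative control for the Recurrence Index.
    """
    if config is None:
        config = PipelineConfig(lowpass=None)
    seeds = _stage_seeds(config.seed, ["decode", "boot", "shuffle", "shuffle_boot"])
    train_times = epochs.times[window_indices(epochs.times, *config.phase_window)]
    test_window = config.phase_window

    def analyse(ep: Epochs, decode_seed: int, boot_seed: int):
        ev = decode_by_subject(ep, train_times, test_window, k_folds=config.folds,
                               gamma=config.gamma, seed=decode_seed)
        phases = _make_phases(ev, config)
        slopes = phase_slopes(ev, phases, phases, lowpass_hz=config.lowpass)
        h = hypothesis_matrix(phases, phases)
        result = recurrence_index(slopes, h, n_boot=config.n_boot, seed=boot_seed)
        return ev, phases, slopes, result

    ev, phases, slopes, result = analyse(epochs, seeds["decode"], seeds["boot"])
    report = {
        "n_phases": len(phases),
        "phases": phases,
        "slopes": slopes,
        "recurrence": result,
        "manifest": RunManifest(asdict(config), config.seed, seeds),
    }
    if slopes.slopes.shape[0] >= 3:
        near, far, p = neighbor_ri(slopes, result.hypothesis, result.boot_slopes)
        report["neighbor"] = {"near": near, "far": far, "p": p}
    if shuffled:
        null_ep = epochs.copy()
        null_ep.labels = permute_labels(epochs.labels, seeds["shuffle"])
        _, _, null_slopes, null_result = analyse(null_ep, seeds["shuffle"],
                                                 seeds["shuffle_boot"])
        report["shuffled_recurrence"] = null_result
        report["shuffled_slopes"] = null_slopes
    return report
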
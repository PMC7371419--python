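"""Order-of-reactivation inference from a reactivation table.

The direction of information flow is read off the sign of the regression
slope of reactivation time on training time: a positive slope means the
representations reactivate in the same order as they were trained, a negative
slope means the order is reversed. Besides the pooled fixed-effects fit, a
set of linear mixed models with different random-effect structures (subject
and/or trial intercepts, subject slopes) is fitted by maximum likelihood and
compared by BIC, since onset variability between trials and subjects is
precisely what the method is designed to tolerate. A shuffled-label control
re-runs the whole decode-and-peak pipeline with permuted class labels to
verify the slope vanishes when stimulus information is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .decoding import decode_by_subject
from .epochs import Epochs
from .reactivation import ReactivationTable, build_table
from .resampling import permute_labels

__all__ = ["OrderFit", "ModelSelection", "RANDOM_STRUCTURES", "fit_order_lm",
           "fit_order_lmm", "subject_level_fit", "shuffled_control",
           "default_cluster", "table_to_frame"]

RANDOM_STRUCTURES = (
    "none",
    "subject_intercept",
    "trial_intercept",
    "subject_and_trial_intercept",
    "subject_intercept_and_slope",
)


@dataclass
class OrderFit:
    """A fitted linear relation reactivation_time = beta0 + beta1 * train_time."""

    beta0: float
    beta1: float
    se0: float
    se1: float
    t_stat: float
    dof: float
    p_value: float
    random_structure: str = "none"
    bic: float = np.nan
    n_obs: int = 0
    converged: bool = True

    def predict(self, train_times: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(train_times)


@dataclass
class ModelSelection:
    """Candidate mixed-model fits and the BIC-minimising winner."""

    candidates: list = field(default_factory=list)
    winner: int = -1

    @property
    def best(self) -> OrderFit:
        return self.candidates[self.winner]


def table_to_frame(table: ReactivationTable) -> pd.DataFrame:
    """Long-format frame: one row per (trial, train_time) observation."""
    n_trials, n_train = table.peak_times.shape
    return pd.DataFrame({
        "subject": np.repeat(table.subjects, n_train),
        "trial": np.repeat(np.arange(n_trials), n_train),
        "train_time": np.tile(table.train_times, n_trials),
        "peak_time": table.peak_times.ravel(),
    })


def _fit_from_ols(df: pd.DataFrame, structure: str = "none",
                  cluster: str | None = None) -> OrderFit:
    x = sm.add_constant(df["train_time"].to_numpy())
    model = sm.OLS(df["peak_time"].to_numpy(), x)
    if cluster is not None:
        groups = df[cluster].to_numpy()
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        dof = float(np.unique(groups).size - 1)
    else:
        res = model.fit()
        dof = float(res.df_resid)
    t = float(res.tvalues[1])
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return OrderFit(
        beta0=float(res.params[0]), beta1=float(res.params[1]),
        se0=float(res.bse[0]), se1=float(res.bse[1]),
        t_stat=t, dof=dof, p_value=p, random_structure=structure,
        bic=float(res.bic), n_obs=int(res.nobs),
    )


def default_cluster(table: ReactivationTable) -> str:
    """Coarsest exchangeable unit for sandwich inference: subjects when
    there are enough of them, otherwise trials."""
    return "subject" if np.unique(table.subjects).size >= 5 else "trial"


def fit_order_lm(table: ReactivationTable, cluster: str | None = None) -> OrderFit:
    """Pooled OLS of peak time on training time over all (trial, time) points.

    Point estimates are the closed-form least-squares solution. The rows are
    not independent — peak times of one trial share that trial's reactivation
    onset, and cross-validated trials of one subject share classifiers — so
    plain OLS standard errors overstate the evidence. ``cluster`` ("trial" or
    "subject") keeps the same estimates but computes cluster-robust sandwich
    standard errors at that unit, with the t reference on (n_clusters - 1)
    degrees of freedom; the pipeline clusters at the coarsest unit available
    (see :func:`default_cluster`).
    """
    df = table_to_frame(table)
    if np.unique(df["train_time"]).size < 2:
        raise ValueError("need at least 2 distinct training time points")
    return _fit_from_ols(df, cluster=cluster)


def _mixedlm(df: pd.DataFrame, structure: str):
    if structure == "subject_intercept":
        return smf.mixedlm("peak_time ~ train_time", df, groups=df["subject"])
    if structure == "trial_intercept":
        return smf.mixedlm("peak_time ~ train_time", df, groups=df["trial"])
    if structure == "subject_and_trial_intercept":
        return smf.mixedlm("peak_time ~ train_time", df, groups=df["subject"],
                           vc_formula={"trial": "0 + C(trial)"})
    if structure == "subject_intercept_and_slope":
        return smf.mixedlm("peak_time ~ train_time", df, groups=df["subject"],
                           re_formula="~train_time")
    raise ValueError(f"unknown random structure: {structure}")


def _fit_from_mixed(df: pd.DataFrame, structure: str) -> OrderFit:
    model = _mixedlm(df, structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)  # ML so BICs are comparable across structures
    k = len(res.params)
    n = int(res.nobs)
    bic = float(-2.0 * res.llf + k * np.log(n))
    beta0 = float(res.params["Intercept"])
    beta1 = float(res.params["train_time"])
    se1 = float(res.bse["train_time"])
    dof = float(n - 2)
    t = beta1 / se1 if se1 > 0 else np.nan
    p = float(2.0 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else np.nan
    return OrderFit(beta0, beta1, float(res.bse["Intercept"]), se1, t, dof, p,
                    structure, bic, n, bool(getattr(res, "converged", True)))


def fit_order_lmm(table: ReactivationTable,
                  candidates=RANDOM_STRUCTURES) -> ModelSelection:
    """Fit candidate mixed models by ML and select the BIC-minimising one.

    Candidates with no random effects are fitted by OLS. A candidate that
    fails to converge is flagged (``converged=False``) and excluded from
    selection rather than raising.
    """
    df = table_to_frame(table)
    if np.unique(df["train_time"]).size < 2:
        raise ValueError("need at least 2 distinct training time points")
    fits = []
    for structure in candidates:
        if structure == "none":
            fits.append(_fit_from_ols(df))
            continue
        if "subject" in structure and np.unique(df["subject"]).size < 2:
            fits.append(OrderFit(*(np.nan,) * 7, structure, np.nan, 0, False))
            continue
        try:
            fits.append(_fit_from_mixed(df, structure))
        except Exception:
            fits.append(OrderFit(*(np.nan,) * 7, structure, np.nan, 0, False))
    usable = [i for i, f in enumerate(fits) if f.converged and np.isfinite(f.bic)]
    if not usable:
        raise RuntimeError("no candidate mixed model converged")
    winner = min(usable, key=lambda i: fits[i].bic)
    return ModelSelection(fits, winner)


def subject_level_fit(table: ReactivationTable) -> ModelSelection:
    """Between-subject fit on trial-averaged reactivation times.

    Peak times are averaged over trials within subject and training time
    point, removing the within-subject trial dependence, and mixed models
    with subject random intercept (and optionally slope) are compared.
    """
    if np.unique(table.subjects).size < 3:
        raise ValueError("need at least 3 subjects")
    df = table_to_frame(table)
    agg = df.groupby(["subject", "train_time"], as_index=False)["peak_time"].mean()
    agg["trial"] = agg["subject"]
    fits = []
    for structure in ("subject_intercept", "subject_intercept_and_slope"):
        try:
            fits.append(_fit_from_mixed(agg, structure))
        except Exception:
            fits.append(OrderFit(*(np.nan,) * 7, structure, np.nan, 0, False))
    usable = [i for i, f in enumerate(fits) if f.converged and np.isfinite(f.bic)]
    if not usable:
        raise RuntimeError("no candidate mixed model converged")
    winner = min(usable, key=lambda i: fits[i].bic)
    return ModelSelection(fits, winner)


def shuffled_control(epochs: Epochs, train_times, test_window=None, *,
                     test_epochs: Epochs | None = None, k_folds: int = 5,
                     gamma: float = 0.05, lowpass_hz: float | None = 30.0,
                     peak_window=None, seed: int = 0,
                     cluster: str | None = "auto") -> OrderFit:
    """Re-run decode -> peak timing -> regression with permuted class labels.

    Permuting labels removes stimulus information without altering the
    temporal structure of the data; the returned fit is the pipeline's null.
    The permuted label vector is applied to both members of a paired
    train/test epoch set.
    """
    perm = permute_labels(epochs.labels, seed)
    shuffled = epochs.copy()
    shuffled.labels = perm
    shuffled_test = None
    if test_epochs is not None:
        shuffled_test = test_epochs.copy()
        shuffled_test.labels = perm
    ev = decode_by_subject(shuffled, train_times, test_window, k_folds=k_folds,
                           gamma=gamma, seed=seed, test_epochs=shuffled_test)
    table = build_table(ev, window=peak_window, lowpass_hz=lowpass_hz)
    if cluster == "auto":
        cluster = default_cluster(table)
    return fit_order_lm(table, cluster=cluster)
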
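"""Decoder scoring: VAF, contiguous five-fold cross-validation, prediction-
interval sweep, and the across-joint repeated-measures comparison.

The accuracy metric is the variance accounted for,

    VAF = 100 * (1 - Var(measured - decoded) / Var(measured)),

with the population (biased) variance convention; the choice of convention
cancels in the ratio for equal-length signals but is fixed here so worked
examples are exact. VAF is 100 for a perfect fit, 0 for predicting the mean,
and negative for predictors worse than the mean.

Cross-validation folds are contiguous time blocks, never shuffled samples:
EMG and kinematics are strongly autocorrelated, and shuffling would leak
nearly-identical samples between training and validation. Each fold trains a
fresh decoder on the four remaining blocks (with delay-line resets at the
splice) and scores the held-out block either closed-loop (the headline mode:
only EMG drives the decoder after a measured burn-in) or teacher-forced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as spstats

from .errors import InputError, ParameterError, PartitionError, UndefinedMetricError
from .narx import (NarxConfig, TrainOptions, predict_series_parallel,
                   simulate_parallel, train)
from .preprocess import EnvelopeTrial

MODES = ("closed_loop", "teacher_forced")
DEFAULT_INTERVALS_MS = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)


def vaf(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Variance accounted for, in percent (may be negative)."""
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.size != predicted.size:
        raise InputError("measured and predicted must have equal length")
    if measured.size < 2:
        raise InputError("need at least 2 samples to compute VAF")
    signal_var = float(np.var(measured))
    if signal_var == 0:
        raise UndefinedMetricError("VAF undefined: measured signal has zero variance")
    residual_var = float(np.var(measured - predicted))
    return 100.0 * (1.0 - residual_var / signal_var)


def make_folds(n_samples: int, k: int = 5) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous k-fold partition: k disjoint validation blocks covering all
    samples, the remainder (n mod k) appended to the final block; each fold's
    training set is the complement."""
    if k < 2:
        raise PartitionError("need at least 2 folds")
    if n_samples < k:
        raise PartitionError(f"cannot split {n_samples} samples into {k} blocks")
    base = n_samples // k
    edges = [i * base for i in range(k)] + [n_samples]
    folds = []
    for i in range(k):
        val = np.arange(edges[i], edges[i + 1])
        train_idx = np.concatenate([np.arange(0, edges[i]),
                                    np.arange(edges[i + 1], n_samples)])
        folds.append((train_idx, val))
    return folds


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(fold,)).generate_state(1)[0]
               % 2**31)


@dataclass
class CvReport:
    """Per-fold, per-joint VAF table (percent) plus summary statistics."""

    vaf_table: np.ndarray  # (k folds, n_joints)
    mean_vaf: np.ndarray  # (n_joints,)
    sd_vaf: np.ndarray  # (n_joints,) sample sd across folds
    mode: str
    config: NarxConfig
    seeds: list[int]
    joint_names: tuple[str, ...]
    train_mse: list[float]


def cross_validate(config: NarxConfig, trial: EnvelopeTrial,
                   opts: TrainOptions | None = None,
                   mode: str = "closed_loop", k: int = 5) -> CvReport:
    """Contiguous k-fold cross-validation of a freshly trained decoder.

    Burn-in samples (and, in training, the burn-in after each splice) are
    excluded from both the loss and the VAF.
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    opts = opts or TrainOptions()
    env, ang = trial.envelopes, trial.angles
    n = trial.n_steps
    burn = config.burn_in
    folds = make_folds(n, k)
    table = np.empty((k, ang.shape[1]))
    seeds, mses = [], []
    for f, (_, val_idx) in enumerate(folds):
        start, end = int(val_idx[0]), int(val_idx[-1]) + 1
        segments_env = [s for s in (env[:start], env[end:]) if s.shape[0] > burn]
        segments_ang = [s for s in (ang[:start], ang[end:]) if s.shape[0] > burn]
        fold_opts = replace(opts, seed=_fold_seed(opts.seed, f))
        seeds.append(fold_opts.seed)
        params, report = train(config, segments_env, segments_ang, fold_opts)
        mses.append(report.final_mse)
        env_val, ang_val = env[start:end], ang[start:end]
        if env_val.shape[0] <= burn + 1:
            raise PartitionError("validation block shorter than burn-in + 2")
        if mode == "closed_loop":
            pred = simulate_parallel(params, env_val, ang_val[:burn])
        else:
            pred = predict_series_parallel(params, env_val, ang_val)
        for j in range(ang.shape[1]):
            table[f, j] = vaf(ang_val[burn:, j], pred[burn:, j])
    return CvReport(
        vaf_table=table,
        mean_vaf=table.mean(axis=0),
        sd_vaf=table.std(axis=0, ddof=1),
        mode=mode,
        config=config,
        seeds=seeds,
        joint_names=trial.joint_names,
        train_mse=mses,
    )


@dataclass
class SweepReport:
    intervals_ms: list[float]
    vaf_mean: np.ndarray  # (n_intervals, n_joints)
    vaf_sd: np.ndarray
    grand_mean: np.ndarray  # (n_intervals,)
    best_interval_ms: float
    reports: list[CvReport]


def sweep_prediction_interval(config: NarxConfig, trial: EnvelopeTrial,
                              intervals_ms=DEFAULT_INTERVALS_MS,
                              opts: TrainOptions | None = None,
                              mode: str = "closed_loop", k: int = 5) -> SweepReport:
    """Cross-validate at each prediction interval tau (m = tau / dt) and pick
    the interval with the highest grand-mean VAF (ties toward the smallest)."""
    dt_ms = 1000.0 / trial.fs
    reports = []
    for tau in intervals_ms:
        m_real = tau / dt_ms
        if abs(m_real - round(m_real)) > 1e-9 or round(m_real) < 1:
            raise ParameterError(
                f"interval {tau} ms is not a positive multiple of the decoding "
                f"step {dt_ms} ms"
            )
        cfg = replace(config, m=int(round(m_real)), dt_s=1.0 / trial.fs)
        reports.append(cross_validate(cfg, trial, opts, mode=mode, k=k))
    vaf_mean = np.stack([r.mean_vaf for r in reports])
    vaf_sd = np.stack([r.sd_vaf for r in reports])
    grand = np.array([r.vaf_table.mean() for r in reports])
    best = int(np.argmax(grand))  # argmax returns the first (smallest tau) on ties
    return SweepReport(
        intervals_ms=[float(t) for t in intervals_ms],
        vaf_mean=vaf_mean,
        vaf_sd=vaf_sd,
        grand_mean=grand,
        best_interval_ms=float(intervals_ms[best]),
        reports=reports,
    )


# -- statistics -------------------------------------------------------------

@dataclass
class PairwiseComparison:
    pair: tuple[int, int]
    t: float
    p_raw: float
    p_adj: float
    degenerate: bool = False


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    pairwise: list[PairwiseComparison]


def _check_table(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("need a complete [n_units x n_conditions] table, n,c >= 2")
    if not np.isfinite(x).all():
        raise InputError("table must be complete (finite values only)")
    return x


def bonferroni_pairwise(vaf_by_condition: np.ndarray) -> list[PairwiseComparison]:
    """Paired two-sided t-tests for every condition pair with Bonferroni
    adjustment p_adj = min(1, p * n_pairs)."""
    x = _check_table(vaf_by_condition)
    c = x.shape[1]
    pairs = [(i, j) for i in range(c) for j in range(i + 1, c)]
    out = []
    for i, j in pairs:
        diff = x[:, i] - x[:, j]
        if np.allclose(diff, diff[0]):
            # zero-variance difference: the paired t is undefined
            out.append(PairwiseComparison((i, j), t=0.0, p_raw=1.0, p_adj=1.0,
                                          degenerate=True))
            continue
        t, p = spstats.ttest_rel(x[:, i], x[:, j])
        out.append(PairwiseComparison((i, j), t=float(t), p_raw=float(p),
                                      p_adj=float(min(1.0, p * len(pairs)))))
    return out


def rm_anova(vaf_by_condition: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA across conditions (e.g. joints).

    Decomposition: SS_error = SS_total - SS_subjects - SS_conditions;
    F = MS_conditions / MS_error with df1 = c-1, df2 = (c-1)(n-1);
    partial eta squared = SS_c / (SS_c + SS_e). No sphericity correction is
    applied.
    """
    x = _check_table(vaf_by_condition)
    n, c = x.shape
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subjects = float(c * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_conditions = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subjects - ss_conditions, 0.0)
    df1 = c - 1
    df2 = (c - 1) * (n - 1)
    ms_c = ss_conditions / df1
    ms_e = ss_error / df2
    if ms_e == 0:
        f_stat = 0.0 if ms_c == 0 else np.inf
    else:
        f_stat = ms_c / ms_e
    p = float(spstats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    denom = ss_conditions + ss_error
    eta = ss_conditions / denom if denom > 0 else 0.0
    return AnovaResult(F=float(f_stat), df1=df1, df2=df2, p=p,
                       partial_eta_sq=float(eta),
                       pairwise=bonferroni_pairwise(x))
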
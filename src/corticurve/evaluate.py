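"""Validation machinery: rank-order accuracy, stability, combined-data
evaluations and the statistical comparisons between indicator methods.

Rank-order accuracy is the Spearman correlation between "true" and
estimated indicator values across individuals — what matters for
studies comparing individuals, more than absolute error.  Stability is
the mean pairwise Spearman correlation of an indicator across the
schedules of a set.  Combined-data evaluations randomly allocate each
individual one schedule from a set (ten replicates), measure the
accuracy loss relative to single-schedule application, and probe the
duration bias: the Spearman correlation of indicator values with the
allocated sampling duration, which observation-based AUC indicators
acquire and model-based indicators are designed to avoid.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .asm import PopulationCurve, fit_individual_amplitude
from .curve import GammaKernelParams, ResponseCurveParams
from .errors import DegenerateTestError, ValidationError
from .indicators import (
    NOMINAL_PEAK_TIME,
    indicators_model_based,
    indicators_obs,
    true_indicators,
)
from .mlm import MultilevelGammaModel
from .preprocess import ParticipantSeries
from .simulate import SamplingSchedule, ScheduleSet, SimulatedCohort, build_combined_dataset, downsample

__all__ = [
    "INDICATORS",
    "spearman",
    "rank_accuracy",
    "stability",
    "fisher_average",
    "compare_methods_t",
    "compare_methods_permutation",
    "z_test_per_schedule",
    "duration_bias",
    "obs_truncated",
    "truth_table",
    "indicator_table_obs",
    "indicator_table_asm",
    "indicator_table_mm",
    "evaluate_single_schedules",
    "evaluate_combined",
    "plot_accuracy",
]

INDICATORS = ("AUCg", "AUCi", "reactivity", "max_increase")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("spearman undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def fisher_average(r_values) -> float:
    """tanh(mean(atanh(r))): Fisher-Z averaged correlation coefficients."""
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValidationError("|r| = 1 has infinite Fisher transform")
    return float(np.tanh(np.mean(np.arctanh(r))))


def compare_methods_t(r_a, r_b) -> dict:
    """Two-sided paired t-test on raw (untransformed) correlation vectors."""
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValidationError("paired t-test needs paired vectors of length >= 2")
    diff = a - b
    if np.ptp(diff) == 0:
        # zero variance: identical vectors give the null result, a constant
        # nonzero difference is an infinitely large effect
        if diff[0] == 0:
            return {"t": 0.0, "p": 1.0, "df": a.size - 1, "direction": 0.0,
                    "degenerate": True}
        return {"t": float(np.sign(diff[0]) * np.inf), "p": 0.0,
                "df": a.size - 1, "direction": float(np.sign(diff[0])),
                "degenerate": True}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": a.size - 1,
            "direction": float(np.sign(diff.mean())), "degenerate": False}


def compare_methods_permutation(r_a, r_b) -> dict:
    """Exact sign-flip permutation test on paired differences (two-sided).

    Enumerates all 2^k sign assignments of the paired differences and
    compares |mean| of each against the observed |mean|.
    """
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("permutation test needs paired vectors of equal length")
    d = a - b
    k = d.size
    if k > 20:
        raise ValidationError("exact enumeration limited to 20 pairs")
    signs = np.array(
        [[1 if (mask >> i) & 1 else -1 for i in range(k)] for mask in range(2**k)]
    )
    means = signs @ d / k
    observed = abs(d.mean())
    p = float(np.mean(np.abs(means) >= observed - 1e-15))
    return {"p": p, "observed_mean_diff": float(d.mean()),
            "direction": float(np.sign(d.mean())), "n_permutations": 2**k}


def z_test_per_schedule(r1: float, r2: float, n: int) -> dict:
    """Fisher-Z test comparing two correlations estimated on n individuals.

    Independent-samples approximation Z = (z1 - z2) / sqrt(2/(n-3));
    both correlations share the "true" vector, so treat the p-value as
    approximate (a dependent-correlations correction is not applied).
    """
    if n <= 3:
        raise ValidationError("Z-test needs n > 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValidationError("|r| = 1 has infinite Fisher transform")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(2.0 / (n - 3))
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


# ---------------------------------------------------------------------------
# indicator tables
# ---------------------------------------------------------------------------

def truth_table(cohort: SimulatedCohort) -> pd.DataFrame:
    """"True" indicators from the red-noise trajectories, one row per individual."""
    rows = []
    for ind in cohort:
        s = true_indicators(ind.times, ind.red)
        rows.append({"participant_id": ind.id, "AUCg": s.AUCg, "AUCi": s.AUCi,
                     "reactivity": s.reactivity, "max_increase": s.max_increase})
    return pd.DataFrame(rows)


def _rows_from_sets(dataset, sets, method, schedule_id):
    rows = []
    for series, s in zip(dataset, sets):
        rows.append({"participant_id": series.participant_id, "method": method,
                     "schedule_id": schedule_id, "AUCg": s.AUCg, "AUCi": s.AUCi,
                     "reactivity": s.reactivity, "max_increase": s.max_increase})
    return rows


def indicator_table_obs(
    dataset: Sequence[ParticipantSeries],
    peak_time: float = NOMINAL_PEAK_TIME,
    method: str = "OBS",
    schedule_id: str = "",
) -> pd.DataFrame:
    sets = [indicators_obs(s, peak_time, method) for s in dataset]
    return pd.DataFrame(_rows_from_sets(dataset, sets, method, schedule_id))


def indicator_table_asm(
    dataset: Sequence[ParticipantSeries],
    pop: PopulationCurve,
    schedule_id: str = "",
) -> pd.DataFrame:
    sets = []
    for s in dataset:
        fit = fit_individual_amplitude(s, pop)
        sets.append(indicators_model_based(fit.curve, method="ASM"))
    return pd.DataFrame(_rows_from_sets(dataset, sets, "ASM", schedule_id))


def indicator_table_mm(
    dataset: Sequence[ParticipantSeries],
    model: MultilevelGammaModel,
    schedule_id: str = "",
) -> pd.DataFrame:
    est = model.estimate_individuals(dataset)
    sets = []
    for _, row in est.iterrows():
        curve = ResponseCurveParams(
            GammaKernelParams(row["alpha"], row["beta"]),
            float(row["A"]), float(row["b0"]), float(row["b1"]), float(row["dT"]),
        )
        sets.append(indicators_model_based(curve, method="MM"))
    return pd.DataFrame(_rows_from_sets(dataset, sets, "MM", schedule_id))


def rank_accuracy(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    group_keys: Sequence[str] = ("method", "schedule_id"),
) -> pd.DataFrame:
    """One row per (group, indicator): Spearman r_s, MAE, bias, n.

    MAE is the mean absolute difference true - estimated; bias is the
    mean of true - estimated.  Estimates must cover exactly the truth's
    participants within each group.
    """
    group_keys = list(group_keys)
    rows = []
    truth_idx = truth.set_index("participant_id")
    for keys, grp in estimates.groupby(group_keys, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        missing = set(grp["participant_id"]) - set(truth_idx.index)
        if missing:
            raise ValidationError(f"estimates contain unknown participants: {sorted(missing)[:5]}")
        t = truth_idx.loc[grp["participant_id"].to_numpy()]
        for ind in INDICATORS:
            est = grp[ind].to_numpy(dtype=float)
            tru = t[ind].to_numpy(dtype=float)
            rows.append(
                dict(zip(group_keys, keys))
                | {"indicator": ind, "r_s": spearman(est, tru),
                   "mae": float(np.abs(tru - est).mean()),
                   "bias": float((tru - est).mean()), "n": est.size}
            )
    return pd.DataFrame(rows)


def stability(values_by_schedule: pd.DataFrame) -> dict:
    """Mean pairwise Spearman correlation across schedule columns.

    ``values_by_schedule``: participants x schedules frame of one
    indicator under one method; every participant evaluated under every
    schedule.
    """
    cols = list(values_by_schedule.columns)
    if len(cols) < 2:
        raise ValidationError("stability needs >= 2 schedules")
    pairs = {}
    for a, b in combinations(cols, 2):
        pairs[(a, b)] = spearman(values_by_schedule[a], values_by_schedule[b])
    return {"pairwise": pairs, "mean_r_s": float(np.mean(list(pairs.values())))}


def duration_bias(indicator_values, durations) -> float:
    """Spearman correlation of indicator values with allocated duration."""
    d = np.asarray(durations, dtype=float)
    if np.ptp(d) == 0:
        raise DegenerateTestError("duration correlation undefined for a single duration")
    return spearman(indicator_values, d)


def obs_truncated(
    dataset: Sequence[ParticipantSeries],
    allocation: Mapping[str, str],
    schedule_set: ScheduleSet,
    peak_time: float = NOMINAL_PEAK_TIME,
) -> pd.DataFrame:
    """OBS indicators after truncating at the latest schedule-common timepoint.

    Harmonizes sampling duration across a combined dataset: the cut-off
    is the largest timepoint present in *every* schedule of the set.
    """
    common = set(schedule_set.schedules[0].timepoints)
    for s in schedule_set.schedules[1:]:
        common &= set(s.timepoints)
    common.discard(0.0)
    if not common:
        raise ValidationError("no common timepoint beyond baseline; cannot truncate")
    cutoff = max(common)
    truncated = []
    for series in dataset:
        t = series.times_array()
        mask = t <= cutoff
        truncated.append(series.with_samples(t[mask], series.cortisol_array()[mask]))
    return indicator_table_obs(truncated, peak_time, method="OBS_s")


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def _method_tables(dataset, schedule_id, pop, mm, peak_time):
    tables = [indicator_table_obs(dataset, peak_time, schedule_id=schedule_id)]
    if pop is not None:
        tables.append(indicator_table_asm(dataset, pop, schedule_id=schedule_id))
    if mm is not None:
        tables.append(indicator_table_mm(dataset, mm, schedule_id=schedule_id))
    return pd.concat(tables, ignore_index=True)


def evaluate_single_schedules(
    cohort: SimulatedCohort,
    schedules: Sequence[SamplingSchedule],
    pop: PopulationCurve | None = None,
    mm: MultilevelGammaModel | None = None,
    peak_time: float = NOMINAL_PEAK_TIME,
) -> pd.DataFrame:
    """Accuracy of each method when one schedule is applied to everyone."""
    truth = truth_table(cohort)
    frames = []
    for sched in schedules:
        dataset = [downsample(ind, sched) for ind in cohort]
        est = _method_tables(dataset, sched.id, pop, mm, peak_time)
        frames.append(rank_accuracy(est, truth))
    return pd.concat(frames, ignore_index=True)


def evaluate_combined(
    cohort: SimulatedCohort,
    schedule_set: ScheduleSet,
    pop: PopulationCurve | None = None,
    mm: MultilevelGammaModel | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    peak_time: float = NOMINAL_PEAK_TIME,
    include_obs_s: bool | None = None,
) -> dict:
    """Combined-data evaluation over ``n_replicates`` random allocations.

    Returns ``accuracy`` (per replicate x method x indicator),
    ``duration_r_s`` (per replicate x method x indicator Spearman with
    allocated duration, when durations vary) and
    ``single_schedule_accuracy``.
    """
    truth = truth_table(cohort)
    durations = {s.id: s.duration for s in schedule_set.schedules}
    vary_duration = len(set(durations.values())) > 1
    if include_obs_s is None:
        include_obs_s = vary_duration

    acc_frames, dur_rows = [], []
    for rep in range(n_replicates):
        dataset, allocation = build_combined_dataset(
            cohort, schedule_set, seed=seed + rep
        )
        est = _method_tables(dataset, f"combined_rep{rep}", pop, mm, peak_time)
        if include_obs_s:
            obs_s = obs_truncated(dataset, allocation, schedule_set, peak_time)
            obs_s["schedule_id"] = f"combined_rep{rep}"
            est = pd.concat([est, obs_s], ignore_index=True)
        acc = rank_accuracy(est, truth)
        acc["replicate"] = rep
        acc_frames.append(acc)
        if vary_duration:
            alloc_dur = est["participant_id"].map(
                lambda pid: durations[allocation[pid]]
            ).to_numpy()
            for method, grp in est.groupby("method", sort=False):
                d = alloc_dur[grp.index.to_numpy()]
                for ind in INDICATORS:
                    dur_rows.append(
                        {"replicate": rep, "method": method, "indicator": ind,
                         "r_s_duration": duration_bias(grp[ind].to_numpy(), d)}
                    )
    single = evaluate_single_schedules(cohort, schedule_set.schedules, pop, mm, peak_time)
    return {
        "accuracy": pd.concat(acc_frames, ignore_index=True),
        "duration_r_s": pd.DataFrame(dur_rows),
        "single_schedule_accuracy": single,
    }


def summarize_combined(results: dict) -> pd.DataFrame:
    """Mean combined accuracy, Fisher-averaged single-schedule accuracy
    and their gap, per method x indicator (Tables-style summary)."""
    acc = results["accuracy"]
    single = results["single_schedule_accuracy"]
    rows = []
    for (method, ind), grp in acc.groupby(["method", "indicator"], sort=False):
        comb = float(grp["r_s"].mean())
        s = single[(single["method"] == (method if method != "OBS_s" else "OBS"))
                   & (single["indicator"] == ind)]["r_s"]
        single_mean = fisher_average(s) if len(s) else np.nan
        row = {"method": method, "indicator": ind, "r_s_combined": comb,
               "r_s_single": single_mean, "accuracy_drop": single_mean - comb}
        dur = results["duration_r_s"]
        if len(dur):
            hit = dur[(dur["method"] == method) & (dur["indicator"] == ind)]
            if len(hit):
                row["r_s_duration"] = float(hit["r_s_duration"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def duration_robustness_experiment(
    n: int = 2000,
    n_train: int = 500,
    n_replicates: int = 10,
    seed: int = 0,
    mm_max_iter: int = 30,
) -> dict:
    """End-to-end duration-robustness study on the shipped simulator.

    Simulates an evaluation cohort and a separate training cohort, fits
    the ASM population curve and the multilevel model on densely sampled
    training data, then runs the combined-data evaluation on the
    duration-varying schedule set.  Returns the raw results plus the
    per-method summary (combined accuracy, single-schedule accuracy,
    accuracy drop, duration correlation).
    """
    from .asm import AmplitudeScalingModel
    from .simulate import SamplingSchedule, SimConfig, default_schedule_sets, simulate_cohort

    cohort = simulate_cohort(SimConfig(n_individuals=n, seed=seed))
    train = simulate_cohort(SimConfig(n_individuals=n_train, seed=seed + 10_000))
    dense = SamplingSchedule("train_dense", tuple(float(t) for t in range(0, 81, 10)))
    train_data = [downsample(ind, dense) for ind in train]
    asm = AmplitudeScalingModel(select_by_bic=False).fit(train_data)
    mm = MultilevelGammaModel(max_iter=mm_max_iter, compute_se=False, seed=seed).fit(
        train_data
    )
    results = evaluate_combined(
        cohort,
        default_schedule_sets()["duration"],
        pop=asm.population_curve_,
        mm=mm,
        n_replicates=n_replicates,
        seed=seed + 20_000,
    )
    results["summary"] = summarize_combined(results)
    results["asm_population_curve"] = asm.population_curve_
    results["mm"] = mm
    return results


def plot_accuracy(summary: pd.DataFrame, path=None):
    """Bar panels of combined vs single-schedule accuracy per indicator."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    indicators = summary["indicator"].unique()
    fig, axes = plt.subplots(1, len(indicators), figsize=(4 * len(indicators), 3.2),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, ind in zip(axes, indicators):
        sub = summary[summary["indicator"] == ind]
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub["r_s_single"], width=0.4, label="single schedule")
        ax.bar(x + 0.2, sub["r_s_combined"], width=0.4, label="combined data")
        ax.set_xticks(x, sub["method"])
        ax.set_title(ind)
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("rank-order accuracy (Spearman $r_s$)")
    axes[-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
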
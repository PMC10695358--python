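"""End-to-end orchestration: simulate (or load) behavior and BOLD, compute
learning signals, apply QC and burn-in, extract trial-locked time courses,
summarize analysis windows, and fit the three mixed-model families:

  * all stop trials, median activity 4-10 s post stop signal (with the
    failed-stop indicator as a fixed effect);
  * failed stops only, 4-10 s;
  * failed stops only, 1-5 s (the early salience window).

Each family is compared by likelihood ratio against drop-one models excluding
dP(Stop) or dRT (each exclusion removes the fixed effect and its random
slope).  A master seed drives per-stage, per-subject child seeds so results
are fully deterministic and enlarging the cohort does not perturb existing
subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .task_sim import RunConfig, BehavioralRun, simulate_cohort, STOP
from .learning_signals import (RPEModelParams, apply_burn_in, compute_signals,
                               qc_filter_runs)
from .bold_sim import RoiSignalSpec, RoiTimeSeries, synthesize_bold
from .timecourse import (center_timecourses, condition_average,
                         condition_contrast, extract_trial_timecourse,
                         window_stat)
from .mixed_model import (MixedModelFit, fit_lmm, lrt_compare,
                          model_comparison_table, standardize_predictors)

LATE_WINDOW = (4.0, 10.0)
EARLY_WINDOW = (1.0, 5.0)


@dataclass
class PipelineConfig:
    """Study conditions for a synthetic end-to-end run."""

    n_subjects: int = 200
    waves: tuple[int, ...] = (1, 2)
    run_config: RunConfig = field(default_factory=RunConfig)
    rpe_params: RPEModelParams = field(default_factory=RPEModelParams)
    roi_specs: tuple[RoiSignalSpec, ...] = (
        RoiSignalSpec.defaults("striatal_functional"),)
    windows: dict = field(default_factory=lambda: {
        "late": LATE_WINDOW, "early": EARLY_WINDOW})
    window_statistic: str = "median"
    n_burn: int = 25
    go_rt_mu_sd: float = 0.03
    qc_bounds: tuple[float, float] = (0.20, 0.80)
    seed: int = 0


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def compute_cohort_signals(runs: Sequence[BehavioralRun],
                           params: RPEModelParams, seed: int
                           ) -> dict[tuple[str, int], pd.DataFrame]:
    """Learning-signal tables keyed by (subject, wave), seeded per run."""
    out = {}
    for run, child in zip(runs, _child_seeds(seed, len(runs))):
        rng = np.random.default_rng(child)
        out[(run.subject_id, run.wave)] = compute_signals(run, params, rng)
    return out


def extract_stop_trial_stats(run: BehavioralRun, series: RoiTimeSeries,
                             signals: pd.DataFrame,
                             windows: dict, statistic: str = "median",
                             center: bool = True) -> pd.DataFrame:
    """Window statistics for every stop trial of one run on one ROI series.

    Courses are extracted around each stop signal, optionally centered by the
    per-bin mean across the run's stop-trial courses, and summarized per
    window.
    """
    courses = []
    for t in run.trials:
        if t.trial_type != STOP:
            continue
        courses.append(extract_trial_timecourse(
            series, t.stop_signal_time, subject=run.subject_id, wave=run.wave,
            trial=t.index, condition=t.outcome))
    if center and courses:
        courses = center_timecourses(courses)
    rows = []
    for c in courses:
        row = {"subject": c.subject, "wave": c.wave, "trial": c.trial,
               "condition": c.condition, "roi": series.roi}
        for name, window in windows.items():
            row[f"stat_{name}"] = window_stat(c, window, statistic)
        rows.append(row)
    stats_df = pd.DataFrame(rows)
    return stats_df.merge(
        signals[["trial", "stop_failure", "delta_pstop", "delta_rt", "rpe"]],
        on="trial", how="left")


def build_trial_table(runs: Sequence[BehavioralRun],
                      signal_tables: dict,
                      series_by_run: dict,
                      windows: Optional[dict] = None,
                      statistic: str = "median",
                      n_burn: int = 25) -> pd.DataFrame:
    """Assemble the modeling table: one row per retained stop trial.

    ``series_by_run`` maps (subject, wave) to a RoiTimeSeries.  Burn-in trials
    are removed after signal computation; standardized trial number and
    predictors are appended (columns trial_z, dpstop_z, drt_z).
    """
    windows = windows or {"late": LATE_WINDOW, "early": EARLY_WINDOW}
    frames = []
    for run in runs:
        key = (run.subject_id, run.wave)
        if key not in series_by_run:
            continue
        frames.append(extract_stop_trial_stats(
            run, series_by_run[key], signal_tables[key], windows, statistic))
    table = pd.concat(frames, ignore_index=True)
    table = apply_burn_in(table, n_burn=n_burn)
    table = table.rename(columns={"delta_pstop": "dpstop", "delta_rt": "drt"})
    table = table.dropna(subset=["dpstop"])
    keep = table.dropna(subset=["drt"]).copy()
    keep = standardize_predictors(keep, ["trial", "dpstop", "drt"])
    keep = keep.rename(columns={"trial_z": "trial_z", "dpstop_z": "dpstop_z",
                                "drt_z": "drt_z"})
    return keep


def fit_model_family(table: pd.DataFrame, response: str,
                     include_stop_failure: bool,
                     method: str = "ml") -> dict[str, MixedModelFit]:
    """Full model plus drop-one reductions for dP(Stop) and dRT.

    Dropping a learning signal removes both its fixed effect and its random
    slope, mirroring the rule that every modeled signal gets a corresponding
    subject-level random effect.
    """
    base_fixed = ["trial_z"] + (["stop_failure"] if include_stop_failure else [])
    full_fixed = base_fixed + ["dpstop_z", "drt_z"]
    fits = {
        "full": fit_lmm(table, response, fixed=full_fixed,
                        random_slopes=("dpstop_z", "drt_z"), method=method),
        "no_dpstop": fit_lmm(table, response, fixed=base_fixed + ["drt_z"],
                             random_slopes=("drt_z",), method=method),
        "no_drt": fit_lmm(table, response, fixed=base_fixed + ["dpstop_z"],
                          random_slopes=("dpstop_z",), method=method),
    }
    return fits


def _fit_to_dict(fit: MixedModelFit) -> dict:
    return {
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "ci_low": {k: float(v) for k, v in fit.conf_int[0].items()},
        "ci_high": {k: float(v) for k, v in fit.conf_int[1].items()},
        "random_effect_sd": {k: float(v) for k, v in fit.re_sd.items()},
        "logLik": fit.llf, "AIC": fit.aic, "BIC": fit.bic,
        "n_params": fit.n_params, "n_obs": fit.n_obs,
        "r2_marginal": fit.r2_marginal, "r2_conditional": fit.r2_conditional,
        "singular": fit.singular,
    }


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> dict:
    """Simulate a cohort end to end and fit the three model families.

    Returns a report dict (JSON-serializable except for the embedded fits) and
    optionally writes the trial table, QC report and JSON summary to
    ``out_dir``.
    """
    stage_seeds = _child_seeds(config.seed, 4)
    behavior_seed = int(stage_seeds[0].generate_state(1)[0] % (2 ** 31))
    signal_seed = int(stage_seeds[1].generate_state(1)[0] % (2 ** 31))

    runs = simulate_cohort(config.n_subjects, config.waves, config.run_config,
                           seed=behavior_seed, go_rt_mu_sd=config.go_rt_mu_sd)
    kept, qc_report = qc_filter_runs(runs, *config.qc_bounds)
    signal_tables = compute_cohort_signals(kept, config.rpe_params, signal_seed)

    # BOLD synthesis per retained run per ROI
    series: dict[str, dict] = {spec.roi: {} for spec in config.roi_specs}
    bold_children = stage_seeds[2].spawn(len(kept) * len(config.roi_specs))
    ci = 0
    for run in kept:
        key = (run.subject_id, run.wave)
        for spec in config.roi_specs:
            rng = np.random.default_rng(bold_children[ci]); ci += 1
            series[spec.roi][key] = synthesize_bold(
                run, signal_tables[key], spec, seed=rng)

    report = {
        "n_runs_simulated": len(runs),
        "n_runs_retained": len(kept),
        "qc_exclusions": qc_report.to_dict(orient="records"),
        "models": {},
    }
    tables = {}
    for spec in config.roi_specs:
        table = build_trial_table(kept, signal_tables, series[spec.roi],
                                  windows=config.windows,
                                  statistic=config.window_statistic,
                                  n_burn=config.n_burn)
        tables[spec.roi] = table
        failed = table[table["stop_failure"] == 1.0]
        families = {
            "all_stops_late": (table, "stat_late", True),
            "failed_stops_late": (failed, "stat_late", False),
            "failed_stops_early": (failed, "stat_early", False),
        }
        roi_models = {}
        for fam_name, (data, response, with_c) in families.items():
            fits = fit_model_family(data, response, include_stop_failure=with_c)
            comparison = model_comparison_table(fits)
            roi_models[fam_name] = {
                "fits": {k: _fit_to_dict(v) for k, v in fits.items()},
                "comparison": comparison.to_dict(orient="records"),
                "n_trials": int(len(data.dropna(subset=[response]))),
            }
        report["models"][spec.roi] = roi_models

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qc_report.to_csv(out / "qc_exclusions.csv", index=False)
        for roi, table in tables.items():
            table.to_csv(out / f"trial_table_{roi}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    report["_tables"] = tables
    return report


def simulate_model_response(table: pd.DataFrame, betas: dict, re_sds: dict,
                            resid_sd: float, rng: np.random.Generator,
                            subject_col: str = "subject",
                            wave_col: str = "wave") -> np.ndarray:
    """Generate a response from the Table-1 linear predictor on standardized
    predictors with known coefficients, subject/wave random effects and
    Gaussian noise."""
    n = len(table)
    y = np.full(n, betas.get("intercept", 0.0))
    for name, col in (("trial", "trial_z"), ("stop_failure", "stop_failure"),
                      ("dpstop", "dpstop_z"), ("drt", "drt_z")):
        if name in betas:
            y = y + betas[name] * table[col].to_numpy(dtype=float)
    subjects = table[subject_col].to_numpy()
    uniq_s = pd.unique(subjects)
    u0 = dict(zip(uniq_s, rng.normal(0, re_sds.get("intercept", 0.0), len(uniq_s))))
    u_dp = dict(zip(uniq_s, rng.normal(0, re_sds.get("dpstop", 0.0), len(uniq_s))))
    u_drt = dict(zip(uniq_s, rng.normal(0, re_sds.get("drt", 0.0), len(uniq_s))))
    waves = table[wave_col].to_numpy()
    uniq_w = pd.unique(waves)
    v = dict(zip(uniq_w, rng.normal(0, re_sds.get("wave", 0.0), len(uniq_w))))
    y = (y
         + np.array([u0[s] for s in subjects])
         + np.array([u_dp[s] for s in subjects]) * table["dpstop_z"].to_numpy()
         + np.array([u_drt[s] for s in subjects]) * table["drt_z"].to_numpy()
         + np.array([v[w] for w in waves])
         + rng.normal(0, resid_sd, n))
    return y


DEFAULT_RECOVERY_BETAS = {"intercept": 0.0, "trial": 0.1, "stop_failure": 0.2,
                          "dpstop": 1.5, "drt": -0.05}
DEFAULT_RECOVERY_RE_SDS = {"intercept": 0.3, "dpstop": 0.2, "drt": 0.1,
                           "wave": 0.1}


def recovery_experiment(n_subjects: int = 200, waves: tuple[int, ...] = (1, 2),
                        n_replicates: int = 50,
                        betas: Optional[dict] = None,
                        re_sds: Optional[dict] = None,
                        resid_sd: float = 1.0,
                        run_config: Optional[RunConfig] = None,
                        n_burn: int = 25, seed: int = 0,
                        with_lrt: bool = False) -> dict:
    """Parameter recovery for the all-stop-trials mixed model.

    Each replicate simulates a fresh behavioral cohort, computes learning
    signals, standardizes predictors over retained stop trials, generates the
    response from the declared generative coefficients (on the standardized
    scale), refits the model, and records estimates, 95% CI coverage and sign
    agreement; optionally also drop-one likelihood-ratio rejections at
    alpha 0.05.
    """
    betas = dict(DEFAULT_RECOVERY_BETAS if betas is None else betas)
    re_sds = dict(DEFAULT_RECOVERY_RE_SDS if re_sds is None else re_sds)
    run_config = run_config or RunConfig()
    name_map = {"trial": "trial_z", "stop_failure": "stop_failure",
                "dpstop": "dpstop_z", "drt": "drt_z"}
    records = []
    for rep, child in enumerate(_child_seeds(seed, n_replicates)):
        s1, s2 = child.spawn(2)
        cohort_seed = int(s1.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(s2)
        runs = simulate_cohort(n_subjects, waves, run_config, seed=cohort_seed)
        frames = []
        for run in runs:
            sig = compute_signals(run)
            sig = sig[sig["trial_type"] == STOP]
            frames.append(sig)
        table = pd.concat(frames, ignore_index=True)
        table = apply_burn_in(table, n_burn=n_burn)
        table = table.rename(columns={"delta_pstop": "dpstop",
                                      "delta_rt": "drt"})
        table = table.dropna(subset=["drt"])
        table = standardize_predictors(table, ["trial", "dpstop", "drt"])
        table = table.copy()
        table["y"] = simulate_model_response(table, betas, re_sds, resid_sd, rng)
        fits = None
        if with_lrt:
            fits = fit_model_family(table, "y", include_stop_failure=True)
            fit = fits["full"]
        else:
            fit = fit_lmm(table, "y",
                          fixed=("trial_z", "stop_failure", "dpstop_z", "drt_z"),
                          random_slopes=("dpstop_z", "drt_z"))
        rec = {"replicate": rep, "n_trials": len(table)}
        for gen_name, col in name_map.items():
            if gen_name not in betas:
                continue
            est = float(fit.params[col])
            lo = float(fit.conf_int.loc[col, 0])
            hi = float(fit.conf_int.loc[col, 1])
            true = betas[gen_name]
            rec[f"est_{gen_name}"] = est
            rec[f"cover_{gen_name}"] = lo <= true <= hi
            rec[f"sign_{gen_name}"] = np.sign(est) == np.sign(true)
        if with_lrt and fits is not None:
            rec["lrt_p_dpstop"] = lrt_compare(fits["full"], fits["no_dpstop"]).p
            rec["lrt_p_drt"] = lrt_compare(fits["full"], fits["no_drt"]).p
        records.append(rec)
    results = pd.DataFrame(records)
    summary = {"n_replicates": n_replicates, "betas": betas,
               "mean_estimates": {}, "coverage": {}, "sign_agreement": {}}
    for gen_name in betas:
        if f"est_{gen_name}" not in results:
            continue
        summary["mean_estimates"][gen_name] = float(results[f"est_{gen_name}"].mean())
        summary["coverage"][gen_name] = float(results[f"cover_{gen_name}"].mean())
        summary["sign_agreement"][gen_name] = float(results[f"sign_{gen_name}"].mean())
    if with_lrt:
        summary["lrt_rejection_rate"] = {
            "dpstop": float((results["lrt_p_dpstop"] < 0.05).mean()),
            "drt": float((results["lrt_p_drt"] < 0.05).mean())}
    summary["replicates"] = results
    return summary


def cohort_window_contrast(runs: Sequence[BehavioralRun], signal_tables: dict,
                           roi_spec: RoiSignalSpec, seed: int,
                           window: tuple[float, float] = LATE_WINDOW) -> dict:
    """Group-average correct-minus-failed stop contrast in a window, one ROI.

    Synthesizes the ROI series for every run, extracts and centers stop-trial
    courses per run, averages by condition across the cohort and returns the
    mean contrast over bins in the closed window, together with the two
    condition means.
    """
    courses = []
    for run, child in zip(runs, _child_seeds(seed, len(runs))):
        key = (run.subject_id, run.wave)
        series = synthesize_bold(run, signal_tables[key], roi_spec,
                                 seed=np.random.default_rng(child))
        run_courses = [extract_trial_timecourse(
            series, t.stop_signal_time, subject=run.subject_id, wave=run.wave,
            trial=t.index, condition=t.outcome)
            for t in run.trials if t.trial_type == STOP]
        courses.extend(center_timecourses(run_courses))
    curves = condition_average(courses)
    contrast = condition_contrast(curves)
    lo, hi = window
    mask = (contrast.bin_centers >= lo - 1e-9) & (contrast.bin_centers <= hi + 1e-9)
    out = {"contrast_mean": float(np.nanmean(contrast.mean[mask])),
           "roi": roi_spec.roi, "window": window}
    for label, curve in curves.items():
        out[f"mean_{label}"] = float(np.nanmean(curve.mean[mask]))
    return out


def individual_difference_correlation(activity, rt_change) -> float:
    """Product-moment correlation of per-subject mean window activity with
    per-subject mean post-minus-pre RT change."""
    a = np.asarray(activity, dtype=float)
    b = np.asarray(rt_change, dtype=float)
    if len(a) != len(b):
        raise ValueError("vectors must be the same length")
    if len(a) < 3:
        raise ValueError("need at least three subjects")
    r, _ = sp_stats.pearsonr(a, b)
    return float(r)
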
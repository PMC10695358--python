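"""Trial-level learning signals and inclusion/exclusion rules.

Two quantities are treated as learnable features of the task: the probability
that a trial is a stop trial, P(Stop), estimated as the running proportion of
prior stop trials (the estimate an unboundedly rational observer would hold
under the task's variable-ratio schedule), and the stop-signal delay,
operationalized behaviorally as the post-minus-pre change in go reaction time
around each stop trial.  The reward-prediction-error model combines the
per-trial updates of the two:

    RPE = beta1 * dP(Stop) + beta2 * dRT + eps,   eps ~ Normal(0, epsilon_sd)

dP(Stop) is positive after a stop trial and negative after a go trial, and
shrinks as 1/k with trial number k.  With beta1 > 0 and beta2 < 0 the RPE is
positive after correct stops (where dRT ~ 0) and negative after failed stops
(where post-error slowing makes dRT > 0), matching the valence structure the
analysis is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task_sim import (BehavioralRun, CORRECT_STOP, FAILED_STOP, GO, STOP)


@dataclass(frozen=True)
class RPEModelParams:
    """Weights of the linear RPE model; epsilon_sd is the residual scale."""

    beta1: float = 1.5    # weight on dP(Stop)
    beta2: float = -1.0   # weight on dRT (proxy for dSSD); negative: slowing
    epsilon_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.epsilon_sd < 0:
            raise ValueError("epsilon_sd must be >= 0")


def pstop_series(trial_types: Sequence[str]) -> np.ndarray:
    """Running P(Stop) estimate *before* each trial.

    The estimate at trial k is the proportion of stop trials among trials
    1..k-1; at trial 1 (empty prior set) it is defined as 0 unless a design
    prior is supplied via :func:`delta_pstop`'s ``prior`` argument.
    """
    if len(trial_types) == 0:
        raise ValueError("trial_types must be non-empty")
    is_stop = np.asarray([t == STOP for t in trial_types], dtype=float)
    k = np.arange(1, len(is_stop) + 1, dtype=float)
    cum_before = np.concatenate([[0.0], np.cumsum(is_stop)[:-1]])
    est = np.zeros_like(k)
    est[1:] = cum_before[1:] / (k[1:] - 1)
    return est


def delta_pstop(trial_types: Sequence[str]) -> np.ndarray:
    """Per-trial update of the running P(Stop) estimate.

    The change attributed to trial k is (estimate after k) - (estimate before
    k), i.e. (#stop in 1..k)/k - (#stop in 1..k-1)/(k-1).  Positive after a
    stop trial, negative after a go trial, with 1/k shrinkage.
    """
    est_before = pstop_series(trial_types)
    is_stop = np.asarray([t == STOP for t in trial_types], dtype=float)
    k = np.arange(1, len(is_stop) + 1, dtype=float)
    est_after = np.cumsum(is_stop) / k
    return est_after - est_before


def delta_rt(run: BehavioralRun, stop_index: int) -> Optional[float]:
    """Post-minus-pre go RT change around a stop trial (positive = slowing).

    Uses the nearest valid go responses flanking the stop trial (go omissions
    and other stop trials never contribute).  Returns None when either flank
    is missing, e.g. for a stop trial at the run boundary; such trials are
    dropped listwise downstream.

    ``stop_index`` is the 1-based trial index and must point at a stop trial.
    """
    trials = run.trials
    if not 1 <= stop_index <= len(trials):
        raise IndexError(f"trial index {stop_index} out of range")
    if trials[stop_index - 1].trial_type != STOP:
        raise ValueError(f"trial {stop_index} is not a stop trial")
    rt_pre = None
    for t in reversed(trials[: stop_index - 1]):
        if t.trial_type == GO and t.rt is not None:
            rt_pre = t.rt
            break
    rt_post = None
    for t in trials[stop_index:]:
        if t.trial_type == GO and t.rt is not None:
            rt_post = t.rt
            break
    if rt_pre is None or rt_post is None:
        return None
    return float(rt_post - rt_pre)


def rpe(dp: float, drt: float, params: RPEModelParams,
        rng: Optional[np.random.Generator] = None) -> float:
    """Linear RPE: beta1*dP(Stop) + beta2*dRT + Normal(0, epsilon_sd) noise.

    Deterministic when ``epsilon_sd`` is 0 (or no rng is given).
    """
    if not (np.isfinite(dp) and np.isfinite(drt)):
        raise ValueError("rpe requires finite inputs")
    value = params.beta1 * dp + params.beta2 * drt
    if params.epsilon_sd > 0 and rng is not None:
        value += rng.normal(0.0, params.epsilon_sd)
    return float(value)


def compute_signals(run: BehavioralRun,
                    params: Optional[RPEModelParams] = None,
                    rng=None) -> pd.DataFrame:
    """Per-trial learning-signal table for one run.

    Columns: trial, trial_type, onset, ssd, rt, outcome, stop_failure,
    pstop_est, delta_pstop, delta_rt, rpe.  RT-change and RPE are defined for
    stop trials only and NaN elsewhere or when a flanking go RT is missing.
    """
    params = params or RPEModelParams()
    if rng is not None and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    types = [t.trial_type for t in run.trials]
    est = pstop_series(types)
    dps = delta_pstop(types)
    rows = []
    for i, t in enumerate(run.trials):
        drt = np.nan
        rpe_val = np.nan
        stop_failure = np.nan
        if t.trial_type == STOP:
            stop_failure = 1.0 if t.outcome == FAILED_STOP else 0.0
            d = delta_rt(run, t.index)
            if d is not None:
                drt = d
                rpe_val = rpe(dps[i], d, params, rng)
        rows.append({
            "subject": run.subject_id,
            "wave": run.wave,
            "trial": t.index,
            "trial_type": t.trial_type,
            "onset": t.onset,
            "ssd": np.nan if t.ssd is None else t.ssd,
            "rt": np.nan if t.rt is None else t.rt,
            "outcome": t.outcome,
            "stop_failure": stop_failure,
            "pstop_est": est[i],
            "delta_pstop": dps[i],
            "delta_rt": drt,
            "rpe": rpe_val,
        })
    return pd.DataFrame(rows)


def qc_filter_runs(runs: Sequence[BehavioralRun],
                   lo: float = 0.20, hi: float = 0.80
                   ) -> tuple[list[BehavioralRun], pd.DataFrame]:
    """Retain runs whose stop accuracy lies in the closed band [lo, hi].

    Extreme accuracy indicates a broken staircase or disengagement.  Boundary
    values are retained (exclusion is strict: accuracy < lo or > hi).  Runs
    with zero stop trials are excluded with their own reason.  Returns the
    retained runs and a report of exclusions.
    """
    kept: list[BehavioralRun] = []
    report = []
    for run in runs:
        acc = run.stop_accuracy
        if run.n_stop == 0:
            reason = "no_stop_trials"
        elif acc < lo:
            reason = "low_stop_accuracy"
        elif acc > hi:
            reason = "high_stop_accuracy"
        else:
            kept.append(run)
            continue
        report.append({"subject": run.subject_id, "wave": run.wave,
                       "stop_accuracy": acc, "reason": reason})
    return kept, pd.DataFrame(report,
                              columns=["subject", "wave", "stop_accuracy",
                                       "reason"])


def apply_burn_in(table: pd.DataFrame, n_burn: int = 25,
                  trial_col: str = "trial") -> pd.DataFrame:
    """Drop the first ``n_burn`` trials from an analysis table.

    Signals are computed on the full sequence first and filtered afterwards,
    so estimates at retained trials are unchanged by the filter.  Early trials
    are removed because subjects are still learning the practical arrangement
    of the task.
    """
    if n_burn < 0:
        raise ValueError("n_burn must be >= 0")
    out = table[table[trial_col] > n_burn].copy()
    if out.empty and not table.empty:
        warnings.warn("burn-in removed every trial", stacklevel=2)
    return out


@dataclass
class CohortLedger:
    """Ordered accounting of cohort exclusions."""

    initial: int
    stages: list[tuple[str, int]] = field(default_factory=list)

    @property
    def final(self) -> int:
        return self.initial - sum(n for _, n in self.stages)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": "initial", "removed": 0, "remaining": self.initial}]
        remaining = self.initial
        for label, n in self.stages:
            remaining -= n
            rows.append({"stage": label, "removed": n, "remaining": remaining})
        return pd.DataFrame(rows)


def cohort_accounting(initial: int,
                      removals: Sequence[tuple[str, int]]) -> CohortLedger:
    """Build an exclusion ledger; counts must stay non-negative throughout."""
    ledger = CohortLedger(initial=initial)
    remaining = initial
    for label, n in removals:
        if n < 0:
            raise ValueError(f"negative removal count for {label!r}")
        remaining -= n
        if remaining < 0:
            raise ValueError(
                f"ledger impossible: stage {label!r} leaves {remaining} subjects")
        ledger.stages.append((str(label), int(n)))
    return ledger
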
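"""Stop-signal-task behavioral simulator.

The task is a two-alternative forced choice: on every trial the subject
responds to an arrow, but on a minority of trials (15% by default) an auditory
stop signal sounds after a stop-signal delay (SSD) and the response must be
withheld.  The SSD is titrated by a one-up/one-down staircase so that stop
accuracy converges to roughly 50%.

Behavior is generated by the independent horse-race model: on every trial a
go process finishes at an ex-Gaussian latency; on stop trials a stop process
finishes at ``ssd + ssrt``.  A response is emitted iff the go process wins the
race.  Post-error slowing is injected as a constant added to the go finishing
time of the trial following a failed stop, so the behavioral RT-change signal
exists in synthetic data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GO = "go"
STOP = "stop"
CORRECT_GO = "correct_go"
GO_OMISSION = "go_omission"
CORRECT_STOP = "correct_stop"
FAILED_STOP = "failed_stop"

STOP_OUTCOMES = (CORRECT_STOP, FAILED_STOP)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one simulated SST run.

    Time parameters are in seconds.  ``go_rt_mu/sigma/tau`` are the
    ex-Gaussian parameters of the go finishing time; ``ssrt`` is the constant
    latency of the covert stop process.  ``post_error_slowing`` is added to
    the go finishing time of the trial immediately after a failed stop.
    """

    n_trials: int = 128
    p_stop: float = 0.15
    ssd_init: float = 0.250
    ssd_step: float = 0.050
    ssd_bounds: tuple[float, float] = (0.0, 0.900)
    go_rt_mu: float = 0.400
    go_rt_sigma: float = 0.050
    go_rt_tau: float = 0.100
    ssrt: float = 0.250
    post_error_slowing: float = 0.050
    go_deadline: float = 1.5
    trial_duration: float = 1.5
    iti_range: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_stop <= 1.0):
            raise ValueError(f"p_stop must lie in [0, 1], got {self.p_stop}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.ssd_bounds[0] < 0 or self.ssd_bounds[1] < self.ssd_bounds[0]:
            raise ValueError(f"invalid ssd_bounds {self.ssd_bounds}")
        for name in ("ssd_init", "ssd_step", "go_rt_mu", "go_rt_sigma",
                     "go_rt_tau", "ssrt", "post_error_slowing",
                     "go_deadline", "trial_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TrialRecord:
    """One SST trial. ``index`` is 1-based; times in seconds from run start."""

    index: int
    trial_type: str
    onset: float
    ssd: Optional[float] = None
    rt: Optional[float] = None
    outcome: str = CORRECT_GO

    def __post_init__(self) -> None:
        if self.trial_type == STOP:
            if self.ssd is None:
                raise ValueError("stop trial requires an ssd")
            if self.outcome not in STOP_OUTCOMES:
                raise ValueError(f"stop trial outcome {self.outcome!r}")
            if self.outcome == FAILED_STOP and self.rt is None:
                raise ValueError("failed stop requires an rt")
            if self.outcome == CORRECT_STOP and self.rt is not None:
                raise ValueError("correct stop cannot carry an rt")
        else:
            if self.ssd is not None:
                raise ValueError("go trial cannot carry an ssd")
            if self.outcome not in (CORRECT_GO, GO_OMISSION):
                raise ValueError(f"go trial outcome {self.outcome!r}")
            if self.outcome == GO_OMISSION and self.rt is not None:
                raise ValueError("omission cannot carry an rt")

    @property
    def stop_signal_time(self) -> Optional[float]:
        """Absolute time of the stop signal (onset + SSD); None on go trials."""
        if self.trial_type != STOP:
            return None
        return self.onset + self.ssd


@dataclass
class BehavioralRun:
    """An ordered sequence of trials for one subject in one wave/session."""

    subject_id: str
    wave: int
    config: RunConfig
    trials: list[TrialRecord] = field(default_factory=list)

    @property
    def n_stop(self) -> int:
        return sum(1 for t in self.trials if t.trial_type == STOP)

    @property
    def stop_accuracy(self) -> float:
        """Proportion of stop trials ending in a correct stop; NaN if none."""
        n = self.n_stop
        if n == 0:
            return float("nan")
        good = sum(1 for t in self.trials if t.outcome == CORRECT_STOP)
        return good / n

    @property
    def duration(self) -> float:
        last = self.trials[-1]
        return last.onset + self.config.trial_duration


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_trial_sequence(config: RunConfig, seed) -> list[str]:
    """Draw an i.i.d. Bernoulli(p_stop) sequence of trial types.

    Reproducible for a fixed seed; degenerate rates 0 and 1 give all-go and
    all-stop sequences.
    """
    rng = _as_rng(seed)
    draws = rng.random(config.n_trials) < config.p_stop
    return [STOP if d else GO for d in draws]


def staircase_update(ssd: float, outcome: str, config: RunConfig) -> float:
    """One-up/one-down SSD titration targeting 50% stop accuracy.

    A correct stop makes the next stop trial harder (SSD + step); a failed
    stop makes it easier (SSD - step).  The result is clamped to
    ``config.ssd_bounds``.
    """
    if outcome not in STOP_OUTCOMES:
        raise ValueError(f"staircase_update requires a stop outcome, got {outcome!r}")
    step = config.ssd_step if outcome == CORRECT_STOP else -config.ssd_step
    lo, hi = config.ssd_bounds
    return float(min(hi, max(lo, ssd + step)))


def _go_finish_time(config: RunConfig, rng: np.random.Generator,
                    extra_delay: float = 0.0) -> float:
    # ex-Gaussian: Normal(mu, sigma) + Exponential(tau); tau=0 degenerates cleanly
    t = rng.normal(config.go_rt_mu, config.go_rt_sigma)
    if config.go_rt_tau > 0:
        t += rng.exponential(config.go_rt_tau)
    return max(t, 0.0) + extra_delay


def simulate_trial(trial_type: str, ssd: Optional[float], config: RunConfig,
                   rng, index: int = 1, onset: float = 0.0,
                   extra_go_delay: float = 0.0) -> TrialRecord:
    """Race one trial: the response is emitted iff the go process wins.

    On stop trials the stop process finishes at ``ssd + ssrt``; a go finishing
    time below that (and below the response deadline) yields a failed stop
    carrying the go RT, otherwise a correct stop.  Go trials yield the go RT
    or an omission past the deadline.
    """
    rng = _as_rng(rng)
    finish = _go_finish_time(config, rng, extra_go_delay)
    if trial_type == GO:
        if finish > config.go_deadline:
            return TrialRecord(index, GO, onset, outcome=GO_OMISSION)
        return TrialRecord(index, GO, onset, rt=float(finish), outcome=CORRECT_GO)
    if ssd is None:
        raise ValueError("stop trial requires an ssd")
    responded = finish < ssd + config.ssrt and finish <= config.go_deadline
    if responded:
        return TrialRecord(index, STOP, onset, ssd=float(ssd),
                           rt=float(finish), outcome=FAILED_STOP)
    return TrialRecord(index, STOP, onset, ssd=float(ssd), outcome=CORRECT_STOP)


def simulate_run(subject_id: str, wave: int, config: RunConfig,
                 seed) -> BehavioralRun:
    """Simulate one full run: trial sequence, staircase, race, onsets.

    Deterministic for a fixed seed.  SSD evolves by the staircase across stop
    trials; with the default race parameters long-run stop accuracy hovers
    near the 50% design target.
    """
    rng = _as_rng(seed)
    types = generate_trial_sequence(config, rng)
    trials: list[TrialRecord] = []
    ssd = config.ssd_init
    onset = 0.0
    slow_next = False
    for i, ttype in enumerate(types, start=1):
        extra = config.post_error_slowing if slow_next else 0.0
        if ttype == STOP:
            rec = simulate_trial(STOP, ssd, config, rng, index=i, onset=onset,
                                 extra_go_delay=extra)
            ssd = staircase_update(ssd, rec.outcome, config)
        else:
            rec = simulate_trial(GO, None, config, rng, index=i, onset=onset,
                                 extra_go_delay=extra)
        slow_next = rec.outcome == FAILED_STOP
        trials.append(rec)
        lo, hi = config.iti_range
        iti = rng.uniform(lo, hi) if hi > lo else lo
        onset += config.trial_duration + iti
    return BehavioralRun(subject_id=subject_id, wave=wave, config=config,
                         trials=trials)


def simulate_cohort(n_subjects: int, waves: Sequence[int] = (1, 2),
                    config: Optional[RunConfig] = None, seed=0,
                    go_rt_mu_sd: float = 0.0) -> list[BehavioralRun]:
    """Simulate a cohort: one run per subject per wave.

    Per-subject seeds are spawned from the master seed, so enlarging the
    cohort does not perturb existing subjects.  ``go_rt_mu_sd`` > 0 draws each
    subject's mean go RT from Normal(config.go_rt_mu, go_rt_mu_sd), shared
    across that subject's waves.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or RunConfig()
    master = np.random.SeedSequence(seed)
    runs: list[BehavioralRun] = []
    for s_idx, child in enumerate(master.spawn(n_subjects)):
        subject_id = f"sub-{s_idx + 1:03d}"
        sub_seeds = child.spawn(len(waves) + 1)
        cfg = config
        if go_rt_mu_sd > 0:
            sub_rng = np.random.default_rng(sub_seeds[0])
            mu = max(float(sub_rng.normal(config.go_rt_mu, go_rt_mu_sd)), 0.05)
            cfg = config.replace(go_rt_mu=mu)
        for w_idx, wave in enumerate(waves):
            rng = np.random.default_rng(sub_seeds[w_idx + 1])
            runs.append(simulate_run(subject_id, wave, cfg, rng))
    return runs


def run_to_events(run: BehavioralRun) -> pd.DataFrame:
    """Tidy BIDS-events-style table for one run (missing values as NaN)."""
    rows = []
    for t in run.trials:
        rows.append({
            "onset": t.onset,
            "duration": run.config.trial_duration,
            "trial_type": t.trial_type,
            "ssd": np.nan if t.ssd is None else t.ssd,
            "response_time": np.nan if t.rt is None else t.rt,
            "outcome": t.outcome,
            "subject_id": run.subject_id,
            "wave": run.wave,
        })
    return pd.DataFrame(rows)
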
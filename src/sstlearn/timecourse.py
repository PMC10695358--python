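"""Trial-locked BOLD time-course extraction by fine TR-overlap binning.

Raw (non-HRF-adjusted) activity is sampled in 0.1 s bins spanning -10 s to
+20 s around the stop signal; each bin receives the mean of every TR volume
whose acquisition interval overlaps it.  This FIR-like description makes no
assumption about response latency.  Go trials are anchored at a pseudo-event:
the go onset plus the SSD of the most recent preceding stop trial.

Conventions (the overlap rule itself leaves these open): a bin with center c
covers [c - 0.05, c + 0.05); volume i covers [t0 + i*TR, t0 + (i+1)*TR);
overlap means non-empty intersection.  Windows are closed and membership is by
bin center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bold_sim import RoiTimeSeries
from .task_sim import BehavioralRun, GO, STOP

#: -10.0 ... +20.0 s in 0.1 s steps: 301 bins.
def default_bin_centers() -> np.ndarray:
    return np.round(np.arange(-100, 201) * 0.1, 10)


@dataclass
class TrialTimecourse:
    """Event-locked binned activity for one trial.

    ``values`` holds NaN where no volume overlapped the bin (edge truncation).
    """

    subject: str
    wave: int
    trial: int
    condition: str
    bin_centers: np.ndarray
    values: np.ndarray

    def copy_with(self, values: np.ndarray) -> "TrialTimecourse":
        return TrialTimecourse(self.subject, self.wave, self.trial,
                               self.condition, self.bin_centers, values)


@dataclass
class ConditionCurve:
    """Per-bin mean and count for one condition (or a contrast)."""

    label: str
    bin_centers: np.ndarray
    mean: np.ndarray
    n: np.ndarray


def extract_trial_timecourse(series: RoiTimeSeries, event_time: float,
                             bin_centers: Optional[np.ndarray] = None,
                             bin_width: float = 0.1,
                             subject: str = "n/a", wave: int = 0,
                             trial: int = 0,
                             condition: str = "n/a") -> TrialTimecourse:
    """Bin a TR-sampled series around an event.

    Each bin's value is the mean of all volumes whose acquisition interval
    intersects the bin interval; bins with no overlapping recorded volume are
    NaN.  An event entirely outside the recorded series yields an all-NaN
    course with a warning.
    """
    if bin_centers is None:
        bin_centers = default_bin_centers()
    n_vol = len(series.values)
    tr = series.tr
    half = bin_width / 2.0
    # bin intervals relative to the series origin
    a = event_time + bin_centers - half - series.t0
    b = a + bin_width
    # volume i overlaps [a, b) iff i*tr < b and (i+1)*tr > a
    lo = np.floor(a / tr).astype(int)
    hi = np.ceil(b / tr).astype(int) - 1
    # guard float edges: drop volumes that do not actually intersect
    lo = np.where((lo + 1) * tr <= a, lo + 1, lo)
    hi = np.where(hi * tr >= b, hi - 1, hi)
    lo_c = np.clip(lo, 0, n_vol - 1)
    hi_c = np.clip(hi, 0, n_vol - 1)
    empty = (hi < 0) | (lo > n_vol - 1) | (hi_c < lo_c)
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    with np.errstate(invalid="ignore"):
        sums = csum[hi_c + 1] - csum[lo_c]
        counts = (hi_c - lo_c + 1).astype(float)
        values = np.where(empty, np.nan, sums / counts)
    if np.all(empty):
        warnings.warn(f"event at {event_time:.2f}s lies outside the recorded "
                      "series; all bins absent", stacklevel=2)
    return TrialTimecourse(subject=subject, wave=wave, trial=trial,
                           condition=condition,
                           bin_centers=np.asarray(bin_centers, dtype=float),
                           values=values)


def go_pseudo_event(run: BehavioralRun, go_trial_index: int) -> float:
    """Anchor time for a go trial: onset + SSD of the last preceding stop.

    Go trials carry no stop signal, so an expected SSD stands in: the SSD of
    the most recent preceding stop trial, or the configured initial SSD when
    no stop trial has occurred yet.
    """
    trials = run.trials
    if not 1 <= go_trial_index <= len(trials):
        raise IndexError(f"trial index {go_trial_index} out of range")
    rec = trials[go_trial_index - 1]
    if rec.trial_type != GO:
        raise ValueError(f"trial {go_trial_index} is not a go trial")
    ssd = run.config.ssd_init
    for t in reversed(trials[: go_trial_index - 1]):
        if t.trial_type == STOP:
            ssd = t.ssd
            break
    return rec.onset + ssd


def center_timecourses(courses: Sequence[TrialTimecourse]
                       ) -> list[TrialTimecourse]:
    """Subtract the per-bin mean over all courses (conditions pooled).

    After centering, the per-bin mean of the returned set is zero wherever
    values are present.  A single course centers to all zeros.
    """
    if len(courses) == 0:
        raise ValueError("need at least one timecourse")
    stack = np.vstack([c.values for c in courses])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        grand = np.nanmean(stack, axis=0)
    return [c.copy_with(c.values - grand) for c in courses]


def condition_average(courses: Sequence[TrialTimecourse]
                      ) -> dict[str, ConditionCurve]:
    """Per-bin mean within each condition label, with per-bin counts."""
    by_label: dict[str, list[TrialTimecourse]] = {}
    for c in courses:
        by_label.setdefault(c.condition, []).append(c)
    out = {}
    for label, group in by_label.items():
        stack = np.vstack([c.values for c in group])
        n = np.sum(np.isfinite(stack), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
        out[label] = ConditionCurve(label=label,
                                    bin_centers=group[0].bin_centers,
                                    mean=mean, n=n)
    return out


def condition_contrast(curves: dict[str, ConditionCurve],
                       positive: str = "correct_stop",
                       negative: str = "failed_stop") -> ConditionCurve:
    """Per-bin difference of two condition curves (positive - negative)."""
    for label in (positive, negative):
        if label not in curves:
            warnings.warn(f"condition {label!r} absent; contrast undefined",
                          stacklevel=2)
            a = next(iter(curves.values()))
            return ConditionCurve(label=f"{positive}-{negative}",
                                  bin_centers=a.bin_centers,
                                  mean=np.full_like(a.mean, np.nan),
                                  n=np.zeros_like(a.n))
    p, q = curves[positive], curves[negative]
    return ConditionCurve(label=f"{positive}-{negative}",
                          bin_centers=p.bin_centers, mean=p.mean - q.mean,
                          n=np.minimum(p.n, q.n))


def window_stat(course: TrialTimecourse, window: tuple[float, float] = (4.0, 10.0),
                stat: str = "median") -> float:
    """Summary statistic over bins whose centers lie in the closed window.

    No HRF adjustment is applied: the statistic is taken on the raw binned
    activity.  Returns NaN when every bin in the window is absent (such trials
    are dropped listwise downstream).
    """
    lo, hi = window
    mask = (course.bin_centers >= lo - 1e-9) & (course.bin_centers <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} contains no bins")
    vals = course.values[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan")
    if stat == "median":
        return float(np.median(vals))
    if stat == "peak":
        return float(np.max(vals))
    if stat == "trough":
        return float(np.min(vals))
    raise ValueError(f"stat must be median/peak/trough, got {stat!r}")


def timecourses_to_frame(courses: Sequence[TrialTimecourse]) -> pd.DataFrame:
    """Tidy long-format table: subject, wave, trial, condition, bin_center, value."""
    frames = []
    for c in courses:
        frames.append(pd.DataFrame({
            "subject": c.subject, "wave": c.wave, "trial": c.trial,
            "condition": c.condition, "bin_center": c.bin_centers,
            "value": c.values,
        }))
    return pd.concat(frames, ignore_index=True)
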
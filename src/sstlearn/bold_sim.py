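"""ROI-level BOLD synthesis with two embedded post-stop-signal components.

The generative model mirrors the two signals the analysis is built to
separate: (a) a fast, narrow salience response on failed stops only, peaking
1-3 s after the stop signal, whose amplitude can track the P(Stop) update; and
(b) a valenced reward-prediction-error response under the canonical
double-gamma hemodynamic response, peaking 4-6 s post-event, positive after
correct stops and negative after failed stops.  Striatal ROIs carry both
components; control ROIs (ACC, frontal orbital cortex) carry the salience
component only.

values = baseline + salience_events (*) fast HRF + rpe_events (*) canonical HRF
         + sinusoidal drift + AR(1) noise, sampled every TR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .task_sim import BehavioralRun, FAILED_STOP, STOP

STRIATAL_ROIS = ("accumbens", "caudate", "putamen", "striatal_functional")
CONTROL_ROIS = ("ACC", "FOC")


@dataclass(frozen=True)
class HrfSpec:
    """Difference-of-gammas hemodynamic response.

    ``peak_delay`` and ``undershoot_delay`` are gamma shape*scale products in
    seconds (SPM convention: the response gamma then peaks at
    ``peak_delay - peak_disp``); dispersions are the gamma scales.  The kernel
    is normalized to unit peak so event amplitudes are in response units.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    @classmethod
    def canonical(cls) -> "HrfSpec":
        """SPM-style canonical double gamma; peaks ~5 s post event."""
        return cls()

    @classmethod
    def fast_narrow(cls) -> "HrfSpec":
        """Fast narrow response for the failed-stop salience spike.

        Peaks at 1.75 s with support essentially confined to 0-4 s, so the
        spike it models lives in the 1-3 s window and does not leak into the
        4-10 s valenced window.
        """
        return cls(peak_delay=2.0, undershoot_delay=8.0, peak_disp=0.25,
                   undershoot_disp=1.0, undershoot_ratio=0.0, duration=12.0)


def hrf_kernel(spec: HrfSpec, dt: float) -> np.ndarray:
    """Sample the HRF on a grid of step ``dt`` seconds, unit peak, h(0)=0."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, spec.duration + dt / 2, dt)
    h = stats.gamma.pdf(t, spec.peak_delay / spec.peak_disp,
                        scale=spec.peak_disp)
    if spec.undershoot_ratio != 0:
        h = h - spec.undershoot_ratio * stats.gamma.pdf(
            t, spec.undershoot_delay / spec.undershoot_disp,
            scale=spec.undershoot_disp)
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return h


@dataclass(frozen=True)
class RoiSignalSpec:
    """Generative parameters for one ROI's time series.

    ``salience_gain`` plus ``salience_pstop_gain * dP(Stop)`` sets the failed-
    stop spike amplitude; ``rpe_gain`` multiplies each stop trial's RPE value.
    Amplitudes are arbitrary BOLD units; noise is AR(1) with stationary sd
    ``noise_sd`` at the TR sampling rate.
    """

    roi: str = "striatal_functional"
    salience_gain: float = 1.0
    salience_pstop_gain: float = 30.0
    rpe_gain: float = 25.0
    baseline: float = 0.0
    noise_ar: float = 0.3
    noise_sd: float = 0.25
    drift_amp: float = 0.1
    drift_period: float = 128.0

    @classmethod
    def defaults(cls, roi: str) -> "RoiSignalSpec":
        """Per-ROI defaults: RPE component in striatal ROIs only."""
        if roi in CONTROL_ROIS:
            return cls(roi=roi, rpe_gain=0.0)
        if roi in STRIATAL_ROIS:
            return cls(roi=roi)
        raise ValueError(f"unknown roi {roi!r}")


@dataclass
class RoiTimeSeries:
    """TR-sampled ROI signal. Volume i covers [t0 + i*tr, t0 + (i+1)*tr)."""

    roi: str
    tr: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def acq_onsets(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.tr

    @property
    def duration(self) -> float:
        return self.t0 + len(self.values) * self.tr


def neural_event_amplitudes(run: BehavioralRun, signals, roi_spec: RoiSignalSpec
                            ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-event (time, amplitude) lists for the two neural components.

    Both components are locked to the stop-signal time (trial onset + SSD).
    The salience component fires on failed stops; the RPE component fires on
    every stop trial with a defined RPE (trials whose RPE is missing — no
    flanking go RT — are skipped with a warning).  ``signals`` is the table
    from :func:`sstlearn.compute_signals`.
    """
    sal_t, sal_a, rpe_t, rpe_a = [], [], [], []
    skipped = []
    sig = signals.set_index("trial")
    for t in run.trials:
        if t.trial_type != STOP:
            continue
        event_time = t.stop_signal_time
        row = sig.loc[t.index]
        if t.outcome == FAILED_STOP:
            sal_t.append(event_time)
            sal_a.append(roi_spec.salience_gain
                         + roi_spec.salience_pstop_gain * row["delta_pstop"])
        if np.isfinite(row["rpe"]):
            rpe_t.append(event_time)
            rpe_a.append(roi_spec.rpe_gain * row["rpe"])
        else:
            skipped.append(t.index)
    if skipped:
        warnings.warn(
            f"RPE undefined on stop trials {skipped} (missing flanking go "
            "RT); events skipped", stacklevel=2)
    return {"salience": (np.asarray(sal_t), np.asarray(sal_a)),
            "rpe": (np.asarray(rpe_t), np.asarray(rpe_a))}


def _ar1_noise(n: int, phi: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi ** 2, 0.0)) if abs(phi) < 1 else sd
    e = rng.normal(0.0, innov_sd, n)
    if phi == 0:
        return e
    return sp_signal.lfilter([1.0], [1.0, -phi], e)


def synthesize_bold(run: BehavioralRun, signals, roi_spec: RoiSignalSpec,
                    duration: Optional[float] = None, seed=None,
                    tr: float = 2.0, dt: float = 0.1,
                    hrf_canonical: Optional[HrfSpec] = None,
                    hrf_fast: Optional[HrfSpec] = None,
                    events: Optional[dict] = None) -> RoiTimeSeries:
    """Assemble one ROI time series from the generative model.

    The neural impulse trains are built on a fine grid of step ``dt``,
    convolved with their respective HRFs, sampled every ``tr`` seconds, and
    summed with baseline, low-frequency drift and AR(1) noise.  Deterministic
    under a fixed seed.  ``duration`` defaults to the run duration + 30 s and
    must cover every event.
    """
    if duration is None:
        duration = run.duration + 30.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if events is None:
        events = neural_event_amplitudes(run, signals, roi_spec)
    n_grid = int(np.ceil(duration / dt)) + 1
    neural = np.zeros(n_grid)
    comps = {"salience": hrf_kernel(hrf_fast or HrfSpec.fast_narrow(), dt),
             "rpe": hrf_kernel(hrf_canonical or HrfSpec.canonical(), dt)}
    total = np.zeros(n_grid)
    for name, kernel in comps.items():
        times, amps = events[name]
        if len(times) == 0:
            continue
        if np.any(np.asarray(times) >= duration):
            raise ValueError("event beyond series duration; extend duration")
        impulses = np.zeros(n_grid)
        idx = np.round(np.asarray(times) / dt).astype(int)
        np.add.at(impulses, idx, np.asarray(amps))
        total += np.convolve(impulses, kernel)[:n_grid]
    n_vol = int(np.floor(duration / tr))
    sample_idx = np.round(np.arange(n_vol) * tr / dt).astype(int)
    values = roi_spec.baseline + total[sample_idx]
    if roi_spec.drift_amp != 0:
        t_vol = np.arange(n_vol) * tr
        values = values + roi_spec.drift_amp * np.sin(
            2 * np.pi * t_vol / roi_spec.drift_period)
    values = values + _ar1_noise(n_vol, roi_spec.noise_ar, roi_spec.noise_sd, rng)
    return RoiTimeSeries(roi=roi_spec.roi, tr=tr, values=values)
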
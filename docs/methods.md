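# Methods

This note documents the models implemented by `sstlearn`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Behavioral model

Behavior is generated by the independent horse-race model of stopping: on
every trial a go process finishes at an ex-Gaussian latency
Normal(μ, σ) + Exponential(τ); on stop trials a stop process finishes at
SSD + SSRT with a constant stop-signal reaction time.  A response is emitted
iff the go process finishes first (and before the response deadline).  The
race account is the standard generative reading of the SST; the task itself
only fixes the schedule (128 trials, 15% stop rate, staircased SSD).

Defaults (seconds): μ = 0.40, σ = 0.05, τ = 0.10 (mean go RT 0.50, typical of
adult two-choice responding); SSRT = 0.25, in the conventional 200–300 ms
band; staircase step 0.05, initial SSD 0.25, bounds [0, 0.90] — standard
one-up/one-down values that target 50% stop accuracy; go deadline 1.5 s.
Post-error slowing is injected as a constant (default 0.05 s) added to the go
finishing time of the trial after a failed stop, so the ΔRT signal exists in
synthetic data by construction.  Trial onsets are trial duration (1.5 s) plus
a uniform 2–4 s inter-trial interval; onsets matter only for BOLD synthesis.

The stop rate is exposed as a parameter (default 0.15; the task is sometimes
described as "1 in 7", treated here as approximate).  `p_stop` is accepted on
the closed interval [0, 1] so the degenerate all-go and all-stop sequences are
expressible.

## Learning signals

P(Stop) before trial k is the proportion of stop trials among trials 1..k−1,
with the empty prior set defined as 0 (a design prior can be injected by the
caller; nothing downstream depends on the trial-1 value).  The per-trial
update telescopes: summed updates equal final minus initial estimate.

ΔRT for a stop trial is the RT of the nearest valid go response after the
trial minus the nearest valid one before it (positive = slowing).  Go
omissions and other stop trials never contribute; the search extends past
them.  Trials missing either flank carry no ΔRT and are dropped listwise by
the models.  The post − pre sign convention is a documented choice: the
task-side phrasing ("change in reaction time coinciding with the trial")
admits both orientations.

RPE = β₁ΔP(Stop) + β₂ΔRT + ε with defaults β₁ = 1.5, β₂ = −1.0,
ε ~ Normal(0, 0.02).  The magnitudes were set so the valence pattern holds
under the behavioral defaults: after burn-in, ΔP(Stop) on a stop trial is
≈ +1/k ≤ 0.04 (contribution ≤ +0.06) while post-error slowing contributes
β₂ · 0.05 ≈ −0.05, so failed stops net negative and correct stops (ΔRT ≈ 0)
net positive.  A weaker |β₂| would leave failed-stop RPE positive, which is
not the structure the analysis is designed to detect.

QC retains runs with stop accuracy in the closed band [0.20, 0.80]
("less than 20%" / "higher than 80%" exclusion is strict, so boundary values
are retained); runs with no stop trials are excluded with their own reason.
The first 25 trials are excluded from analysis sets *after* signals are
computed on the full sequence, so retained-trial estimates are unaffected.

## BOLD generative model

One ROI series is baseline + salience events ⊛ fast HRF + RPE events ⊛
canonical HRF + sinusoidal drift + AR(1) noise, assembled on a 0.1 s grid and
sampled every TR = 2 s.  Both event trains are locked to the stop-signal time
(trial onset + SSD), not trial onset.

* Canonical HRF: difference of gammas with SPM's parameters (peak delay 6,
  undershoot delay 16, unit dispersions, undershoot ratio 1/6); the sampled
  kernel peaks at 5.0 s, inside the expected 4–6 s band.  Kernels are
  normalized to unit peak so event amplitudes are in response units.
* Salience HRF: a fast narrow gamma (shape 8, scale 0.25; peak 1.75 s) whose
  support is essentially confined to 0–4 s.  The component models a spike
  observed at 1–3 s after failed stops only; a wider kernel would leak into
  the 4–10 s valenced window and blur the very dissociation the component is
  meant to carry, so narrowness is part of the component's definition.
* Amplitudes: salience amplitude = `salience_gain` +
  `salience_pstop_gain`·ΔP(Stop) on failed stops (defaults 1.0 and 30; ΔP is
  ≤ 0.04 after burn-in, so the modulation is comparable to the base gain);
  RPE amplitude = `rpe_gain`·RPE (default 25 for striatal ROIs, 0 for
  ACC/FOC, making the valenced component striatal by construction).  Gains
  were chosen a priori so that embedded effects are detectable at cohort
  sizes of 100–200 subjects with the default noise, mirroring a well-powered
  large-sample design; an analytic power check (expected LRT χ² ≈ 14 for the
  early-window ΔP effect at 100 subjects × 2 waves) preceded implementation.
* Noise: AR(1) with φ = 0.3 and stationary SD 0.25 at the TR rate, plus a
  0.1-amplitude sinusoidal drift with a 128 s period — the minimum structure
  needed for realistic mixed-model testing.

Not emulated: physiological and motion noise, voxelwise spatial structure,
scanner drift nonstationarity, HRF variability across subjects, and any
nonlinearity of BOLD summation (the generator is exactly linear in events).
Passing tests therefore certify the analysis machinery — estimation,
binning, model comparison — under a faithful but idealized signal model, not
robustness to artifact-laden real data.

## Trial-locked extraction

Activity is sampled in 0.1 s bins from −10 s to +20 s around the event
(301 bins).  Each bin receives the mean of every TR volume whose acquisition
interval overlaps it; bins with no recorded overlapping volume are absent
(NaN).  Conventions the overlap rule leaves open are fixed as: bin with
center c covers [c − 0.05, c + 0.05); volume i covers [t₀ + i·TR,
t₀ + (i+1)·TR); overlap = non-empty intersection.  A vectorized cumulative-sum
implementation is verified against a brute-force interval-scan oracle on
random fixtures.

Go trials have no stop signal, so a pseudo-event anchors them: go onset plus
the SSD of the most recent preceding stop trial (initial SSD if none).

Centering subtracts the per-bin mean across all of a subject's trial courses
(conditions pooled) from each course; a flag pools across subjects instead.
Window statistics (median/peak/trough) are taken over bins whose centers lie
in the closed window — defaults (4, 10) s and (1, 5) s — on raw binned
activity with no HRF adjustment.  Window endpoints are parameters because the
source material uses both "4–10 s" and "5–10 s" for the late window; the
tabled 4–10 s is the default.

## Mixed models

Three families are fitted per ROI: all stop trials at 4–10 s (with the
failed-stop indicator as a fixed effect), failed stops only at 4–10 s, and
failed stops only at 1–5 s (the indicator is constant there and is omitted).
Predictors (trial number, ΔP(Stop), ΔRT) are z-scored over retained trials.
Every modeled learning signal gets a subject-level random slope; dropping a
signal for model comparison removes both the fixed effect and its slope.

Estimation is statsmodels `MixedLM`.  Random slopes use a diagonal
(uncorrelated) covariance by default, matching reports that present separate
per-term SDs; `full_cov=True` fits the unstructured covariance.  The wave
random intercept is crossed with subjects in the ideal specification; since
`MixedLM` supports a single grouping factor it is fitted as a
wave-within-subject variance component.  With two waves the crossed term is
weakly identified either way; on shared fixtures the fit agrees with lme4's
crossed fit to ~1e-3 in log-likelihood (see the oracle test).  ML estimation
is the default and is required for likelihood-ratio comparison; REML is
available for variance reporting and is refused by `lrt_compare`.

Fit indices: AIC = −2ℓ + 2k and BIC = −2ℓ + k·log n with k counting fixed
effects, covariance parameters and the residual variance.  Confidence
intervals are Wald.  R² follows the Nakagawa decomposition with Johnson's
random-slope extension: the random-effect variance is the mean over
observations of zᵀΣz.  A converged fit with a variance component below 1e−8
of total variance is flagged singular rather than rejected.  Boundary
variance components occasionally stall one optimizer; the fit walks through
statsmodels' default chain and three fallbacks before raising.

## Parameter recovery

The recovery experiment validates the estimation machinery at the design
scale (200 subjects × 2 waves): behavior is simulated, learning signals
computed and standardized, and the response generated from the model's own
linear predictor with declared coefficients (defaults +1.5 for ΔP(Stop),
−0.05 for ΔRT — the spec'd recovery values), subject/wave random effects and
unit residual noise; refitting must recover the signs and cover the
generative values with ≈95% of Wald intervals.  Generating the response
through the BOLD convolution path instead would scale the true coefficient by
an HRF-and-window factor with no closed form, making coverage untestable;
that path is validated separately by sign recovery and the ROI dissociation.

## Problem sizes

Test and validation runs use cohorts of 8–200 subjects, 50 recovery
replicates, 1,000 binning-oracle fixtures and 1,000 null simulations for LRT
calibration — sizes at which every Monte-Carlo check has comfortable margins
while the full suite completes in minutes on one CPU.

## Known limitations

* The wave random intercept is nested-in-subject, not crossed (above).
* Wald intervals can undercover for variance-boundary fits; profile
  likelihood is not implemented.
* The running-proportion P(Stop) estimator is the only learning model
  offered (no delta-rule/learning-rate variants), by design.
* SSRT is a constant in the race model; no SSRT estimation from data is
  provided.
* The NIfTI path assumes volumes and masks are already on a common grid; no
  registration or resampling is attempted.
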
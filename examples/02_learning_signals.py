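"""Compute the trial-level learning signals for one simulated run.

P(Stop) is estimated as the running proportion of prior stop trials; its
per-trial update shrinks as 1/k.  The RT-change signal is the post-minus-pre
go RT around each stop trial (positive = slowing).  The linear RPE combines
the two with weights beta1 > 0 and beta2 < 0, so it is positive after correct
stops and negative after failed stops.
"""

import numpy as np
import pandas as pd

from sstlearn import (RPEModelParams, RunConfig, apply_burn_in,
                      compute_signals, simulate_run)

run = simulate_run("sub-001", 1, RunConfig(), seed=3)
signals = compute_signals(run, RPEModelParams(), rng=np.random.default_rng(0))

stops = signals[signals.trial_type == "stop"]
print(stops[["trial", "outcome", "pstop_est", "delta_pstop", "delta_rt",
             "rpe"]].round(4).to_string(index=False))

# one run has only ~19 stop trials; the valence pattern is an expectation,
# so average over a small cohort to make it visible
frames = [compute_signals(simulate_run(f"s{i}", 1, RunConfig(), seed=i),
                          rng=np.random.default_rng(i)) for i in range(40)]
cohort = pd.concat(frames)
post = apply_burn_in(cohort[cohort.trial_type == "stop"], 25)
means = post.groupby("stop_failure")["rpe"].mean()
print(f"\nmean RPE after correct stops (40 runs, post burn-in): {means[0.0]:+.4f}")
print(f"mean RPE after failed stops  (40 runs, post burn-in): {means[1.0]:+.4f}")
# Opposite signs of roughly equal magnitude: the staircase holds the task at
# 50% accuracy, so both outcomes are equally informative.
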
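"""Simulate stop-signal-task behavior and inspect the staircase calibration.

The one-up/one-down stop-signal-delay staircase should drive stop accuracy
toward 50% regardless of a subject's go-RT distribution.
"""

import numpy as np

from sstlearn import RunConfig, run_to_events, simulate_run

cfg = RunConfig()  # 128 trials, 15% stop rate, 0.05 s staircase step
runs = [simulate_run(f"sub-{i:03d}", 1, cfg, seed=i) for i in range(50)]

acc = np.array([r.stop_accuracy for r in runs])
print(f"simulated {len(runs)} runs of {cfg.n_trials} trials")
print(f"mean stop accuracy: {acc.mean():.3f} (staircase target: 0.500)")
print(f"range across runs:  [{acc.min():.2f}, {acc.max():.2f}]")

events = run_to_events(runs[0])
print("\nfirst five events of run 1:")
print(events.head().to_string(index=False))
# Stop accuracy near 0.5 means the race between going and stopping was held
# at threshold, which is what makes failed and correct stops equally
# informative learning events.
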
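"""Parameter-recovery check for the mixed-model machinery.

Behavior is simulated, learning signals computed, and the response generated
from the model's own linear predictor with known standardized coefficients
(+1.5 for dP(Stop), -0.05 for dRT).  Refitting should recover the signs and
cover the generative values with ~95% of Wald intervals.
"""

from sstlearn import recovery_experiment

out = recovery_experiment(n_subjects=60, waves=(1, 2), n_replicates=10, seed=9)

print(f"replicates: {out['n_replicates']}")
for name in ("dpstop", "drt"):
    print(f"{name:8s} generative {out['betas'][name]:+.2f}  "
          f"mean estimate {out['mean_estimates'][name]:+.3f}  "
          f"CI coverage {out['coverage'][name]:.0%}  "
          f"sign agreement {out['sign_agreement'][name]:.0%}")
# Coverage near 95% and perfect sign agreement indicate the estimation and
# interval machinery are calibrated at this design size.
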
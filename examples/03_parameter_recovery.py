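"""Parameter recovery: simulate from known parameters, refit, and compare.

Draws per-target discount rates and inverse temperatures for 12 synthetic
participants, simulates their 150-trial sessions, refits by maximum
likelihood, and reports the true-vs-recovered correlation, bias, and RMSE
per parameter plus the per-participant predicted-vs-observed choice
correlation.
"""

import numpy as np

import prosocial_effort as pe

spec = pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity"))

def sampler(rng):
    return pe.ParamVector(
        k={t: float(rng.uniform(0.6, 1.3)) for t in spec.targets},
        beta={t: float(rng.uniform(2.0, 10.0)) for t in spec.targets},
    )

report = pe.parameter_recovery(spec, sampler, n_participants=12, seed=4, n_starts=8)
print(report.summary().round(3).to_string(index=False))
print(f"\nmean predicted-vs-observed choice correlation: "
      f"{np.nanmean(report.predictive_r):.3f}")
print("\nHigh recovery r for k means the fitting procedure can identify how "
      "steeply each participant discounts rewards by effort; the predictive "
      "correlation checks that fitted choice probabilities track behavior.")
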
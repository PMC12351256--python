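"""Fit parametric marginals to one column and sample from the best fit.

Generates a right-skewed intake-like variable, compares candidate families by
AIC, and draws a reproducible synthetic sample from the winner.
"""

import numpy as np

from ranksynth import best_fit, fit_marginal, sample_marginal

rng = np.random.default_rng(0)
dmi = rng.gamma(16.0, 0.55, size=263)  # dry matter intake, kg/d

for family in ("normal", "gamma", "lognormal", "weibull"):
    m = fit_marginal(dmi, family, column="DMI")
    print(f"{family:>10}: params={tuple(round(p, 3) for p in m.params)} "
          f"AIC={m.aic:.1f}")

chosen = best_fit(dmi, ["normal", "gamma", "lognormal", "weibull"],
                  column="DMI")
print(f"\nAIC-selected family: {chosen.family}")

sample = sample_marginal(chosen, n=5000, seed=1)
print(f"5,000 draws from the fit: mean {sample.mean():.2f} kg/d "
      f"(data mean {dmi.mean():.2f}) -- the synthetic marginal reproduces "
      "the location of the observed intakes.")
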
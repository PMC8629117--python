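"""Three-parameter growing degree-day model.

Fits (start day t0, base temperature Tb, requirement F*) by a seeded
global search on data generated from the accumulation model itself, then
bootstraps percentile CIs and predicts with the CI-corner envelope.
"""

import numpy as np

import phenocue as pc

climate = pc.simulate_climate(pc.ClimateGenSpec(seed=3))
pheno, truth = pc.simulate_phenology(
    climate, pc.PhenoGenSpec(mechanism="gdd", noise_sd=1.0, seed=4),
    years=np.arange(1961, 2011),
)
print(f"truth: t0={truth.gdd_params.start_day}, "
      f"Tb={truth.gdd_params.base_temp} °C, F*={truth.gdd_params.requirement}")

fit = pc.fit_gdd(pheno, climate, seed=7)
print(f"fit:   t0={fit.params.start_day}, Tb={fit.params.base_temp:.2f} °C, "
      f"F*={fit.params.requirement:.1f} (SSQ {fit.objective:.0f})")

pc.bootstrap_gdd(fit, pheno, climate, reps=100, seed=8)
print(f"95% CIs: Tb [{fit.ci_low.base_temp:.2f}, {fit.ci_high.base_temp:.2f}], "
      f"F* [{fit.ci_low.requirement:.0f}, {fit.ci_high.requirement:.0f}]")

for p in pc.predict_gdd(fit, [1995, 2005], climate, observed=pheno):
    print(f"  {p.year}: predicted day {p.predicted:.0f} "
          f"[{p.pi_low:.0f}, {p.pi_high:.0f}], observed {p.observed}")
# Tb and F* trade off along a ridge (a lower threshold with a larger
# requirement predicts similar dates), which is why the bootstrap CIs —
# and hence the CI-corner prediction intervals — are wide.
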
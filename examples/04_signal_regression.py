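"""Penalized B-spline signal regression (PSR).

Regresses the event date on the whole 365-day temperature history at
once; the coefficient function is a cubic B-spline with a first-order
difference penalty, λ chosen by GCV.  Days whose partial coefficient
exceeds twice its SE are flagged as important.
"""

import numpy as np

import phenocue as pc
from phenocue import psr

climate, pheno, truth = pc.default_scenario(seed=0)
train = pheno.subset(1961, 2010)
matrix = pc.build_climate_matrix(climate, train.years)

model = pc.fit_psr(train, matrix, knots=20)
win = psr.important_window(model)
peak = model.lags[np.argmax(np.abs(model.beta))]
print(f"adj R² {model.r2_adj:.2f}, λ = {model.lam:g}, edf {model.edf:.1f}")
print(f"important days: lags {win[0]}..{win[1]}; peak |coefficient| at lag {peak}")
print(f"total effect of +1 °C everywhere: {model.beta.sum():+.2f} days")

preds = pc.predict_psr(model, pc.build_climate_matrix(climate, [2011, 2012]),
                       observed=pheno)
for p in preds:
    print(f"  {p.year}: predicted {p.predicted:.1f} "
          f"[{p.pi_low:.1f}, {p.pi_high:.1f}], observed {p.observed}")
# beta is in days per °C per day: summed over the planted window it
# should approach the planted slope of -6 days/°C.
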
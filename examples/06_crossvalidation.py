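"""Cross-validated predictive evaluation of all methods.

Eleven 5-year folds over 1961-2015: each fold's cue is re-identified
from the other 50 years, the held-out years are predicted, and accuracy
(MAE), precision (PI width), calibration (coverage) and the
error-vs-year trend are reported.
"""

import phenocue as pc
from phenocue import evaluation as ev

climate, pheno, _ = pc.default_scenario(seed=0)
plan = ev.make_training_sets((1961, 2015), mode="kfold")
report = ev.run_experiment(
    pheno, climate,
    ["swa", "csp", "psr", ev.GDDMethod(bootstrap_reps=20)],
    plan, seed=42,
)
print(report.summary().round(2).to_string(index=False))
slope, r2 = report.error_trend()
print(f"error-vs-year trend: {slope:+.3f} days/year, R² {r2:.2f}")
# MAE is in days (lower = more accurate); pi_width is the mean 95%
# interval width (lower = more precise); coverage is the fraction of
# observed dates inside their interval (0.95 = well calibrated).  On
# this stationary planted-cue system the error trend R² stays small;
# on real data a large R² signals a drifting cue-phenology relationship.
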
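# Methods

`phenocue` implements five statistical routes from daily mean
temperature to the timing of an annual phenological event (here written
as a mean event date in days since 1 April), plus a cross-validated
framework for judging how well each identified cue predicts. This note
records the models, the defaults and why, the numerical choices, and
what the synthetic test bed does and does not establish.

## Data model

The response is one mean event date per year, rounded to whole days.
When individual (per-nest) records are supplied, records more than 30
days after the year's first record are excluded before averaging —
strictly more than, so a record exactly 30 days after the first is kept
— to avoid second or replacement breeding attempts contaminating the
annual mean.

All calendar-anchored methods share one design object: a years × lags
matrix in which entry (y, d) is the mean temperature on the day `d` days
before the reference day (default 20 May) of year y. Lags walk back
through real calendar dates, so a 365-lag history crosses 29 February
when present; no day is skipped or duplicated. Whether lag 0 (the
reference day itself) is included is configurable: window searches use
lags 0..364 by default, while the day-by-day sensitivity profile starts
at lag 1 (the day before the reference), matching how that method is
usually described.

## Sliding-window searches (SWA, SWR)

Every window `(open, close)` with `open ≥ close` and duration up to 365
days is scored with each of four aggregates of the daily means within
it: mean, minimum, maximum, and the within-window warming slope (OLS
gradient of temperature on day index, oldest day first; undefined and
therefore excluded for 1-day windows). The aggregate is regressed
against the event dates and candidates are ranked by AICc, with an
intercept-only model as the baseline. AICc uses the Gaussian ML
log-likelihood with k counting coefficients plus the residual variance
(baseline k=2, slope model k=3); this k-convention places n=3 exactly on
the small-sample correction's pole for the baseline, so a 3-year series
is not scorable. Ties within 1e-8 of AICc resolve toward shorter
duration, then the more recent window, then statistic name — parsimony
and biological proximity to the event.

The absolute search anchors windows to the reference day; the relative
search anchors them to each year's own event date (lag 1 = the day
before the event). Relative cues are refused at prediction time: the
window cannot be located until the event has happened.

The search is fully vectorized (window sums by cumulative sums,
min/max by running accumulation, OLS across all candidates at once),
which reorders floating-point summation relative to a naive loop;
agreement with a brute-force double loop is tested at 1e-8 on AICc
rather than bitwise.

## Climate sensitivity profile (CSP)

Event dates are regressed on each single lag day's temperature; the
per-lag slope and R² profiles are each smoothed by a penalized cubic
B-spline (50 basis functions, second-order difference penalty,
smoothing parameter by GCV). A lag day is "sensitive" when its smoothed
coefficient is at or beyond the 2.5% empirical quantile of the smoothed
coefficient profile (lower tail when the dominant effect is negative,
upper otherwise — the tail is chosen by the sign of the largest-|coef|
value, since the profile median sits at ~0 whenever most lags are
insensitive) *and* its smoothed R² is at or above the 97.5% quantile of
the smoothed R² profile. Quantiles are type-7 empirical quantiles over
all lags. The critical window is the longest run of consecutive
sensitive days (ties toward the run nearer the reference day); a mean-
temperature cue over that window is then fitted as an ordinary linear
model. Flat profiles raise an explicit empty-window error rather than
passing every lag.

A structural consequence worth knowing: the 2.5%/97.5% rule admits only
about 9 of 365 lags, so the extracted window is a narrow slice sitting
at the profile peak. When the true sensitive period is a wide plateau,
the slice falls *inside* the true window but its midpoint wanders along
the plateau, and the narrow cue explains less variance than a full-
window mean. This is inherent to the extraction rule, not a fitting
artefact, and it is why the profile method's R² trails the window
search's on the same data.

## Penalized signal regression (PSR)

The event date is regressed on the entire 365-day history at once:
y = α + Σ_d β(d)·x(d) + ε, with β expanded in a cubic B-spline basis
(default 20 basis functions; the count may not exceed the sample size
minus two) and a first-order difference penalty on the basis
coefficients. λ is chosen by GCV on a 41-point log grid from 1e-4 to
1e6. Pointwise standard errors come from the penalized least-squares
covariance σ̂²·M⁻¹(Z'Z)M⁻¹ (M the penalized, Z'Z the raw Gram matrix),
with σ̂² = RSS/(n − edf) and edf the hat-matrix trace. Days with
|β| > 2·SE are flagged important. Predictions carry the interval
ŷ ± t_{n−edf}·sqrt(se_fit² + σ̂²). The temperature matrix enters in raw
°C with only a free intercept — no per-column centering.

## Growing degree-day model (GDD)

From start day t0, each day's excess of the daily mean over the base
temperature Tb accumulates; the event is predicted on the first day the
sum reaches F*. Parameters live in the box t0 ∈ [1, 200] (day of
year), Tb ∈ [1, 10] °C, F* ∈ [50, 1000] °C·days. Years never reaching
F* predict 31 December — a large but finite error that keeps the
objective defined on the whole box.

Two objectives are available: `direct` (default) minimizes
Σ(predicted − observed)²; `regression` minimizes the residual sum of
squares of a linear model of predicted on observed dates, the literal
reading of how the calibration is sometimes described. The regression
form forgives scale/offset bias in the predictor, so `direct` is the
default for predictive work; both are exposed.

Because predictions are whole days, the objective is piecewise constant
with a strong Tb–F* trade-off ridge, and derivative-based refinement
sees zero gradient everywhere. The optimizer therefore layers three
stages, all seeded and deterministic: a coarse grid scan of the box
keeping several well-separated low-objective starts; a shrinking-step
pattern search from each start whose move set includes the Tb/F* and
t0/F* trade-off diagonals; and a `dual_annealing` run (simulated-
annealing class, no local search phase) seeded at the best polished
point, itself re-polished if it improves. Bootstrap confidence
intervals resample years with replacement, refit each replicate with a
slightly lighter budget (too coarse a replicate budget visibly biases
the percentile CIs away from the thorough point fit), and take 2.5/97.5
percentiles per parameter. Prediction intervals evaluate all 2³ corner
combinations of the per-parameter CI bounds and take the min/max
envelope, a conservative superset of pairing lower bounds together and
upper bounds together. The parameter ridge is also why these intervals
are far wider than the regression-based methods'.

## Predictive evaluation

Three split designs: `near_future` (training spans shrunk in 10-year
increments from either end of the full range, each predicting the 5
years after its end), `fixed_test` (the same spans all predicting the
terminal 5-year block), and `kfold` (the full range partitioned into
5-year folds, each predicted from the complementary years — eleven
folds for a 55-year series; the operative description of the original
cross-validation, though it is sometimes labelled "5-fold"). Within
every split the cue is re-identified from scratch on the training years
only. Metrics: MAE, mean signed error (predicted − observed), mean 95%
prediction-interval width, closed-interval coverage, and the OLS trend
(slope and multiple R²) of per-(method, fold) mean signed error against
fold mid-year. Metrics are computed on real-valued predictions; no
rounding. The trend can be pooled over all methods or restricted to
the regression-based subset (SWA, CSP, PSR).

## Synthetic test bed

The climate generator produces daily means as
annual mean + warming·(year − year₀) + amplitude·cos(2π(doy − phase)/365.25) + AR(1) noise,
with the AR(1) noise parameterized by its stationary SD so the noise
scale does not change meaning with the autocorrelation. Defaults — 55
years, annual mean 9.5 °C, amplitude 6.5 °C peaking at day-of-year 200,
warming 0.03 °C/yr, ρ = 0.7, SD 2.5 °C — emulate a temperate-maritime
station series.

Phenology is generated from one of three planted mechanisms: a
fixed-window cue (default: mean over lags 81..14 before 20 May,
intercept 74 days, slope −6 days/°C, echoing the headline cue of the
study system this package is built around, on the days-since-1-April
scale), a distributed coefficient function over all lags, or degree-day
accumulation (default t0=60, Tb=4 °C, F*=200 °C·days). Gaussian noise
(default SD 2 days) is added and dates are rounded to whole days, as
real annual means are. The rounding matters: it caps attainable R² at
≈0.997 even with zero mechanism noise. For the relative-frame
mechanism the event day must solve a self-consistency equation (the
window moves with the event); it is resolved by scanning the whole-day
lattice for the most self-consistent day, which leaves ≈1 day of
intrinsic discretization noise.

All generators are pure functions of (spec, seed). What passing
recovery tests show: each method, run under its own assumptions,
recovers planted structure at realistic noise. What they do not show:
robustness to missing data, non-Gaussian noise, observation effort
changing over time, or cue–phenology relationships drifting through
time — the last being precisely the diagnostic the error-trend metric
is for on real data.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the study's
native scale (50–55 years, 365 lags) but scale down replication counts
where the full-fidelity figure is pure repetition: GDD bootstrap
replicates default to 1,000 for a standalone fit but the K-fold
experiments and acceptance script use 20–200, and annealing iteration
budgets are set to the point where the three-stage optimizer's result
stops improving on the synthetic scenarios. Every stochastic stage
(generators, annealing, bootstrap) is seeded explicitly; identical
configuration and seed reproduce outputs byte-for-byte.

## Known limitations

* Absolute-frame methods identify proxies, not biological cues; the
  relative search can identify seasonal-transition artefacts and is
  excluded from prediction by construction.
* The CSP quantile rule returns a narrow peak slice, not the full
  sensitive period (see above).
* GDD parameters are weakly identified along the Tb–F* ridge; point
  estimates should be read jointly with their bootstrap CIs.
* Degree-day accumulation starts within the event year (t0 ≤ 200);
  autumn-start (cross-year) accumulation is out of scope.
* The PSR interval uses the penalized covariance without accounting for
  λ selection, which is one reason signal-regression intervals can
  undercover on real data.
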
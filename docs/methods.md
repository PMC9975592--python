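# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `cndc`, in the order the pipeline runs.

## Photothermal accumulation

The cumulative photothermal effect LTF is a daily sum of
`fT(j) · fI(j)`. The temperature factor is evaluated on *hourly*
temperatures and averaged over the calendar day: hourly evaluation
preserves the diurnal asymmetry of the piecewise-linear response (a day
averaging 24 °C but swinging 17–31 °C does not earn a full thermal
day), while the daily product is what the accumulation requires.
Cardinal temperatures default to Tb = 7, T0 = 24, Tm = 35 °C.

The light factor uses the *daily cumulative* PAR integral, in
mmol m⁻² d⁻¹, with curvature α = 0.001 per mmol. Unit convention
matters here: typical greenhouse daily integrals of 5.3–9.5 mol m⁻²
are 5 300–9 500 mmol, putting `fI = 1 − e^(−αI)` at 0.99+ — light
nearly saturates and temperature dominates day-to-day variation. Read
in mol the same factor would be ≈0.005 and LTF would be meaninglessly
small; the mmol reading is the only one under which the published
growth-rate magnitudes (b ≈ 0.07–0.12 per unit LTF over a 42–45 day
cycle reaching LTF ≈ 20–30) are attainable. Weather readers therefore
take PAR in mol per hour and the conversion is internal.

Day handling: calendar-day grouping in the file's local time; interior
days with missing hours are an error (silently interpolating weather
would bias LTF), while partial first/last days are dropped.

## Growth models

All three responses (FW, DW g/plant; N uptake mg/plant) follow
`Y = a·e^(b·LTF)`. Fitting is nonlinear least squares on the natural
scale (Levenberg–Marquardt, `xtol` 1e−10, deterministic), initialised
at the closed-form log-linear OLS solution; the log-scale estimates are
retained on the results object for comparison because which scale the
original fits used is not stated. Natural scale was chosen as the
default since the reported F statistics are of the magnitude produced
by natural-scale ANOVA. The F statistic uses 1 model degree of freedom
(the rate; the intercept plays the role of the regression constant) and
n − 2 residual df. Adjusted R² is computed on the natural scale.

The rate parameter's response to N application rate F is an OLS
quadratic `b(F) = c0 + c1·F + c2·F²`; its vertex `(−c1/2c2,
c0 − c1²/4c2)` is the optimal rate and maximal rate parameter. For the
published FW coefficients the vertex sits at F* ≈ 0.23 g N/kg, slightly
outside the tested 0–0.2 range, so `optimal_n_rate` reports the
unconstrained vertex by default and accepts an interval for the
constrained maximum; the published maxima (0.121, 0.099, 0.112) are the
unconstrained vertex values to three decimals.

## Dilution envelope

Parameters: Nmax = 6.83 % of DW (mean of the four day-11 treatment
means), plateau fractions 0.7 (critical) and 0.4 (minimum), exponent
b = 0.33, breakpoint 1.5 t/ha. Plateau fractions and the exponent are
parameters, not constants, so the envelope generalises to other crops.

The published critical curve reuses the plateau value (4.78) as the
power-law coefficient, which makes Nc jump from 4.78 to
4.78·1.5^−0.33 ≈ 4.18 at the breakpoint. The coefficient recipe
`a_c = 0.7·Nmax·1.5^b ≈ 5.47` instead joins the branches continuously.
Both are implemented behind `DilutionParams.mode`; the default is
`as_printed` because it is the headline form of the curve, and the two
modes differ above the breakpoint by exactly the factor `1.5^b`
(asserted in the tests). The breakpoint itself belongs to the plateau.
The fresh-weight-domain breakpoint is always derived as
`fw_dw_ratio × dw_break` (38.46 t/ha at the defaults) rather than
hard-coded, because printed restatements of it disagree with each
other (38.64 vs 38.4).

NNI classification: the standard dilution-curve convention is used
(NNI < 1 deficient, > 1 excess). A configurable tolerance (default
0.05) defines the optimal band, since exact equality with 1 is
untestable in floating point. The curve-fitting operation excludes
plateau points (dw ≤ breakpoint) before the log-log OLS: plateau
observations carry no information about the power law and would bias
the exponent toward zero.

## Demand and supply

`N_demand = k · FW · (Nc − Na)/100` with crop coefficient k = 0.39
treated as an opaque calibrated constant. The /100 makes the percentage
difference a mass fraction; this is the only unit reading under which
a 30 g plant one percentage point below critical needs ~117 mg N,
the scale of reported per-plant demands. A negative gap (luxury
uptake) is reported as zero demand plus a separate `surplus` quantity
— a fertiliser recommendation cannot be negative. Supply divides
demand by the apparent N use efficiency, keyed by cultivation system
(substrate 0.38, soil 0.17) with override.

Planting density is a required, explicit parameter for any conversion
between g/plant and the t/ha axis of the dilution curve; no silent
default is applied in the library (the CLI pipeline falls back to
577 000 plants/ha with a printed notice — the density that maps a
mature ≈2.6 g/plant crop onto the 1.5 t/ha breakpoint).

## Synthetic trials

The generator emulates the structure of the three source experiments:

* **Weather regimes.** `exp13` (mean 19 °C, diurnal half-range 5 °C,
  daily PAR 5.3 ± 1.5 mol m⁻², 11 h daylight) and `exp2` (26.3 °C,
  half-range 6 °C, 9.5 ± 2.5 mol m⁻², 10 h daylight). Temperature is a
  sinusoid (minimum ~03:00, maximum ~15:00) plus AR(1) noise (sd
  0.5 °C, autocorrelation 0.7); daily PAR totals are truncated-normal
  draws spread as a half-sine over the daylight window. The PAR sds
  are ≈1/6 of the reported maximum day-to-day variation; the daylight
  lengths match the Shanghai autumn/winter seasons of the experiments.
* **Trial designs.** Soil-style (rates 0–0.2 g N/kg, 45 days, sampling
  days 11/18/31/38/45, 9 plants) and substrate-style (42 days, weekly
  sampling, 12 plants).
* **Trajectories.** Rates `b` come from the published b(F) quadratics;
  the FW intercept is the published 0.2816 g/plant; the DW intercept
  follows from the FW/DW ratio 25.64 and the N-uptake intercept from
  the Nmax plateau young plants sit on (both derived, flagged as
  assumptions — per-treatment intercepts are not published). %N is the
  uptake/DW ratio clipped into the [Nmin, Nmax] envelope, after which
  uptake is re-derived so the three responses stay internally
  consistent.
* **Noise.** Multiplicative lognormal, mean one, CV 0.08 per sampled
  plant and response — destructive sampling measures distinct
  individuals, and biomass errors scale with size. Noiseless
  trajectories are independent of the noise seed.

What the generator does *not* emulate: treatment-by-time interaction
beyond the b(F) quadratics, within-day N dynamics, pot-level
covariance, or the real experiments' measured values (undeposited).
Passing recovery tests therefore demonstrate that the estimators are
consistent with the package's own forward model under realistic noise,
not that the published field numbers are reproduced.

A consequence of the envelope clip worth knowing: at high N rates the
uptake exponent exceeds the DW exponent, %N would rise above Nmax, and
the clip bends the uptake trajectory to track `b_dw` instead. The
recovery study therefore scores estimates against the *observable*
truth — a refit of the noiseless trajectory — which equals the
injected b(F) for FW/DW and the clip-adjusted rate for uptake.

## Validation statistics

`agreement` reports Pearson r, r², RMSE, the relative standard error of
prediction — the residual standard error of the OLS regression of
simulated on measured, as a percentage of the measured mean (the
reading of "SE of regression estimate / measured value" that yields
double-digit percentages on growth data) — and the regression slope.
r² is the squared Pearson correlation of the 1:1 pairs, not a
through-origin regression. The regression direction (simulated on
measured) is fixed, so RE and slope are direction-asymmetric while r
and RMSE are not. A slope t test is available through the underlying
statsmodels results as the interpretation of significance testing on
the 1:1 regression.

The Monte-Carlo recovery study defaults to 200 replicates at CV 0.08
with the weather fixed across replicates, so bias isolates estimator
properties from environmental variation. These sizes run in seconds;
they were chosen so the bias standard error (≈0.007 on the dilution
exponent) is well below the ±0.02 band the recovery property asserts.

## Known limitations

* Single-crop parameterisation; no per-organ N partitioning.
* No radiation-interception/canopy model, humidity or CO₂ effects.
* No soil N mineralisation or leaching; supply is a static budget.
* The machine-learning N-demand predictor built on phenotype imagery
  in the source work is out of scope (its inputs are unavailable); the
  demand interface accepts any externally predicted Na.
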
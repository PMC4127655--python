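# Methods

## The growth model and why exposure time matters

`drgrowth` analyses drug dose-response experiments on proliferating cell
lines.  The metabolising cell count under a one-compartment growth/kill model
is

    N(t, c) = N0 · 2^(t/T0 − t/Tc†) = N0 · 2^(t/Tc),    1/Tc = 1/T0 − 1/Tc†,

where `T0` is the untreated doubling time (hours), `Tc†` the
concentration-dependent kill (or arrest) halving time, and `Tc` the net
doubling-or-halving time.  Three dose-response models summarise an experiment
read at exposure time `t`:

* **G** (growth-rate based): `G = T0/Tc` while the count grows, `1/Tc` on the
  decay branch.  `G` does not involve `t`.
* **D** (net difference, the NCI60 convention):
  `(N(t,c) − N0)/(N(t,0) − N0)` while growing, `(N(t,c) − N0)/N0` otherwise.
* **R** (relative count): `N(t,c)/N(t,0) = 2^(−t/Tc†)`.

D and R drift with exposure time at a rate set by the line's growth rate, so
fast-growing lines look overly sensitive under the conventional summaries.
The G-model summaries — GI50 (`G = 1/2`), TGI (`G = 0`), LC48
(`G = −1/48 h⁻¹`) and AUC0 (area of `100·G` above zero, in percent ×
log10-concentration units) — are free of that bias.  Exact transformations
recover `G` from `D` or `R` observed at a known time given `T0`; they are
what `drgrowth.legacy` applies to historical screens.

The decay-branch condition `N(t,c) ≥ N0` is equivalent to
`t/T0 ≥ −log2 R`; ties are assigned to the growth branch, where the two
branches agree.  The D→G transform requires `D > −1`; values at `−1`
correspond to complete kill and are not representable.

## Kill-rate parameterisation

The simulator models `1/Tc†(c)` as a five-parameter logistic in log10
concentration:

    kill(c) = b − (b − d) / (1 + exp(a·(c − e)))^f

with steepness `a` (per log10 unit), maximal kill `b` (h⁻¹), baseline
`d` (h⁻¹), midpoint `e` (log10 concentration) and asymmetry `f`.  Its
inverse has the closed form `c = e + ln(((b−d)/(b−r))^{1/f} − 1)/a` for any
`f > 0`, which is used both to calibrate `e` so that a named statistic falls
at a requested concentration and to compute the analytic GI50/TGI/LC48 of a
model (`nan` when the required kill rate is outside `(d, b)`, i.e. the
statistic is censored).

The nine reference cell-line models use `a = 2`, `b = 1/5 h⁻¹`, `d = 0`,
`f = 1`, doubling times {60, 30, 15, 15, 30, 60, 15, 60, 30} h and GI50
values on the even grid `−8.40 + 0.225·j` (`j = 0..8`); these choices
reproduce the reference TGI/LC48 table to two decimals for every line.

## Plate model and pre-processing

A well absorbance is modelled as

    Y_ktil = δ_kt · α_ti + β_kt + ε_ktil,
    ε ~ N(0, |δ_kt·α_ti + β_kt|^{2ξ} · σ²),

with per-plate multiplicative effect `δ_kt`, additive background `β_kt`
(pinned by the medium-only background wells), summarised absorbance `α_ti`
per (time, concentration), and a power-of-the-mean technical variance
(`ξ ≈ 1.4` in MTS data).  Fitting is iteratively reweighted least squares:
a damped Gauss–Newton solve of the bilinear mean (weights `|mean|^{−2ξ}`)
alternating with a profile-maximum-likelihood update of `(ξ, σ)`.
Convergence: relative parameter change `< 1e−8`, at most 50 outer rounds;
the mean solve stops when the weighted residual sum of squares no longer
improves relatively by `1e−13`.  Fitted means are clipped at `1e−6` inside
the weights and the variance likelihood.  When the mean residual square is
below `1e−22` the data are treated as noise-free: `ξ = 0` and `σ` is the
root mean square residual, and outlier detection is skipped.

**Identifiability.**  `δ·α` is only identified up to a scale per exposure
time.  The default constraint sets the geometric mean of `δ_kt` over the
replicates of each time to 1 (`delta_constraint="geomean"`; `"first"` pins
the first replicate's plate instead).  The geometric-mean choice averages
the plate-scale noise over replicates, and it is the choice whose implied
estimator dispersion matches the reference simulation study; all downstream
ratios are unaffected in the noise-free case.

**Outliers** are wells whose residual exceeds 3 fitted standard deviations
(`|mean|^ξ·σ`); they are removed and the model refitted, twice by default.
Summarised absorbances below 0.025 OD are reported at that floor (negative
estimates are physically meaningless), and entries at the floor are marked
so downstream stages can treat them as left-censored.

**Colour correction.**  Coloured drugs (e.g. doxorubicin) inflate background
absorbance with dose.  Cell-free plates with the same layout are passed
through the same fit; their `α̂` values estimate the drug-colour excess per
concentration and are subtracted from the drugged cell wells (floored at 0)
before any analysis.

## Growth fit

The summarised absorbances at two (or more) times follow
`α_ti = α0 · 2^{t(1/T0 − s_i/Tc†_i)}` with `s_i = 0` for the untreated
control.  Unweighted nonlinear least squares (Levenberg–Marquardt, analytic
Jacobian) estimates `α0` (= γN0, the proportionality factor times the seeded
count), `Ts0 = 1/T0` and `Tsc_i` with `Tc†_i = 1/Tsc_i²` — the squared
transform keeps kill times positive, which also caps every net rate at the
untreated rate.  Starting values come from log2 slopes between the first and
last time.  The unweighted (homoscedastic) second stage is deliberate: the
heteroscedastic raw noise was already absorbed by the pre-processing stage.

Two deliberate censoring rules:

* An `α̂` at the pre-processing floor is a left-censored observation.
  Feeding it to least squares as an exact value drags the shared `α0`/`T0`
  down (the large-dose underestimation visible in two-time-point designs),
  so floored entries are excluded from the joint fit; the affected
  concentration gets the least-steep decay rate consistent with the floor,
  flagged censored.  The GI50/TGI/LC48 crossings always lie in un-floored
  territory, so only the deep-decay tail of the curve is approximate.
* A fitted `1/T0 ≤ 0` raises `DegenerateGrowthError`: without net growth the
  growth-based statistics are undefined (GI50 doubles the doubling time, TGI
  cancels growth).  Simulation-study and bootstrap replicates that hit this
  are excluded and counted.  For slow lines read after only 24 h of net
  growth this is common (~15% of replicates at `T0 = 60` h), and excluding
  them is what reproduces the reference dispersion table.

## Dose-response curves and statistics

G and D have a kink at total growth inhibition, so the monotone fit is
applied to a smooth precursor: the net rates `Γ_i = 1/Tc_i` for G, the
relative net changes `Δ_i = (α_ti − α̂_0)/α̂_0` for D (with `α̂_0` the
untreated control at the earliest time), and the ratios `α_ti/α_t0` for R.
Isotonic regression (pool-adjacent-violators, equal weights, delegated to
`scipy.optimize.isotonic_regression`) enforces a non-increasing curve;
linear interpolation in log10 concentration runs on the precursor scale, so
the mapped curve is exactly the branchwise image of a piecewise-linear
function and is continuous at the TGI crossing.  For D the growth branch is
`Δ/Δ(0)` (the untreated net change), which reproduces the D-model exactly on
exact inputs.

Threshold statistics are the smallest concentration where the curve equals
the threshold, inverted linearly within the bracketing segment; a curve that
never reaches the threshold is censored at the nearest ladder endpoint
(`low`/`high`), never extrapolated.  AUC_q integrates
`max(100·(curve − q), 0)` by the trapezoid rule after inserting the exact
kink and crossing nodes, over log10 concentration.  D-model thresholds are
{0.5, 0, −0.5}; R-model thresholds {0.75, 0.5, 0.25}.

## Parametric bootstrap

Confidence intervals repeat the whole analysis on data drawn from the fitted
plate model: per replicate, regenerate every well, refit **without** outlier
rejection, re-run the growth fit and G-curve, and take the 2.5%/97.5%
percentiles over `J` (default 200) replicate statistics.  Censored replicate
statistics enter the percentiles at their endpoint values and the censoring
fraction is reported.  Replicates that fail (e.g. degenerate growth) are
dropped with a count; more than 20% failures is an error.

By default the plate effects are **resampled**, not conditioned on: `δ*` is
drawn lognormal with log-scale SD estimated from the spread of the fitted
`log δ̂` (per-time means removed; degrees of freedom = plates − times), with
the scale itself redrawn from its χ² sampling distribution in every
replicate to propagate its few-degrees-of-freedom uncertainty, and `β*`
lognormal from the fitted `log β̂`.  This matters: the between-time plate
scale is the dominant variance source of the G statistics, and conditioning
on the observed plate effects (`resample_plate_effects=False`, available
for a technical-noise-only interval) yields intervals that cover the truth
far below nominal under repetitions of the experiment.  With resampling,
nested simulation puts the empirical coverage of the 95% intervals in the
low nineties at the default design (three replicate plate sets).

## The simulator

`simulate_plate_set` generates the reference study: `N0 = 10,000` cells per
well, absorbance proportionality `γ = 0.4/10,000` OD per cell, 18 drug
concentrations in triplicate plus three untreated controls and three
background wells per plate, one plate per exposure time with effective times
{1, 25, 49, 73} h (assay added at 24 h intervals, incubated 2 h, count
referred to the interval midpoint), and `K = 3` replicate plate sets per
experiment (the replicate count is not part of the reference description;
three mirrors standard lab practice and is a config knob).  Noise:
`β ~ lognormal(−0.8, 0.13)`, `δ ~ lognormal(0, 0.38)` (log-scale
parameters), technical error `N(0, |mean|^{2ξ}σ²)` with `ξ = 1.42`,
`σ = 0.074`.

The concentration ladder defaults to 18 equally spaced log10 points on
`[−8.6, −5.6]`: it brackets every reference statistic (−8.40 … −5.90) with
0.2–0.3 decades of margin, and its spacing (0.176) keeps the
piecewise-linear discretisation error of every crossing below the 0.01
precision of the reference table — the property that noise-free analysis
reproduces the reference statistics exactly.  The ladder is a `StudyDesign`
knob; a wider ladder admits more of the wild estimates produced by noisy
short-exposure experiments and correspondingly inflates the dispersion
aggregates.

`run_simulation_study` analyses each exposure time as a separate
two-time-point experiment pairing the 1 h read with that time (the two-plate
lab design), and aggregates bias, SD and MSE of GI50/TGI/LC48 against each
model's analytic truth, with censored estimates entering at their endpoint
values and per-replicate failures excluded and counted.  The packaged
dispersion checks run 300 replicates; the sampling error of an SD at that
size is about ±8%, which sets the meaningful comparison resolution.

## What the simulations do and do not show

The generator reproduces the plate geometry, the lognormal plate effects and
the power-variance technical noise of a real MTS screen, with the drug
effect constant over time.  It does not emulate delayed drug action,
cell-cycle arrest followed by death (a two-compartment process), edge
effects (real designs avoid border wells), pipetting drift along the
dilution series, or drug decay over the incubation — so passing tests
validate the statistical workflow under its own model, not the biology of
any particular drug.  Model adequacy on real data is checked the way the
workflow intends: extra read-out times and residual diagnostics
(`PreprocessedAbsorbance.standardized_residuals`).

## Numerical choices and limitations

* Isotonic fit on rates, not on `G` values, avoids bias at the TGI
  singularity; hand-held legacy tables are isotonised on the transformed `G`
  values directly (the precursor is not available there).
* Curves are never extrapolated beyond the tested ladder; statistics outside
  it are reported censored.  Parametric extrapolation is out of scope.
* The two-time-point design is fragile for slow growers at short exposure:
  `1/T̂0` has standard error comparable to `1/T0` itself and a sizeable
  fraction of experiments is uninformative (degenerate).  Longer exposure or
  more read-out times, not more wells, is the remedy.
* AUC0 is integrated over log10 concentration (dilution series are
  geometric), giving the ≤ `100·(c_I − c_1)` ceiling.
* The technical-variance exponent is estimated jointly from all plates;
  with very few wells `ξ̂` is noisy, and the outlier threshold (3 SD, two
  passes) is then conservative rather than exact.
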
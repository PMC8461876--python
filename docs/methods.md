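# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind each phenoplate module, and what the tests do and do
not establish about real instrument data.

## Plate data model

Wells are addressed `A1`–`H12`, row-major and 0-based internally. Units
are fixed at parse time: minutes for kinetic time axes, hours for growth
curves, μL for volumes, mM for concentrations, dimensionless OD. Reader
exports come in two CSV dialects — a *wide* dialect (8×12 grids, kinetic
reads stacked as blocks preceded by `time,<minutes>` lines) and a tidy
*long* dialect (`well,time,value`). Vendor binaries are out of scope;
users export to CSV. Both dialects round-trip through the serializers,
which the suite checks property-style on random layouts.

## Photometric pipette calibration

Absorbance of the dichromate standard is modelled as linear in dispensed
volume within each working range (low 3–10 μL, mid 10–50 μL, high
50–200 μL; eight levels, triplicate). Each range is associated with its
own stock concentration (2 / 1 / 0.4 mM defaults) through the layout, not
hard-coded, because path length varies with fill volume and an empirical
per-range curve is the only safe calibration. Blank wells, when
designated, are subtracted as a mean offset before fitting; the intercept
absorbs any residual.

Fits are unweighted OLS (`scipy.stats.linregress`): the relationship is
strongly linear and replicate noise approximately homoscedastic within a
range. Replicate groups are keyed by (tip, range, programmed volume);
singleton groups report systematic error only (CV undefined at n = 1,
reported as absent). Compliance lookup uses the nearest defined limit
volume at or below the programmed volume, else the smallest defined;
comparisons are inclusive (an error exactly at the limit passes). Numeric
accuracy limits are configuration input — ISO 8655 publishes them, this
package does not embed them.

Per-tip standard errors propagate the standard curve's slope and
intercept uncertainty in quadrature with the tip-level OLS errors. All
volume estimates in a run share one fitted curve, so their errors are
correlated; ignoring that understates the SE of the tip slope by ~30%
under the default simulation noise and drops the empirical 3-SE coverage
from ~99.5% to ~95%.

Inverse correction `programmed = (desired − b)/a` is clipped to the
calibrated programmed range with a warning rather than extrapolated:
tips biased low by ~40% need programmed volumes beyond the top level to
dispense the top level, and the linear model is unverified out there.

## Sterility statistics

Growth classification is `OD > blank + δ` with δ = 0.1 by default —
saturated LB cultures exceed that by an order of magnitude while reader
noise stays well below it; the threshold is configurable. Effectiveness is
the percentage of wells left sterile; conditions where every well grew
score 0%. Because per-condition well counts are small (8–72), the exact
Clopper–Pearson 95% interval (statsmodels `proportion_confint`,
`method="beta"`) accompanies every estimate. Factorial summaries report
one row per condition and unweighted marginal means per factor level;
no logistic model is fitted — the consumer is a wash-protocol decision,
not inference on factor effects.

## Enzyme kinetics

Initial rates use the *earliest* window of `window_points` (default 5)
consecutive reads whose OLS fit reaches r² ≥ 0.98, not the globally
best-fitting window: early reads approximate v₀ before substrate
depletion bends the trace, and a late flat segment can fit perfectly while
measuring nothing. A window with zero residual *and* zero signal variance
(flat trace) counts as r² = 1 so that zero-rate wells report slope 0
rather than erroring. Depletion assays report activity as |slope| with
the sign retained on the rate object.

Rate conversion is Beer–Lambert: `|dA/dt|/(ε·ℓ)` gives mM/min, times the
reaction volume in mL gives μmol/min (mM·mL = μmol). Defaults:
ε = 6.3 mM⁻¹cm⁻¹ (NADPH at 340 nm), ℓ = 0.56 cm (200 μL fill),
V = 0.2 mL. Specific activity per mg is not computed unless a molecular
weight is supplied; μmol/min is the default output unit.

The MM fit (`scipy.optimize.curve_fit`) is initialised at
V_max⁰ = max observed rate and K_M⁰ = interpolated substrate at half-max,
bounded positive, with asymptotic standard errors from the Jacobian.
Requiring ≥ 4 distinct substrate levels keeps the two-parameter hyperbola
identifiable. The pH optimum band is the contiguous run of levels
(containing the argmax) whose mean activity is within 10% of the maximum —
ties in a flat profile legitimately return the whole range.

## Growth rates and phases

μ(t) is the centred finite difference of ln OD after a centred moving
average of ln OD. Smoothing in log space means a pure exponential (linear
in log space) passes through unchanged and its rate is recovered to
machine precision on interior points. Edges without a full smoothing
window, and points with non-positive OD, are masked rather than padded:
edge padding biases the first and last rate estimates.

The default smoothing window is 5 points (~50 min of a 10-min-sampled
curve). The choice is a noise/resolution trade-off: the log-derivative
amplifies additive OD noise by 1/OD, and under σ = 0.005 OD noise a
3-point window leaves μ(t) outside a ±0.05 h⁻¹ band on >10% of points in
the low-OD third of a typical logistic curve, while a 5-point window keeps
~94–100% of points inside that band (measured over 100 noise
realizations). The cost is phase-boundary localisation of ±2 samples
instead of ±1; both window widths are tested for their respective
guarantees and the window is a parameter.

Exponential-phase detection takes the longest contiguous run where
μ ≥ 70% of the 95th percentile of μ (percentile rather than max for
robustness to single-spike noise; both configurable, minimum 3 points).
The mean growth rate is the trapezoidal time-average of μ over that
window. This rule is a reconstruction — "the exponential phase" is not an
operational definition — and deliberately simple.

## Yields and anaerobicity QC

Yields are end-point differences over glucose consumed:
`(final − initial)/(glucose_initial − glucose_residual)`, mol/mol.
Biomass yield is ΔOD per mM glucose and keeps OD units — no OD→gDW factor
is applied, because any such factor is strain- and instrument-specific.
Negative apparent production (evaporation, measurement noise) floors at 0
with a warning instead of erroring: a batch pipeline should flag, not
halt, on a slightly negative pyruvate delta.

Plate anaerobicity QC computes final/initial OD ratios per well and their
deviation from the plate median; wells with leaking seals show up as
positive deviations (oxygen accelerates growth). Zero initial OD masks
the well. The summary reports plate median and IQR; flagging thresholds
(e.g. 3×MAD) are left to the caller.

## Embeddings and cluster scoring

Features are standardised column-wise to zero mean, unit variance
(population sd); zero-variance columns are dropped with a warning and the
scaling parameters retained for exact inverse transform. PCA
(scikit-learn) retains the smallest k whose cumulative explained variance
reaches the target (default 0.90); component signs follow a deterministic
convention (largest-|loading| element positive) so repeated runs agree.
Scaling is applied before both PCA and t-SNE.

t-SNE runs a sweep over perplexities (default 5 and 10 — both well under
the (n−1)/3 feasibility bound at the default n = 36) and learning rates
(default 200), with `restarts` random-initialisation fits per
configuration from seeds derived from the master seed. "Most robust" is
operationalised as the configuration with the lowest *mean* final KL
divergence; the returned embedding is the lowest-KL restart within it.
Every result records its perplexity, learning rate, KL and seed. Cluster
agreement k-means the embedding (10 restarts, seeded) and reports the
adjusted Rand index plus the contingency table.

## Synthetic generators: what they emulate, what they do not

All generators are pure functions of (parameters, seed) and emit their
ground truth alongside the data; no test re-infers truth from data.

* **Calibration plates** — per-tip linear bias (slopes 0.62–1.38,
  intercepts within ±0.6 μL by default, the degraded-accuracy regime seen
  after enlarging the pipetting air-gap, with systematic errors up to
  ~40%), read through a linear standard curve with Gaussian absorbance
  noise (sd 0.003). One plate row per tip; the 8 levels × 3 replicates
  split across two plates. Not emulated: curve nonlinearity at high
  absorbance, meniscus/path-length effects, evaporation.
* **Contamination outcomes** — i.i.d. Bernoulli per well. Not emulated:
  spatial carry-over correlation between wells sharing a tip.
* **NADPH traces** — linear depletion at the MM rate until NADPH
  exhausts, 6-s reads over 2 min so the initial slope is resolved even at
  saturating substrate, Gaussian read noise. Not emulated: substrate
  depletion curvature within the initial window, enzyme inactivation,
  the background NADPH–oxygen reaction.
* **Growth curves** — piecewise-constant μ over three regimes
  (dissolved-oxygen, oxygen-transfer for the unsealed aerobic condition
  only, anaerobic), integrated and capped at a carrying capacity, plus
  OD noise. Not emulated: lag phase, death phase, smooth regime
  transitions.
* **Strain datasets** — 7-analyte archetype means with a log-linear
  glucose response (multiplicative, keeping yields positive and monotone
  in glucose by construction; the wild type responds strongly, the
  lactate-overproducing deletion mutants barely move) and Gaussian noise
  at 5% of each condition mean; one noiseless bioreactor reference per
  archetype; the D1 and D28 evolution stages share one distribution so
  the correct clustering merges them. The archetype numbers are synthetic
  constants chosen for mixed-acid directionality (WT formate/acetate
  dominant, mutants lactate dominant), not measurements. Not emulated:
  analyte covariance, carbon balance closure, pH dynamics.

Consequently, passing tests demonstrate estimator correctness and
statistical calibration *under these generative assumptions*; they do not
certify performance against curve nonlinearity, correlated noise, or
metabolic effects absent from the generators.

## Problem sizes and seeds

Statistical checks use 200 seeded runs for calibration recovery and for
MM K_M bias, 1000 Bernoulli simulations for effectiveness bias, 100-point
grids for estimator scans, and 20 seeded datasets for the t-SNE
clustering property — sizes at which the measured proportions are stable
to a few tenths of a percent while the whole suite runs in well under a
minute. The default master seed for stochastic pipeline steps is
20210923; every stochastic result records the seed that produced it.

## Known limitations

* Calibration assumes the absorbance–volume relationship is linear over
  each range; a saturating reader or very high stock concentration breaks
  the inversion silently (the extrapolation flag catches only
  out-of-span absorbances).
* The exponential-phase rule can latch onto a transient aerobic regime in
  multi-regime curves; callers comparing anaerobic rates should window
  explicitly.
* t-SNE KL values are comparable only within one perplexity, so the
  cross-perplexity selection is a heuristic (lower perplexity tends to
  lower KL); with the default two-value sweep this is benign, but wide
  sweeps should compare configurations at equal perplexity.
* The CLI holds whole plates in memory; it is not a streaming tool.
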
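# Methods

This note documents the models implemented in `ringrelease`, the defaults
chosen where the underlying study left details open, the numerical behaviour
of the fitting and simulation code, and the limits of what the synthetic
data can establish about real experiments.

## System and scope

The reference system is a matrix-type silicone elastomer vaginal ring
loaded with 24.4 mg (nominal 25 mg) of dapivirine, a poorly water-soluble
weak base (MW 329.4 g/mol, pKa 5.30, log P 5.35).  Two 28-day, 37 °C IVRT
protocols are modelled:

1. **Monophasic co-solvent/water.**  Ring immersed in 200 mL medium for the
   first 24 h, sampled daily thereafter with the whole volume discarded and
   replaced with 100 mL; no weekend sampling, with a 200 mL Friday refill
   carrying the vessel over the 3-day gap.  Media span 0–50% isopropanol,
   over which dapivirine solubility rises ~4 orders of magnitude
   (0.084 → 645 µg/mL).
2. **Biphasic buffer/octanol.**  100 mL aqueous buffer (pH 7 phosphate or
   pH 4.2 acetate) under a 20 mL octanol layer; 1.0 mL sampled from each
   phase daily and replaced with drug-free medium; octanol aliquots diluted
   1:20 for assay.  The octanol layer acts as an absorptive sink standing in
   for tissue/systemic uptake.

Out of scope: chromatographic data processing, swelling/erosion matrix
theory, in vitro–in vivo correlation modelling, and vaginal-fluid
compositional models.

## Reconstruction (mass balance)

Full replacement makes each day's bookkeeping trivial: everything measured
in the vessel was released since the last replacement, so the interval
amount is `C_i·V_i` and the cumulative curve — a running sum of non-negative
terms — is non-decreasing by construction.  Monday samples after a Friday
refill are 3-day intervals; fits always use cumulative values at true times
(t or √t), so the weekend granularity cannot bias slopes, and "daily
release" is reported as interval amount divided by interval length.

Partial sampling requires the correction `A_n = V·C_n + Σ_{i<n} v_s·C_i`:
the drug now in the phase plus what earlier aliquots carried away.  Because
`A_n` is assembled from noisy measurements it is *not* forced monotone;
decreases are surfaced in a QC field rather than silently clipped.  The
1.0 mL replacement is drug-free medium; the resulting dilution of the
vessel is a physical effect reproduced by the simulator, while the
reconstruction implements exactly the accumulation formula above.

`invert_to_concentrations` is the exact algebraic inverse of both
bookkeeping schemes.  It exists so that any cumulative release law —
including published rate equations — can be turned into the concentration
series a perfect assay would record, giving round-trip identities that the
test suite exploits heavily.  Negative early values of a fitted line (e.g.
a Higuchi fit with negative intercept) are clamped to zero; fits on such
regenerated data start from the first non-negative day.

HPLC calibration is weighted least squares of response on concentration.
The weighting default is 1/x² (variance proportional to concentration), the
most common bioanalytical convention; 1/x and unweighted are available.
Back-calculated concentrations are floored at zero and flagged when the
response falls below the calibrated range.

## Kinetic fitting

All three models are fitted as straight lines by ordinary least squares:
cumulative vs t (zero-order), cumulative vs √t (Higuchi), and log₁₀
fractional release vs log₁₀ t (Korsmeyer–Peppas, slope = n, intercept =
log₁₀ k).  95% confidence intervals are parametric t-intervals with n−2
degrees of freedom — the standard reporting convention for dissolution rate
equations.  Design choices:

- **Peppas window.**  Default: all points with fractional release in
  (0, 1]; non-positive fractions are excluded with a warning.  The textbook
  restriction to the early curve is available as `max_fraction=0.6` but is
  not the default, matching how the reference tables were evidently fitted
  (28-day windows).
- **Time-basis selection** is by higher R², with ties resolved to Higuchi —
  the expected mechanism for a matrix ring.  The CLI allows an explicit
  override, which is noted in the output.
- **Degenerate data.**  A constant cumulative curve is returned as a perfect
  zero-slope fit (R² = 1, zero-width CIs) on either basis rather than a NaN
  fit; all-equal abscissae raise a singular-fit error; fewer than 3 points
  raise an insufficient-data error.
- **Negative intercepts** (physically, a lag before quasi-steady release)
  are reported as fitted; clamping to zero happens only where a cumulative
  *curve* is generated for simulation or display.
- **Interval correction** replaces the increments inside a user-stated
  window with the fitted model's predicted increments and reports the change
  in final cumulative release — the procedure used to back-calculate release
  across a transient artefact such as a mis-prepared medium batch.
- **Replicate screening.**  After pooling, residuals of each ring from the
  pooled fit are centred by their per-time median across rings and screened
  against 3× a MAD-based robust SD.  The median-centring matters: a single
  divergent ring drags the pooled mean, and raw residual screening then
  mis-flags the clean rings.  Flagging never drops data automatically;
  exclusion is an explicit analyst decision (`exclude_replicates`), mirroring
  how anomalous rings are reported alongside full-panel fits.

### Confidence-interval coverage and the noise model

The OLS t-intervals assume independent, roughly homoscedastic errors in the
*cumulative* observations.  Under multiplicative noise applied to cumulative
values (CV 5%), simulated coverage of the slope CI is ≈96% — consistent with
the nominal 95% given mild heteroscedasticity.  But if independent
multiplicative noise is applied to per-interval amounts and then summed —
arguably closer to how assay error actually enters — the cumulative errors
become a random walk, and nominal-95% OLS intervals cover the true slope
only ~26% of the time.  The coverage property in the test suite therefore
uses the former noise model, and reported CIs for real cumulative data
should be read as conditional on that assumption.  (Rates estimated from
cumulative curves with accumulated noise are still unbiased; it is the
interval width that is optimistic.)

## Sink and mechanism rules

Saturation ratios are computed from the daily sample concentrations (not
modelled instantaneous peaks): strict sink requires every ratio < 0.10,
relaxed < 0.30.  Mechanism classification is a total, deterministic map:

| sink (relaxed) | better basis | n | label |
|---|---|---|---|
| no | t | — | partition-controlled |
| no | √t | suppressed | transitional (non-sink), with warning |
| yes | t | — | zero-order release |
| yes | √t | within 0.5 ± δ | Fickian matrix diffusion |
| yes | √t | (0.5+δ, 1) | anomalous transport |
| yes | √t | < 0.5−δ | pseudo-Fickian diffusion |
| yes | √t | ≥ 1 | super-case-II transport |

δ defaults to 0.05 and the Fickian reference to n = 0.5 — the convention
used in the ring-release literature — although thin-film/cylinder theory
would put the reference nearer 0.45; both are parameters.  The Peppas label
is suppressed under non-sink conditions because the power law presumes
dissolution does not retard release.

`scale_volume_for_target` is a deliberately transparent linear
extrapolation (`volume × target / release`); applied to the biphasic 28-day
totals at 100 mL it gives ~253 mL (full panel, 1.58 mg) or ~408 mL
(anomalous rings excluded, 0.98 mg) to reach a 4 mg in vivo-matching
target.  The package makes no attempt to reconcile these further; the
linearity assumption is the whole model.

## Simulators

**Monophasic.**  The matrix can deliver at most its diffusion-limited
cumulative `a√t + b`; each interval is further capped at `φ·S·V_i`.  The
un-delivered surplus carries over (the matrix retains drug), so in a poor
solvent the cap binds every day and cumulative release is exactly linear at
rate `φ·S·V` — the partition-controlled regime — while in a good solvent the
cap never binds and the Higuchi law is reproduced exactly.  φ defaults to
0.5, calibrated once against the measured water-only rate (7.55 µg/day vs
S·V = 8.4 µg/day) and the 10/90 rate (25.0 vs 55.6 µg/day); it subsumes
boundary-layer hydrodynamics and is a testing device, not a physical claim.
With the published solubility ladder and a 2022 µg/day^½ law, the fitted
basis switches from zero-order to Higuchi between the 10% and 30% co-solvent
media, reproducing the observed transition zone.

**Biphasic.**  Between sampling events the two-compartment linear ODE above
is integrated by fixed-step classical RK4 (default 100 substeps/day).  A
fixed step was chosen over adaptive integration for bit-level
reproducibility under a seed.  The released-mass state `R` is integrated
alongside, and `R = M_b + M_o + removed` is checked at every sampling day;
the run is retried with doubled substeps (up to 5 attempts) if drift exceeds
0.1% or any mass goes negative, then fails loudly.  (For this linear system
every Runge–Kutta scheme conserves the invariant exactly, so the check
guards the event bookkeeping and genuinely unstable parameter choices.)
Defaults k_r = 2 /day and q_t = 400 mL/day were set once so that the pH 4.2
steady state produces octanol accumulation of the observed order
(~60–70 µg/day) given the measured buffer solubilities; D defaults to
10^logD(pH) with only the neutral species partitioning.  The octanol-contact
anomaly is modelled as an extra constant-rate source from ring to octanol
from a start day, added to both `M_o` and `R` so conservation still holds.

**Noise** is multiplicative lognormal with unit mean (default CV 3%,
typical HPLC repeatability), applied to recorded concentrations only —
sampling removal uses true masses, so measurement error never corrupts the
simulated mass balance.  All randomness flows from one seed; replicate *r*
uses the numpy substream `(seed, r)`.

### What the synthetic data do and do not establish

The simulators reproduce the *statistical and bookkeeping* structure of the
experiments: schedules, volumes, dilution, replicate noise, solubility
capping, two-phase partitioning, and anomalous-ring artefacts.  They do not
model hydrodynamics, polymer swelling, ion-pair partition, buffer-species
effects on solubility, or inter-day assay drift.  Passing the round-trip and
recovery tests therefore validates the analysis chain (reconstruction,
fitting, classification) — it does not validate the physics of any
particular ring formulation.

## Physicochemical model notes

All logarithms are base 10.  The Yasuda–Shedlovsky extrapolation regresses
(psKa + log[H₂O]) on 1/ε and evaluates at the pure-water point; defaults
ε_water = 78.3 and log[H₂O] = log₁₀ 55.5 are configurable, and a simpler
linear-in-cosolvent-% mode is provided for instruments reporting that
abscissa.  A known deviation worth remembering: Henderson–Hasselbalch
predicts a pH 4.2 / pH 7 solubility ratio of ≈13.6× for pKa 5.30, while the
measured buffer solubilities give ≈28× (0.499 / 0.018 µg/mL) — buffer
species and ionic-strength effects that the ideal model ignores.  The
package reports the model value; reconciling the gap is a measurement
question, not a bookkeeping one.

## Problem sizes

Every simulation in the tests and the acceptance script uses the study's own
dimensions — 28 daily events, 4 replicate rings, 100/20 mL volumes — and the
stochastic coverage check uses 500 simulated experiments at CV 5%.  The full
suite runs in a few seconds on one CPU.
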
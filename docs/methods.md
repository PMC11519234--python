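# Methods notes

## Scope and data model

`frthresh` operates on *stage-level* data of incremental cycling tests:
one row per completed stage with power output (W), heart rate
(beats·min⁻¹) and respiratory frequency (breaths·min⁻¹), plus optional
metabolic channels (V̇o₂, V̇co₂, V̇_E in L·min⁻¹). Breath-by-breath
acquisition, stage averaging (typically the last 10 s of each stage) and
analyzer calibration/drift handling are upstream of this package: inputs
are taken as given, already averaged and STPD-standardised. A series needs
at least 4 stages to validate and at least 6 for threshold detection.

## Respiratory-frequency thresholds (fRT1/fRT2)

The detector formalises "f_R starts rising disproportionately" as an
excess over a running baseline: stage *i* triggers when
f_Ri − mean(f_R over all prior stages) strictly exceeds twice the sample
SD (n−1 denominator) of those prior values, provided PO_i strictly
exceeds `min_po`. Notes on the fine print, each of which is fixed by the
bundled worked example:

* the baseline includes **all** prior stages, the unloaded stage and the
  ≤ 60 W stages included, and is **never reset** after the first trigger;
* comparisons use unrounded values (the scan table displays 1-decimal);
* eligibility is strict (`PO > min_po`): in the worked example the 60 W
  stage numerically satisfies excess > gate yet is not selected;
* `min_po = 60` W corresponds to excluding the first four stages of a
  +20 W/min protocol; for other protocols set it to the PO of the fourth
  loaded stage.

The three segment lines are OLS fits of f_R (response) on HR (predictor);
boundary stages belong to both adjacent segments. Final thresholds are
segment intersections computed at full precision; rounding (f_R one
decimal, HR nearest integer, coefficients four decimals) happens only in
displays. Slopes closer than `parallel_tol` (10⁻⁶ breaths·min⁻¹ per
beat·min⁻¹) are treated as parallel and yield an *undetermined* status —
as do a missing first or second provisional trigger, a degenerate segment
fit, and (defensively) an inverted pair of intersections. Statuses, not
exceptions, so cohorts can be processed in batch.

Threshold HR is mapped to V̇o₂ and PO through OLS fits of V̇o₂ on HR and
V̇o₂ on PO over **all** completed stages with V̇o₂ data. The widest window
maximises stability; a narrower window around the threshold would track
local nonlinearity better but is poorly identified on 1-min stages.

## V-slope thresholds (GET1/GET2)

Both gas-exchange thresholds use one two-segment search: for every
admissible boundary index the lower limb is fitted on the points at and
below, the upper on the points at and above (shared boundary point), and
the split score is

    criterion = perpendicular distance(limb intersection, single line) / MSE(single line)

with the single line fitted to all points and MSE = SSE/(n−2). Ties keep
the earliest split. Numerical choices:

* distance is measured in raw axis units (both axes L·min⁻¹); no axis
  normalisation is applied before the distance computation;
* `min_segment = 3` points per limb — a 2-point limb has zero residual
  and destabilises the criterion;
* splits whose limb intersection falls **outside the predictor range of
  the data** are inadmissible. Near-parallel noisy limbs can intersect
  arbitrarily far from the data, which would otherwise win the criterion
  through sheer distance while representing no physiological breakpoint;
* exactly collinear data return the earliest admissible split with
  criterion 0 and slope change 0 (which the acceptance rules then reject);
* the strict acceptance inequalities (> 15% slope change for GET2, > 0.1
  absolute for GET1) carry a 10⁻⁹ tie tolerance so boundary-exact data
  resolve to *undetermined*.

Filters before the search: both relations drop the first two stages; GET2
drops trailing stages whose stage-to-stage V̇o₂ increase is below
120 mL·min⁻¹ (scanning backwards, stopping at the first compliant
increment); GET1 drops leading points while the slope of the first
`min_segment`-point window is below 0.6 (re-checked after each removal)
and caps its domain at the determined GET2's V̇o₂. When GET2 is
undetermined, GET1 proceeds on the uncapped data and carries a
`no-get2-cap` provenance note. GET2 is reported at the break's V̇co₂
(other coordinates linearly interpolated between the bracketing stages);
GET1 is reported directly at the break's V̇o₂ — the accepted break
location *is* the threshold; no further computation.

## Gas-exchange computation

V̇o₂ and V̇co₂ follow the Haldane transformation (nitrogen balance
between inspired and expired air), with ambient-air defaults
F_IO2 = 0.2093 and F_ICO2 = 0.0003, giving an inspired nitrogen fraction
of exactly 0.7904. The full V̇co₂ expression retains the −F_ICO2 term
(it reduces to the simpler form when F_ICO2 = 0). Tiny negative uptakes
(|value| < 10⁻³ L·min⁻¹, measurement noise around zero) are clamped to 0
with a warning; larger ones are input errors. Ratios (RER, ventilatory
equivalents) are reported as undefined — not infinity — when their
denominator is zero.

## Agreement statistics

Differences are test-minus-reference; limits of agreement use 1.96 times
the sample SD of differences; proportional bias is the p-value of
regressing differences on pair means (NaN when the differences are
constant and the slope test is vacuous). SEE = √(SSE/(n−2)) of the
regression of the reference on the test method; relative SEE is a
percentage of the response mean. Hedges' g uses the pooled sample SD and
the correction J = 1 − 3/(4·df − 1); the `paired` flag is reporting
metadata only. All classification bands are half-open with the labelled
edge inclusive (r = 0.7 → *very large*; SEE 20% → *very poor*; g = 0.6 →
*moderate*), so every value maps to exactly one class.

## Synthetic generator: what it emulates and what it does not

`frthresh.synthetic` produces stage series with *known* threshold
locations so that detector accuracy can be measured against embedded
truth. The structural model: HR linear in PO; f_R continuous
piecewise-linear in the noiseless HR with two breakpoints (the fRT
truths); V̇o₂ linear in PO; V̇co₂ piecewise-linear in V̇o₂ with its
break at the first f_R breakpoint (the GET1 truth); V̇_E
piecewise-linear in V̇co₂ with its break at the second f_R breakpoint
(the GET2 truth). The V̇co₂ slopes (0.95 → 1.25) make the RER rise from
≈ 0.9 to ≈ 1.1 across the test. Noise is i.i.d. Gaussian per channel per
stage — the simplest model consistent with stage-averaged data.

Defaults describe a middle-aged cohort on a +20 W/1-min protocol:
W_max 240 W (13-min test), HR from 80 to ≈ 176 beats·min⁻¹, V̇o₂ from
0.45 to ≈ 3.0 L·min⁻¹ (≈ 38 mL·kg⁻¹·min⁻¹ at 78 kg), breakpoints at
≈ 75% and ≈ 86% of HR_max. The f_R segment slopes (0.02, 0.45, 2.3
breaths·min⁻¹ per beat·min⁻¹) keep the pre-threshold segment nearly flat
relative to the f_R noise (σ = 1.0 breaths·min⁻¹), so the per-stage f_R
increment at each breakpoint — (s₂−s₁)·ΔHR ≈ 3.4 and (s₃−s₂)·ΔHR ≈ 15
breaths·min⁻¹ — is at least three noise SDs. The gas-channel noise SDs
(σ_V̇co₂ = 0.015, σ_V̇_E = 0.6, σ_V̇o₂ = 0.03 L·min⁻¹) satisfy the same
≥ 3σ condition for their breaks. This is a deliberate regime choice: a
2·SD running-baseline scan is only meaningful where the breakpoint
deviation dominates both the baseline trend and the noise. With a
steeply rising pre-threshold f_R or substantially larger noise, the scan
fires spuriously on the trend (or not at all) and detection accuracy
degrades gracefully toward *undetermined* — mirroring the double-digit
undetermined rates reported for breakpoint methods on real cohorts.

What passing synthetic tests therefore show: the detectors recover
breakpoints of the assumed piecewise-linear + i.i.d.-noise form, at
realistic magnitudes, with ≥ 90% determinacy and median error within one
stage. What they do not show: robustness to autocorrelated or
heteroscedastic noise, start-of-test hyperventilation transients,
f_R plateaus (tidal-volume-dominated breathing), or protocol deviations —
real-data properties the generator intentionally omits.

## Problem sizes used in the validation suite

The recovery tests use 200 seeded subjects (the synthetic cohort's
default conditions); oracle equivalence uses 100 random instances of up
to 30 points; t-test calibration uses 2000 replicates of 20 pairs. The
whole suite runs in a few seconds on one CPU.

## Known limitations

* The worked example's intersection HR values are reproduced at full
  precision from the printed stage table (≈ 145.4 and ≈ 166.5); displays
  round HR to the nearest integer.
* The V-slope criterion is scale-dependent (raw axis units); axes with
  very different numeric ranges (V̇_E vs V̇co₂) weight the distance
  almost entirely along the larger axis. The in-range admissibility rule
  limits, but does not remove, this sensitivity.
* Stage-level detection cannot resolve thresholds below the resolution of
  one stage; all accuracy statements are relative to the stage increment.
* HR- and PO-referenced threshold values from incremental tests
  overestimate the constant-load work rate eliciting the same internal
  intensity; no mean-response-time correction is applied here.
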
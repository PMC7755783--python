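# Methods

## Model

A patient's analyte level is modelled as a personal homeostatic **set
point** `S`, drawn across the population with between-subject biological
variation CVg, around which serial true values fluctuate with
within-subject variation CVi; each measurement further adds analytical
imprecision CVa.  All three act multiplicatively and are expressed as
coefficients of variation in percent.  A single result is then

```
x = S · (1 + e_i + e_a),    e_i ~ N(0, CVi/100),  e_a ~ N(0, CVa/100)
```

and the difference of two independent results from a *stable* patient,
expressed as a percentage of the set point, is Gaussian with standard
deviation `√2 · √(CVa² + CVi²)`.  The reference change value

```
RCV = k · √2 · √(CVa² + CVi²)
```

is the two-sided `(1 − α)` bound of that null distribution, with coverage
factor `k = 1.96` (95%) or `2.58` (99%).  A serial change beyond the RCV is
unlikely under stability and therefore worth holding for review.

Set-point spread (CVg) cancels out of within-patient differences; it
matters for two things only: the **index of individuality** CVi/CVg (below
0.60 an individual's results occupy a narrow band inside the population
interval, the regime where delta checks beat reference-interval flagging),
and the size of the jump produced by a specimen mix-up, which splices
another patient's set point into the series.

## Analytical imprecision, top-down

CVa is estimated from internal QC material: the sample (n−1) CV of a long
series of control results, computed per instrument × control level on the
raw concentrations, with **no exclusion** of out-of-control points (the
imprecision patients actually experienced).  With two analysers and two
levels this gives up to four estimates per analyte; the **largest** is used
as CVa — a deliberately conservative choice that widens the RCV.  A
per-instrument aggregation mode is available
(`cva_from_qc(..., per_instrument=True)`) for laboratories whose patient
streams map cleanly onto instruments.  The denominator choice (n−1 vs n) is
immaterial at typical QC series lengths of 500–1800 points.

## Rules and their variants

Delta-check metrics are kept **signed** (`current − previous`), because
conventional cutoffs are asymmetric for analytes reflecting tissue damage
(AST, ALT, bilirubins can rise much faster than they fall); flagging
compares the signed metric against `lower_limit ≤ 0 ≤ upper_limit` with
**strict** inequalities, so a value exactly at a cutoff does not flag.
RCV-based limits are symmetric ±RCV; asymmetric overrides can be expressed
directly as `DeltaRule` limits.

Non-evaluable metrics never flag: percent change with a non-positive
previous result, and rate metrics for intervals below a **0.5-day floor**
(same-day repeats stay evaluable by DD/DPC; a rate over a fraction of a
day would be dominated by the division).  Non-evaluable and excluded pairs
are reported separately so nothing is silently dropped.

Three modifications of the base ±RCV percent-change rule address its
over-detection on real workloads:

1. **Within-RI exclusion** — pairs whose results both lie inside the closed
   reference interval `[ref_low, ref_high]` are excluded: such changes,
   even if statistically real, rarely carry clinical or error-detection
   significance.  One-sided intervals ("0 ~ 199") use `ref_low = 0`.
2. **Time scaling** — the metric becomes rate percent change compared with
   ±RCV in %/day, i.e. a pair flags when `|DPC| > RCV · Δt`.  The cutoff
   *relaxes* with elapsed time, reflecting that slow drift over weeks is
   not the same evidence of error as the same jump overnight.  The
   opposite (literal) scaling — dividing the *limits* by Δt, which
   tightens with time — is implemented behind
   `literal_time_scaling`/`divide_limits_by_interval` for comparison, but
   only the relaxing direction reduces outpatient over-detection, so it is
   the default.
3. **Absolute cutoff at 2·ULN** — a DD rule with limits
   ±(RCV/100)·2·ULN in analyte units.  For analytes with narrow reference
   intervals a small absolute change is a large percentage; anchoring the
   percentage at twice the upper normal limit converts the RCV into an
   absolute difference with clinically sensible scale.

## Pairing and detection rates

Each result is paired with the most recent prior result of the same
patient and analyte, if that prior lies within the setting's lookback
window: **40 days for inpatients, 60 for outpatients**; health-examination
recipients reuse the outpatient window (their natural revisit interval is
longer than any sensible window, so the choice is rarely binding and is
configurable).  A result is "current" in at most one pair but may serve as
the "previous" of the next visit, producing chained pairs.  Ties between
prior results at identical timestamps resolve to the later one in stable
input order, keeping pairing a pure function of its inputs.

The detection rate of a rule is `100 · n_flagged / n_pairs`, with excluded
and non-evaluable pairs counted in the denominator as unflagged.  This
makes the within-RI exclusion a guaranteed monotone reduction and keeps
denominators comparable across variants; an `evaluable`-only denominator is
available where a conditional rate is wanted.

## Synthetic cohorts

No patient-level dataset accompanies the methodology, so the simulator
generates cohorts with exactly the structure the model assumes — set
points with CVg, serial fluctuation CVi, measurement noise CVa, uniform
inter-visit intervals per setting (1–7 days inpatient, 7–56 outpatient,
30–60 health exam), an optional fraction of patients with set points
displaced outside the reference interval, and optional log-linear drift.
Presets derived from the packaged panel place the set point at the
reference-interval midpoint (70% of the upper limit for one-sided
intervals) and, because the panel ships no CVg values, default to
**CVg = 2·CVi** — an explicit preset, not a measured quantity.  Specimen
mix-ups are injected by swapping measured values between two patients with
the same analyte on the same collection day, the mechanism delta checks
target; injected instants are returned as truth labels for
sensitivity/specificity/PPV scoring.

What the generator does **not** emulate: disease progression and
pharmacokinetics (drift is log-linear only), instrument-specific bias,
diurnal variation (glucose in particular varies far more within a day than
a stationary CVi captures), and correlated panel-wide changes from, e.g.,
haemodilution.  Passing tests therefore demonstrate internal consistency
and calibration of the rules under the model's own assumptions, not
detection performance on real hospital workloads.

## Numerical choices and test design

- RCV is kept at full floating precision internally; reports round to two
  decimals.  Rules built from rounded, published RCVs and from full-
  precision ones differ in the third decimal of the cutoff.
- The Monte-Carlo oracle for the RCV closed form simulates result pairs
  around a known set point and takes the empirical two-sided `(1 − α)`
  quantile of the percent difference **relative to the set point** — the
  quantity the RCV formalises, exact at any CV.  Percent change relative
  to the *previous result* coincides with it only in the small-CV limit:
  the ratio's denominator noise skews the null, inflating the upper tail
  and deflating the lower.  For a combined CV of ~2.9% (calcium) the
  effect shifts the 99%-rule two-sided flag rate from 0.99% to ~1.04%;
  at ~1.2% (sodium) it is negligible.  Calibration is therefore asserted
  at large scale (100 000 pairs, 3 Monte-Carlo SE) on sodium, where the
  Gaussian tail mass is the correct description, and at desk scale on
  calcium, where the 3-SE band comfortably contains the skew.  This is a
  property of percent-change delta checks generally: for high-CV analytes
  the ±RCV rule is intrinsically slightly asymmetric in realised rates.
- Simulation sizes in the test suite (up to 20 000 patients × 6 visits for
  the calibration check; 500 patients × 17 analytes for variant-ordering
  checks) are chosen so Monte-Carlo error is well below the asserted
  tolerances while the whole suite runs in seconds.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical cohorts,
  QC series and CLI outputs.

## Known limitations

- The published detection rates on the source hospital's ~857 000 real
  pairs are not reproducible without those data; on synthetic cohorts the
  package reproduces the *qualitative* ordering (95% CI ≥ 99% CI;
  within-RI exclusion and time scaling only reduce rates), which is what
  the variant-ordering tests assert.
- One cell of the published RCV table (direct bilirubin at the 99% level)
  is internally inconsistent with its own printed inputs by ~0.05
  percentage points; the package reports the value the formula yields.
- Mix-up injection swaps whole values at the same nominal collection time;
  partial swaps, label errors across analytes, and carry-over are out of
  scope.
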
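# Methods

## Growth model and VDT estimation

Nodule growth is treated as exponential in volume, so the growth rate is
summarised by the volume doubling time, VDT = *t*·lg 2/lg(*V*/*V*₀). The
estimate is signed: positive for growth, negative for shrinkage, and
represented as an unbounded (infinite) value when the volume ratio is
exactly 1 — never as a float sentinel in user-facing output, where it
serialises as the strings `"inf"`/`"-inf"`.

With three or more timepoints the VDT comes from an ordinary
least-squares fit of log volume against time (VDT = ln 2 / slope); with
two it reduces to the closed form. We read "regression across all time
points" as this log-linear exponential fit, since the growth model is
exponential; saturating (Gompertz/logistic-curve) growth models are out
of scope. A zero fitted slope yields an unbounded VDT; duplicate
timepoints are rejected.

Months convert to days at 365/12 (3 months = 91.25 d, 6 months =
182.5 d). Reported millimetre values round to one decimal and reported
day counts to the nearest whole day with halves rounding away from zero
(182.5 → 183); all threshold comparisons use unrounded values.

## Measurement-error calculus

The repeatability coefficient (RC) — the 95% limit for the difference
between two repeated measurements — relates to the single-measurement
standard deviation by RC = 1.96·√2·σ. Defaults: relative RC of 15% for
volumetry of acceptably segmented nodules, absolute RC of 1.5 mm for
caliper diameters, coverage factor 1.96. Segmentations are graded on the
five-level visual scheme (excellent/good/satisfactory/poor/failure);
*poor* and *failure* count as volumetry failure and force the manual
pathway. The `ErrorModel` accepts RC = 0 so that idealised error-free
scenarios (used for fidelity checks and threshold calibration limits)
are expressible. Volumes below 1 mm³ are accepted, as detection-limit
reasoning needs 4 mm³ starting sizes.

Derived intervals: a single caliper diameter has 95% half-width RC/√2
(±1.1 mm at default), the mean of *n* diameters shrinks by √*n* (±0.6 mm
for the standard three orthogonal measurements). For effective diameters
the relative volume half-width RC/√2 propagates through the cube root as
a factor 1/3 (linearisation), giving a size-independent *relative*
half-width and absolute values of ±0.2–0.3 mm over the 100–500 mm³
range. The exact asymmetric bounds (1 ± ε)^(1/3) are available via
`ci_effective_diameter(..., exact=True)`; both variants reproduce the
same one-decimal reference values, and the symmetric linearisation is
the default because the ± notation of the interval is symmetric.

## VDT confidence intervals

Measurement error on the volume ratio *V*/*V*₀ is modelled as Gaussian
around the true ratio. Two independent measurements, each at
σ = RC/(1.96·√2), combine to a 95% half-width equal to the RC itself, so
the measured ratio lies in *r*·(1 ± RC). Each ratio bound maps through
the VDT formula, producing intervals that are asymmetric (wider above
the point estimate than below) and that narrow with longer follow-up or
faster growth. When the lower ratio bound falls to 1 or below while the
lesion truly grows, the confidence set crosses infinity — it becomes
{VDT ≥ lower} ∪ {VDT ≤ negative bound} and growth cannot be
distinguished from shrinkage. The multiplicative-bound convention
*r*·(1 ± ε) is the simplest consistent reading of the Gaussian-ratio
assumption; a σ-on-log-ratio convention would differ only at second
order in ε, and only the interval's qualitative shape is externally
checkable. Monte-Carlo checks at 20,000 replicates confirm 95% ± 1.5%
coverage of simulated two-scan estimates, including in the
crossing-infinity regime.

## Stage-shift calculus and threshold calibration

The T1c boundary is a 20-mm effective diameter, i.e. a sphere volume of
≈ 4188.79 mm³; this reproduces the 68/45/30/51-day worked boundary VDTs
at the published category borders, confirming the convention. The
boundary VDT is increasing in baseline volume (a nodule nearer the
boundary shifts stage at slower growth) and increasing in interval
length. The new-nodule table documents its cells as *upper bounds*: the
slowest VDT able to grow the assumed pre-detection size (4 or 15 mm³) to
the detected size within the screening interval.

`calibrate_vdt_threshold` inverts the CI: it solves (Brent's method,
bracketed below the VDT at which the interval crosses infinity) for the
measured-VDT referral threshold whose 95% upper bound equals a target
(600 days by default). With the default 15% RC it yields ≈ 236/339/433 d
at 3/6/12 months — the same ordering and magnitude as, but not exactly
equal to, the shipped 250/400/500-day thresholds. The shipped policy
therefore uses the stated thresholds verbatim and the calibrator is a
companion analysis tool, since the exact calibration convention behind
the published thresholds is not recoverable from the printed numbers.

## Decision engine

Size categories: volumetric < 100 / [100, 250) / [250, 500) / ≥ 500 mm³
and manual < 6 / [6, 8) / [8, 10) / ≥ 10 mm map to very-low / low /
intermediate / high risk; the half-open-interval convention follows the
"≥ 100 and < 250" phrasing and is applied uniformly. Categories map to
actions: 12-month (negative screen), 6-month, 3-month (indeterminate),
workup (positive). Suspicious morphology upgrades the category exactly
one step (idempotent for multiple flags); clearly benign morphology
takes precedence over suspicious flags (a calcified spiculated nodule is
benign) and ends evaluation.

Design choices where the source rules leave room:

- **Relevant component.** Solid nodules are sized on the whole nodule;
  part-solid, cystic and (if present) non-solid nodules on the solid
  component. A part-solid nodule whose solid component exceeds 80% of
  the total diameter (compared by whichever method covers both series)
  is reclassified and managed as solid, i.e. on the whole-nodule size.
- **Cumulative-growth MDT trigger.** ≥ 5 mm (the "at least 5 mm"
  wording) rather than > 5 mm; the comparator is configurable
  (`mdt_comparator`). Cumulative change uses effective diameter under
  volumetry and average diameter under the manual pathway, always
  against the earliest same-method observation.
- **Interval keying.** The VDT threshold at a follow-up is keyed to the
  time since the *previous* scan, while the VDT itself uses all
  timepoints (fit). Lookups snap to the nearest scheduled interval, and
  anything at or beyond the longest key uses its threshold (the "≥ 12
  months" rule) — real scan dates never land exactly on 91.25/182.5/365
  days, so an exact-match rule would be unusable; a configuration error
  is raised only for an empty table or non-positive interval.
- **Shrinkage.** Any negative VDT (or negative manual delta) routes to
  the very-low category and annual screening, and is mutually exclusive
  with substantial growth.
- **1-month lesions** (infection-suggestive findings; part-solid solid
  component ≥ 10 mm; cystic lesions with pneumonia as a realistic
  differential): at the recheck, regression follows the benign pathway
  and persistence or growth goes to workup.
- **New nodules.** Prevalent (visible in retrospect) with evident growth
  → workup; dubious with feasible volumetry → interval-keyed VDT
  criterion, returning to annual screening when growth is not
  substantial (the non-growing branch is not spelled out in the source
  flowchart; annual screening mirrors the incident-recheck rule);
  dubious without volumetry → 3-month recheck. Incident (part-)solid
  nodules at ≥ 30 mm³ (≥ 4 mm manual) → 3-month recheck, below → annual;
  incident non-solid → annual. "Evident growth" and "substantial
  morphology change" are operator-supplied flags, not computed.
- **Airway lesions.** Benign signs (multisegment mucus, air bubbles,
  tracheal drop sign) end evaluation; segmental-or-smaller lesions are
  managed like a small solid nodule of the bronchus diameter (≤ 6 mm
  annual/negative, > 6 mm 6-month/low); tracheal or proximal lesions are
  intermediate/3-month; at follow-up persistence or growth → MDT,
  regression → negative. Size change, not VDT, drives the follow-up
  branch because bronchial lesions cannot be consistently measured.
- **Aggregation.** Workup outranks MDT referral, which outranks
  follow-up (shortest interval first); benign recommendations are
  ignored unless nothing else exists.

Every path appends stable rule identifiers (registry in
`nodulekit/rules.py`) to the recommendation's trace; a generated
cross-product of nodule states exercises every identifier.

## Cohort simulator

Trajectories follow *V*(*t*) = *V*₀·2^(t/VDT) with multiplicative
Gaussian volume noise at the single-measurement σ (truncated at −90% to
keep volumes positive; at the default 5.4% σ the truncation is a
> 16-σ event and practically never binds). Diameter-policy measurements
add Gaussian noise at the diameter σ to the true effective diameter and
average two perpendicular measurements (the comparison policy's
convention; the manual fallback inside the rule engine averages three —
the count is a parameter). Stage shift is evaluated on noiseless true
volumes at the referral time or, absent referral, the end of the
schedule. False positives are referred nodules with true VDT ≥ 600 days
(or non-growing/shrinking).

The default evaluation cohort draws true VDTs log-uniformly on
[600, 2000] days — entirely within the slow-growing/indolent range
reported for screening-detected malignancies, so every referral is by
construction unnecessary — at the worst-case category-boundary baselines
(99/249/499 mm³) with scans at 0 and 91.25 days. The worst case for the
diameter policy uses 499 mm³ baselines scanned at 0, 91.25 and 456.25
days (3-month follow-up, then a year). Problem sizes: directional policy
comparisons use 10,000 nodules and coverage checks 20,000 replicates,
which give binomial standard errors well below the asserted margins;
both complete in a few seconds.

### What the generator does and does not emulate

It emulates exponential growth with scan-to-scan measurement
variability under an idealised, size-independent repeatability model.
It does not emulate resolving inflammatory nodules, segmentation-quality
degradation with nodule complexity or attachment, inter-software or
inter-scanner bias, growth-rate changes over time, or the screening
population's nodule-size and malignancy mix. Passing directional tests
therefore show that the policy orderings follow from the stated error
model and growth model — not a forecast of absolute referral rates in a
real programme.

## Numerical notes and limitations

- Threshold calibration brackets the root in (t/500, VDT_cross) where
  VDT_cross = *t*·ln 2/(−ln(1 − RC)) is the crossing-infinity boundary;
  tolerance 1e-9 days.
- `vdt_fit` centres times before the slope computation for conditioning.
- Risk categories are an ordered enum with saturating upgrade/downgrade
  (benign is off the ladder: it neither upgrades nor is reachable by
  downgrading).
- The engine assumes each series uses a consistent measurement method at
  the endpoints; mixed series fall back to the manual pathway when both
  endpoints cannot be assessed volumetrically.
- Malignancy-probability models, AI risk scoring, TNM staging beyond the
  T1a/T1c size boundaries, and full re-implementations of other
  guidelines (Lung-RADS, Fleischner) are out of scope; the two
  comparison policies exist only as growth-criterion variants.
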
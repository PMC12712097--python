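# nodulekit

Decision support and growth-kinetics tooling for pulmonary nodule
management in low-dose-CT lung cancer screening.

Screening programmes find many small nodules; nearly all are benign. The
management problem is to schedule follow-up scans and diagnostic workup so
that aggressive tumours are caught before a *major stage shift* — a T1a
tumour (< 1 cm) growing to stage T1c (≥ 2 cm) — while benign and indolent
lesions are not sent to unnecessary workup. `nodulekit` implements the
European (ESTI) screening recommendation that addresses this by estimating
lesion **aggressiveness** and explicitly budgeting for **measurement
error**. It is aimed at screening-programme methodologists, radiology
software developers and researchers comparing management policies.

## The model

Lung tumours are modelled as growing exponentially, so growth rate is the
**volume doubling time**

&nbsp;&nbsp;&nbsp;&nbsp;VDT = *t* · lg 2 / lg(*V*/*V*₀)

for volumes *V*₀ and *V* measured *t* days apart (negative for shrinkage,
infinite for constant volume; with ≥ 3 scans, a least-squares fit of
log-volume on time). Volumes translate to **effective diameters**
*d* = (6*V*/π)^(1/3), the equal-volume sphere diameter.

Measurement error is parameterised by the **repeatability coefficient**
RC = 1.96·√2·σ — 15% (relative) for volumetry of well-segmented nodules,
1.5 mm (absolute) for caliper diameters. Propagating the volumetric RC
through the VDT formula gives asymmetric 95% intervals for measured VDTs
that widen sharply for slow growth over short intervals (to the point of
extending across infinity). The recommendation therefore keys its
substantial-growth thresholds to the follow-up interval — **VDT < 250 d at
3 months, < 400 d at 6 months, < 500 d at ≥ 12 months** — so that the
upper confidence limit of a referred lesion stays near the 600-day
slow-growing boundary, instead of using one flat threshold.

On top of this the package implements the full management rule engine
(baseline size/morphology categories for solid, part-solid, non-solid,
cystic and airway nodules; growth-driven follow-up including the 5-mm
cumulative-growth MDT trigger; new-nodule handling with the 30-mm³
threshold; participant-level aggregation), every recommendation carrying
an auditable trace of the rules that fired, plus a cohort simulator for
quantifying false-positive referral and stage-shift trade-offs between
policies.

## Worked example

```python
from nodulekit import (NoduleRecord, SizeMeasurement, classify_baseline,
                       assess_followup, worst_case_stage_shift_vdt)

vol = lambda t, v: SizeMeasurement(t_days=t, volume_mm3=v, method="volumetry")

rec = classify_baseline(NoduleRecord(id="n2", type="solid",
                                     total_series=(vol(0, 300.0),)))
print(rec.action.value, rec.interval_months, rec.category.name)
# follow_up 3 INTERMEDIATE   — 300 mm³ is in the [250, 500) band

grown = NoduleRecord(id="n2", type="solid",
                     total_series=(vol(0, 300.0), vol(91.25, 450.0)))
fu = assess_followup(grown)
print(fu.action.value, "|", " -> ".join(fu.rule_trace))
# workup | BASE.SIZE_CATEGORY -> BASE.CATEGORY_ACTION -> FU.SUBSTANTIAL_GROWTH
#   (growing 300->450 mm³ in 3 months is a VDT of ~156 d, below the 250-d
#    threshold for a 3-month interval)

print(worst_case_stage_shift_vdt(100.0, 365.0))
# 68.0   — a 100 mm³ nodule reaches stage T1c within a year only if its
#          VDT is 68 days or less
```

The `examples/` directory holds short narrative scripts, one per
capability (`vdt_basics.py`, `error_intervals.py`, `stage_shift_table.py`,
`baseline_management.py`, `policy_tradeoffs.py`); each builds a small
input, runs the method and explains the printed numbers. A thin CLI wraps
the same functions:

```sh
nodulekit vdt --v0 100 --v 200 --days 100     # two-point VDT
nodulekit table1                              # new-nodule slowest-VDT table
nodulekit classify records.json               # recommendations + rule traces
nodulekit simulate --policy constant_600_vdt --n 5000 --seed 7
```

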
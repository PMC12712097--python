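"""Classify screening-detected nodules and aggregate to participant level.

Baseline management is driven by nodule type, size of the relevant
component, and morphology; follow-up management is driven by growth.  The
nodule with the strongest action (or shortest follow-up interval)
determines the participant's management; clearly benign nodules are
ignored.
"""

from nodulekit import (
    NoduleRecord,
    SizeMeasurement,
    assess_followup,
    classify_baseline,
    participant_management,
)


def vol(t, v):
    return SizeMeasurement(t_days=t, volume_mm3=v, method="volumetry")


nodules = {
    "calcified 80 mm3": NoduleRecord(
        id="n1", type="solid", total_series=(vol(0, 80.0),),
        morphology_benign=frozenset({"calcification_benign_pattern"}),
    ),
    "solid 300 mm3": NoduleRecord(id="n2", type="solid", total_series=(vol(0, 300.0),)),
    "solid 300 mm3 + spiculation": NoduleRecord(
        id="n3", type="solid", total_series=(vol(0, 300.0),),
        morphology_suspicious=frozenset({"spiculation"}),
    ),
}

recs = []
for label, nodule in nodules.items():
    rec = classify_baseline(nodule)
    recs.append(rec)
    interval = f"{rec.interval_months}-month" if rec.interval_months else "--"
    print(f"{label:30s} -> {rec.action.value:22s} {interval:9s} "
          f"({rec.category.name.lower()}, screen {rec.screen_result.value})")

agg = participant_management(recs)
print(f"\nparticipant management: {agg.action.value} "
      "(the spiculated nodule dominates; the calcified one is ignored)")

# follow-up: the 300 mm3 nodule grew to 450 mm3 in 3 months (VDT ~156 d)
grown = NoduleRecord(id="n2", type="solid",
                     total_series=(vol(0, 300.0), vol(91.25, 450.0)))
fu = assess_followup(grown)
print(f"\n3-month follow-up, 300->450 mm3: {fu.action.value} "
      f"(VDT ~156 d < 250-d threshold at 3 months)")
print("rule trace:", " -> ".join(fu.rule_trace))
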
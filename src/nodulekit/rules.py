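"""Registry of stable rule identifiers emitted in recommendation traces.

Every management decision carries an ordered ``rule_trace`` of the
identifiers below, so a recommendation can always be audited back to the
branch of the flowchart that produced it.  Identifiers are stable strings;
tests assert that every registered rule is reachable.
"""

RULES = {
    # baseline classification
    "BASE.BENIGN_MORPHOLOGY": "clearly benign morphology; no further evaluation",
    "BASE.THIN_WALLED_CYST": "thin-walled (<2 mm) unilocular cyst is benign",
    "BASE.RECLASSIFY_SOLID": "part-solid with solid component >80% of diameter handled as solid",
    "BASE.INFECTIOUS_1MO": "findings suggesting infection/inflammation: 1-month follow-up",
    "BASE.PARTSOLID_CORE_GE10MM": "part-solid solid component >=10 mm: 1-month follow-up",
    "BASE.CYSTIC_SUSPICIOUS": "cystic component counts as suspicious morphology",
    "BASE.NONSOLID_DEFAULT": "non-solid nodule without solid component: very low risk",
    "BASE.SIZE_CATEGORY": "risk category from size of the relevant component",
    "BASE.MORPHOLOGY_UPGRADE": "suspicious morphology upgrades risk one category",
    "BASE.CATEGORY_ACTION": "category mapped to action/interval/screen result",
    # airway nodules
    "AIRWAY.BENIGN_SIGNS": "multisegment mucus / air bubbles / tracheal drop sign: benign",
    "AIRWAY.SEGMENTAL_SMALL": "segmental-or-smaller bronchus <=6 mm: very low risk, 12 months",
    "AIRWAY.SEGMENTAL_LARGE": "bronchus >6 mm: low risk, 6 months",
    "AIRWAY.PROXIMAL": "endotracheal/proximal endobronchial: intermediate risk, 3 months",
    "AIRWAY.REGRESSION": "airway lesion regressed: lowest risk, negative result",
    "AIRWAY.PERSISTENT": "airway lesion persistent or grown: MDT referral",
    # follow-up assessment
    "FU.ONE_MONTH_REGRESSION": "1-month recheck lesion regressed: benign pathway",
    "FU.ONE_MONTH_PERSISTENT": "1-month recheck lesion constant or grown: workup",
    "FU.SHRINKING": "shrinking nodule (negative VDT): very low risk, 12 months",
    "FU.SUBSTANTIAL_GROWTH": "substantial growth: diagnostic workup",
    "FU.CUMULATIVE_5MM_MDT": "slow-growing, cumulative diameter change >=5 mm: MDT referral",
    "FU.DOWNGRADE": "no substantial growth: downgrade one risk category",
    # new nodules
    "NEW.PREVALENT_EVIDENT_GROWTH": "prevalent nodule with evident growth: workup",
    "NEW.PREVALENT_VDT": "prevalent dubious nodule assessed by interval-keyed VDT threshold",
    "NEW.PREVALENT_NO_VOLUMETRY": "prevalent dubious nodule, volumetry infeasible: 3-month follow-up",
    "NEW.INCIDENT_GE_THRESHOLD": "incident (part-)solid nodule at/above 30 mm3 or 4 mm: 3-month follow-up",
    "NEW.INCIDENT_LT_THRESHOLD": "incident solid nodule below 30 mm3: regular 12-month screening",
    "NEW.INCIDENT_NONSOLID": "incident non-solid nodule: regular 12-month screening",
    "NEW.RECHECK_GROWTH": "new-nodule 3-month recheck grew substantially: workup",
    "NEW.RECHECK_STABLE": "new-nodule 3-month recheck stable: 12-month screening",
    # participant aggregation
    "PARTICIPANT.SHORTEST_INTERVAL": "shortest follow-up interval / strongest action governs",
    "PARTICIPANT.BENIGN_IGNORED": "clearly benign nodules do not affect management",
}
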
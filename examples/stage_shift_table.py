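"""Worst-case stage-shift VDTs and the new-nodule growth table.

A baseline T1a nodule shifts to stage T1c (>= 20 mm effective diameter,
sphere volume ~4189 mm3) within its follow-up interval only if its VDT is
at or below a boundary value.  The same arithmetic bounds how fast a
truly new nodule must have grown from below the scanner detection limit.
"""

from nodulekit import new_nodule_vdt_table, worst_case_stage_shift_vdt

for v0, t, label in [
    (100.0, 365.0, "100 mm3 nodule, 1-year follow-up"),
    (250.0, 182.5, "250 mm3 nodule, 6-month follow-up"),
    (500.0, 91.25, "500 mm3 nodule, 3-month follow-up"),
    (30.0, 365.0, "30 mm3 new nodule, 1-year follow-up"),
]:
    vdt = worst_case_stage_shift_vdt(v0, t)
    print(f"{label}: reaches T1c only if VDT <= {vdt:.0f} days")

print("\nSlowest VDT (days) for a new nodule to reach its detected size")
print("(rows: interval x assumed detection limit; columns: detected size, mm3)")
print(new_nodule_vdt_table().to_string())
print("\n-> a 30 mm3 nodule appearing at a 3-month screen implies a VDT of "
      "31 days or faster (4 mm3 detection limit): far likelier infection "
      "than cancer.")
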
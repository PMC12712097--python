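"""Compare growth-threshold policies on a synthetic slow-growing cohort.

Simulates benign/indolent nodules (true VDT >= 600 days, so every workup
referral is a false positive) at the category-boundary baseline volumes,
measured with 15% volumetric repeatability noise at a 3-month follow-up.
Interval-keyed VDT thresholds keep false-positive referrals rare; a flat
600-day threshold refers many slow growers at short intervals.
"""

from nodulekit import run_policy
from nodulekit.simulate import slow_growing_cohort

cohort = slow_growing_cohort(5000, seed=7)
print(f"cohort: {len(cohort)} nodules, true VDT 600-2000 d, "
      "scans at 0 and 91.25 days\n")
for policy in ("esti_interval_vdt", "constant_600_vdt"):
    out = run_policy(cohort, policy)
    print(f"{policy:22s}: {out.n_workup_referrals:4d} referrals "
          f"({100 * out.fp_rate:.1f}% false positives)")

# the diameter rule's weakness shows in the worst case: border-of-high
# nodules followed at 3 months and then a year
worst = slow_growing_cohort(5000, seed=8, baseline_volumes_mm3=(499.0,),
                            scan_times_days=(0.0, 91.25, 456.25))
for policy in ("esti_interval_vdt", "diameter_lungrads_like"):
    out = run_policy(worst, policy)
    print(f"{policy:22s}: {out.n_workup_referrals:4d} referrals "
          f"({100 * out.fp_rate:.1f}% false positives) [worst-case cohort]")
print("\n-> lowering the VDT threshold at short intervals (250 d at 3 months) "
      "absorbs measurement error; flat-threshold and caliper-based rules "
      "send many benign nodules to workup.")
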
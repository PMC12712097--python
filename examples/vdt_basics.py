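"""Estimate volume doubling times and their measurement-error bounds.

A nodule measured at 100 mm3 that reaches 200 mm3 after 100 days has
doubled once, so its VDT is 100 days.  With more than two scans a
least-squares exponential fit uses all timepoints.  Because volumetry
carries a ~15% repeatability error, a VDT measured over a short interval
has wide, asymmetric confidence bounds — for slow growers they can extend
across infinity, meaning growth cannot be told from shrinkage.
"""

from nodulekit import ErrorModel, vdt_ci, vdt_fit, vdt_two_point

est = vdt_two_point(100.0, 200.0, 100.0)
print(f"two-point VDT: {est.vdt_days:.0f} days (one doubling over 100 days)")

series = [(t, 100.0 * 2 ** (t / 200.0)) for t in (0.0, 91.0, 182.0, 365.0)]
fit = vdt_fit(series)
print(f"fitted VDT over {fit.n_timepoints} scans: {fit.vdt_days:.0f} days "
      "(noiseless series generated with VDT 200 d)")

em = ErrorModel()  # 15% volumetric / 1.5 mm caliper repeatability
fast = vdt_ci(70.0, 91.25, em)
slow = vdt_ci(600.0, 91.25, em)
print(f"95% CI for a true 70-day VDT at 3 months: "
      f"[{fast.lower_days:.0f}, {fast.upper_days:.0f}] days — fast growth is "
      "measurable even at short follow-up")
print(f"true 600-day VDT at 3 months: crosses infinity = "
      f"{slow.crosses_infinity} — a slow grower cannot be distinguished "
      "from a shrinking nodule after only 3 months")
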
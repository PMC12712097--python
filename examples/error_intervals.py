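"""Why volumetry beats calipers: confidence intervals for nodule size.

The repeatability coefficient (RC) is the 95% limit for the difference of
two repeated measurements; a single measurement has sigma = RC/(1.96*sqrt2).
Caliper diameters carry an RC of 1.5 mm regardless of nodule size, while
volumetry carries a relative RC of 15%, which translates into a small,
size-dependent error on the effective diameter (the equal-volume sphere
diameter).
"""

from nodulekit import (
    ErrorModel,
    ci_effective_diameter,
    ci_mean_diameter,
    ci_single_diameter,
    effective_diameter,
)

em = ErrorModel()
print(f"single caliper diameter:     +-{ci_single_diameter(em):.1f} mm (any size)")
print(f"mean of three calipers:      +-{ci_mean_diameter(em, 3):.1f} mm")
for v in (100.0, 250.0, 500.0):
    d = effective_diameter(v)
    ci = ci_effective_diameter(v, em)
    print(f"effective diameter of {v:5.0f} mm3 nodule: {d:4.1f} mm, CI +-{ci:.1f} mm")
print("-> volumetric effective diameters are 2-3x more precise than averaged "
      "caliper measurements, which is why volumetry is the primary size measure.")
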
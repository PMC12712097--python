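"""Volume-doubling-time (VDT) estimation and its measurement-error bounds.

Lung tumours are modelled as exponentially growing, so growth rate is
summarised by the volume doubling time

    VDT = t * lg 2 / lg(V / V0)

for volumes V0 at baseline and V after t days.  VDT is positive for growth,
negative for shrinkage, and unbounded (infinite) for a constant volume.
With three or more timepoints the VDT is estimated by an ordinary
least-squares fit of log volume against time (the exponential-growth fit);
with two timepoints the closed form above is used.

Measurement error in the volume ratio V/V0 is modelled as Gaussian around
the true ratio with 95% half-width equal to the volumetry repeatability
coefficient (each of the two measurements contributes sigma = RC/(1.96
sqrt 2), and the half-widths add in quadrature back to RC).  Because of the
logarithm, the resulting VDT confidence interval is asymmetric — wider
above than below — and for slow growth over short intervals the lower ratio
bound can fall below 1, in which case the interval "extends across
infinity": growth cannot be distinguished from shrinkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .measurement import ErrorModel, sigma_single

__all__ = [
    "VdtEstimate",
    "VdtInterval",
    "vdt_two_point",
    "vdt_from_ratio",
    "vdt_fit",
    "diameter_growth",
    "ratio_ci",
    "vdt_ci",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class VdtEstimate:
    """A VDT point estimate.

    ``vdt_days`` is signed: positive for growth, negative for shrinkage,
    ``math.inf`` when the volume did not change (no measurable growth).
    """

    vdt_days: float
    method: str  # "two_point" | "fit" | "manual_diameter"
    n_timepoints: int
    t_span_days: float

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise InvalidInputError("a VDT needs at least 2 timepoints")
        if not self.t_span_days > 0:
            raise InvalidInputError("t_span_days must be positive")

    @property
    def is_unbounded(self) -> bool:
        return math.isinf(self.vdt_days)

    @property
    def is_growth(self) -> bool:
        return self.vdt_days > 0 and not self.is_unbounded

    @property
    def is_shrinkage(self) -> bool:
        return self.vdt_days < 0 and not math.isinf(self.vdt_days)


def vdt_from_ratio(ratio: float, t_days: float) -> float:
    """Signed VDT (days) from a volume ratio V/V0 over ``t_days``."""
    if not ratio > 0:
        raise InvalidInputError(f"volume ratio must be positive, got {ratio!r}")
    if not t_days > 0:
        raise InvalidInputError(f"t_days must be positive, got {t_days!r}")
    if ratio == 1.0:
        return math.inf
    return t_days * _LN2 / math.log(ratio)


def vdt_two_point(v0_mm3: float, v_mm3: float, t_days: float) -> VdtEstimate:
    """Two-timepoint VDT: ``t * lg2 / lg(V/V0)``.

    >>> vdt_two_point(100, 200, 100).vdt_days
    100.0
    """
    if not (v0_mm3 > 0 and v_mm3 > 0):
        raise InvalidInputError("volumes must be positive")
    if not t_days > 0:
        raise InvalidInputError("t_days must be positive")
    return VdtEstimate(
        vdt_days=vdt_from_ratio(v_mm3 / v0_mm3, t_days),
        method="two_point",
        n_timepoints=2,
        t_span_days=float(t_days),
    )


def vdt_fit(series: Sequence[Tuple[float, float]]) -> VdtEstimate:
    """VDT from a least-squares line through (t, log volume).

    ``series`` is a list of ``(t_days, volume_mm3)`` with strictly
    increasing times and positive volumes.  With exactly two points this
    reduces to :func:`vdt_two_point`; a zero fitted slope yields an
    unbounded VDT.
    """
    pts = [(float(t), float(v)) for t, v in series]
    if len(pts) < 2:
        raise InvalidInputError("vdt_fit needs at least 2 timepoints")
    ts = np.array([t for t, _ in pts])
    vs = np.array([v for _, v in pts])
    if np.any(vs <= 0):
        raise InvalidInputError("volumes must be positive")
    if np.any(np.diff(ts) <= 0):
        raise InvalidInputError("timepoints must be strictly increasing (no duplicates)")
    if len(pts) == 2:
        est = vdt_two_point(vs[0], vs[1], ts[1] - ts[0])
        return VdtEstimate(est.vdt_days, "two_point", 2, est.t_span_days)
    # OLS slope of ln V on t; VDT = ln2 / slope
    tc = ts - ts.mean()
    y = np.log(vs)
    slope = float(tc @ (y - y.mean()) / (tc @ tc))
    vdt = math.inf if slope == 0.0 else _LN2 / slope
    return VdtEstimate(
        vdt_days=vdt,
        method="fit",
        n_timepoints=len(pts),
        t_span_days=float(ts[-1] - ts[0]),
    )


def diameter_growth(d0_mm: float, d1_mm: float, t_days: float) -> Tuple[float, float]:
    """Diameter change and annualised growth rate.

    Returns ``(delta_mm, mm_per_year)`` with ``delta = d1 - d0`` and
    ``rate = delta * 365 / t``.  For intervals shorter than a year the raw
    delta over the longest available interval is what threshold tests use.
    """
    if not (d0_mm > 0 and d1_mm > 0):
        raise InvalidInputError("diameters must be positive")
    if not t_days > 0:
        raise InvalidInputError("t_days must be positive")
    delta = d1_mm - d0_mm
    return delta, delta * 365.0 / t_days


def ratio_ci(t_days: float, error_model: ErrorModel) -> float:
    """Relative 95% half-width of the measured volume ratio V/V0.

    Two independent volumetric measurements each carry sigma =
    RC/(coverage sqrt 2); their combined 95% half-width is
    ``coverage * sqrt(2) * sigma``, which equals the volumetric RC itself.
    Independent of ``t_days`` (kept in the signature for interface
    symmetry with :func:`vdt_ci`).
    """
    if not t_days > 0:
        raise InvalidInputError("t_days must be positive")
    return error_model.coverage * math.sqrt(2.0) * sigma_single(error_model, "volume")


@dataclass(frozen=True)
class VdtInterval:
    """95% confidence set for a VDT.

    When ``crosses_infinity`` is False the set is the ordinary interval
    ``[lower_days, upper_days]``.  When True the measured ratio's lower
    bound fell at or below 1 while the point estimate indicates growth (or
    vice versa): the set is ``{VDT >= lower_days} | {VDT <= upper_days}``
    with ``upper_days`` negative (shrinkage branch) — growth cannot be
    distinguished from shrinkage at this follow-up time.
    """

    point: VdtEstimate
    lower_days: float
    upper_days: float
    crosses_infinity: bool

    @property
    def width_days(self) -> float:
        if self.crosses_infinity:
            return math.inf
        return self.upper_days - self.lower_days

    def contains(self, vdt_days: float) -> bool:
        """Membership of a signed VDT (inf counts as 'no growth')."""
        if self.crosses_infinity:
            # {VDT >= lower} U {infinite} U {VDT <= upper (negative)}
            if math.isinf(vdt_days):
                return True
            return vdt_days >= self.lower_days or vdt_days <= self.upper_days
        if math.isinf(vdt_days):
            return math.isinf(self.upper_days) or math.isinf(self.lower_days)
        return self.lower_days <= vdt_days <= self.upper_days


def vdt_ci(
    true_vdt_days: float, t_days: float, error_model: ErrorModel
) -> VdtInterval:
    """95% confidence set for the VDT measured over ``t_days`` when the true
    VDT is ``true_vdt_days``.

    The true ratio ``r = 2**(t/VDT)`` is perturbed multiplicatively to
    ``r * (1 +- ratio_ci)`` and each bound is mapped through the VDT
    formula.  The upper VDT margin is wider than the lower (logarithm
    convexity); if the lower ratio bound reaches 1 the set crosses
    infinity.
    """
    if not t_days > 0:
        raise InvalidInputError("t_days must be positive")
    if true_vdt_days == 0:
        raise InvalidInputError("true VDT cannot be zero")
    r = 2.0 ** (t_days / true_vdt_days) if not math.isinf(true_vdt_days) else 1.0
    eps = ratio_ci(t_days, error_model)
    point = VdtEstimate(
        vdt_days=float(true_vdt_days),
        method="two_point",
        n_timepoints=2,
        t_span_days=float(t_days),
    )
    if eps == 0.0:
        return VdtInterval(point, true_vdt_days, true_vdt_days, False)
    r_hi = r * (1.0 + eps)
    r_lo = r * (1.0 - eps)
    if r_lo <= 0:
        raise InvalidInputError("ratio error >= 100%: lower ratio bound non-positive")
    v_hi = vdt_from_ratio(r_hi, t_days)  # faster-growth bound
    v_lo = vdt_from_ratio(r_lo, t_days)  # slower-growth / shrinkage bound
    crosses = (r > 1.0 and r_lo <= 1.0) or (r < 1.0 and r_hi >= 1.0) or r == 1.0
    if crosses:
        # growth branch bound and shrinkage branch bound
        grow = min(x for x in (v_hi, v_lo) if x > 0)
        shrink_candidates = [x for x in (v_hi, v_lo) if x < 0]
        shrink = max(shrink_candidates) if shrink_candidates else -math.inf
        return VdtInterval(point, grow, shrink, True)
    lower, upper = sorted((v_hi, v_lo))
    return VdtInterval(point, lower, upper, False)
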
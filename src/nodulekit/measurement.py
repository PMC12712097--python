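"""Size representations, volume/diameter conversions, and the
repeatability-based confidence-interval calculus.

Nodule size is primarily measured by CT volumetry (mm³).  Volumes are
translated to *effective diameters* — the diameter of a sphere of equal
volume — for comparison with diameter-based guidelines and T staging.  If
segmentation fails, three orthogonal caliper diameters are averaged instead.

Measurement error is parameterised by the repeatability coefficient (RC),
the 95% limit for the difference between two repeated measurements of the
same quantity.  RC relates to the standard deviation sigma of a single
measurement by ``RC = 1.96 * sqrt(2) * sigma``.  The RC is *relative* for
volumetry (default 15% for well-segmented nodules) and *absolute* for manual
diameters (default 1.5 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Tuple

from .errors import InvalidInputError

__all__ = [
    "SegQuality",
    "Method",
    "SizeMeasurement",
    "ErrorModel",
    "effective_diameter",
    "sphere_volume",
    "average_diameter",
    "sigma_single",
    "ci_single_diameter",
    "ci_mean_diameter",
    "ci_effective_diameter",
    "report_mm",
    "report_days",
]


class SegQuality(str, Enum):
    """Five-level visual grade of a volumetry segmentation.

    ``poor`` (segmented volume not representative, mismatch > 20%) and
    ``failure`` (no usable segmentation) count as volumetry failure and
    force manual diameter measurement.
    """

    EXCELLENT = "excellent"
    GOOD = "good"
    SATISFACTORY = "satisfactory"
    POOR = "poor"
    FAILURE = "failure"


#: grades at which a volumetric measurement is usable
VOLUMETRY_USABLE = frozenset(
    {SegQuality.EXCELLENT, SegQuality.GOOD, SegQuality.SATISFACTORY}
)


class Method(str, Enum):
    VOLUMETRY = "volumetry"
    MANUAL = "manual"


def _positive(name: str, value: float) -> float:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise InvalidInputError(f"{name} must be a positive finite number, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class SizeMeasurement:
    """One observation of one nodule component at one timepoint.

    Parameters
    ----------
    t_days
        Days since the baseline scan (>= 0).
    volume_mm3
        Segmented volume in mm³, if volumetry was attempted.
    diameters_mm
        Three orthogonal caliper diameters (two axial + craniocaudal) in mm,
        if manual measurement was performed.
    seg_quality
        Visual grade of the segmentation (required for volumetry).
    method
        Which measurement drives size assessment at this timepoint.
    """

    t_days: float
    volume_mm3: Optional[float] = None
    diameters_mm: Optional[Tuple[float, float, float]] = None
    seg_quality: Optional[SegQuality] = None
    method: Method = Method.VOLUMETRY

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_days) and self.t_days >= 0):
            raise InvalidInputError(f"t_days must be >= 0, got {self.t_days!r}")
        if self.volume_mm3 is None and self.diameters_mm is None:
            raise InvalidInputError(
                "a SizeMeasurement needs volume_mm3 and/or diameters_mm"
            )
        if self.volume_mm3 is not None:
            _positive("volume_mm3", self.volume_mm3)
        if self.diameters_mm is not None:
            if len(self.diameters_mm) != 3:
                raise InvalidInputError(
                    f"diameters_mm must have exactly 3 entries, got {len(self.diameters_mm)}"
                )
            for d in self.diameters_mm:
                _positive("diameter", d)
        method = Method(self.method)
        object.__setattr__(self, "method", method)
        if self.seg_quality is not None:
            object.__setattr__(self, "seg_quality", SegQuality(self.seg_quality))
        if method is Method.VOLUMETRY:
            if self.volume_mm3 is None:
                raise InvalidInputError("method=volumetry requires volume_mm3")
            if self.seg_quality is not None and self.seg_quality not in VOLUMETRY_USABLE:
                raise InvalidInputError(
                    f"method=volumetry requires seg_quality in "
                    f"{{excellent, good, satisfactory}}, got {self.seg_quality.value}"
                )
        elif method is Method.MANUAL:
            if self.diameters_mm is None:
                raise InvalidInputError("method=manual requires diameters_mm")

    @property
    def average_diameter_mm(self) -> Optional[float]:
        if self.diameters_mm is None:
            return None
        return average_diameter(self.diameters_mm)

    @property
    def effective_diameter_mm(self) -> Optional[float]:
        if self.volume_mm3 is None:
            return None
        return effective_diameter(self.volume_mm3)

    def size_mm(self) -> float:
        """Diameter-scale size by the active method (effective or average)."""
        if self.method is Method.VOLUMETRY:
            return effective_diameter(self.volume_mm3)
        return average_diameter(self.diameters_mm)


@dataclass(frozen=True)
class ErrorModel:
    """Repeatability coefficients and coverage factor of the measurement
    error model.

    ``rc_volume_rel`` is the relative (fractional) RC of a volumetric
    measurement; ``rc_diameter_mm`` the absolute RC of a single caliper
    diameter.  ``coverage`` is the normal coverage factor for the 95% level.
    Zero RCs describe an idealised error-free measurement and are accepted.
    """

    rc_volume_rel: float = 0.15
    rc_diameter_mm: float = 1.5
    coverage: float = 1.96

    def __post_init__(self) -> None:
        for name in ("rc_volume_rel", "rc_diameter_mm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidInputError(f"{name} must be >= 0, got {v!r}")
        _positive("coverage", self.coverage)


def effective_diameter(volume_mm3: float) -> float:
    """Diameter (mm) of the sphere with volume ``volume_mm3``: (6 V / pi)^(1/3).

    >>> round(effective_diameter(100.0), 1)
    5.8
    """
    v = _positive("volume_mm3", volume_mm3)
    return (6.0 * v / math.pi) ** (1.0 / 3.0)


def sphere_volume(diameter_mm: float) -> float:
    """Volume (mm³) of a sphere of the given diameter: pi/6 d³."""
    d = _positive("diameter_mm", diameter_mm)
    return math.pi / 6.0 * d**3


def average_diameter(diameters_mm: Iterable[float]) -> float:
    """Arithmetic mean of three orthogonal caliper diameters (mm)."""
    ds = tuple(diameters_mm)
    if len(ds) != 3:
        raise InvalidInputError(f"expected 3 diameters, got {len(ds)}")
    return sum(_positive("diameter", d) for d in ds) / 3.0


def sigma_single(error_model: ErrorModel, mode: str) -> float:
    """Standard deviation of a single measurement, ``RC / (coverage sqrt 2)``.

    ``mode='volume'`` returns a relative fraction; ``mode='diameter'``
    returns mm.
    """
    if mode == "volume":
        rc = error_model.rc_volume_rel
    elif mode == "diameter":
        rc = error_model.rc_diameter_mm
    else:
        raise InvalidInputError(f"mode must be 'volume' or 'diameter', got {mode!r}")
    return rc / (error_model.coverage * math.sqrt(2.0))


def ci_single_diameter(error_model: ErrorModel) -> float:
    """95% CI half-width (mm) of a single caliper diameter: RC / sqrt 2.

    Size-independent; +-1.1 mm at the default 1.5-mm RC.
    """
    return error_model.coverage * sigma_single(error_model, "diameter")


def ci_mean_diameter(error_model: ErrorModel, n: int = 3) -> float:
    """95% CI half-width (mm) of the mean of ``n`` independent caliper
    diameters; the single-measurement CI shrinks by sqrt(n)."""
    if not (isinstance(n, int) and n >= 1):
        raise InvalidInputError(f"n must be an integer >= 1, got {n!r}")
    return ci_single_diameter(error_model) / math.sqrt(n)


def ci_effective_diameter(
    volume_mm3: float, error_model: ErrorModel, exact: bool = False
) -> float:
    """95% CI half-width (mm) of the effective diameter derived from one
    volumetric measurement.

    With relative volume half-width ``e = rc_volume_rel / sqrt 2``, the
    cube root linearises to a relative diameter half-width of ``e / 3``
    (default).  ``exact=True`` uses the asymmetric exact bounds
    ``(1 +- e)^(1/3)`` and returns the half-span of the resulting interval.
    The relative half-width is size-independent; the absolute one grows
    with the nodule.
    """
    d = effective_diameter(volume_mm3)
    e = error_model.rc_volume_rel / math.sqrt(2.0)
    if exact:
        if e >= 1.0:
            raise InvalidInputError("relative volume error >= 100%; exact bounds undefined")
        return d * ((1.0 + e) ** (1 / 3) - (1.0 - e) ** (1 / 3)) / 2.0
    return d * e / 3.0


def report_mm(value_mm: float) -> float:
    """Round a millimetre value to the one-decimal reporting convention.

    Threshold comparisons always use unrounded values; this is for output.
    """
    return round(float(value_mm), 1)


def report_days(value_days: float) -> float:
    """Round a day count to the nearest whole day for reporting.

    Halves round away from zero (182.5 d reports as 183 d).
    """
    if math.isinf(value_days):
        return value_days
    return math.copysign(math.floor(abs(value_days) + 0.5), value_days)
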
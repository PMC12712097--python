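"""Worst-case stage-shift VDTs, the new-nodule VDT table, and calibration
of interval-dependent VDT thresholds.

A *major stage shift* during screening follow-up is a baseline T1a tumour
(< 1 cm) that progresses to stage T1c or higher (>= 2 cm effective
diameter) before the next scan.  For a nodule entering follow-up at volume
V0, the fastest growth compatible with staying below T1c over an interval
t is the VDT at which V0 just reaches the volume of a 20-mm sphere — any
lesion with a shorter (or equal) VDT shifts stage within the interval.

The same boundary-VDT arithmetic produces the new-nodule table: a nodule
absent at the prior scan must have grown from below the scanner detection
limit (conservatively 4 mm³; 15 mm³ for older low-dose protocols) to its
detected size within the screening interval, so each (initial size,
interval, detected size) cell gives the *slowest* VDT able to produce the
observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, InvalidInputError
from .kinetics import ratio_ci, vdt_ci, vdt_two_point
from .measurement import ErrorModel, report_days, sphere_volume

__all__ = [
    "StageThresholds",
    "DAYS_PER_MONTH",
    "worst_case_stage_shift_vdt",
    "new_nodule_vdt_table",
    "calibrate_vdt_threshold",
    "growth_factor_over_interval",
]

#: calendar month used for interval conversion (3 mo = 91.25 d, 6 mo = 182.5 d)
DAYS_PER_MONTH = 365.0 / 12.0


@dataclass(frozen=True)
class StageThresholds:
    """Tumour-size stage boundaries used for stage-shift reasoning.

    T1a < 10 mm <= T1b < 20 mm <= T1c; the T1c boundary volume is the
    sphere volume of the 20-mm effective diameter.
    """

    t1c_diameter_mm: float = 20.0
    t1b_diameter_mm: float = 10.0

    @property
    def t1c_volume_mm3(self) -> float:
        return sphere_volume(self.t1c_diameter_mm)

    @property
    def t1b_volume_mm3(self) -> float:
        return sphere_volume(self.t1b_diameter_mm)


def worst_case_stage_shift_vdt(
    v0_mm3: float,
    t_days: float,
    stage: StageThresholds = StageThresholds(),
) -> float:
    """Boundary VDT (days, nearest-day rounded) at which a nodule of
    baseline volume ``v0_mm3`` reaches the T1c sphere volume within
    ``t_days``.

    Any lesion growing with a VDT at or below the returned value exceeds
    the T1c boundary within the interval.

    >>> worst_case_stage_shift_vdt(100, 365)
    68.0
    """
    target = stage.t1c_volume_mm3
    if not v0_mm3 > 0:
        raise InvalidInputError("baseline volume must be positive")
    if v0_mm3 >= target:
        raise InvalidInputError(
            f"baseline volume {v0_mm3} mm3 already at or above the T1c volume "
            f"({target:.2f} mm3)"
        )
    return report_days(vdt_two_point(v0_mm3, target, t_days).vdt_days)


#: Table defaults: detection-limit initial sizes, screening intervals, and
#: detected-size columns of the published new-nodule VDT table.
DEFAULT_INITIAL_SIZES_MM3: Tuple[float, ...] = (4.0, 15.0)
DEFAULT_INTERVALS_MONTHS: Tuple[float, ...] = (3.0, 6.0, 12.0)
DEFAULT_DETECTED_SIZES_MM3: Tuple[float, ...] = (30.0, 100.0, 250.0, 500.0)


def new_nodule_vdt_table(
    initial_sizes_mm3: Sequence[float] = DEFAULT_INITIAL_SIZES_MM3,
    intervals_months: Sequence[float] = DEFAULT_INTERVALS_MONTHS,
    detected_sizes_mm3: Sequence[float] = DEFAULT_DETECTED_SIZES_MM3,
) -> pd.DataFrame:
    """Slowest VDT (days) able to grow each initial size to each detected
    size within each screening interval.

    Rows are indexed by (interval months, initial size mm³); columns are
    detected sizes.  Cells are rounded to the nearest day.  The defaults
    reproduce the published 24-cell table.
    """
    for s in tuple(initial_sizes_mm3) + tuple(detected_sizes_mm3):
        if not s > 0:
            raise InvalidInputError(f"sizes must be positive, got {s!r}")
    for m in intervals_months:
        if not m > 0:
            raise InvalidInputError(f"intervals must be positive, got {m!r}")
    rows = []
    index = []
    for months in intervals_months:
        t_days = months * DAYS_PER_MONTH
        for v0 in initial_sizes_mm3:
            cells = []
            for v in detected_sizes_mm3:
                if v <= v0:
                    raise InvalidInputError(
                        f"detected size {v} mm3 must exceed initial size {v0} mm3"
                    )
                cells.append(report_days(vdt_two_point(v0, v, t_days).vdt_days))
            rows.append(cells)
            index.append((months, v0))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(
            index, names=["interval_months", "initial_mm3"]
        ),
        columns=pd.Index(list(detected_sizes_mm3), name="detected_mm3"),
    )


def calibrate_vdt_threshold(
    t_days: float,
    error_model: ErrorModel,
    target_upper_days: float = 600.0,
) -> float:
    """Measured-VDT threshold whose 95% CI upper bound equals
    ``target_upper_days`` at follow-up time ``t_days``.

    A referral rule "measured VDT < threshold" with this threshold keeps
    the upper confidence limit of referred lesions at the target (600 days
    by default, the slow-growing boundary), so that few lesions with a true
    VDT beyond the target are sent to workup.  Monotone increasing in
    ``t_days``: shorter follow-up forces a lower threshold.

    This is a companion/analysis tool: the shipped policy uses the stated
    250/400/500-day thresholds verbatim.
    """
    if not t_days > 0:
        raise InvalidInputError("t_days must be positive")
    if not target_upper_days > 0:
        raise InvalidInputError("target_upper_days must be positive")
    eps = ratio_ci(t_days, error_model)
    if eps == 0.0:
        return float(target_upper_days)
    if eps >= 1.0:
        raise CalibrationError("ratio error >= 100%: no finite upper CI bound exists")

    # the upper bound is finite only while the lower ratio bound stays
    # above 1, i.e. for measured VDT below t ln2 / (-ln(1-eps))
    x_cross = t_days * math.log(2.0) / (-math.log(1.0 - eps))

    def upper_minus_target(x: float) -> float:
        return vdt_ci(x, t_days, error_model).upper_days - target_upper_days

    # lower bracket small enough that upper(x) ~ x < target, but large
    # enough that 2**(t/x) stays within float range
    lo = t_days / 500.0
    hi = x_cross * (1.0 - 1e-12)
    if upper_minus_target(lo) > 0 or upper_minus_target(hi) < 0:
        raise CalibrationError(
            f"no VDT threshold in (0, {x_cross:.1f}) d has CI upper bound "
            f"{target_upper_days} d at t = {t_days} d"
        )
    return float(brentq(upper_minus_target, lo, hi, xtol=1e-9))


def growth_factor_over_interval(vdt_days: float, t_days: float) -> Tuple[float, float]:
    """Volume and effective-diameter growth factors over ``t_days`` for a
    nodule growing with doubling time ``vdt_days``.

    Returns ``(volume_ratio, diameter_ratio)`` with
    ``volume_ratio = 2**(t/VDT)`` and the diameter ratio its cube root.
    """
    if not t_days > 0:
        raise InvalidInputError("t_days must be positive")
    if vdt_days == 0:
        raise InvalidInputError("vdt_days cannot be zero")
    ratio = 1.0 if math.isinf(vdt_days) else 2.0 ** (t_days / vdt_days)
    return ratio, ratio ** (1.0 / 3.0)
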
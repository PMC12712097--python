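"""Policy configuration: size cut-offs, growth thresholds, and the error
model, with canonical JSON (de)serialisation.

The defaults encode the European screening recommendation: volumetric size
categories at 100/250/500 mm³ (manual-diameter fallback 6/8/10 mm),
interval-keyed VDT thresholds of 250 d at 3 months, 400 d at 6 months and
500 d at >= 12 months, a 1.5-mm manual growth threshold, a 5-mm cumulative
diameter change triggering multidisciplinary-team referral, and a 30-mm³
(4-mm) threshold for truly new nodules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

from .errors import ConfigurationError
from .measurement import ErrorModel

__all__ = ["PolicyConfig", "DEFAULT_POLICY"]


@dataclass(frozen=True)
class PolicyConfig:
    """Tunable thresholds of the management policy.

    ``vdt_thresholds_days`` maps follow-up interval (days since the
    previous scan) to the VDT below which growth is *substantial*; lookups
    use the nearest scheduled interval and intervals at or beyond the
    longest key use that key's threshold (the ">= 12 months" rule).
    """

    volume_cutoffs_mm3: Tuple[float, float, float] = (100.0, 250.0, 500.0)
    diameter_cutoffs_mm: Tuple[float, float, float] = (6.0, 8.0, 10.0)
    vdt_thresholds_days: Dict[float, float] = field(
        default_factory=lambda: {91.25: 250.0, 182.5: 400.0, 365.0: 500.0}
    )
    manual_growth_mm: float = 1.5
    mdt_cumulative_mm: float = 5.0
    mdt_comparator: str = "ge"  # "ge" (at least 5 mm) or "gt" (more than 5 mm)
    new_nodule_volume_mm3: float = 30.0
    new_nodule_diameter_mm: float = 4.0
    part_solid_reclass_fraction: float = 0.80
    airway_bronchus_cutoff_mm: float = 6.0
    error_model: ErrorModel = field(default_factory=ErrorModel)

    def __post_init__(self) -> None:
        if list(self.volume_cutoffs_mm3) != sorted(self.volume_cutoffs_mm3) or min(
            self.volume_cutoffs_mm3
        ) <= 0:
            raise ConfigurationError("volume cut-offs must be positive and increasing")
        if list(self.diameter_cutoffs_mm) != sorted(self.diameter_cutoffs_mm) or min(
            self.diameter_cutoffs_mm
        ) <= 0:
            raise ConfigurationError("diameter cut-offs must be positive and increasing")
        if not self.vdt_thresholds_days:
            raise ConfigurationError("vdt_thresholds_days may not be empty")
        keys = sorted(self.vdt_thresholds_days)
        if keys[0] <= 0 or any(v <= 0 for v in self.vdt_thresholds_days.values()):
            raise ConfigurationError("VDT threshold intervals and values must be positive")
        if self.mdt_comparator not in ("ge", "gt"):
            raise ConfigurationError("mdt_comparator must be 'ge' or 'gt'")
        for name in ("manual_growth_mm", "mdt_cumulative_mm", "new_nodule_volume_mm3",
                     "new_nodule_diameter_mm", "airway_bronchus_cutoff_mm"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.part_solid_reclass_fraction < 1:
            raise ConfigurationError("part_solid_reclass_fraction must be in (0, 1)")

    def vdt_threshold(self, interval_days: float) -> float:
        """Substantial-growth VDT threshold for a follow-up interval.

        Intervals at or beyond the longest scheduled interval use its
        threshold; otherwise the nearest scheduled interval's threshold
        applies (ties resolve to the shorter interval).
        """
        if not interval_days > 0:
            raise ConfigurationError(
                f"interval must be positive, got {interval_days!r}"
            )
        keys = sorted(self.vdt_thresholds_days)
        if interval_days >= keys[-1]:
            return self.vdt_thresholds_days[keys[-1]]
        nearest = min(keys, key=lambda k: (abs(k - interval_days), k))
        return self.vdt_thresholds_days[nearest]

    def with_error_model(self, error_model: ErrorModel) -> "PolicyConfig":
        return replace(self, error_model=error_model)

    # -- canonical serialisation ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "airway_bronchus_cutoff_mm": self.airway_bronchus_cutoff_mm,
            "diameter_cutoffs_mm": list(self.diameter_cutoffs_mm),
            "error_model": {
                "coverage": self.error_model.coverage,
                "rc_diameter_mm": self.error_model.rc_diameter_mm,
                "rc_volume_rel": self.error_model.rc_volume_rel,
            },
            "manual_growth_mm": self.manual_growth_mm,
            "mdt_comparator": self.mdt_comparator,
            "mdt_cumulative_mm": self.mdt_cumulative_mm,
            "new_nodule_diameter_mm": self.new_nodule_diameter_mm,
            "new_nodule_volume_mm3": self.new_nodule_volume_mm3,
            "part_solid_reclass_fraction": self.part_solid_reclass_fraction,
            "vdt_thresholds_days": {
                str(k): self.vdt_thresholds_days[k]
                for k in sorted(self.vdt_thresholds_days)
            },
            "volume_cutoffs_mm3": list(self.volume_cutoffs_mm3),
        }

    def to_json(self) -> str:
        """Canonical JSON form (sorted keys, fixed separators)."""
        return json.dumps(self.to_dict(), sort_keys=True, separators=(", ", ": "),
                          indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PolicyConfig":
        d = dict(d)
        em = d.pop("error_model", None)
        kwargs = {}
        if em is not None:
            kwargs["error_model"] = ErrorModel(**em)
        if "vdt_thresholds_days" in d:
            kwargs["vdt_thresholds_days"] = {
                float(k): float(v) for k, v in d.pop("vdt_thresholds_days").items()
            }
        for key in ("volume_cutoffs_mm3", "diameter_cutoffs_mm"):
            if key in d:
                kwargs[key] = tuple(d.pop(key))
        known = cls.__dataclass_fields__
        for k, v in d.items():
            if k not in known:
                raise ConfigurationError(f"unknown policy field: {k!r}")
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PolicyConfig":
        return cls.from_dict(json.loads(text))


DEFAULT_POLICY = PolicyConfig()
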
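"""Synthetic longitudinal nodule cohorts and management-policy comparison.

Trajectories follow the exponential growth model ``V(t) = V0 * 2**(t/VDT)``
(an unbounded VDT means constant volume).  Measured volumes perturb the
true volume multiplicatively with Gaussian noise at the single-measurement
sigma of the error model (sigma = RC/(1.96 sqrt 2), 5.41% at the default
15% repeatability coefficient); measured diameters add Gaussian noise at
the diameter sigma to the true effective diameter.  Noise is truncated at
-90% so volumes stay positive.

Three growth-threshold policies are compared on identical noise draws:

``esti_interval_vdt``
    Interval-keyed VDT thresholds (250 d at 3 months, 400 d at 6 months,
    500 d at >= 12 months).
``constant_600_vdt``
    A single VDT < 600 d referral threshold at every interval (the
    European position-statement convention).
``diameter_lungrads_like``
    Referral on a > 1.5 mm increase of the average of two perpendicular
    caliper diameters (a Lung-RADS-style diameter rule).

A *false-positive referral* is a workup referral of a nodule whose true
VDT is >= 600 days (including non-growing and shrinking nodules); a
*stage shift* is a true volume at or above the T1c sphere volume at or
before the referral / the next screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .kinetics import vdt_fit
from .measurement import ErrorModel, Method, SizeMeasurement, effective_diameter, sigma_single
from .policy import DEFAULT_POLICY, PolicyConfig
from .stage_shift import StageThresholds

__all__ = [
    "TrajectorySpec",
    "PolicyOutcome",
    "POLICY_LABELS",
    "simulate_trajectory",
    "run_policy",
    "compare_policies",
    "slow_growing_cohort",
]

POLICY_LABELS = ("esti_interval_vdt", "constant_600_vdt", "diameter_lungrads_like")

#: slow-growing boundary: true VDT at or beyond this is a benign/indolent
#: lesion whose referral counts as a false positive
FALSE_POSITIVE_VDT_DAYS = 600.0


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground truth for one simulated nodule."""

    true_vdt_days: float  # signed; math.inf = constant volume
    baseline_volume_mm3: float
    scan_times_days: Tuple[float, ...] = (0.0, 91.25)
    noise: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_vdt_days == 0:
            raise InvalidInputError("true_vdt_days cannot be zero")
        if not self.baseline_volume_mm3 > 0:
            raise InvalidInputError("baseline_volume_mm3 must be positive")
        times = tuple(float(t) for t in self.scan_times_days)
        if len(times) < 2 or times[0] != 0.0 or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise InvalidInputError(
                "scan_times_days must start at 0 and strictly increase"
            )
        object.__setattr__(self, "scan_times_days", times)

    def true_volume(self, t_days: float) -> float:
        if math.isinf(self.true_vdt_days):
            return self.baseline_volume_mm3
        return self.baseline_volume_mm3 * 2.0 ** (t_days / self.true_vdt_days)


def _measured_volumes(spec: TrajectorySpec, rng: np.random.Generator) -> np.ndarray:
    true = np.array([spec.true_volume(t) for t in spec.scan_times_days])
    sigma = sigma_single(spec.noise, "volume")
    eps = rng.normal(0.0, sigma, size=true.shape) if sigma > 0 else np.zeros_like(true)
    eps = np.maximum(eps, -0.9)  # keep measured volumes positive
    return true * (1.0 + eps)


def _measured_diameters(
    spec: TrajectorySpec, rng: np.random.Generator, n_measurements: int
) -> np.ndarray:
    true_d = np.array(
        [effective_diameter(spec.true_volume(t)) for t in spec.scan_times_days]
    )
    sigma = sigma_single(spec.noise, "diameter")
    if sigma == 0:
        return true_d
    noise = rng.normal(0.0, sigma, size=(len(true_d), n_measurements))
    return true_d + noise.mean(axis=1)


def simulate_trajectory(spec: TrajectorySpec) -> List[SizeMeasurement]:
    """Measured volumetric observations of one nodule, one per scan time.

    Reproducible: the spec's seed fully determines the noise draws.
    """
    rng = np.random.default_rng(spec.seed)
    measured = _measured_volumes(spec, rng)
    return [
        SizeMeasurement(t_days=t, volume_mm3=float(v), method=Method.VOLUMETRY)
        for t, v in zip(spec.scan_times_days, measured)
    ]


@dataclass(frozen=True)
class PolicyOutcome:
    """Tallied outcomes of one policy over one cohort."""

    policy: str
    n_nodules: int
    n_workup_referrals: int
    n_false_positive_referrals: int
    n_stage_shift: int
    n_followup_scans: int

    def __post_init__(self) -> None:
        if not (
            0
            <= self.n_false_positive_referrals
            <= self.n_workup_referrals
            <= self.n_nodules
        ):
            raise InvalidInputError(
                "outcome counts must satisfy 0 <= FP <= referrals <= nodules"
            )

    @property
    def fp_rate(self) -> float:
        return self.n_false_positive_referrals / self.n_nodules

    @property
    def referral_rate(self) -> float:
        return self.n_workup_referrals / self.n_nodules


def _policy_config(policy: str, base: PolicyConfig) -> PolicyConfig:
    if policy == "esti_interval_vdt":
        return base
    if policy == "constant_600_vdt":
        return replace(
            base, vdt_thresholds_days={365.0: FALSE_POSITIVE_VDT_DAYS}
        )
    if policy == "diameter_lungrads_like":
        return base
    raise ConfigurationError(
        f"unknown policy {policy!r}; known: {', '.join(POLICY_LABELS)}"
    )


def _is_true_slow(spec: TrajectorySpec) -> bool:
    """True VDT at/above 600 d, non-growing or shrinking: a referral of
    this nodule is a false positive."""
    v = spec.true_vdt_days
    return math.isinf(v) or v < 0 or v >= FALSE_POSITIVE_VDT_DAYS


def run_policy(
    cohort: Sequence[TrajectorySpec],
    policy: str,
    base_policy: PolicyConfig = DEFAULT_POLICY,
    stage: StageThresholds = StageThresholds(),
    diameter_measurements: int = 2,
) -> PolicyOutcome:
    """Push every trajectory through a policy's growth criterion and tally
    referrals, false positives, stage shifts and follow-up scans.

    Each nodule is scanned at its spec's scan times until the policy's
    substantial-growth criterion fires (workup referral) or the schedule
    ends.  VDT policies estimate the VDT by least squares over all scans so
    far; the diameter policy compares the measured average diameter against
    baseline within a one-year window.
    """
    if not cohort:
        raise InvalidInputError("cohort may not be empty")
    cfg = _policy_config(policy, base_policy)
    use_diameter = policy == "diameter_lungrads_like"

    n_workup = n_fp = n_shift = n_scans = 0
    for spec in cohort:
        rng = np.random.default_rng(spec.seed)
        times = spec.scan_times_days
        volumes = _measured_volumes(spec, rng)
        diameters = (
            _measured_diameters(spec, rng, diameter_measurements)
            if use_diameter
            else None
        )

        referred_at: Optional[float] = None
        for i in range(1, len(times)):
            n_scans += 1
            if use_diameter:
                window = [j for j in range(i) if times[i] - times[j] <= 365.0]
                ref = window[0] if window else i - 1
                grew = (diameters[i] - diameters[ref]) > cfg.manual_growth_mm
            else:
                est = vdt_fit(list(zip(times[: i + 1], volumes[: i + 1])))
                threshold = cfg.vdt_threshold(times[i] - times[i - 1])
                grew = est.is_growth and est.vdt_days < threshold
            if grew:
                referred_at = times[i]
                break

        if referred_at is not None:
            n_workup += 1
            if _is_true_slow(spec):
                n_fp += 1
        horizon = referred_at if referred_at is not None else times[-1]
        if spec.true_volume(horizon) >= stage.t1c_volume_mm3:
            n_shift += 1

    return PolicyOutcome(
        policy=policy,
        n_nodules=len(cohort),
        n_workup_referrals=n_workup,
        n_false_positive_referrals=n_fp,
        n_stage_shift=n_shift,
        n_followup_scans=n_scans,
    )


def compare_policies(
    cohort: Sequence[TrajectorySpec],
    policies: Sequence[str] = POLICY_LABELS,
    replicates: int = 1,
    seed: int = 0,
    base_policy: PolicyConfig = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Per-policy mean and Monte-Carlo standard error of each outcome.

    Each replicate re-draws the measurement noise (fresh per-trajectory
    seeds derived from ``seed``); all policies within a replicate see the
    same noise.  Deterministic for a fixed seed and independent of the
    order in which policies are listed.
    """
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(replicates, len(cohort)))

    rows = []
    metrics = (
        "n_workup_referrals",
        "n_false_positive_referrals",
        "n_stage_shift",
        "n_followup_scans",
    )
    for policy in sorted(set(policies)):
        per_rep: Dict[str, List[float]] = {m: [] for m in metrics}
        for r in range(replicates):
            reseeded = [
                replace(s, seed=int(rep_seeds[r, i])) for i, s in enumerate(cohort)
            ]
            out = run_policy(reseeded, policy, base_policy=base_policy)
            for m in metrics:
                per_rep[m].append(getattr(out, m))
        row = {"policy": policy, "n_nodules": len(cohort), "replicates": replicates}
        for m in metrics:
            vals = np.array(per_rep[m], dtype=float)
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_se"] = (
                vals.std(ddof=1) / math.sqrt(replicates) if replicates > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("policy")


def slow_growing_cohort(
    n: int,
    seed: int,
    vdt_range_days: Tuple[float, float] = (600.0, 2000.0),
    baseline_volumes_mm3: Sequence[float] = (99.0, 249.0, 499.0),
    scan_times_days: Tuple[float, ...] = (0.0, 91.25),
    noise: ErrorModel = ErrorModel(),
) -> List[TrajectorySpec]:
    """Cohort of benign/indolent nodules (true VDT >= 600 d) at the
    worst-case category-boundary baseline volumes.

    Any workup referral from this cohort is by construction a false
    positive, so it isolates each policy's unnecessary-workup behaviour.
    VDTs are drawn log-uniformly over ``vdt_range_days``; baseline volumes
    cycle through the category boundaries (99/249/499 mm³ by default).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    lo, hi = vdt_range_days
    if not (lo >= FALSE_POSITIVE_VDT_DAYS and hi >= lo):
        raise InvalidInputError(
            f"vdt_range_days must lie within [{FALSE_POSITIVE_VDT_DAYS}, inf)"
        )
    rng = np.random.default_rng(seed)
    vdts = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        TrajectorySpec(
            true_vdt_days=float(vdts[i]),
            baseline_volume_mm3=float(
                baseline_volumes_mm3[i % len(baseline_volumes_mm3)]
            ),
            scan_times_days=scan_times_days,
            noise=noise,
            seed=int(seeds[i]),
        )
        for i in range(n)
    ]
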
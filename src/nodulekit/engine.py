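"""The nodule-management rule engine.

Implements the baseline/follow-up flowcharts of the European screening
recommendation for solid, part-solid, non-solid (ground-glass), cystic and
airway nodules, plus new-nodule handling and per-participant aggregation.

Baseline management uses nodule type, the size of the relevant component
(whole nodule if solid, solid component otherwise) and morphology: clearly
benign features end evaluation; suspicious features upgrade the size-based
risk category by one step.  Risk categories map to actions: very low ->
regular 12-month screening (negative screen), low -> 6-month follow-up,
intermediate -> 3-month follow-up (both indeterminate), high -> diagnostic
workup (positive screen).

At follow-up, growth drives management: shrinkage returns the nodule to
regular screening, substantial growth (interval-keyed VDT threshold, or a
>1.5-mm average-diameter increase when volumetry fails) triggers workup, a
cumulative effective/average diameter increase of >= 5 mm from baseline in
a slow grower triggers multidisciplinary-team (MDT) referral, and anything
else downgrades the risk category one step.

Every recommendation carries an ordered trace of the rule identifiers (see
:mod:`nodulekit.rules`) that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import List, Optional, Sequence, Tuple

from .errors import InvalidInputError
from .kinetics import VdtEstimate, vdt_fit
from .measurement import Method, SizeMeasurement, average_diameter, effective_diameter
from .policy import DEFAULT_POLICY, PolicyConfig

__all__ = [
    "NoduleType",
    "RiskCategory",
    "Action",
    "ScreenResult",
    "BronchusLocation",
    "NoduleContext",
    "NoduleRecord",
    "GrowthAssessment",
    "Recommendation",
    "SUSPICIOUS_TOKENS",
    "BENIGN_TOKENS",
    "size_category",
    "classify_baseline",
    "substantial_growth",
    "assess_followup",
    "assess_new_nodule",
    "classify_airway",
    "participant_management",
]


class NoduleType(str, Enum):
    SOLID = "solid"
    PART_SOLID = "part_solid"
    NON_SOLID = "non_solid"
    CYSTIC = "cystic"
    AIRWAY = "airway"


class RiskCategory(IntEnum):
    """Ordered risk of major stage shift within one year."""

    BENIGN = 0
    VERY_LOW = 1
    LOW = 2
    INTERMEDIATE = 3
    HIGH = 4

    def upgrade(self) -> "RiskCategory":
        """One step up; saturates at HIGH, BENIGN stays BENIGN."""
        if self is RiskCategory.BENIGN or self is RiskCategory.HIGH:
            return self
        return RiskCategory(self.value + 1)

    def downgrade(self) -> "RiskCategory":
        """One step down; saturates at VERY_LOW."""
        if self.value <= RiskCategory.VERY_LOW.value:
            return RiskCategory.VERY_LOW if self is not RiskCategory.BENIGN else self
        return RiskCategory(self.value - 1)


class Action(str, Enum):
    NONE_REGULAR_SCREENING = "none_regular_screening"
    FOLLOW_UP = "follow_up"
    WORKUP = "workup"
    MDT_REFERRAL = "mdt_referral"


class ScreenResult(str, Enum):
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"
    POSITIVE = "positive"


class BronchusLocation(str, Enum):
    TRACHEA_OR_PROXIMAL = "trachea_or_proximal"
    SEGMENTAL_OR_SMALLER = "segmental_or_smaller"


SUSPICIOUS_TOKENS = frozenset(
    {
        "spiculation",
        "architectural_distortion",
        "cystic_component",
        "bubble_lucencies",
        "concave_sign",
        "narrowed_vessels",
        "bronchial_cutoff",
        "gg_component_ge_30mm",
    }
)

BENIGN_TOKENS = frozenset(
    {
        "calcification_benign_pattern",
        "fat",
        "intrapulmonary_lymph_node",
        "thin_walled_cyst_lt_2mm",
        "tree_in_bud",
        "ild_pattern_gg",
        "multisegment_mucus",
        "airway_air_bubbles",
        "tracheal_drop_sign",
    }
)

#: benign signs specific to airway lesions
AIRWAY_BENIGN_TOKENS = frozenset(
    {"multisegment_mucus", "airway_air_bubbles", "tracheal_drop_sign"}
)


@dataclass(frozen=True)
class NoduleContext:
    """Non-morphology context flags of a nodule."""

    is_new: bool = False
    visible_in_retrospect: bool = False
    evident_growth: bool = False
    infectious_pattern_1mo: bool = False
    pneumonia_differential: bool = False
    bronchus_location: Optional[BronchusLocation] = None
    bronchus_diameter_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bronchus_location is not None:
            object.__setattr__(
                self, "bronchus_location", BronchusLocation(self.bronchus_location)
            )
        if self.bronchus_diameter_mm is not None and not self.bronchus_diameter_mm > 0:
            raise InvalidInputError("bronchus_diameter_mm must be positive")


def _check_series(name: str, series: Sequence[SizeMeasurement]) -> Tuple[SizeMeasurement, ...]:
    s = tuple(series)
    for a, b in zip(s, s[1:]):
        if b.t_days <= a.t_days:
            raise InvalidInputError(f"{name} timepoints must be strictly increasing")
    return s


@dataclass(frozen=True)
class NoduleRecord:
    """A nodule's type, morphology, context and time-ordered observations.

    ``total_series`` measures the whole nodule; ``solid_series`` the solid
    component, required for part-solid nodules (and cystic nodules with a
    nodular component).
    """

    id: str
    type: NoduleType
    total_series: Tuple[SizeMeasurement, ...]
    solid_series: Tuple[SizeMeasurement, ...] = ()
    morphology_suspicious: frozenset = frozenset()
    morphology_benign: frozenset = frozenset()
    morphology_changed: bool = False
    context: NoduleContext = field(default_factory=NoduleContext)

    def __post_init__(self) -> None:
        object.__setattr__(self, "type", NoduleType(self.type))
        total = _check_series("total_series", self.total_series)
        if not total:
            raise InvalidInputError(f"nodule {self.id!r}: total_series may not be empty")
        object.__setattr__(self, "total_series", total)
        object.__setattr__(
            self, "solid_series", _check_series("solid_series", self.solid_series)
        )
        for name, known in (
            ("morphology_suspicious", SUSPICIOUS_TOKENS),
            ("morphology_benign", BENIGN_TOKENS),
        ):
            tokens = frozenset(getattr(self, name))
            unknown = tokens - known
            if unknown:
                raise InvalidInputError(
                    f"nodule {self.id!r}: unknown {name} token(s): {sorted(unknown)}"
                )
            object.__setattr__(self, name, tokens)
        if self.type is NoduleType.PART_SOLID and not self.solid_series:
            raise InvalidInputError(
                f"nodule {self.id!r}: part-solid nodules require solid_series"
            )

    @property
    def n_timepoints(self) -> int:
        return len(self.total_series)

    def component_series(self) -> Tuple[SizeMeasurement, ...]:
        """The series driving management: solid component when present for
        subsolid/cystic nodules, otherwise the whole nodule."""
        if self.type in (NoduleType.PART_SOLID, NoduleType.CYSTIC, NoduleType.NON_SOLID):
            if self.solid_series:
                return self.solid_series
        return self.total_series

    def truncated(self, n: int) -> "NoduleRecord":
        """Copy keeping only the first ``n`` timepoints of each series."""
        cutoff = self.total_series[: n]
        t_max = cutoff[-1].t_days
        return replace(
            self,
            total_series=cutoff,
            solid_series=tuple(m for m in self.solid_series if m.t_days <= t_max),
        )


@dataclass(frozen=True)
class GrowthAssessment:
    """Growth summary of a nodule's relevant component at follow-up."""

    vdt: Optional[VdtEstimate]
    delta_avg_diameter_mm: float
    cumulative_delta_diameter_mm: float
    substantial: bool
    shrinking: bool
    method: Method
    morphology_changed: bool = False

    def __post_init__(self) -> None:
        if self.substantial and self.shrinking:
            raise InvalidInputError("substantial and shrinking are mutually exclusive")


@dataclass(frozen=True)
class Recommendation:
    """A management recommendation with its audit trail."""

    action: Action
    interval_months: Optional[float]
    screen_result: ScreenResult
    category: RiskCategory
    rule_trace: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rule_trace:
            raise InvalidInputError("rule_trace may not be empty")
        if self.action is Action.WORKUP and self.screen_result is not ScreenResult.POSITIVE:
            raise InvalidInputError("workup implies a positive screen result")


# -- size categorisation ---------------------------------------------------


def size_category(
    volume_mm3: Optional[float] = None,
    avg_diameter_mm: Optional[float] = None,
    policy: PolicyConfig = DEFAULT_POLICY,
) -> RiskCategory:
    """Risk category from size alone.

    Volumetry scale: <100 mm³ very low, [100, 250) low, [250, 500)
    intermediate, >=500 high.  Manual (average-diameter) scale: <6 mm very
    low, [6, 8) low, [8, 10) intermediate, >=10 mm high.  Exactly one of
    the two sizes must be given.
    """
    if (volume_mm3 is None) == (avg_diameter_mm is None):
        raise InvalidInputError("give exactly one of volume_mm3 / avg_diameter_mm")
    if volume_mm3 is not None:
        value, cuts = volume_mm3, policy.volume_cutoffs_mm3
    else:
        value, cuts = avg_diameter_mm, policy.diameter_cutoffs_mm
    if not value > 0:
        raise InvalidInputError("size must be positive")
    if value < cuts[0]:
        return RiskCategory.VERY_LOW
    if value < cuts[1]:
        return RiskCategory.LOW
    if value < cuts[2]:
        return RiskCategory.INTERMEDIATE
    return RiskCategory.HIGH


def _category_recommendation(
    category: RiskCategory, trace: List[str]
) -> Recommendation:
    """Map a risk category to its action/interval/screen-result triple."""
    trace = trace + ["BASE.CATEGORY_ACTION"]
    if category is RiskCategory.BENIGN:
        return Recommendation(
            Action.NONE_REGULAR_SCREENING, None, ScreenResult.NEGATIVE, category, tuple(trace)
        )
    if category is RiskCategory.VERY_LOW:
        return Recommendation(
            Action.FOLLOW_UP, 12, ScreenResult.NEGATIVE, category, tuple(trace)
        )
    if category is RiskCategory.LOW:
        return Recommendation(
            Action.FOLLOW_UP, 6, ScreenResult.INDETERMINATE, category, tuple(trace)
        )
    if category is RiskCategory.INTERMEDIATE:
        return Recommendation(
            Action.FOLLOW_UP, 3, ScreenResult.INDETERMINATE, category, tuple(trace)
        )
    return Recommendation(Action.WORKUP, None, ScreenResult.POSITIVE, category, tuple(trace))


def _one_month_recommendation(trace: List[str]) -> Recommendation:
    return Recommendation(
        Action.FOLLOW_UP, 1, ScreenResult.INDETERMINATE, RiskCategory.INTERMEDIATE,
        tuple(trace),
    )


def _measurement_size(m: SizeMeasurement) -> float:
    return m.size_mm()


def _solid_fraction(nodule: NoduleRecord) -> Optional[float]:
    """Solid-to-total diameter fraction at baseline, when both measurable
    by the same method (effective diameters for volumetry, averages for
    manual)."""
    if not nodule.solid_series:
        return None
    solid, total = nodule.solid_series[0], nodule.total_series[0]
    if solid.volume_mm3 is not None and total.volume_mm3 is not None:
        return effective_diameter(solid.volume_mm3) / effective_diameter(total.volume_mm3)
    if solid.diameters_mm is not None and total.diameters_mm is not None:
        return average_diameter(solid.diameters_mm) / average_diameter(total.diameters_mm)
    return None


# -- baseline --------------------------------------------------------------


def classify_baseline(
    nodule: NoduleRecord, policy: PolicyConfig = DEFAULT_POLICY
) -> Recommendation:
    """Management recommendation for a nodule at its baseline scan."""
    if nodule.type is NoduleType.AIRWAY:
        return classify_airway(nodule, policy)

    trace: List[str] = []

    # clearly benign morphology ends evaluation (and beats suspicious flags)
    if "thin_walled_cyst_lt_2mm" in nodule.morphology_benign:
        trace.append("BASE.THIN_WALLED_CYST")
        return Recommendation(
            Action.NONE_REGULAR_SCREENING, None, ScreenResult.NEGATIVE,
            RiskCategory.BENIGN, tuple(trace),
        )
    if nodule.morphology_benign:
        trace.append("BASE.BENIGN_MORPHOLOGY")
        return Recommendation(
            Action.NONE_REGULAR_SCREENING, None, ScreenResult.NEGATIVE,
            RiskCategory.BENIGN, tuple(trace),
        )

    ntype = nodule.type
    # a part-solid nodule that is >80% solid by diameter is handled as solid
    if ntype is NoduleType.PART_SOLID:
        frac = _solid_fraction(nodule)
        if frac is not None and frac > policy.part_solid_reclass_fraction:
            trace.append("BASE.RECLASSIFY_SOLID")
            ntype = NoduleType.SOLID

    # infection/inflammation-suggestive findings: 1-month recheck
    if ntype in (NoduleType.PART_SOLID, NoduleType.NON_SOLID) and nodule.context.infectious_pattern_1mo:
        trace.append("BASE.INFECTIOUS_1MO")
        return _one_month_recommendation(trace)
    if ntype is NoduleType.CYSTIC and nodule.context.pneumonia_differential:
        trace.append("BASE.INFECTIOUS_1MO")
        return _one_month_recommendation(trace)

    # large solid component of a part-solid lesion: 1-month recheck
    if ntype is NoduleType.PART_SOLID:
        core = nodule.solid_series[0]
        if _measurement_size(core) >= policy.diameter_cutoffs_mm[2]:
            trace.append("BASE.PARTSOLID_CORE_GE10MM")
            return _one_month_recommendation(trace)

    suspicious = set(nodule.morphology_suspicious)
    if nodule.type is NoduleType.CYSTIC:
        # a cystic component is itself a suspicious feature
        suspicious.add("cystic_component")
        trace.append("BASE.CYSTIC_SUSPICIOUS")

    # size of the relevant component
    if ntype is NoduleType.NON_SOLID and not nodule.solid_series:
        category = RiskCategory.VERY_LOW
        trace.append("BASE.NONSOLID_DEFAULT")
    else:
        series = (
            nodule.solid_series
            if (ntype in (NoduleType.PART_SOLID, NoduleType.CYSTIC, NoduleType.NON_SOLID)
                and nodule.solid_series)
            else nodule.total_series
        )
        m = series[0]
        if m.method is Method.VOLUMETRY:
            category = size_category(volume_mm3=m.volume_mm3, policy=policy)
        else:
            category = size_category(
                avg_diameter_mm=average_diameter(m.diameters_mm), policy=policy
            )
        trace.append("BASE.SIZE_CATEGORY")

    if suspicious:
        category = category.upgrade()
        trace.append("BASE.MORPHOLOGY_UPGRADE")

    return _category_recommendation(category, trace)


# -- growth assessment -----------------------------------------------------


def _build_assessment(
    nodule: NoduleRecord,
    policy: PolicyConfig,
    upto: Optional[int] = None,
) -> Tuple[GrowthAssessment, float]:
    """Growth assessment of the relevant component over observations
    [0..upto]; returns (assessment, interval-since-previous-scan days)."""
    series = nodule.component_series()
    if upto is None:
        upto = len(series) - 1
    obs = series[: upto + 1]
    if len(obs) < 2:
        raise InvalidInputError(
            f"nodule {nodule.id!r}: growth assessment needs >= 2 observations"
        )
    interval = obs[-1].t_days - obs[-2].t_days

    vol_obs = [m for m in obs if m.volume_mm3 is not None and m.method is Method.VOLUMETRY]
    use_volumetry = (
        obs[0].method is Method.VOLUMETRY
        and obs[-1].method is Method.VOLUMETRY
        and len(vol_obs) >= 2
    )
    if use_volumetry:
        method = Method.VOLUMETRY
        vdt: Optional[VdtEstimate] = vdt_fit(
            [(m.t_days, m.volume_mm3) for m in vol_obs]
        )
        sizes = {m.t_days: effective_diameter(m.volume_mm3) for m in vol_obs}
        times = sorted(sizes)
    else:
        method = Method.MANUAL
        vdt = None
        man_obs = [m for m in obs if m.diameters_mm is not None]
        if len(man_obs) < 2:
            raise InvalidInputError(
                f"nodule {nodule.id!r}: neither volumetry nor manual diameters "
                "available at two timepoints"
            )
        sizes = {m.t_days: average_diameter(m.diameters_mm) for m in man_obs}
        times = sorted(sizes)

    t_last = times[-1]
    cumulative = sizes[t_last] - sizes[times[0]]
    # diameter change over the longest available window of at most one year
    window = [t for t in times if t_last - t <= 365.0]
    ref = window[0] if window else times[-2]
    delta = sizes[t_last] - sizes[ref]

    if use_volumetry:
        shrinking = vdt.is_shrinkage
    else:
        shrinking = delta < 0

    assessment = GrowthAssessment(
        vdt=vdt,
        delta_avg_diameter_mm=delta,
        cumulative_delta_diameter_mm=cumulative,
        substantial=False,
        shrinking=shrinking,
        method=method,
        morphology_changed=nodule.morphology_changed,
    )
    substantial = (not shrinking) and substantial_growth(assessment, interval, policy)
    return dataclasses.replace(assessment, substantial=substantial), interval


def substantial_growth(
    assessment: GrowthAssessment,
    interval_days: float,
    policy: PolicyConfig = DEFAULT_POLICY,
) -> bool:
    """Does this assessment meet the policy's substantial-growth criterion?

    Volumetry: positive VDT below the interval-keyed threshold (250 d at 3
    months, 400 d at 6 months, 500 d at >= 12 months with defaults).
    Manual: average-diameter increase above 1.5 mm over at most one year,
    or a substantial morphology change.
    """
    if assessment.method is Method.VOLUMETRY:
        if assessment.vdt is None:
            raise InvalidInputError("volumetric assessment lacks a VDT estimate")
        threshold = policy.vdt_threshold(interval_days)
        return assessment.vdt.is_growth and assessment.vdt.vdt_days < threshold
    if assessment.morphology_changed:
        return True
    if interval_days > 366.0:
        # manual growth threshold applies over at most one year
        return False
    return assessment.delta_avg_diameter_mm > policy.manual_growth_mm


# -- follow-up -------------------------------------------------------------


def _cumulative_trigger(assessment: GrowthAssessment, policy: PolicyConfig) -> bool:
    d = assessment.cumulative_delta_diameter_mm
    if policy.mdt_comparator == "ge":
        return d >= policy.mdt_cumulative_mm
    return d > policy.mdt_cumulative_mm


def assess_followup(
    nodule: NoduleRecord, policy: PolicyConfig = DEFAULT_POLICY
) -> Recommendation:
    """Management recommendation for a nodule with follow-up observations.

    The baseline risk category is re-derived from the first observation and
    then updated per follow-up: shrinkage -> very low risk / 12 months,
    substantial growth -> workup, cumulative diameter change >= 5 mm in a
    slow grower -> MDT referral, otherwise one-step downgrade.
    """
    if nodule.n_timepoints < 2:
        raise InvalidInputError(
            f"nodule {nodule.id!r}: follow-up assessment needs >= 2 observations "
            "(use classify_baseline)"
        )
    if nodule.type is NoduleType.AIRWAY:
        return classify_airway(nodule, policy)

    baseline = classify_baseline(nodule.truncated(1), policy)
    trace: List[str] = list(baseline.rule_trace)

    if baseline.action is Action.NONE_REGULAR_SCREENING:
        # clearly benign at baseline: stays out of management
        return Recommendation(
            baseline.action, baseline.interval_months, baseline.screen_result,
            baseline.category, tuple(trace),
        )

    series = nodule.component_series()
    if baseline.interval_months == 1:
        # 1-month recheck lesions: regression -> benign pathway, else workup
        first, last = series[0], series[-1]
        if _measurement_size(last) < _measurement_size(first):
            trace.append("FU.ONE_MONTH_REGRESSION")
            return Recommendation(
                Action.NONE_REGULAR_SCREENING, None, ScreenResult.NEGATIVE,
                RiskCategory.BENIGN, tuple(trace),
            )
        trace.append("FU.ONE_MONTH_PERSISTENT")
        return Recommendation(
            Action.WORKUP, None, ScreenResult.POSITIVE, RiskCategory.HIGH, tuple(trace)
        )

    category = baseline.category
    for i in range(1, len(series)):
        assessment, interval = _build_assessment(nodule, policy, upto=i)
        if assessment.substantial:
            trace.append("FU.SUBSTANTIAL_GROWTH")
            return Recommendation(
                Action.WORKUP, None, ScreenResult.POSITIVE, RiskCategory.HIGH,
                tuple(trace),
            )
        if assessment.shrinking:
            trace.append("FU.SHRINKING")
            category = RiskCategory.VERY_LOW
            continue
        if _cumulative_trigger(assessment, policy):
            trace.append("FU.CUMULATIVE_5MM_MDT")
            return Recommendation(
                Action.MDT_REFERRAL, None, ScreenResult.POSITIVE, category,
                tuple(trace),
            )
        trace.append("FU.DOWNGRADE")
        category = category.downgrade()

    return _category_recommendation(category, trace)


# -- new nodules -----------------------------------------------------------


def assess_new_nodule(
    nodule: NoduleRecord,
    interval_since_prior_days: float,
    policy: PolicyConfig = DEFAULT_POLICY,
) -> Recommendation:
    """Management of a nodule first seen at a follow-up screen.

    Prevalent nodules (visible in retrospect on earlier scans) are managed
    by growth: evident growth goes to workup; dubious cases use the
    interval-keyed VDT threshold when volumetry is feasible, or a 3-month
    recheck otherwise.  Incident nodules (truly new) go to a 3-month
    recheck when the (solid-component) size is >= 30 mm³ (>= 4 mm if
    volumetry fails), otherwise back to regular 12-month screening;
    incident non-solid nodules always return to regular screening.
    """
    if not nodule.context.is_new:
        raise InvalidInputError(f"nodule {nodule.id!r}: context.is_new is not set")
    if not interval_since_prior_days > 0:
        raise InvalidInputError("interval_since_prior_days must be positive")
    if nodule.type is NoduleType.AIRWAY:
        # truly new airway nodules are managed like airway nodules at baseline
        return classify_airway(nodule, policy)

    trace: List[str] = []
    series = nodule.component_series()

    if nodule.context.visible_in_retrospect:
        if nodule.context.evident_growth:
            trace.append("NEW.PREVALENT_EVIDENT_GROWTH")
            return Recommendation(
                Action.WORKUP, None, ScreenResult.POSITIVE, RiskCategory.HIGH,
                tuple(trace),
            )
        vol_obs = [m for m in series if m.volume_mm3 is not None]
        if len(vol_obs) >= 2:
            trace.append("NEW.PREVALENT_VDT")
            assessment, _ = _build_assessment(nodule, policy)
            if substantial_growth(assessment, interval_since_prior_days, policy):
                trace.append("FU.SUBSTANTIAL_GROWTH")
                return Recommendation(
                    Action.WORKUP, None, ScreenResult.POSITIVE, RiskCategory.HIGH,
                    tuple(trace),
                )
            return Recommendation(
                Action.FOLLOW_UP, 12, ScreenResult.NEGATIVE, RiskCategory.VERY_LOW,
                tuple(trace),
            )
        trace.append("NEW.PREVALENT_NO_VOLUMETRY")
        return Recommendation(
            Action.FOLLOW_UP, 3, ScreenResult.INDETERMINATE, RiskCategory.INTERMEDIATE,
            tuple(trace),
        )

    # incident nodules
    if nodule.type is NoduleType.NON_SOLID and not nodule.solid_series:
        trace.append("NEW.INCIDENT_NONSOLID")
        return Recommendation(
            Action.FOLLOW_UP, 12, ScreenResult.NEGATIVE, RiskCategory.VERY_LOW,
            tuple(trace),
        )

    if len(series) >= 2:
        # the 3-month recheck of a previously flagged new nodule
        assessment, interval = _build_assessment(nodule, policy)
        if assessment.substantial:
            trace.append("NEW.RECHECK_GROWTH")
            return Recommendation(
                Action.WORKUP, None, ScreenResult.POSITIVE, RiskCategory.HIGH,
                tuple(trace),
            )
        trace.append("NEW.RECHECK_STABLE")
        return Recommendation(
            Action.FOLLOW_UP, 12, ScreenResult.NEGATIVE, RiskCategory.VERY_LOW,
            tuple(trace),
        )

    m = series[0]
    if m.method is Method.VOLUMETRY:
        flagged = m.volume_mm3 >= policy.new_nodule_volume_mm3
    else:
        flagged = average_diameter(m.diameters_mm) >= policy.new_nodule_diameter_mm
    if flagged:
        trace.append("NEW.INCIDENT_GE_THRESHOLD")
        return Recommendation(
            Action.FOLLOW_UP, 3, ScreenResult.INDETERMINATE, RiskCategory.INTERMEDIATE,
            tuple(trace),
        )
    trace.append("NEW.INCIDENT_LT_THRESHOLD")
    return Recommendation(
        Action.FOLLOW_UP, 12, ScreenResult.NEGATIVE, RiskCategory.VERY_LOW, tuple(trace)
    )


# -- airway nodules --------------------------------------------------------


def classify_airway(
    nodule: NoduleRecord, policy: PolicyConfig = DEFAULT_POLICY
) -> Recommendation:
    """Management of an endoluminal airway lesion.

    Benign signs (multisegment mucus, air bubbles, tracheal drop sign) end
    evaluation.  At baseline, segmental-or-smaller lesions are managed like
    a small solid nodule of the affected bronchus's diameter (<= 6 mm:
    very low risk / 12 months; > 6 mm: low risk / 6 months); endotracheal
    or proximal endobronchial lesions are intermediate risk / 3 months.
    At follow-up, regression is a negative result; persistence or growth
    goes to the MDT.
    """
    if nodule.type is not NoduleType.AIRWAY:
        raise InvalidInputError(f"nodule {nodule.id!r} is not an airway nodule")
    trace: List[str] = []

    if nodule.morphology_benign & AIRWAY_BENIGN_TOKENS:
        trace.append("AIRWAY.BENIGN_SIGNS")
        return Recommendation(
            Action.NONE_REGULAR_SCREENING, None, ScreenResult.NEGATIVE,
            RiskCategory.BENIGN, tuple(trace),
        )

    if nodule.n_timepoints >= 2:
        first, last = nodule.total_series[0], nodule.total_series[-1]
        if _measurement_size(last) < _measurement_size(first):
            trace.append("AIRWAY.REGRESSION")
            return Recommendation(
                Action.FOLLOW_UP, 12, ScreenResult.NEGATIVE, RiskCategory.VERY_LOW,
                tuple(trace),
            )
        trace.append("AIRWAY.PERSISTENT")
        return Recommendation(
            Action.MDT_REFERRAL, None, ScreenResult.POSITIVE, RiskCategory.INTERMEDIATE,
            tuple(trace),
        )

    loc = nodule.context.bronchus_location
    if loc is None:
        raise InvalidInputError(
            f"nodule {nodule.id!r}: airway nodules need context.bronchus_location"
        )
    if loc is BronchusLocation.TRACHEA_OR_PROXIMAL:
        trace.append("AIRWAY.PROXIMAL")
        return Recommendation(
            Action.FOLLOW_UP, 3, ScreenResult.INDETERMINATE, RiskCategory.INTERMEDIATE,
            tuple(trace),
        )
    d = nodule.context.bronchus_diameter_mm
    if d is None:
        raise InvalidInputError(
            f"nodule {nodule.id!r}: segmental airway nodules need "
            "context.bronchus_diameter_mm"
        )
    if d <= policy.airway_bronchus_cutoff_mm:
        trace.append("AIRWAY.SEGMENTAL_SMALL")
        return Recommendation(
            Action.FOLLOW_UP, 12, ScreenResult.NEGATIVE, RiskCategory.VERY_LOW,
            tuple(trace),
        )
    trace.append("AIRWAY.SEGMENTAL_LARGE")
    return Recommendation(
        Action.FOLLOW_UP, 6, ScreenResult.INDETERMINATE, RiskCategory.LOW, tuple(trace)
    )


# -- participant aggregation -----------------------------------------------

_ACTION_RANK = {
    Action.NONE_REGULAR_SCREENING: 0,
    Action.FOLLOW_UP: 1,
    Action.MDT_REFERRAL: 2,
    Action.WORKUP: 3,
}


def participant_management(
    recommendations: Sequence[Recommendation],
) -> Recommendation:
    """Aggregate per-nodule recommendations to participant level.

    Workup or MDT referral dominates any follow-up; among follow-ups the
    shortest interval wins; clearly benign nodules do not affect
    management.
    """
    recs = list(recommendations)
    if not recs:
        raise InvalidInputError("participant_management needs at least one recommendation")
    actionable = [r for r in recs if r.action is not Action.NONE_REGULAR_SCREENING]
    if not actionable:
        trace = recs[0].rule_trace + ("PARTICIPANT.BENIGN_IGNORED",)
        return replace(recs[0], rule_trace=trace)

    def key(r: Recommendation):
        interval = r.interval_months if r.interval_months is not None else 0
        return (_ACTION_RANK[r.action], -interval)

    best = max(actionable, key=key)
    extra = ["PARTICIPANT.SHORTEST_INTERVAL"]
    if len(actionable) < len(recs):
        extra.append("PARTICIPANT.BENIGN_IGNORED")
    return replace(best, rule_trace=best.rule_trace + tuple(extra))
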
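import pytest
from hypothesis import HealthCheck, settings

from nodulekit.engine import NoduleContext, NoduleRecord
from nodulekit.measurement import ErrorModel, Method, SizeMeasurement

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_error_model():
    return ErrorModel()


def vol(t_days, volume_mm3, seg_quality="good"):
    """Volumetric observation shorthand."""
    return SizeMeasurement(
        t_days=t_days,
        volume_mm3=volume_mm3,
        seg_quality=seg_quality,
        method=Method.VOLUMETRY,
    )


def man(t_days, d1, d2=None, d3=None):
    """Manual-caliper observation shorthand (single value = isotropic)."""
    d2 = d1 if d2 is None else d2
    d3 = d1 if d3 is None else d3
    return SizeMeasurement(
        t_days=t_days, diameters_mm=(d1, d2, d3), method=Method.MANUAL
    )


def solid(nid, *measurements, **kwargs):
    return NoduleRecord(id=nid, type="solid", total_series=tuple(measurements), **kwargs)


def growth_series(v0, vdt_days, times):
    """Noiseless exponential volumetric series."""
    return tuple(vol(t, v0 * 2 ** (t / vdt_days)) for t in times)


def build_rule_corpus():
    """Cross-product of nodule states covering every engine rule.

    Returns a list of ``(kind, record, kwargs)`` where kind is one of
    'baseline', 'followup', 'new'; running each through the matching engine
    entry point exercises every registered rule identifier at least once.
    """
    cases = []

    def base(record):
        cases.append(("baseline", record, {}))

    def fup(record):
        cases.append(("followup", record, {}))

    def new(record, interval=365.0):
        cases.append(("new", record, {"interval_since_prior_days": interval}))

    # baseline solid nodules across size bins x morphology
    for v0 in (50.0, 99.0, 150.0, 300.0, 600.0):
        for morph in (frozenset(), frozenset({"spiculation"}),
                      frozenset({"spiculation", "narrowed_vessels"})):
            base(solid(f"s-{v0}-{len(morph)}", vol(0, v0),
                       morphology_suspicious=morph))
    base(solid("s-benign", vol(0, 80.0),
               morphology_benign=frozenset({"calcification_benign_pattern"})))
    # manual-measurement fallback sizes
    for d in (5.0, 7.0, 9.0, 11.0):
        base(NoduleRecord(id=f"m-{d}", type="solid", total_series=(man(0, d),)))

    # subsolid nodules
    base(NoduleRecord(id="ps-small-core", type="part_solid",
                      total_series=(vol(0, 900.0),),
                      solid_series=(vol(0, 120.0),)))
    base(NoduleRecord(id="ps-reclass", type="part_solid",
                      total_series=(vol(0, 520.0),),
                      solid_series=(vol(0, 420.0),)))  # >80% solid by diameter
    base(NoduleRecord(id="ps-large-core", type="part_solid",
                      total_series=(vol(0, 3000.0),),
                      solid_series=(vol(0, 700.0),)))  # core >= 10 mm
    base(NoduleRecord(id="ns-plain", type="non_solid", total_series=(vol(0, 400.0),)))
    base(NoduleRecord(id="ns-gg30", type="non_solid", total_series=(vol(0, 15000.0),),
                      morphology_suspicious=frozenset({"gg_component_ge_30mm"})))
    base(NoduleRecord(id="ns-infect", type="non_solid", total_series=(vol(0, 400.0),),
                      context=NoduleContext(infectious_pattern_1mo=True)))

    # cystic nodules
    base(NoduleRecord(id="cy-thin", type="cystic", total_series=(vol(0, 300.0),),
                      morphology_benign=frozenset({"thin_walled_cyst_lt_2mm"})))
    base(NoduleRecord(id="cy-nodular", type="cystic", total_series=(vol(0, 800.0),),
                      solid_series=(vol(0, 120.0),)))
    base(NoduleRecord(id="cy-pneumonia", type="cystic", total_series=(vol(0, 800.0),),
                      solid_series=(vol(0, 120.0),),
                      context=NoduleContext(pneumonia_differential=True)))

    # airway nodules
    air = NoduleContext(bronchus_location="segmental_or_smaller", bronchus_diameter_mm=4.0)
    base(NoduleRecord(id="aw-small", type="airway", total_series=(man(0, 4.0),), context=air))
    base(NoduleRecord(id="aw-large", type="airway", total_series=(man(0, 7.0),),
                      context=NoduleContext(bronchus_location="segmental_or_smaller",
                                            bronchus_diameter_mm=7.0)))
    base(NoduleRecord(id="aw-prox", type="airway", total_series=(man(0, 5.0),),
                      context=NoduleContext(bronchus_location="trachea_or_proximal")))
    base(NoduleRecord(id="aw-benign", type="airway", total_series=(man(0, 5.0),),
                      morphology_benign=frozenset({"airway_air_bubbles"}),
                      context=NoduleContext(bronchus_location="trachea_or_proximal")))
    fup(NoduleRecord(id="aw-persist", type="airway",
                     total_series=(man(0, 5.0), man(91, 5.0)),
                     context=NoduleContext(bronchus_location="trachea_or_proximal")))
    fup(NoduleRecord(id="aw-regress", type="airway",
                     total_series=(man(0, 5.0), man(91, 3.0)),
                     context=NoduleContext(bronchus_location="trachea_or_proximal")))

    # follow-up growth regimes on solid nodules
    fup(solid("fu-shrink", vol(0, 300.0), vol(91.25, 240.0)))
    fup(solid("fu-stable", *growth_series(300.0, 900.0, (0.0, 91.25))))
    fup(solid("fu-substantial", *growth_series(300.0, 150.0, (0.0, 91.25))))
    fup(solid("fu-downgrade-chain",
              *growth_series(300.0, 600.0, (0.0, 91.25, 273.75, 638.75))))
    fup(solid("fu-mdt", *growth_series(300.0, 600.0,
                                       (0.0, 365.0, 730.0, 1095.0, 1460.0))))
    fup(NoduleRecord(id="fu-manual-growth", type="solid",
                     total_series=(man(0, 6.0), man(182, 7.8))))
    fup(NoduleRecord(id="fu-1mo-persist", type="part_solid",
                     total_series=(vol(0, 3000.0), vol(30, 3000.0)),
                     solid_series=(vol(0, 700.0), vol(30, 710.0))))
    fup(NoduleRecord(id="fu-1mo-regress", type="part_solid",
                     total_series=(vol(0, 3000.0), vol(30, 2000.0)),
                     solid_series=(vol(0, 700.0), vol(30, 400.0))))
    fup(solid("fu-benign", vol(0, 80.0), vol(365, 80.0),
              morphology_benign=frozenset({"fat"})))

    # new nodules
    new(solid("new-large", vol(0, 40.0), context=NoduleContext(is_new=True)))
    new(solid("new-small", vol(0, 20.0), context=NoduleContext(is_new=True)))
    new(NoduleRecord(id="new-nonsolid", type="non_solid", total_series=(vol(0, 200.0),),
                     context=NoduleContext(is_new=True)))
    new(NoduleRecord(id="new-ps-manual", type="part_solid",
                     total_series=(man(0, 9.0),), solid_series=(man(0, 4.5),),
                     context=NoduleContext(is_new=True)))
    new(solid("new-prev-evident", vol(0, 200.0),
              context=NoduleContext(is_new=True, visible_in_retrospect=True,
                                    evident_growth=True)))
    new(solid("new-prev-vdt-grow", vol(0, 100.0), vol(365.0, 250.0),
              context=NoduleContext(is_new=True, visible_in_retrospect=True)))
    new(solid("new-prev-vdt-stable", vol(0, 100.0), vol(365.0, 105.0),
              context=NoduleContext(is_new=True, visible_in_retrospect=True)))
    new(NoduleRecord(id="new-prev-manual", type="solid",
                     total_series=(man(0, 5.0),),
                     context=NoduleContext(is_new=True, visible_in_retrospect=True)))
    new(solid("new-recheck-grow", vol(0, 40.0), vol(91.25, 90.0),
              context=NoduleContext(is_new=True)), interval=91.25)
    new(solid("new-recheck-stable", vol(0, 40.0), vol(91.25, 41.0),
              context=NoduleContext(is_new=True)), interval=91.25)
    new(NoduleRecord(id="new-airway", type="airway", total_series=(man(0, 5.0),),
                     context=NoduleContext(is_new=True,
                                           bronchus_location="trachea_or_proximal")))
    return cases


def run_corpus_case(kind, record, kwargs):
    from nodulekit import assess_followup, assess_new_nodule, classify_baseline

    if kind == "baseline":
        return classify_baseline(record, **kwargs)
    if kind == "followup":
        return assess_followup(record, **kwargs)
    return assess_new_nodule(record, **kwargs)


@pytest.fixture
def make_vol():
    return vol


@pytest.fixture
def make_man():
    return man


@pytest.fixture
def make_solid():
    return solid
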
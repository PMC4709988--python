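"""Expected-cost evaluation of the three strategies and their comparison."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cadcost import (
    AnalysisOptions,
    BranchProbabilities,
    Strategy,
    UnitCostSchedule,
    compare_strategies,
    cost_cmr_cxa,
    cost_cxa_ffr,
    cost_cxa_only,
    percent_reduction,
)
from cadcost.errors import UndefinedBranchError


def zero_schedule() -> UnitCostSchedule:
    return UnitCostSchedule(
        system_label="zero", currency="EUR", c_cmr=0, c_cxa=0, c_ffr_addon=0,
        c_pci=0, c_cabg=0, c_nonfatal_mi=0, c_stroke=0, c_aborted_scd=0,
        c_dual_antiplatelet_year=0,
    )


def toy_schedule(**over) -> UnitCostSchedule:
    base = dict(
        system_label="toy", currency="EUR", c_cmr=100, c_cxa=300, c_ffr_addon=200,
        c_pci=1000, c_cabg=4000, c_nonfatal_mi=0, c_stroke=0, c_aborted_scd=0,
        c_dual_antiplatelet_year=50,
    )
    base.update(over)
    return UnitCostSchedule(**base)


def test_zero_cost_schedule_yields_zero_for_all_strategies(toy_probs, bare_options):
    for fn in (cost_cmr_cxa, cost_cxa_ffr, cost_cxa_only):
        assert fn(toy_probs, zero_schedule(), bare_options).expected_cost_per_patient == 0.0


def test_degenerate_tree_costs_exactly_the_cmr(bare_options):
    probs = BranchProbabilities(0.0, 0.0, 0.0, (1, 0, 0))
    cost = cost_cmr_cxa(probs, toy_schedule(), bare_options)
    assert cost.expected_cost_per_patient == toy_schedule().c_cmr


def test_cmr_cxa_toy_tree_hand_computation(toy_probs, bare_options):
    """100 + 0.2*300 + 0.1*1000 + 0.1*50 = 265."""
    cost = cost_cmr_cxa(toy_probs, toy_schedule(), bare_options)
    assert cost.expected_cost_per_patient == pytest.approx(265.0, abs=1e-12)


def test_cxa_ffr_toy_diagnostics(bare_options):
    """No downstream events: 500 + 0.35*200 = 570."""
    probs = BranchProbabilities(0.0, 0.0, 0.0, (1, 0, 0), p_ffr_eligible=0.35)
    cost = cost_cxa_ffr(
        probs, toy_schedule(c_cxa=500, c_dual_antiplatelet_year=0), bare_options
    )
    assert cost.expected_cost_per_patient == pytest.approx(570.0, abs=1e-12)


def test_cxa_only_toy_tree(bare_options):
    """500 + 0.35*1000 = 850 with only PCI and no drug costs."""
    probs = BranchProbabilities(0.0, 0.0, 0.0, (1, 0, 0), p_ffr_eligible=0.35)
    cost = cost_cxa_only(
        probs, toy_schedule(c_cxa=500, c_dual_antiplatelet_year=0), bare_options
    )
    assert cost.expected_cost_per_patient == pytest.approx(850.0, abs=1e-12)


def test_components_sum_to_total(toy_probs, demo_schedule):
    for fn in (cost_cmr_cxa, cost_cxa_ffr, cost_cxa_only):
        cost = fn(toy_probs, demo_schedule)
        assert sum(cost.components.values()) == pytest.approx(
            cost.expected_cost_per_patient, rel=1e-9
        )


def test_equal_outcome_coupling_is_bit_identical(toy_probs, demo_schedule):
    """Revascularization/drug/complication/follow-up terms shared verbatim."""
    a = cost_cmr_cxa(toy_probs, demo_schedule)
    b = cost_cxa_ffr(toy_probs, demo_schedule)
    for key in ("revascularization", "drugs", "complications", "followup"):
        assert a.components[key] == b.components[key]


def test_false_negative_cxa_charge_toggle(demo_schedule):
    probs = BranchProbabilities(0.2, 0.0, 0.1, (1, 0, 0))
    on = cost_cmr_cxa(probs, demo_schedule, AnalysisOptions())
    off = cost_cmr_cxa(
        probs, demo_schedule, AnalysisOptions(charge_cxa_to_negative_revasc=False)
    )
    expected_gap = 0.8 * 0.1 * demo_schedule.c_cxa
    assert on.expected_cost_per_patient - off.expected_cost_per_patient == pytest.approx(
        expected_gap
    )


def test_all_mace_mode_adds_stroke_and_aborted_scd(demo_schedule):
    probs = BranchProbabilities(
        0.2, 0.1, 0.0, (1, 0, 0), p_nonfatal_mi=0.01, p_stroke=0.005,
        p_aborted_scd=0.002, p_death=0.01,
    )
    base = cost_cmr_cxa(
        probs, demo_schedule,
        AnalysisOptions(include_rehab=False, include_cardiologist_visit=False),
    )
    mace = cost_cmr_cxa(
        probs, demo_schedule,
        AnalysisOptions(
            include_rehab=False, include_cardiologist_visit=False,
            complication_costing="all_mace",
        ),
    )
    extra = 0.005 * demo_schedule.c_stroke + 0.002 * demo_schedule.c_aborted_scd
    assert mace.expected_cost_per_patient - base.expected_cost_per_patient == pytest.approx(extra)


def test_death_contributes_no_cost(demo_schedule, bare_options):
    alive = BranchProbabilities(0.2, 0.1, 0.0, (1, 0, 0), p_death=0.0)
    dying = alive.replace(p_death=0.5)
    assert (
        cost_cmr_cxa(alive, demo_schedule, bare_options).expected_cost_per_patient
        == cost_cmr_cxa(dying, demo_schedule, bare_options).expected_cost_per_patient
    )


def test_missing_ffr_eligibility_directs_to_curve(demo_schedule):
    probs = BranchProbabilities(0.2, 0.1, 0.0, (1, 0, 0))
    with pytest.raises(UndefinedBranchError, match="stenosis_ffr"):
        cost_cxa_ffr(probs, demo_schedule)
    with pytest.raises(UndefinedBranchError, match="stenosis_ffr"):
        cost_cxa_only(probs, demo_schedule)


def test_undefined_negative_branch_refuses_to_price(demo_schedule):
    probs = BranchProbabilities(1.0, 0.1, None, (1, 0, 0), p_ffr_eligible=0.35)
    with pytest.raises(UndefinedBranchError, match="p_revasc_given_neg"):
        cost_cmr_cxa(probs, demo_schedule)


@pytest.mark.parametrize(
    "cost_a, cost_b, expected",
    [(932, 1090, 14.5), (932, 2298, 59.4), (1090, 2298, 52.6), (1740, 6022, 71.1)],
)
def test_percent_reduction_matches_published_rows(cost_a, cost_b, expected):
    assert round(percent_reduction(cost_a, cost_b), 1) == expected


def test_percent_reduction_identity_and_error():
    assert percent_reduction(123.4, 123.4) == 0.0
    with pytest.raises(ValueError):
        percent_reduction(1.0, 0.0)


def test_compare_strategies_is_compositional(toy_probs, demo_schedule):
    rep = compare_strategies(toy_probs, demo_schedule)
    for a, b in ((Strategy.CMR_CXA, Strategy.CXA_FFR),
                 (Strategy.CMR_CXA, Strategy.CXA_ONLY),
                 (Strategy.CXA_FFR, Strategy.CXA_ONLY)):
        assert rep.reductions[f"{a.value}_vs_{b.value}"] == pytest.approx(
            percent_reduction(rep.cost_of(a), rep.cost_of(b))
        )


def test_zero_cost_comparison_flags_reductions_undefined(toy_probs, bare_options):
    rep = compare_strategies(toy_probs, zero_schedule(), bare_options)
    assert all(v is None for v in rep.reductions.values())
    assert all(rep.cost_of(s) == 0.0 for s in Strategy)


def _schedule_from_vector(vec) -> UnitCostSchedule:
    names = (
        "c_cmr", "c_cxa", "c_ffr_addon", "c_pci", "c_cabg", "c_nonfatal_mi",
        "c_stroke", "c_aborted_scd", "c_dual_antiplatelet_year",
        "c_rehab_post_mi", "c_cardiologist_visit",
    )
    return UnitCostSchedule(
        system_label="vec", currency="X", **dict(zip(names, vec))
    )


money_vectors = st.lists(
    st.floats(min_value=0, max_value=1e5, allow_nan=False), min_size=11, max_size=11
)


@given(v1=money_vectors, v2=money_vectors)
def test_cost_is_linear_in_the_tariff_vector(v1, v2):
    probs = BranchProbabilities(
        0.209, 0.174, 0.033, (0.79, 0.18, 0.03), p_nonfatal_mi=0.003,
        p_stroke=0.005, p_aborted_scd=0.002, p_ffr_eligible=0.35,
    )
    opts = AnalysisOptions(complication_costing="all_mace")
    for fn in (cost_cmr_cxa, cost_cxa_ffr, cost_cxa_only):
        c1 = fn(probs, _schedule_from_vector(v1), opts).expected_cost_per_patient
        c2 = fn(probs, _schedule_from_vector(v2), opts).expected_cost_per_patient
        c12 = fn(
            probs, _schedule_from_vector([a + b for a, b in zip(v1, v2)]), opts
        ).expected_cost_per_patient
        assert c12 == pytest.approx(c1 + c2, rel=1e-9, abs=1e-6)


@given(v=money_vectors, k=st.floats(min_value=1e-3, max_value=1e3))
def test_homogeneity_scales_costs_and_preserves_reductions(v, k):
    probs = BranchProbabilities(
        0.209, 0.174, 0.033, (0.79, 0.18, 0.03), p_nonfatal_mi=0.003,
        p_ffr_eligible=0.35,
    )
    base = compare_strategies(probs, _schedule_from_vector(v))
    scaled = compare_strategies(probs, _schedule_from_vector([k * x for x in v]))
    for s in Strategy:
        assert scaled.cost_of(s) == pytest.approx(k * base.cost_of(s), rel=1e-9, abs=1e-9)
    for key, red in base.reductions.items():
        if red is None:
            assert scaled.reductions[key] is None
        else:
            assert scaled.reductions[key] == pytest.approx(red, rel=1e-6, abs=1e-9)
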
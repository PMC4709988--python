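"""One-way sensitivity, FFR-fraction sweep, and break-even solving."""

import numpy as np
import pytest

from cadcost import (
    AnalysisOptions,
    BranchProbabilities,
    Strategy,
    UnitCostSchedule,
    break_even_multiplier,
    compare_strategies,
    ffr_fraction_sweep,
    one_way_sensitivity,
    percent_reduction,
)
from cadcost.errors import SensitivityParameterError
from cadcost.strategy_costs import cost_strategy


@pytest.fixture
def probs():
    return BranchProbabilities(
        0.209, 0.174, 0.033, (0.79, 0.18, 0.03), p_nonfatal_mi=0.003,
        p_stroke=0.005, p_aborted_scd=0.002, p_death=0.009,
        p_ffr_eligible=0.35, p_ffr_positive=0.062,
    )


def test_zero_change_reproduces_baseline_bit_identically(probs, demo_schedule):
    res = one_way_sensitivity(
        probs, demo_schedule, parameter="c_cmr", relative_change=0.0
    )
    assert res.perturbed_costs == res.baseline_costs
    assert res.perturbed_reductions == res.baseline_reductions
    assert all(d == 0.0 for d in res.delta_reduction_points.values())


def test_cmr_perturbation_shifts_only_the_cmr_arm_linearly(probs, demo_schedule):
    res = one_way_sensitivity(
        probs, demo_schedule, parameter="c_cmr", relative_change=0.10
    )
    assert res.perturbed_costs[Strategy.CMR_CXA] == pytest.approx(
        res.baseline_costs[Strategy.CMR_CXA] + 0.10 * demo_schedule.c_cmr, abs=1e-9
    )
    assert res.perturbed_costs[Strategy.CXA_FFR] == res.baseline_costs[Strategy.CXA_FFR]
    assert res.perturbed_costs[Strategy.CXA_ONLY] == res.baseline_costs[Strategy.CXA_ONLY]


def test_delta_reductions_match_recomputation_from_scratch(probs, demo_schedule):
    res = one_way_sensitivity(
        probs, demo_schedule, parameter="c_cxa", relative_change=-0.10
    )
    perturbed = compare_strategies(probs, demo_schedule.scaled("c_cxa", 0.9))
    baseline = compare_strategies(probs, demo_schedule)
    for key in res.delta_reduction_points:
        assert res.delta_reduction_points[key] == pytest.approx(
            perturbed.reductions[key] - baseline.reductions[key], abs=1e-12
        )


def test_treatment_costs_are_protected_with_override(probs, demo_schedule):
    with pytest.raises(SensitivityParameterError, match="treatment"):
        one_way_sensitivity(
            probs, demo_schedule, parameter="c_pci", relative_change=0.10
        )
    res = one_way_sensitivity(
        probs, demo_schedule, parameter="c_pci", relative_change=0.10,
        allow_treatment_costs=True,
    )
    assert res.parameter_name == "c_pci"


def test_invalid_parameter_and_change_rejected(probs, demo_schedule):
    with pytest.raises(SensitivityParameterError, match="unknown tariff"):
        one_way_sensitivity(
            probs, demo_schedule, parameter="c_nonsense", relative_change=0.1
        )
    with pytest.raises(SensitivityParameterError, match="exceed -1"):
        one_way_sensitivity(
            probs, demo_schedule, parameter="c_cmr", relative_change=-1.5
        )


def test_degenerate_sweep_equals_baseline_comparison(probs, demo_schedule):
    reports = ffr_fraction_sweep(probs, demo_schedule, lo=0.35, hi=0.35, step=0.05)
    assert len(reports) == 1
    baseline = compare_strategies(probs, demo_schedule)
    for s in Strategy:
        assert reports[0].cost_of(s) == baseline.cost_of(s)


def test_sweep_grid_is_inclusive_of_both_endpoints(probs, demo_schedule):
    reports = ffr_fraction_sweep(probs, demo_schedule, lo=0.30, hi=0.55, step=0.05)
    assert len(reports) == 6  # 0.30, 0.35, ..., 0.55
    assert reports[0].variant_label == "ffr_eligible=0.3"
    assert reports[-1].variant_label == "ffr_eligible=0.55"


def test_cmr_arm_constant_and_ffr_arm_increasing_across_sweep(probs):
    rng = np.random.default_rng(5)
    for _ in range(10):
        v = rng.uniform(1, 5000, size=9)
        schedule = UnitCostSchedule(
            system_label="r", currency="X", c_cmr=v[0], c_cxa=v[1], c_ffr_addon=v[2],
            c_pci=v[3], c_cabg=v[4], c_nonfatal_mi=v[5], c_stroke=v[6],
            c_aborted_scd=v[7], c_dual_antiplatelet_year=v[8],
        )
        reports = ffr_fraction_sweep(probs, schedule, lo=0.30, hi=0.55, step=0.05)
        cmr = [r.cost_of(Strategy.CMR_CXA) for r in reports]
        ffr = [r.cost_of(Strategy.CXA_FFR) for r in reports]
        assert all(c == cmr[0] for c in cmr)
        assert all(b > a for a, b in zip(ffr, ffr[1:]))  # c_ffr_addon > 0


def test_sweep_saving_nondecreasing_in_ffr_fraction(probs, demo_schedule):
    reports = ffr_fraction_sweep(probs, demo_schedule, lo=0.30, hi=0.55, step=0.05)
    savings = [r.reductions["cmr_cxa_vs_cxa_ffr"] for r in reports]
    assert all(b >= a - 1e-12 for a, b in zip(savings, savings[1:]))


def test_sweep_decoupling_keeps_cxa_only_at_baseline(probs, demo_schedule):
    coupled = ffr_fraction_sweep(probs, demo_schedule, lo=0.30, hi=0.55, step=0.05)
    decoupled = ffr_fraction_sweep(
        probs, demo_schedule, lo=0.30, hi=0.55, step=0.05, couple_cxa_only=False
    )
    baseline = compare_strategies(probs, demo_schedule)
    assert all(
        r.cost_of(Strategy.CXA_ONLY) == baseline.cost_of(Strategy.CXA_ONLY)
        for r in decoupled
    )
    assert coupled[0].cost_of(Strategy.CXA_ONLY) != baseline.cost_of(Strategy.CXA_ONLY)


def test_sweep_rejects_bad_grids(probs, demo_schedule):
    with pytest.raises(SensitivityParameterError):
        ffr_fraction_sweep(probs, demo_schedule, lo=0.5, hi=0.3, step=0.05)
    with pytest.raises(SensitivityParameterError):
        ffr_fraction_sweep(probs, demo_schedule, lo=0.3, hi=0.5, step=0.0)


def test_breakeven_toy_closed_form(bare_options):
    """cxa_ffr = 500 + 0.35*m*200, cxa_only = 850 -> m = 5."""
    probs = BranchProbabilities(0.0, 0.0, 0.0, (1, 0, 0), p_ffr_eligible=0.35)
    schedule = UnitCostSchedule(
        system_label="toy", currency="X", c_cmr=100, c_cxa=500, c_ffr_addon=200,
        c_pci=1000, c_cabg=0, c_nonfatal_mi=0, c_stroke=0, c_aborted_scd=0,
        c_dual_antiplatelet_year=0,
    )
    res = break_even_multiplier(
        probs, schedule, bare_options, parameter="c_ffr_addon",
        pair=("cxa_ffr", "cxa_only"),
    )
    assert res.solvable
    assert res.multiplier == pytest.approx(5.0, abs=1e-12)
    assert res.achieved_gap <= 1e-9 * 850


def test_breakeven_already_equal_pair_returns_unit_multiplier(probs, demo_schedule):
    res = break_even_multiplier(
        probs, demo_schedule, parameter="c_cmr", pair=("cxa_ffr", "cxa_ffr")
    )
    assert res.solvable and res.multiplier == 1.0 and res.achieved_gap == 0.0


def test_breakeven_parameter_absent_from_both_strategies(probs, demo_schedule):
    res = break_even_multiplier(
        probs, demo_schedule, parameter="c_cmr", pair=("cxa_ffr", "cxa_only")
    )
    assert not res.solvable
    assert res.multiplier is None
    assert "does not enter" in res.note


def test_breakeven_parallel_lines_unsolvable(probs, demo_schedule):
    # Revascularization terms are identical in cmr_cxa and cxa_ffr.
    res = break_even_multiplier(
        probs, demo_schedule, parameter="c_dual_antiplatelet_year",
        pair=("cmr_cxa", "cxa_ffr"),
    )
    assert not res.solvable
    assert "parallel" in res.note


def _bisect_gap(probs, schedule, options, parameter, pair, lo, hi, iters=80):
    def gap(m):
        scaled = schedule.scaled(parameter, m)
        return (
            cost_strategy(pair[0], probs, scaled, options).expected_cost_per_patient
            - cost_strategy(pair[1], probs, scaled, options).expected_cost_per_patient
        )

    a, b = lo, hi
    fa = gap(a)
    for _ in range(iters):
        mid = 0.5 * (a + b)
        fm = gap(mid)
        if fa * fm <= 0:
            b = mid
        else:
            a, fa = mid, fm
    return 0.5 * (a + b)


def test_breakeven_agrees_with_bisection_on_random_schedules(probs):
    rng = np.random.default_rng(17)
    options = AnalysisOptions()
    checked = 0
    for _ in range(20):
        v = rng.uniform(10, 5000, size=11)
        schedule = UnitCostSchedule(
            system_label="r", currency="X", c_cmr=v[0], c_cxa=v[1], c_ffr_addon=v[2],
            c_pci=v[3], c_cabg=v[4], c_nonfatal_mi=v[5], c_stroke=v[6],
            c_aborted_scd=v[7], c_dual_antiplatelet_year=v[8],
            c_rehab_post_mi=v[9], c_cardiologist_visit=v[10],
        )
        res = break_even_multiplier(
            probs, schedule, options, parameter="c_ffr_addon",
            pair=("cxa_ffr", "cxa_only"),
        )
        if not res.solvable:
            continue
        m_num = _bisect_gap(
            probs, schedule, options, "c_ffr_addon", ("cxa_ffr", "cxa_only"),
            lo=0.0, hi=max(2.0 * res.multiplier, 1.0),
        )
        assert res.multiplier == pytest.approx(m_num, rel=1e-6)
        checked += 1
    assert checked >= 10
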
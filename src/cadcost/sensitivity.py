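"""Robustness analyses: one-way sensitivity, FFR-fraction sweep, break-even.

One-way deterministic sensitivity analysis perturbs a single tariff by a
relative amount (classically ±10%) while holding everything else at
baseline, then re-evaluates all three strategies.  Treatment
(revascularization-procedure) tariffs are not varied by default: with
equal outcomes the procedures are identical across arms, so varying them
shifts all strategies together without changing their ranking.

Because each expected cost is affine in any single tariff, the break-even
multiplier that equalizes two strategies' costs has a closed form: writing
cost_s(m) = a_s + d_s*m for the multiplier m on the chosen tariff,
m* = (a_B - a_A) / (d_A - d_B), with the pair unsolvable when the tariff
enters both strategies with the same coefficient (parallel lines).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import BranchProbabilities
from .errors import SensitivityParameterError
from .strategy_costs import (
    MONEY_FIELDS,
    TREATMENT_COST_FIELDS,
    AnalysisOptions,
    ComparisonReport,
    Strategy,
    UnitCostSchedule,
    compare_strategies,
    cost_strategy,
)

__all__ = [
    "SensitivityResult",
    "BreakEvenResult",
    "one_way_sensitivity",
    "ffr_fraction_sweep",
    "break_even_multiplier",
]


@dataclass(frozen=True)
class SensitivityResult:
    """Baseline vs single-parameter-perturbed strategy costs and reductions."""

    parameter_name: str
    relative_change: float
    baseline_costs: dict[Strategy, float]
    perturbed_costs: dict[Strategy, float]
    baseline_reductions: dict[str, float | None]
    perturbed_reductions: dict[str, float | None]
    delta_reduction_points: dict[str, float | None]


@dataclass(frozen=True)
class BreakEvenResult:
    """Multiplier on one tariff equalizing two strategies' expected costs."""

    parameter_name: str
    strategy_pair: tuple[Strategy, Strategy]
    multiplier: float | None
    achieved_gap: float | None
    solvable: bool
    note: str = ""


def _validate_parameter(parameter: str, *, allow_treatment_costs: bool) -> None:
    if parameter not in MONEY_FIELDS:
        raise SensitivityParameterError(
            f"unknown tariff field {parameter!r}; choose one of {MONEY_FIELDS}"
        )
    if parameter in TREATMENT_COST_FIELDS and not allow_treatment_costs:
        raise SensitivityParameterError(
            f"{parameter!r} is a treatment cost; with equal outcomes across "
            f"arms treatment costs are held fixed in sensitivity analyses "
            f"(pass allow_treatment_costs=True for exploratory use)"
        )


def one_way_sensitivity(
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
    *,
    parameter: str,
    relative_change: float,
    allow_treatment_costs: bool = False,
) -> SensitivityResult:
    """Re-run the model with exactly one tariff scaled by (1 + relative_change)."""
    options = options or AnalysisOptions()
    _validate_parameter(parameter, allow_treatment_costs=allow_treatment_costs)
    if relative_change <= -1.0:
        raise SensitivityParameterError(
            f"relative_change must exceed -1 (got {relative_change}); tariffs "
            f"cannot go negative"
        )

    baseline = compare_strategies(probs, schedule, options)
    perturbed = compare_strategies(
        probs, schedule.scaled(parameter, 1.0 + relative_change), options
    )

    deltas: dict[str, float | None] = {}
    for key, base_red in baseline.reductions.items():
        pert_red = perturbed.reductions[key]
        deltas[key] = (
            pert_red - base_red
            if base_red is not None and pert_red is not None
            else None
        )
    return SensitivityResult(
        parameter_name=parameter,
        relative_change=relative_change,
        baseline_costs={s: baseline.cost_of(s) for s in Strategy},
        perturbed_costs={s: perturbed.cost_of(s) for s in Strategy},
        baseline_reductions=dict(baseline.reductions),
        perturbed_reductions=dict(perturbed.reductions),
        delta_reduction_points=deltas,
    )


def ffr_fraction_sweep(
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
    *,
    lo: float = 0.30,
    hi: float = 0.55,
    step: float = 0.05,
    couple_cxa_only: bool = True,
) -> list[ComparisonReport]:
    """Sweep the FFR-eligible (≥50%-stenosis) fraction over an inclusive grid.

    Each grid value replaces ``p_ffr_eligible``.  By default the same
    fraction drives both the CXA+FFR arm's FFR count and the CXA-only
    arm's revascularized fraction (the two trees share the quantity); with
    ``couple_cxa_only=False`` the CXA-only arm stays at its baseline value.
    """
    options = options or AnalysisOptions()
    if not (0.0 <= lo <= hi <= 1.0):
        raise SensitivityParameterError(
            f"need 0 <= lo <= hi <= 1, got lo={lo}, hi={hi}"
        )
    if step <= 0.0:
        raise SensitivityParameterError(f"step must be positive, got {step}")

    grid: list[float] = []
    x = lo
    while x < hi - 1e-12:
        grid.append(round(x, 12))
        x += step
    grid.append(hi)

    baseline_ffr = probs.p_ffr_eligible
    reports: list[ComparisonReport] = []
    for frac in grid:
        swept = probs.replace(p_ffr_eligible=frac)
        if couple_cxa_only:
            rep = compare_strategies(
                swept, schedule, options, variant_label=f"ffr_eligible={frac:g}"
            )
        else:
            from .strategy_costs import build_report, cost_cmr_cxa, cost_cxa_ffr, cost_cxa_only

            fixed = probs.replace(p_ffr_eligible=baseline_ffr)
            costs = {
                Strategy.CMR_CXA: cost_cmr_cxa(swept, schedule, options),
                Strategy.CXA_FFR: cost_cxa_ffr(swept, schedule, options),
                Strategy.CXA_ONLY: cost_cxa_only(fixed, schedule, options),
            }
            rep = build_report(
                costs,
                system_label=schedule.system_label,
                variant_label=f"ffr_eligible={frac:g}",
                options=options,
            )
        reports.append(rep)
    return reports


def break_even_multiplier(
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
    *,
    parameter: str,
    pair: tuple[Strategy | str, Strategy | str],
    gap_tolerance_rel: float = 1e-9,
) -> BreakEvenResult:
    """Solve for the tariff multiplier equalizing the pair's expected costs.

    Expected costs are affine in the multiplier, so the solution is the
    intersection of two lines.  ``solvable=False`` when the lines are
    parallel (equal coefficients) or the intersection requires a negative
    multiplier.
    """
    options = options or AnalysisOptions()
    if parameter not in MONEY_FIELDS:
        raise SensitivityParameterError(
            f"unknown tariff field {parameter!r}; choose one of {MONEY_FIELDS}"
        )
    strategies = (Strategy(pair[0]), Strategy(pair[1]))

    # Affine decomposition per strategy: intercept at multiplier 0, slope
    # from the baseline evaluation.
    zeroed = schedule.scaled(parameter, 0.0)
    intercepts = {}
    slopes = {}
    for s in strategies:
        a = cost_strategy(s, probs, zeroed, options).expected_cost_per_patient
        b = cost_strategy(s, probs, schedule, options).expected_cost_per_patient
        intercepts[s] = a
        slopes[s] = b - a

    s_a, s_b = strategies
    d = slopes[s_a] - slopes[s_b]
    baseline_gap = (intercepts[s_a] + slopes[s_a]) - (intercepts[s_b] + slopes[s_b])
    scale = max(
        abs(intercepts[s_a] + slopes[s_a]), abs(intercepts[s_b] + slopes[s_b]), 1.0
    )
    tol = gap_tolerance_rel * scale

    if abs(d) <= 1e-15 * scale:
        if abs(baseline_gap) <= tol:
            return BreakEvenResult(
                parameter, strategies, 1.0, abs(baseline_gap), True,
                note="costs already equal; parameter does not separate the pair",
            )
        note = (
            f"{parameter!r} has equal coefficients in both strategies "
            f"(parallel lines); no multiplier can equalize them"
            if slopes[s_a] != 0.0 or slopes[s_b] != 0.0
            else f"{parameter!r} does not enter either strategy's cost"
        )
        return BreakEvenResult(parameter, strategies, None, None, False, note=note)

    m = (intercepts[s_b] - intercepts[s_a]) / d
    if m < 0.0:
        return BreakEvenResult(
            parameter, strategies, None, None, False,
            note=f"intersection at negative multiplier {m:.6g}; tariffs cannot be negative",
        )
    # Verify by re-evaluating the full model at the solution.
    scaled = schedule.scaled(parameter, m)
    gap = abs(
        cost_strategy(s_a, probs, scaled, options).expected_cost_per_patient
        - cost_strategy(s_b, probs, scaled, options).expected_cost_per_patient
    )
    return BreakEvenResult(parameter, strategies, m, gap, gap <= tol)
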
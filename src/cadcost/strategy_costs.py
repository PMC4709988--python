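"""Expected per-patient costs of the three diagnostic strategies.

The model is a cost-minimization comparison: the three work-up strategies
for suspected coronary artery disease are assumed to achieve the same
clinical outcome, so they are ranked purely by expected cost from a health
care payer (tariff) perspective over a 12-month horizon, with no
discounting.

Strategies
----------
``cmr_cxa``
    Stress-perfusion CMR in everyone; only ischemia-positive patients
    proceed to invasive angiography (CXA) and possible revascularization.
    CMR-negative patients who are nevertheless revascularized during
    follow-up (false negatives) incur a CXA plus revascularization costs.
``cxa_ffr``
    Invasive-first: CXA in everyone, with FFR pressure-wire testing added
    in the fraction of patients showing a ≥50% stenosis.  Under the
    equal-outcome assumption the downstream revascularization, drug and
    complication terms are identical to the CMR-guided arm.
``cxa_only``
    Anatomy-guided: CXA in everyone and revascularization of every patient
    with a ≥50% stenosis, with no ischemia testing at all.

Each expected cost is the sum over tree branches of branch probability x
unit tariff, so it is linear in the tariff vector at fixed probabilities.
Death carries no cost.  Costs of one-year dual antiplatelet therapy
(clopidogrel + aspirin) are charged to every revascularized patient; drugs
for risk-factor management are excluded because they apply to every
strategy equally.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, NonNegativeFloat

from .cohort import BranchProbabilities
from .errors import UndefinedBranchError

__all__ = [
    "Strategy",
    "UnitCostSchedule",
    "AnalysisOptions",
    "StrategyCost",
    "ComparisonReport",
    "cost_cmr_cxa",
    "cost_cxa_ffr",
    "cost_cxa_only",
    "cost_strategy",
    "percent_reduction",
    "compare_strategies",
    "MONEY_FIELDS",
    "TREATMENT_COST_FIELDS",
]


class Strategy(str, Enum):
    CMR_CXA = "cmr_cxa"
    CXA_FFR = "cxa_ffr"
    CXA_ONLY = "cxa_only"


class UnitCostSchedule(BaseModel):
    """Per-health-system reimbursement tariffs, all in one currency.

    ``c_ffr_addon`` is the *incremental* tariff of adding an FFR
    measurement to a diagnostic CXA.  ``c_pci_and_cabg`` defaults to the
    sum of the single-procedure tariffs when not given.  Rehabilitation
    after non-fatal myocardial infarction and the post-revascularization
    cardiologist visit are optional items toggled by
    :class:`AnalysisOptions`.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    system_label: str
    currency: str = Field(min_length=1)
    c_cmr: NonNegativeFloat
    c_cxa: NonNegativeFloat
    c_ffr_addon: NonNegativeFloat
    c_pci: NonNegativeFloat
    c_cabg: NonNegativeFloat
    c_pci_and_cabg: NonNegativeFloat | None = None
    c_nonfatal_mi: NonNegativeFloat
    c_stroke: NonNegativeFloat
    c_aborted_scd: NonNegativeFloat
    c_dual_antiplatelet_year: NonNegativeFloat
    c_rehab_post_mi: NonNegativeFloat = 0.0
    c_cardiologist_visit: NonNegativeFloat = 0.0

    @property
    def c_both_effective(self) -> float:
        if self.c_pci_and_cabg is not None:
            return self.c_pci_and_cabg
        return self.c_pci + self.c_cabg

    def scaled(self, parameter: str, multiplier: float) -> "UnitCostSchedule":
        """Return a copy with one tariff multiplied by ``multiplier``."""
        if parameter not in MONEY_FIELDS:
            raise KeyError(f"unknown tariff field {parameter!r}")
        current = getattr(self, parameter)
        if parameter == "c_pci_and_cabg" and current is None:
            current = self.c_both_effective
        return self.model_copy(update={parameter: current * multiplier})


MONEY_FIELDS: tuple[str, ...] = (
    "c_cmr",
    "c_cxa",
    "c_ffr_addon",
    "c_pci",
    "c_cabg",
    "c_pci_and_cabg",
    "c_nonfatal_mi",
    "c_stroke",
    "c_aborted_scd",
    "c_dual_antiplatelet_year",
    "c_rehab_post_mi",
    "c_cardiologist_visit",
)

#: Revascularization-procedure tariffs; one-way sensitivity analyses do not
#: vary these because equal outcomes make treatment identical across arms.
TREATMENT_COST_FIELDS: frozenset[str] = frozenset(
    {"c_pci", "c_cabg", "c_pci_and_cabg"}
)


class AnalysisOptions(BaseModel):
    """Toggles selecting which optional cost items the analysis includes.

    ``complication_costing`` defaults to pricing only non-fatal myocardial
    infarction (death carries no cost); ``all_mace`` additionally prices
    stroke and aborted sudden cardiac death.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    include_rehab: bool = True
    include_cardiologist_visit: bool = True
    complication_costing: Literal["death_and_mi_only", "all_mace"] = "death_and_mi_only"
    # A revascularization in a CMR-negative patient presupposes an angiogram.
    charge_cxa_to_negative_revasc: bool = True
    # Whether the anatomy-guided arm's revascularized patients also receive
    # one year of dual antiplatelet therapy (mirrors the other arms).
    charge_dual_antiplatelet_cxa_only: bool = True


@dataclass(frozen=True)
class StrategyCost:
    """Expected per-patient cost of one strategy with component breakdown."""

    strategy: Strategy
    expected_cost_per_patient: float
    components: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if not math.isclose(
            total, self.expected_cost_per_patient, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValueError(
                f"components sum to {total}, not {self.expected_cost_per_patient}"
            )


def _mix_weighted_revasc_cost(
    probs: BranchProbabilities, schedule: UnitCostSchedule
) -> float:
    if probs.revasc_type_mix is None:
        raise UndefinedBranchError(
            "revascularization type mix is undefined; cannot price revascularizations"
        )
    w_pci, w_cabg, w_both = probs.revasc_type_mix
    return (
        w_pci * schedule.c_pci
        + w_cabg * schedule.c_cabg
        + w_both * schedule.c_both_effective
    )


def _complication_cost(
    probs: BranchProbabilities, schedule: UnitCostSchedule, options: AnalysisOptions
) -> float:
    # Death contributes zero cost in every mode.
    cost = probs.p_nonfatal_mi * schedule.c_nonfatal_mi
    if options.include_rehab:
        cost += probs.p_nonfatal_mi * schedule.c_rehab_post_mi
    if options.complication_costing == "all_mace":
        cost += probs.p_stroke * schedule.c_stroke
        cost += probs.p_aborted_scd * schedule.c_aborted_scd
    return cost


def _downstream_components(
    probs: BranchProbabilities, schedule: UnitCostSchedule, options: AnalysisOptions
) -> dict[str, float]:
    """Revascularization + drug + complication + follow-up terms.

    Shared verbatim between the CMR-guided and CXA+FFR arms: equal outcomes
    mean equal treatment, so these components are computed once and are
    bit-identical between the two strategies.
    """
    p_rev = probs.p_revasc_overall
    comps = {
        "revascularization": p_rev * _mix_weighted_revasc_cost(probs, schedule),
        "drugs": p_rev * schedule.c_dual_antiplatelet_year,
        "complications": _complication_cost(probs, schedule, options),
        "followup": (
            p_rev * schedule.c_cardiologist_visit
            if options.include_cardiologist_visit
            else 0.0
        ),
    }
    return comps


def _require_ffr_eligible(probs: BranchProbabilities) -> float:
    if probs.p_ffr_eligible is None:
        raise UndefinedBranchError(
            "p_ffr_eligible is undefined; derive it from the FFR-positive rate "
            "with the stenosis_ffr module (stenosis_prevalence_from_ffr_rate) "
            "or set it explicitly"
        )
    return probs.p_ffr_eligible


def cost_cmr_cxa(
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
) -> StrategyCost:
    """Expected cost of the CMR-guided strategy.

    Everyone gets a CMR; ischemia-positive patients get a CXA; CMR-negative
    patients later revascularized also get a CXA (configurable); the
    marginal revascularization rate prices procedures, drugs and follow-up.
    """
    options = options or AnalysisOptions()
    p_pos = probs.p_ischemia_pos
    if probs.p_revasc_given_neg is None:
        raise UndefinedBranchError(
            "p_revasc_given_neg is undefined; cannot price the CMR-negative branch"
        )
    p_cxa = p_pos
    if options.charge_cxa_to_negative_revasc:
        p_cxa += (1.0 - p_pos) * probs.p_revasc_given_neg
    components = {
        "diagnostics": schedule.c_cmr + p_cxa * schedule.c_cxa,
        **_downstream_components(probs, schedule, options),
    }
    return StrategyCost(
        Strategy.CMR_CXA, sum(components.values()), components
    )


def cost_cxa_ffr(
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
) -> StrategyCost:
    """Expected cost of the invasive CXA+FFR strategy.

    Everyone gets a CXA; the ≥50%-stenosis fraction gets an add-on FFR;
    downstream terms are identical to :func:`cost_cmr_cxa` by the
    equal-outcome assumption.
    """
    options = options or AnalysisOptions()
    p_ffr = _require_ffr_eligible(probs)
    components = {
        "diagnostics": schedule.c_cxa + p_ffr * schedule.c_ffr_addon,
        **_downstream_components(probs, schedule, options),
    }
    return StrategyCost(
        Strategy.CXA_FFR, sum(components.values()), components
    )


def cost_cxa_only(
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
) -> StrategyCost:
    """Expected cost of the anatomy-guided CXA-only strategy.

    Everyone gets a CXA and every patient with a ≥50% stenosis (the
    FFR-eligible fraction) is revascularized.  Complication rates are the
    same as in the other arms.
    """
    options = options or AnalysisOptions()
    p_sten = _require_ffr_eligible(probs)
    components = {
        "diagnostics": schedule.c_cxa,
        "revascularization": p_sten * _mix_weighted_revasc_cost(probs, schedule),
        "drugs": (
            p_sten * schedule.c_dual_antiplatelet_year
            if options.charge_dual_antiplatelet_cxa_only
            else 0.0
        ),
        "complications": _complication_cost(probs, schedule, options),
        "followup": (
            p_sten * schedule.c_cardiologist_visit
            if options.include_cardiologist_visit
            else 0.0
        ),
    }
    return StrategyCost(
        Strategy.CXA_ONLY, sum(components.values()), components
    )


_COST_FUNCS = {
    Strategy.CMR_CXA: cost_cmr_cxa,
    Strategy.CXA_FFR: cost_cxa_ffr,
    Strategy.CXA_ONLY: cost_cxa_only,
}


def cost_strategy(
    strategy: Strategy | str,
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
) -> StrategyCost:
    """Dispatch to the cost function for ``strategy``."""
    return _COST_FUNCS[Strategy(strategy)](probs, schedule, options)


def percent_reduction(cost_a: float, cost_b: float) -> float:
    """Percent by which ``cost_a`` undercuts ``cost_b``: 100*(1 - a/b)."""
    if cost_b <= 0:
        raise ValueError(f"reference cost must be positive, got {cost_b}")
    return 100.0 * (1.0 - cost_a / cost_b)


#: Pairwise comparisons reported, in display order.
REDUCTION_PAIRS: tuple[tuple[Strategy, Strategy], ...] = (
    (Strategy.CMR_CXA, Strategy.CXA_FFR),
    (Strategy.CMR_CXA, Strategy.CXA_ONLY),
    (Strategy.CXA_FFR, Strategy.CXA_ONLY),
)


@dataclass(frozen=True)
class ComparisonReport:
    """The three strategy costs plus pairwise percent reductions.

    A reduction is ``None`` (flagged undefined) when its reference cost is
    zero.  Keys of ``reductions`` are ``"<a>_vs_<b>"`` meaning the percent
    by which strategy ``a`` is cheaper than strategy ``b``.
    """

    costs: dict[Strategy, StrategyCost]
    reductions: dict[str, float | None]
    system_label: str
    subgroup_label: str = "total"
    variant_label: str = "main"
    options: AnalysisOptions = dataclasses.field(default_factory=AnalysisOptions)

    def cost_of(self, strategy: Strategy | str) -> float:
        return self.costs[Strategy(strategy)].expected_cost_per_patient


def build_report(
    costs: dict[Strategy, StrategyCost],
    *,
    system_label: str,
    subgroup_label: str = "total",
    variant_label: str = "main",
    options: AnalysisOptions | None = None,
) -> ComparisonReport:
    """Assemble a :class:`ComparisonReport` from three strategy costs."""
    options = options or AnalysisOptions()
    reductions: dict[str, float | None] = {}
    for a, b in REDUCTION_PAIRS:
        cb = costs[b].expected_cost_per_patient
        key = f"{a.value}_vs_{b.value}"
        reductions[key] = (
            percent_reduction(costs[a].expected_cost_per_patient, cb)
            if cb > 0
            else None
        )
    return ComparisonReport(
        costs=costs,
        reductions=reductions,
        system_label=system_label,
        subgroup_label=subgroup_label,
        variant_label=variant_label,
        options=options,
    )


def compare_strategies(
    probs: BranchProbabilities,
    schedule: UnitCostSchedule,
    options: AnalysisOptions | None = None,
    *,
    subgroup_label: str = "total",
    variant_label: str = "main",
) -> ComparisonReport:
    """Evaluate all three strategies and their pairwise percent reductions."""
    options = options or AnalysisOptions()
    costs = {
        s: _COST_FUNCS[s](probs, schedule, options) for s in Strategy
    }
    return build_report(
        costs,
        system_label=schedule.system_label,
        subgroup_label=subgroup_label,
        variant_label=variant_label,
        options=options,
    )
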
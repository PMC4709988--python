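"""Run configuration, pipeline orchestration, and report rendering.

A run is described by a single config file (YAML or JSON): the tariff
schedules per health system, which symptom subgroups to analyze, which
option variants to run (with/without rehabilitation and cardiologist
visit), the stenosis-FFR curve calibration, and the sensitivity/break-even
specifications.  :func:`run_analysis` executes the full pipeline — one
strategy comparison per (system, subgroup, variant) cell plus the
robustness analyses — and :func:`render_reports` writes the comparisons as
JSON, delimited text, or a markdown table.

Rendering is deterministic: stable row ordering, costs rounded to whole
currency units and reductions to one decimal in the human-readable
formats, full precision in JSON.  Every output embeds the config hash and
package version for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import __version__
from .cohort import (
    BranchProbabilities,
    PatientRecord,
    Subgroup,
    derive_branch_probabilities,
    summarize_cohort,
)
from .errors import CadCostError, ConfigError, ReportError
from .sensitivity import (
    BreakEvenResult,
    SensitivityResult,
    break_even_multiplier,
    ffr_fraction_sweep,
    one_way_sensitivity,
)
from .stenosis_ffr import StenosisFfrCurve, calibrate_curve, stenosis_prevalence_from_ffr_rate
from .strategy_costs import (
    AnalysisOptions,
    ComparisonReport,
    Strategy,
    UnitCostSchedule,
    compare_strategies,
)

__all__ = [
    "OptionsVariant",
    "SweepSpec",
    "SensitivitySpec",
    "BreakEvenSpec",
    "RunConfig",
    "load_run_config",
    "dump_run_config",
    "config_hash",
    "resolve_probabilities",
    "RunResults",
    "run_analysis",
    "render_reports",
]

logger = logging.getLogger("cadcost")

_SUBGROUP_LABELS = ("total",) + tuple(sg.value for sg in Subgroup)


class OptionsVariant(AnalysisOptions):
    """An :class:`AnalysisOptions` bundle with a display name."""

    name: str = "main"

    def options(self) -> AnalysisOptions:
        return AnalysisOptions(**self.model_dump(exclude={"name"}))


class SweepSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    lo: float = 0.30
    hi: float = 0.55
    step: float = 0.05
    couple_cxa_only: bool = True


class SensitivitySpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    parameters: tuple[str, ...] = ("c_cmr", "c_cxa", "c_ffr_addon")
    relative_changes: tuple[float, ...] = (-0.10, 0.10)


class BreakEvenSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    parameter: str = "c_ffr_addon"
    pairs: tuple[tuple[str, str], ...] = (("cxa_ffr", "cxa_only"),)


class RunConfig(BaseModel):
    """Validated description of a full analysis run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    cost_schedules: dict[str, UnitCostSchedule] = Field(min_length=1)
    subgroups: tuple[str, ...] = ("total",)
    variants: tuple[OptionsVariant, ...] = (OptionsVariant(),)
    stenosis_ffr_anchors: tuple[tuple[float, float], ...] = ((0.35, 0.062),)
    curve_interpolation: Literal["piecewise_linear", "monotone_spline"] = "piecewise_linear"
    curve_provenance_note: str = ""
    sweep: SweepSpec = SweepSpec()
    sensitivity: SensitivitySpec = SensitivitySpec()
    breakeven: BreakEvenSpec = BreakEvenSpec()
    output_dir: str = "out"
    verbosity: Literal["debug", "info", "warning", "error"] = "info"

    @field_validator("subgroups")
    @classmethod
    def _check_subgroups(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("at least one subgroup is required")
        for sg in v:
            if sg not in _SUBGROUP_LABELS:
                raise ValueError(
                    f"unknown subgroup {sg!r}; allowed: {_SUBGROUP_LABELS}"
                )
        return v

    def curve(self) -> StenosisFfrCurve:
        return calibrate_curve(
            self.stenosis_ffr_anchors,
            kind=self.curve_interpolation,
            provenance_note=self.curve_provenance_note,
        )


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file.

    Schedule entries inherit their mapping key as ``system_label`` when the
    label is not given explicitly.  Schema violations raise
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    schedules = raw.get("cost_schedules")
    if isinstance(schedules, dict):
        for label, sched in schedules.items():
            if isinstance(sched, dict):
                sched.setdefault("system_label", label)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid run config: " + "; ".join(lines)) from exc


def dump_run_config(config: RunConfig, destination: str | Path | IO[str]) -> None:
    """Write a config back out as YAML (round-trips through load)."""
    data = config.model_dump(mode="json")
    text = yaml.safe_dump(data, sort_keys=True)
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 digest of the canonicalized configuration."""
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def resolve_probabilities(
    cohort: Sequence[PatientRecord] | BranchProbabilities,
    subgroup: str = "total",
    curve: StenosisFfrCurve | None = None,
) -> BranchProbabilities:
    """Branch probabilities for one subgroup, with ``p_ffr_eligible`` filled.

    From patient records the probabilities are re-derived within the
    subgroup (not scaled from the whole-cohort tree); the FFR-eligible
    fraction is obtained by inverting the stenosis-FFR curve at the
    subgroup's FFR-positive rate.
    """
    if isinstance(cohort, BranchProbabilities):
        if subgroup != "total":
            raise CadCostError(
                "subgroup analyses need patient records; got bare probabilities"
            )
        probs = cohort
    else:
        summary = summarize_cohort(
            list(cohort), None if subgroup == "total" else subgroup
        )
        probs = derive_branch_probabilities(summary)
    if probs.p_ffr_eligible is None:
        if probs.p_ffr_positive is None:
            raise CadCostError(
                "cannot resolve p_ffr_eligible: p_ffr_positive is undefined"
            )
        probs = probs.replace(
            p_ffr_eligible=stenosis_prevalence_from_ffr_rate(
                probs.p_ffr_positive, curve
            )
        )
    return probs


@dataclass(frozen=True)
class RunResults:
    """Everything a full pipeline run produces."""

    reports: list[ComparisonReport]
    sensitivity_results: list[tuple[str, SensitivityResult]]  # (system, result)
    breakeven_results: list[tuple[str, BreakEvenResult]]
    sweep_reports: list[ComparisonReport]
    run_log: list[str]
    config_digest: str


def run_analysis(
    config: RunConfig,
    cohort: Sequence[PatientRecord] | BranchProbabilities,
) -> RunResults:
    """Execute the full pipeline described by ``config``.

    Produces one strategy comparison per (system, subgroup, variant) cell,
    one-way sensitivity results and break-even solutions per system, and
    the FFR-fraction sweep per system, with a parameter-echoing run log.
    """
    curve = config.curve()
    digest = config_hash(config)
    log: list[str] = [f"config_hash={digest} package_version={__version__}"]

    probs_by_subgroup: dict[str, BranchProbabilities] = {}
    for sg in config.subgroups:
        try:
            probs_by_subgroup[sg] = resolve_probabilities(cohort, sg, curve)
        except CadCostError as exc:
            raise CadCostError(f"subgroup '{sg}': {exc}") from exc
        p = probs_by_subgroup[sg]
        log.append(
            f"subgroup={sg} p_ischemia_pos={p.p_ischemia_pos:.6g} "
            f"p_revasc_given_pos={p.p_revasc_given_pos} "
            f"p_revasc_given_neg={p.p_revasc_given_neg} "
            f"p_ffr_positive={p.p_ffr_positive} p_ffr_eligible={p.p_ffr_eligible:.6g}"
        )

    reports: list[ComparisonReport] = []
    for label, schedule in config.cost_schedules.items():
        for sg in config.subgroups:
            for variant in config.variants:
                try:
                    rep = compare_strategies(
                        probs_by_subgroup[sg],
                        schedule,
                        variant.options(),
                        subgroup_label=sg,
                        variant_label=variant.name,
                    )
                except CadCostError as exc:
                    raise CadCostError(
                        f"system '{label}', subgroup '{sg}', variant "
                        f"'{variant.name}': {exc}"
                    ) from exc
                reports.append(rep)
                log.append(
                    f"compare system={label} subgroup={sg} variant={variant.name} "
                    + " ".join(
                        f"{s.value}={rep.cost_of(s):.6g}" for s in Strategy
                    )
                )

    base_sg = config.subgroups[0]
    base_options = config.variants[0].options()
    sens: list[tuple[str, SensitivityResult]] = []
    brk: list[tuple[str, BreakEvenResult]] = []
    sweeps: list[ComparisonReport] = []
    for label, schedule in config.cost_schedules.items():
        for param in config.sensitivity.parameters:
            for change in config.sensitivity.relative_changes:
                res = one_way_sensitivity(
                    probs_by_subgroup[base_sg],
                    schedule,
                    base_options,
                    parameter=param,
                    relative_change=change,
                )
                sens.append((label, res))
                log.append(
                    f"sensitivity system={label} parameter={param} change={change:+g}"
                )
        for pair in config.breakeven.pairs:
            res_b = break_even_multiplier(
                probs_by_subgroup[base_sg],
                schedule,
                base_options,
                parameter=config.breakeven.parameter,
                pair=pair,
            )
            brk.append((label, res_b))
            log.append(
                f"breakeven system={label} parameter={config.breakeven.parameter} "
                f"pair={pair[0]}|{pair[1]} multiplier={res_b.multiplier} "
                f"solvable={res_b.solvable}"
            )
        sweeps.extend(
            ffr_fraction_sweep(
                probs_by_subgroup[base_sg],
                schedule,
                base_options,
                lo=config.sweep.lo,
                hi=config.sweep.hi,
                step=config.sweep.step,
                couple_cxa_only=config.sweep.couple_cxa_only,
            )
        )
        log.append(
            f"sweep system={label} lo={config.sweep.lo} hi={config.sweep.hi} "
            f"step={config.sweep.step}"
        )

    for line in log:
        logger.info(line)
    return RunResults(
        reports=reports,
        sensitivity_results=sens,
        breakeven_results=brk,
        sweep_reports=sweeps,
        run_log=log,
        config_digest=digest,
    )


_REPORT_COLUMNS = (
    "system",
    "subgroup",
    "variant",
    "cost_cmr_cxa",
    "cost_cxa_ffr",
    "cost_cxa_only",
    "reduction_cmr_cxa_vs_cxa_ffr",
    "reduction_cmr_cxa_vs_cxa_only",
    "reduction_cxa_ffr_vs_cxa_only",
)


def _report_row(rep: ComparisonReport, *, rounded: bool) -> list:
    costs = [rep.cost_of(s) for s in Strategy]
    reds = [
        rep.reductions[f"{a.value}_vs_{b.value}"]
        for a, b in (
            (Strategy.CMR_CXA, Strategy.CXA_FFR),
            (Strategy.CMR_CXA, Strategy.CXA_ONLY),
            (Strategy.CXA_FFR, Strategy.CXA_ONLY),
        )
    ]
    if rounded:
        costs = [round(c) for c in costs]
        reds = [None if r is None else round(r, 1) for r in reds]
    return [rep.system_label, rep.subgroup_label, rep.variant_label, *costs, *reds]


def render_reports(
    reports: Sequence[ComparisonReport],
    format: Literal["json", "delimited", "markdown"] = "json",
    destination: str | Path | None = None,
    *,
    delimiter: str = "\t",
    config_digest: str = "",
) -> str:
    """Render comparison reports; returns the text and optionally writes it.

    JSON keeps full precision; delimited and markdown apply the
    presentation rounding (whole currency units, one-decimal percentages).
    Output embeds the config digest and package version.
    """
    if not reports:
        raise ReportError("no reports to render")

    meta = f"config_hash={config_digest or 'n/a'} package_version={__version__}"
    if format == "json":
        payload = {
            "metadata": {
                "config_hash": config_digest or None,
                "package_version": __version__,
            },
            "reports": [
                {
                    "system": rep.system_label,
                    "subgroup": rep.subgroup_label,
                    "variant": rep.variant_label,
                    "costs": {
                        s.value: rep.cost_of(s) for s in Strategy
                    },
                    "components": {
                        s.value: rep.costs[s].components for s in Strategy
                    },
                    "reductions": rep.reductions,
                }
                for rep in reports
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    elif format == "delimited":
        lines = [f"# {meta}", delimiter.join(_REPORT_COLUMNS)]
        for rep in reports:
            row = _report_row(rep, rounded=True)
            lines.append(
                delimiter.join("" if v is None else str(v) for v in row)
            )
        text = "\n".join(lines) + "\n"
    elif format == "markdown":
        header = "| " + " | ".join(_REPORT_COLUMNS) + " |"
        sep = "|" + "|".join(" --- " for _ in _REPORT_COLUMNS) + "|"
        lines = [header, sep]
        for rep in reports:
            row = _report_row(rep, rounded=True)
            lines.append(
                "| " + " | ".join("—" if v is None else str(v) for v in row) + " |"
            )
        lines.append("")
        lines.append(f"<!-- {meta} -->")
        text = "\n".join(lines) + "\n"
    else:
        raise ReportError(f"unknown format {format!r}")

    if destination is not None:
        dest = Path(destination)
        try:
            dest.parent.mkdir(parents=True, exist_ok=True)
            dest.write_text(text, encoding="utf-8")
        except OSError as exc:
            raise ReportError(f"cannot write report to {dest}: {exc}") from exc
    return text
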
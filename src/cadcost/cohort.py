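"""Patient-level cohort ingestion, summarization and branch probabilities.

The cohort table is the registry-style input of the analysis: one row per
patient with symptom class, stress-perfusion CMR result, revascularization
performed during one-year follow-up, and adverse outcome events.  From a
cohort the module derives (i) a descriptive summary (counts of treatments
and events, overall and per symptom subgroup) and (ii) the branch
probabilities that drive the decision-tree cost model: ischemia prevalence,
revascularization rates conditional on the CMR result, the PCI/CABG type
mix, and marginal complication rates.

Death causes overlap in registry reporting (all-cause death subsumes
cardiac death and death of unknown cause).  Events are therefore stored as
atomic flags on each record; the summary reports all-cause death as the
union of the death flags, with cause-specific counts as sub-tallies, so
complication rates are never double counted.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import CohortFormatError, EmptySelectionError, UndefinedBranchError

__all__ = [
    "Subgroup",
    "Sex",
    "Revascularization",
    "EventType",
    "PatientRecord",
    "CohortSummary",
    "BranchProbabilities",
    "load_cohort",
    "write_cohort",
    "summarize_cohort",
    "derive_branch_probabilities",
]


class Subgroup(str, Enum):
    TYPICAL_ANGINA = "typical_angina"
    ATYPICAL_CHEST_PAIN = "atypical_chest_pain"
    OTHER = "other"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Revascularization(str, Enum):
    NONE = "none"
    PCI_ONLY = "pci_only"
    CABG_ONLY = "cabg_only"
    PCI_AND_CABG = "pci_and_cabg"


class EventType(str, Enum):
    ALL_CAUSE_DEATH = "all_cause_death"
    CARDIAC_DEATH = "cardiac_death"
    DEATH_UNKNOWN_CAUSE = "death_unknown_cause"
    NONFATAL_MI = "nonfatal_mi"
    ABORTED_SCD = "aborted_scd"
    STROKE = "stroke"


#: Death flags whose union defines the all-cause death count.
DEATH_EVENTS = frozenset(
    {EventType.ALL_CAUSE_DEATH, EventType.CARDIAC_DEATH, EventType.DEATH_UNKNOWN_CAUSE}
)

_COLUMNS = (
    "patient_id",
    "subgroup",
    "sex",
    "age_years",
    "cmr_ischemia_positive",
    "revascularization",
    "events",
    "followup_complete",
)

_TRUE_TOKENS = {"true", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "0", "no", "n"}


@dataclass(frozen=True)
class PatientRecord:
    """One registry row: who the patient is and what happened within a year."""

    patient_id: str
    subgroup: Subgroup
    sex: Sex
    age_years: float
    cmr_ischemia_positive: bool
    revascularization: Revascularization
    events: frozenset[EventType]
    followup_complete: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.age_years <= 130.0):
            raise CohortFormatError(
                f"age_years must be in [0, 130], got {self.age_years!r}"
            )
        object.__setattr__(self, "events", frozenset(self.events))

    @property
    def died(self) -> bool:
        """True if any death flag is set (all-cause union semantics)."""
        return bool(self.events & DEATH_EVENTS)


def _parse_bool(token: str, *, line: int, fieldname: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise CohortFormatError(
        f"line {line}: field '{fieldname}': cannot parse boolean from {token!r} "
        f"(allowed: {sorted(_TRUE_TOKENS | _FALSE_TOKENS)})"
    )


def _parse_enum(enum_cls, token: str, *, line: int, fieldname: str, default=None):
    t = token.strip()
    if not t and default is not None:
        return default
    try:
        return enum_cls(t)
    except ValueError:
        allowed = "{" + ", ".join(m.value for m in enum_cls) + "}"
        raise CohortFormatError(
            f"line {line}: field '{fieldname}': unknown value {token!r}; "
            f"allowed values are {allowed}"
        ) from None


def load_cohort(
    source: str | Path | IO[str],
    *,
    delimiter: str = ",",
    missing_token: str = "",
) -> list[PatientRecord]:
    """Read a delimited cohort table into validated records.

    ``source`` may be a path or an open text stream.  A header row naming
    the patient-record fields is required; row order is preserved.  The
    ``missing_token`` (default: empty cell) maps to ``sex=unknown``,
    ``revascularization=none``, no events, and ``followup_complete=true``.
    Malformed rows raise :class:`CohortFormatError` naming the line number
    and field.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return load_cohort(fh, delimiter=delimiter, missing_token=missing_token)

    reader = csv.DictReader(source, delimiter=delimiter, restval=None)
    if reader.fieldnames is None:
        raise CohortFormatError("cohort table is empty: no header row found")
    missing_cols = [c for c in _COLUMNS if c not in reader.fieldnames]
    if missing_cols:
        raise CohortFormatError(
            f"header is missing required column(s): {', '.join(missing_cols)}"
        )

    records: list[PatientRecord] = []
    for row in reader:
        line = reader.line_num
        norm = {}
        for col in _COLUMNS:
            val = row.get(col)
            if val is None:
                raise CohortFormatError(f"line {line}: field '{col}': missing cell")
            norm[col] = "" if val.strip() == missing_token else val.strip()

        try:
            age = float(norm["age_years"])
        except ValueError:
            raise CohortFormatError(
                f"line {line}: field 'age_years': cannot parse number from "
                f"{norm['age_years']!r}"
            ) from None

        events: set[EventType] = set()
        if norm["events"]:
            for tok in norm["events"].split(";"):
                if tok.strip():
                    events.add(
                        _parse_enum(EventType, tok, line=line, fieldname="events")
                    )

        try:
            rec = PatientRecord(
                patient_id=norm["patient_id"],
                subgroup=_parse_enum(
                    Subgroup, norm["subgroup"], line=line, fieldname="subgroup"
                ),
                sex=_parse_enum(
                    Sex, norm["sex"], line=line, fieldname="sex", default=Sex.UNKNOWN
                ),
                age_years=age,
                cmr_ischemia_positive=_parse_bool(
                    norm["cmr_ischemia_positive"],
                    line=line,
                    fieldname="cmr_ischemia_positive",
                ),
                revascularization=_parse_enum(
                    Revascularization,
                    norm["revascularization"],
                    line=line,
                    fieldname="revascularization",
                    default=Revascularization.NONE,
                ),
                events=frozenset(events),
                followup_complete=(
                    _parse_bool(
                        norm["followup_complete"],
                        line=line,
                        fieldname="followup_complete",
                    )
                    if norm["followup_complete"]
                    else True
                ),
            )
        except CohortFormatError as exc:
            if str(exc).startswith("line "):
                raise
            raise CohortFormatError(f"line {line}: {exc}") from None
        records.append(rec)
    return records


def write_cohort(
    records: Iterable[PatientRecord],
    destination: str | Path | IO[str],
    *,
    delimiter: str = ",",
) -> None:
    """Write records in the same delimited format :func:`load_cohort` reads."""
    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            write_cohort(records, fh, delimiter=delimiter)
        return
    writer = csv.writer(destination, delimiter=delimiter, lineterminator="\n")
    writer.writerow(_COLUMNS)
    for rec in records:
        writer.writerow(
            [
                rec.patient_id,
                rec.subgroup.value,
                rec.sex.value,
                f"{rec.age_years:g}",
                "true" if rec.cmr_ischemia_positive else "false",
                rec.revascularization.value,
                ";".join(sorted(e.value for e in rec.events)),
                "true" if rec.followup_complete else "false",
            ]
        )


@dataclass(frozen=True)
class CohortSummary:
    """Counts summarizing a cohort (overall or one symptom subgroup).

    ``event_counts`` reports all-cause death as the union of death flags;
    ``cause_of_death_counts`` carries the cause-specific sub-tallies.
    """

    n_total: int
    n_per_subgroup: dict[str, int]
    n_ischemia_positive: int
    n_revasc_total: int
    n_pci_only: int
    n_cabg_only: int
    n_both: int
    n_revasc_given_cmr_positive: int
    n_revasc_given_cmr_negative: int
    event_counts: dict[str, int]
    cause_of_death_counts: dict[str, int]
    subgroup_label: str = "total"

    def __post_init__(self) -> None:
        if self.n_revasc_total != self.n_pci_only + self.n_cabg_only + self.n_both:
            raise ValueError("revascularization type counts do not sum to the total")
        if (
            self.n_revasc_total
            != self.n_revasc_given_cmr_positive + self.n_revasc_given_cmr_negative
        ):
            raise ValueError("conditional revascularization counts do not sum to the total")
        for name, cnt in {
            "n_ischemia_positive": self.n_ischemia_positive,
            "n_revasc_total": self.n_revasc_total,
            **self.event_counts,
        }.items():
            if not (0 <= cnt <= self.n_total):
                raise ValueError(f"count {name}={cnt} outside [0, n_total]")

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)


def summarize_cohort(
    records: Sequence[PatientRecord],
    subgroup_filter: Subgroup | str | None = None,
) -> CohortSummary:
    """Tally a cohort by exact enumeration, optionally within one subgroup."""
    label = "total"
    if subgroup_filter is not None:
        sg = Subgroup(subgroup_filter)
        records = [r for r in records if r.subgroup == sg]
        label = sg.value
    if not records:
        raise EmptySelectionError(f"no records in subgroup '{label}'")

    per_subgroup = Counter(r.subgroup.value for r in records)
    revasc_types = Counter(
        r.revascularization.value
        for r in records
        if r.revascularization is not Revascularization.NONE
    )
    n_rev_pos = sum(
        1
        for r in records
        if r.revascularization is not Revascularization.NONE and r.cmr_ischemia_positive
    )
    n_rev_neg = sum(
        1
        for r in records
        if r.revascularization is not Revascularization.NONE
        and not r.cmr_ischemia_positive
    )

    event_counts = {
        EventType.ALL_CAUSE_DEATH.value: sum(1 for r in records if r.died),
        EventType.NONFATAL_MI.value: sum(
            1 for r in records if EventType.NONFATAL_MI in r.events
        ),
        EventType.ABORTED_SCD.value: sum(
            1 for r in records if EventType.ABORTED_SCD in r.events
        ),
        EventType.STROKE.value: sum(1 for r in records if EventType.STROKE in r.events),
    }
    cause_counts = {
        EventType.CARDIAC_DEATH.value: sum(
            1 for r in records if EventType.CARDIAC_DEATH in r.events
        ),
        EventType.DEATH_UNKNOWN_CAUSE.value: sum(
            1 for r in records if EventType.DEATH_UNKNOWN_CAUSE in r.events
        ),
    }

    return CohortSummary(
        n_total=len(records),
        n_per_subgroup={sg.value: per_subgroup.get(sg.value, 0) for sg in Subgroup},
        n_ischemia_positive=sum(1 for r in records if r.cmr_ischemia_positive),
        n_revasc_total=sum(revasc_types.values()),
        n_pci_only=revasc_types.get(Revascularization.PCI_ONLY.value, 0),
        n_cabg_only=revasc_types.get(Revascularization.CABG_ONLY.value, 0),
        n_both=revasc_types.get(Revascularization.PCI_AND_CABG.value, 0),
        n_revasc_given_cmr_positive=n_rev_pos,
        n_revasc_given_cmr_negative=n_rev_neg,
        event_counts=event_counts,
        cause_of_death_counts=cause_counts,
        subgroup_label=label,
    )


@dataclass(frozen=True)
class BranchProbabilities:
    """All branch parameters of the three decision trees.

    Conditional rates whose denominator is zero are *undefined* and stored
    as ``None`` — never silently zero — so that cost evaluation refuses to
    price a branch it knows nothing about.  ``p_ffr_eligible`` (the fraction
    of patients with a ≥50% stenosis, who would receive FFR testing in the
    invasive arm) is typically filled in from the stenosis-FFR curve.
    """

    p_ischemia_pos: float
    p_revasc_given_pos: float | None
    p_revasc_given_neg: float | None
    revasc_type_mix: tuple[float, float, float] | None  # (pci_only, cabg_only, both)
    p_nonfatal_mi: float = 0.0
    p_stroke: float = 0.0
    p_aborted_scd: float = 0.0
    p_death: float = 0.0
    p_ffr_eligible: float | None = None
    p_ffr_positive: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "p_ischemia_pos",
            "p_revasc_given_pos",
            "p_revasc_given_neg",
            "p_nonfatal_mi",
            "p_stroke",
            "p_aborted_scd",
            "p_death",
            "p_ffr_eligible",
            "p_ffr_positive",
        ):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1], got {val}")
        if self.revasc_type_mix is not None:
            mix = tuple(float(x) for x in self.revasc_type_mix)
            if len(mix) != 3 or any(x < 0 for x in mix):
                raise ValueError("revasc_type_mix must be 3 non-negative fractions")
            if not math.isclose(sum(mix), 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"revasc_type_mix must sum to 1 within 1e-9, got sum={sum(mix)!r}"
                )
            object.__setattr__(self, "revasc_type_mix", mix)
        if (
            self.p_ffr_positive is not None
            and self.p_ffr_eligible is not None
            and self.p_ffr_positive > self.p_ffr_eligible + 1e-12
        ):
            raise ValueError("p_ffr_positive cannot exceed p_ffr_eligible")

    @property
    def p_revasc_overall(self) -> float:
        """Marginal revascularization rate recombined from the tree branches."""
        if self.p_revasc_given_pos is None or self.p_revasc_given_neg is None:
            raise UndefinedBranchError(
                "overall revascularization rate needs both conditional "
                "revascularization branches to be defined"
            )
        return (
            self.p_ischemia_pos * self.p_revasc_given_pos
            + (1.0 - self.p_ischemia_pos) * self.p_revasc_given_neg
        )

    def replace(self, **changes) -> "BranchProbabilities":
        return dataclasses.replace(self, **changes)


def derive_branch_probabilities(summary: CohortSummary) -> BranchProbabilities:
    """Turn cohort counts into decision-tree branch probabilities.

    Conditional rates use their matching conditional denominators; a zero
    denominator yields an undefined (``None``) rate.  ``p_ffr_positive``
    defaults to the overall revascularization proportion — the equal-outcome
    assumption under which FFR testing in the invasive arm is positive in
    the same fraction of patients that the CMR-guided pathway ends up
    revascularizing.  ``p_ffr_eligible`` is left unset for the stenosis-FFR
    curve to fill.
    """
    if summary.n_total <= 0:
        raise EmptySelectionError("summary has no records")
    n = summary.n_total
    n_pos = summary.n_ischemia_positive
    n_neg = n - n_pos

    p_rev_pos = summary.n_revasc_given_cmr_positive / n_pos if n_pos > 0 else None
    if n_pos == 0 and summary.n_revasc_given_cmr_positive > 0:
        raise ValueError("revascularizations among CMR-positive patients but none positive")
    p_rev_neg = summary.n_revasc_given_cmr_negative / n_neg if n_neg > 0 else None

    mix = None
    if summary.n_revasc_total > 0:
        mix = (
            summary.n_pci_only / summary.n_revasc_total,
            summary.n_cabg_only / summary.n_revasc_total,
            summary.n_both / summary.n_revasc_total,
        )

    return BranchProbabilities(
        p_ischemia_pos=n_pos / n,
        p_revasc_given_pos=p_rev_pos,
        p_revasc_given_neg=p_rev_neg,
        revasc_type_mix=mix,
        p_nonfatal_mi=summary.event_counts[EventType.NONFATAL_MI.value] / n,
        p_stroke=summary.event_counts[EventType.STROKE.value] / n,
        p_aborted_scd=summary.event_counts[EventType.ABORTED_SCD.value] / n,
        p_death=summary.event_counts[EventType.ALL_CAUSE_DEATH.value] / n,
        p_ffr_positive=summary.n_revasc_total / n,
        p_ffr_eligible=None,
    )
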
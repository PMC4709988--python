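"""Exception hierarchy for cadcost.

All package-specific failures derive from :class:`CadCostError` so that
callers (and the CLI) can distinguish model/validation problems from
programming errors.
"""


class CadCostError(Exception):
    """Base class for all cadcost errors."""


class CohortFormatError(CadCostError):
    """A cohort table row failed to parse or validate."""


class EmptySelectionError(CadCostError):
    """A subgroup filter left no records to summarize."""


class UndefinedBranchError(CadCostError):
    """A decision-tree branch probability required for costing is undefined."""


class CurveDomainError(CadCostError):
    """A stenosis-FFR curve was evaluated outside its calibrated range."""


class CurveCalibrationError(CadCostError):
    """Anchor points for a stenosis-FFR curve are invalid (non-monotone, out of range)."""


class SensitivityParameterError(CadCostError):
    """An invalid parameter was requested for a sensitivity or break-even analysis."""


class ConfigError(CadCostError):
    """A run configuration file failed validation."""


class ReportError(CadCostError):
    """Report rendering failed (empty input, unwritable destination, ...)."""
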
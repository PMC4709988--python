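"""Monotone mapping between stenosis prevalence and FFR-positive rate.

Anatomical severity (fraction of patients with a ≥50% diameter stenosis on
angiography) and hemodynamic significance (fraction with fractional flow
reserve ≤ 0.80) are related but far from identical: many intermediate
stenoses do not limit flow, so the FFR-positive rate is well below the
stenosis prevalence.  The invasive decision trees need both quantities —
the ≥50%-stenosis fraction determines who receives FFR testing (and, in
the anatomy-guided arm, who is revascularized), while the FFR-positive
rate is anchored to the observed revascularization rate.

The module represents the relationship as a calibratable monotone curve
through the origin, defined by user-supplied anchor points.  The shipped
default is calibrated to a single literature-extrapolated anchor: a 6.2%
FFR-positive rate corresponding to roughly 35% of patients carrying a
≥50% stenosis.  Users with a published stenosis-FFR regression can
calibrate their own curve and record its source in ``provenance_note``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import CurveCalibrationError, CurveDomainError

__all__ = [
    "StenosisFfrCurve",
    "calibrate_curve",
    "default_curve",
    "ffr_rate_from_stenosis_prevalence",
    "stenosis_prevalence_from_ffr_rate",
    "DEFAULT_ANCHOR",
]

#: Default calibration anchor: (stenosis prevalence, FFR-positive rate).
DEFAULT_ANCHOR: tuple[float, float] = (0.35, 0.062)

InterpolationKind = Literal["piecewise_linear", "monotone_spline"]


@dataclass(frozen=True)
class StenosisFfrCurve:
    """A monotone curve y = f(x): stenosis prevalence x -> FFR-positive rate y.

    ``xs``/``ys`` are the full knot vectors including the origin and the
    linear extension to x = 1; ``anchor_points`` are the user-supplied
    calibration pairs only.
    """

    anchor_points: tuple[tuple[float, float], ...]
    interpolation_kind: InterpolationKind = "piecewise_linear"
    provenance_note: str = ""
    xs: tuple[float, ...] = field(default=(), repr=False)
    ys: tuple[float, ...] = field(default=(), repr=False)

    @property
    def max_ffr_rate(self) -> float:
        """Upper end of the calibrated FFR-positive range."""
        return self.ys[-1]

    def to_dict(self) -> dict:
        return {
            "anchor_points": [list(p) for p in self.anchor_points],
            "interpolation_kind": self.interpolation_kind,
            "provenance_note": self.provenance_note,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StenosisFfrCurve":
        return calibrate_curve(
            [tuple(p) for p in data["anchor_points"]],
            kind=data.get("interpolation_kind", "piecewise_linear"),
            provenance_note=data.get("provenance_note", ""),
        )


def calibrate_curve(
    anchor_pairs: Sequence[tuple[float, float]],
    kind: InterpolationKind = "piecewise_linear",
    provenance_note: str = "",
) -> StenosisFfrCurve:
    """Build a monotone curve through the origin and every anchor.

    Anchors must be strictly increasing in both coordinates and lie in
    (0, 1]^2.  Beyond the last anchor the curve continues linearly with the
    final segment's slope, capped so the FFR-positive rate never exceeds 1.
    """
    if not anchor_pairs:
        raise CurveCalibrationError("at least one anchor pair is required")
    anchors = sorted((float(x), float(y)) for x, y in anchor_pairs)
    for x, y in anchors:
        if not (0.0 < x <= 1.0) or not (0.0 < y <= 1.0):
            raise CurveCalibrationError(
                f"anchor ({x}, {y}) outside (0, 1] x (0, 1]"
            )
    for (x0, y0), (x1, y1) in zip(anchors, anchors[1:]):
        if x1 <= x0 or y1 <= y0:
            raise CurveCalibrationError(
                f"anchors must be strictly increasing in both coordinates; "
                f"({x0}, {y0}) -> ({x1}, {y1}) violates this"
            )

    xs = [0.0] + [a[0] for a in anchors]
    ys = [0.0] + [a[1] for a in anchors]
    x_last, y_last = xs[-1], ys[-1]
    if x_last < 1.0:
        # Continue with the final segment's slope, capped at y = 1.
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        y_end = min(1.0, y_last + slope * (1.0 - x_last))
        xs.append(1.0)
        ys.append(y_end)

    return StenosisFfrCurve(
        anchor_points=tuple(anchors),
        interpolation_kind=kind,
        provenance_note=provenance_note,
        xs=tuple(xs),
        ys=tuple(ys),
    )


def default_curve() -> StenosisFfrCurve:
    """Piecewise-linear curve calibrated to the single default anchor."""
    return calibrate_curve(
        [DEFAULT_ANCHOR],
        kind="piecewise_linear",
        provenance_note=(
            "Single-anchor calibration: ~35% of patients with >=50% diameter "
            "stenosis corresponds to a 6.2% FFR-positive (<=0.80) rate, "
            "extrapolated from published stenosis-FFR correlations. Replace "
            "with a literature regression for study-specific work."
        ),
    )


def _pchip(curve: StenosisFfrCurve) -> PchipInterpolator:
    return PchipInterpolator(np.asarray(curve.xs), np.asarray(curve.ys))


def ffr_rate_from_stenosis_prevalence(
    p_stenosis: float, curve: StenosisFfrCurve | None = None
) -> float:
    """Forward map: fraction with ≥50% stenosis -> FFR-positive rate."""
    curve = curve or default_curve()
    if not (0.0 <= p_stenosis <= 1.0):
        raise CurveDomainError(
            f"stenosis prevalence must be in [0, 1], got {p_stenosis}"
        )
    if curve.interpolation_kind == "piecewise_linear":
        return float(np.interp(p_stenosis, curve.xs, curve.ys))
    return float(_pchip(curve)(p_stenosis))


def stenosis_prevalence_from_ffr_rate(
    p_ffr_positive: float, curve: StenosisFfrCurve | None = None
) -> float:
    """Inverse map: FFR-positive rate -> fraction with ≥50% stenosis.

    Refuses to extrapolate: the rate must lie within the calibrated range
    ``[0, curve.max_ffr_rate]``.
    """
    curve = curve or default_curve()
    if not (0.0 <= p_ffr_positive <= curve.max_ffr_rate):
        raise CurveDomainError(
            f"FFR-positive rate {p_ffr_positive} outside the calibrated range "
            f"[0, {curve.max_ffr_rate:.6g}]; recalibrate the curve rather than "
            f"extrapolating"
        )
    if p_ffr_positive == 0.0:
        return 0.0
    if curve.interpolation_kind == "piecewise_linear":
        # Strict monotonicity makes the linear interpolant exactly invertible
        # by swapping the knot axes.
        return float(np.interp(p_ffr_positive, curve.ys, curve.xs))
    f = _pchip(curve)
    return float(
        brentq(lambda x: float(f(x)) - p_ffr_positive, 0.0, 1.0, xtol=1e-12)
    )
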
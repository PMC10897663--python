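"""Centerline geometry: pixel-scale calibration, polyline arc length, and
the pressure-length regression evaluated at MAP."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError
from .mockloop import PlanarPointSet

__all__ = ["LengthFit", "calibrate_scale", "arc_length", "fit_length_pressure"]


@dataclass(frozen=True)
class LengthFit:
    """Ordinary least-squares line through (pressure, length) pairs.

    ``length_at(P) = intercept + slope * P`` gives the centerline length
    (cm) at any pressure, in particular at the MAP of the pulsatile
    acquisition used for PWV.
    """

    slope_cm_per_mmhg: float
    intercept_cm: float
    pressures_mmhg: tuple
    lengths_cm: tuple

    def length_at(self, pressure_mmhg: float) -> float:
        return self.intercept_cm + self.slope_cm_per_mmhg * pressure_mmhg


def calibrate_scale(point_set: PlanarPointSet) -> float:
    """cm per pixel from the reference scale bar (2.5 cm by default)."""
    seg = point_set.scale_segment_px
    px = float(np.linalg.norm(seg[1] - seg[0]))
    if px == 0:
        raise DegenerateDataError("scale segment endpoints coincide")
    return point_set.scale_length_cm / px


def arc_length(point_set: PlanarPointSet, cm_per_px: float,
               min_points: int = 15) -> float:
    """Polyline arc length (cm): sum of consecutive chords times the scale.

    Piecewise-linear by design — the manual protocol defines only ordered
    points, and the polyline rule is reproducible with a bounded,
    testable discretization error.  Duplicate consecutive points contribute
    zero-length segments and are permitted.
    """
    if cm_per_px <= 0:
        raise ValueError("cm_per_px must be positive")
    pts = point_set.points_px
    if pts.shape[0] < min_points:
        raise ValueError(f"at least {min_points} points required")
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(chords.sum() * cm_per_px)


def fit_length_pressure(pairs) -> LengthFit:
    """OLS fit of centerline length (cm) against pressure (mmHg).

    ``pairs`` is an iterable of (pressure_mmhg, length_cm); at least two
    distinct pressures are required.
    """
    pairs = [(float(p), float(length)) for p, length in pairs]
    if len(pairs) < 2:
        raise ValueError("at least two (pressure, length) pairs required")
    pressures = np.array([p for p, _ in pairs])
    lengths = np.array([l for _, l in pairs])
    if np.ptp(pressures) == 0:
        raise DegenerateDataError("all pressures identical: singular fit")
    slope, intercept = np.polyfit(pressures, lengths, 1)
    return LengthFit(float(slope), float(intercept),
                     tuple(pressures), tuple(lengths))


def length_from_point_sets(point_sets) -> LengthFit:
    """Convenience: calibrate, measure, and fit a batch of point sets."""
    pairs = []
    for ps in point_sets:
        scale = calibrate_scale(ps)
        pairs.append((ps.pressure_mmhg, arc_length(ps, scale)))
    return fit_length_pressure(pairs)
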
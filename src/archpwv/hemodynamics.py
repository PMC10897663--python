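"""Scalar hemodynamic derivations: PWV, stent-graft oversizing, eligibility
windows, and percent changes.

Reporting precision follows clinical convention: pressures to 1 mmHg, PWV
to 0.01 m/s, diameters to 0.1 mm, percentages to 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PWVResult",
    "compute_pwv",
    "oversizing_fraction",
    "eligibility_range",
    "eligibility_bounds",
    "percent_change",
]


@dataclass(frozen=True)
class PWVResult:
    """Pulse wave velocity = centerline length / transit time."""

    pwv_m_s: float
    transit_time_s: float
    length_m: float
    configuration: str = ""

    @property
    def reported(self) -> float:
        """PWV at reporting precision (0.01 m/s)."""
        return round(self.pwv_m_s, 2)


def compute_pwv(length_m: float, transit_time_s: float,
                configuration: str = "") -> PWVResult:
    """Quotient of centerline length (m) and transit time (s)."""
    if length_m <= 0:
        raise ValueError("length_m must be positive")
    if transit_time_s <= 0:
        raise ValueError(
            "transit_time_s must be positive (zero signals a failed or "
            "degenerate upstream correlation)")
    return PWVResult(length_m / transit_time_s, transit_time_s, length_m,
                     configuration)


def oversizing_fraction(d_graft_mm: float, d_aorta_mm: float) -> float:
    """Fractional graft oversizing, ``d_graft / d_aorta - 1``.

    The aortic (landing-zone) diameter is the denominator; this is the
    convention under which a 26 mm graft in a 22.8 mm aorta gives 14% and
    the 10-20% eligibility window inverts to 21.7-23.6 mm.
    """
    if d_graft_mm <= 0 or d_aorta_mm <= 0:
        raise ValueError("diameters must be positive")
    return d_graft_mm / d_aorta_mm - 1.0


def eligibility_bounds(d_graft_mm: float, lo: float, hi: float) -> tuple:
    """Unrounded aortic-diameter bounds achieving oversizing in [lo, hi]."""
    if d_graft_mm <= 0:
        raise ValueError("graft diameter must be positive")
    if not 0 <= lo < hi:
        raise ValueError("need 0 <= lo < hi")
    return d_graft_mm / (1.0 + hi), d_graft_mm / (1.0 + lo)


def eligibility_range(d_graft_mm: float, lo: float, hi: float) -> tuple:
    """Aortic-diameter eligibility window, reported to 0.1 mm.

    Membership decisions elsewhere use the unrounded bounds
    (:func:`eligibility_bounds`); the rounded pair matches the clinical
    reporting convention (e.g. 26 mm graft, 10-20% -> 21.7-23.6 mm).
    """
    d_min, d_max = eligibility_bounds(d_graft_mm, lo, hi)
    return round(d_min, 1), round(d_max, 1)


def percent_change(before: float, after: float) -> float:
    """Relative change in percent, ``100 * (after - before) / before``."""
    if before <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (after - before) / before
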
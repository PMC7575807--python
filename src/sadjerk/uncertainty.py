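"""Uncertainty factor and adjusted estimates combining two zero-points.

When the SAD-jerk selection yields a conservative window P1 and a liberal
window P2, each threshold metric has two candidate values (one per filtered
trace).  Rather than pick one, the two are combined with a weight derived
from how far apart the zero-points are — a construction inspired by the
footprint of uncertainty of interval type-2 fuzzy sets.

The geometry is a right triangle with legs ``a = 1`` and ``b2 = P2 - P1``;
its hypotenuse is ``c = sqrt(b2^2 + 1)`` and the uncertainty factor is

    UF = sin(alpha) = a / c,   UF in (0, 1].

Close zero-points (small b2) give UF near 1 — the liberal result is trusted;
distant zero-points shrink UF toward 0 and the conservative result
dominates.  The adjusted longest period is ``l_adj = l2*UF + l1`` and the
adjusted area is the interpolation ``A_adj = (A2 - A1)*UF + A1``.

Two precision modes exist because the published worked example mixes
conventions: its printed l_adj assumes UF pre-rounded to two decimals, while
its printed A_adj uses UF at full precision.  The default mode (``"full"``)
keeps full floating precision everywhere; ``"paper_compat"`` reproduces both
printed numbers by applying each convention where the example did.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "UncertaintyResult",
    "uncertainty_factor",
    "uf_geometry",
    "adjusted_length",
    "adjusted_area",
    "combine_zero_point_estimates",
]

PRECISION_MODES = ("full", "paper_compat")


def _round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _check_mode(precision_mode: str) -> None:
    if precision_mode not in PRECISION_MODES:
        raise ValueError(f"precision_mode must be one of {PRECISION_MODES}, got {precision_mode!r}")


def uf_geometry(P1: float, P2: float) -> tuple:
    """The triangle behind the uncertainty factor: ``(a, b1, b2, c, UF)``.

    ``b1 = P1`` (the distance from 0 to the first zero-point) is part of the
    construction and is reported, but no formula consumes it.
    """
    if P1 < 1:
        raise ValueError(f"P1 must be >= 1, got {P1}")
    if P2 < P1:
        raise ValueError(f"P2 ({P2}) must be >= P1 ({P1})")
    a = 1.0
    b1 = float(P1)
    b2 = float(P2) - float(P1)
    c = math.sqrt(b2 * b2 + a * a)
    return a, b1, b2, c, a / c


def uncertainty_factor(P1: float, P2: float) -> float:
    """UF = 1 / sqrt((P2 - P1)^2 + 1), strictly decreasing in P2 - P1."""
    return uf_geometry(P1, P2)[4]


def adjusted_length(l1: float, l2: float, UF: float, precision_mode: str = "full") -> int:
    """Adjusted longest period ``l_adj = l2*UF + l1`` in whole seconds.

    In ``paper_compat`` mode UF is rounded to two decimals before use; the
    result is rounded half-away-from-zero to integer seconds in both modes.
    """
    _check_mode(precision_mode)
    if l1 < 0 or l2 < 0:
        raise ValueError("period lengths cannot be negative")
    if not (0 < UF <= 1):
        raise ValueError(f"UF must be in (0, 1], got {UF}")
    if precision_mode == "paper_compat":
        UF = round(UF, 2)
    return _round_half_away(l2 * UF + l1)


def adjusted_area(A1: float, A2: float, UF: float) -> float:
    """Adjusted area ``A_adj = (A2 - A1)*UF + A1`` at full floating precision.

    A convex combination of the two candidate areas for ``UF`` in (0, 1];
    integer rounding is a display concern only.
    """
    if not (0 < UF <= 1):
        raise ValueError(f"UF must be in (0, 1], got {UF}")
    return (A2 - A1) * UF + A1


@dataclass(frozen=True)
class UncertaintyResult:
    """Geometry and adjusted estimates for one pair of zero-points."""

    P1: float
    P2: float
    a: float
    b1: float
    b2: float
    c: float
    alpha: float  # radians, sin(alpha) = a/c
    UF: float
    l1: float
    l2: float
    l_adj: int
    A1: float
    A2: float
    A_adj: float
    precision_mode: str = "full"

    def to_dict(self) -> dict:
        doc = {
            "P1": self.P1,
            "P2": self.P2,
            "a": self.a,
            "b1": self.b1,
            "b2": self.b2,
            "c": self.c,
            "alpha_rad": self.alpha,
            "UF": self.UF,
            "l1_s": self.l1,
            "l2_s": self.l2,
            "l_adj_s": self.l_adj,
            "A1_beats": self.A1,
            "A2_beats": self.A2,
            "A_adj_beats": self.A_adj,
            "A_adj_beats_rounded": _round_half_away(self.A_adj),
            "precision_mode": self.precision_mode,
        }
        if self.precision_mode == "paper_compat":
            # also expose the full-precision results for comparison
            doc["l_adj_s_full_precision"] = adjusted_length(self.l1, self.l2, self.UF, "full")
            doc["UF_rounded"] = round(self.UF, 2)
        return doc


def combine_zero_point_estimates(
    P1: float,
    P2: float,
    l1: float,
    l2: float,
    A1: float,
    A2: float,
    precision_mode: str = "full",
) -> UncertaintyResult:
    """Build the full uncertainty-adjusted result for a pair of zero-points.

    ``l1``/``A1`` are the longest period (s) and area above threshold (beats)
    measured on the P1-filtered trace; ``l2``/``A2`` likewise for P2.  The
    area adjustment always uses UF at full floating precision — in
    ``paper_compat`` mode only the length adjustment switches to the rounded
    factor.
    """
    _check_mode(precision_mode)
    a, b1, b2, c, UF = uf_geometry(P1, P2)
    return UncertaintyResult(
        P1=float(P1),
        P2=float(P2),
        a=a,
        b1=b1,
        b2=b2,
        c=c,
        alpha=math.asin(a / c),
        UF=UF,
        l1=float(l1),
        l2=float(l2),
        l_adj=adjusted_length(l1, l2, UF, precision_mode),
        A1=float(A1),
        A2=float(A2),
        A_adj=adjusted_area(A1, A2, UF),
        precision_mode=precision_mode,
    )
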
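"""Hertz contact analysis of the fabric-leg interface.

Each fabric-leg contact element is treated as two curved elastic bodies in
frictionless normal contact.  With the elastic mismatch factors
k = (1 - nu^2)/(pi E) of the leg and k_F of the fabric, a normal load F, and
the body/tube radii R and R_F:

* contact radius        a = [3 pi F (k + k_F) R R_F / (4 (R + R_F))]^(1/3)
* unit pressure         q = 3 F / (2 pi a^2)
* surface displacement  w(r) = (k + k_F) (pi q / (4 a)) (a^2 - r^2)
* interface pressure    P = F / (2 pi a^2)

so q / P = 3 identically.  The rigid-vs-soft pressure-diversity ratio is

    dP = (w_r / w_s) * (k_s + k_F) / (k_r + k_F)

and because w(0) is itself proportional to (k + k_F) at matched (q, a),
Hertz-consistent displacements give dP = 1 exactly: the pressure delivered
by a stretched compression textile does not depend on how stiff the leg
underneath is.  That algebraic identity is the central result this module
exists to state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "ContactState",
    "DeltaPInputs",
    "PressureRatio",
    "contact_radius",
    "unit_pressure",
    "surface_displacement",
    "interface_pressure",
    "mean_pressure",
    "contact_state",
    "pressure_ratio",
]


@dataclass(frozen=True)
class ContactState:
    """Hertz quantities for one fabric-leg contact element (SI units)."""

    F: float
    a: float
    q: float
    omega: float
    P: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.F < 0 or self.a < 0:
            raise ValueError("F and a must be non-negative")
        if not 0.0 <= self.r <= max(self.a, 0.0):
            raise ValueError("r must lie in [0, a]")


@dataclass(frozen=True)
class DeltaPInputs:
    """Displacements and mismatch factors entering the pressure-diversity ratio.

    ``w_r``/``w_s``: circumferential displacement (m) on the rigid and soft
    leg; ``k_r``/``k_s``/``k_F``: elastic mismatch factors (Pa^-1) of the
    rigid leg, soft leg and fabric.
    """

    w_r: float
    w_s: float
    k_r: float
    k_s: float
    k_F: float

    def __post_init__(self) -> None:
        if self.w_r <= 0 or self.w_s <= 0:
            raise ValueError("displacements must be positive")
        if self.k_r <= 0 or self.k_s <= 0 or self.k_F <= 0:
            raise ValueError("mismatch factors must be positive")


class PressureRatio(NamedTuple):
    """Pressure-diversity ratio with its two constituent ratios."""

    delta_p: float
    w_ratio: float
    k_ratio: float


def contact_radius(F: float, k: float, k_F: float, R: float, R_F: float) -> float:
    """Hertz contact-circle radius a (m); scales as F^(1/3)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if k <= 0 or k_F <= 0:
        raise ValueError("mismatch factors must be positive")
    if R <= 0 or R_F <= 0:
        raise ValueError("radii must be positive")
    if R + R_F == 0:
        raise ZeroDivisionError("R + R_F must be non-zero")
    return (3.0 * math.pi * F * (k + k_F) * R * R_F / (4.0 * (R + R_F))) ** (1.0 / 3.0)


def unit_pressure(F: float, a: float) -> float:
    """Peak (unit) contact pressure q = 3 F / (2 pi a^2), Pa."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if a <= 0:
        if F > 0:
            raise ValueError("a must be positive when F > 0")
        return 0.0
    return 3.0 * F / (2.0 * math.pi * a**2)


def surface_displacement(
    k: float, k_F: float, q: float, a: float, r: float = 0.0
) -> float:
    """Surface displacement w(r) = (k + k_F) (pi q / (4 a)) (a^2 - r^2), m.

    The full-contact condition evaluates at the contact-circle centre r = 0,
    where w = (k + k_F) pi q a / 4; w vanishes at the contact edge r = a.
    """
    if k <= 0 or k_F <= 0:
        raise ValueError("mismatch factors must be positive")
    if q < 0:
        raise ValueError("q must be non-negative")
    if a <= 0:
        raise ValueError("a must be positive")
    if r < 0 or r > a:
        raise ValueError("r must lie in [0, a]")
    return (k + k_F) * (math.pi * q / (4.0 * a)) * (a**2 - r**2)


def interface_pressure(F: float, a: float) -> float:
    """Interface pressure P = F / (2 pi a^2), Pa.

    Defined through the applied normal load over twice the contact-circle
    area, so q / P = 3 for any (F, a).  See :func:`mean_pressure` for the
    conventional mean contact pressure F / (pi a^2).
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if a <= 0:
        if F > 0:
            raise ValueError("a must be positive when F > 0")
        return 0.0
    return F / (2.0 * math.pi * a**2)


def mean_pressure(F: float, a: float) -> float:
    """Mean contact pressure F / (pi a^2), Pa (documented alternate; the
    pipeline uses :func:`interface_pressure`)."""
    if a <= 0:
        if F > 0:
            raise ValueError("a must be positive when F > 0")
        return 0.0
    return F / (math.pi * a**2)


def contact_state(
    F: float, k: float, k_F: float, R: float, R_F: float, r: float = 0.0
) -> ContactState:
    """Evaluate the full contact chain (a, q, w, P) for one load F."""
    a = contact_radius(F, k, k_F, R, R_F)
    if a == 0.0:
        return ContactState(F=F, a=0.0, q=0.0, omega=0.0, P=0.0, r=0.0)
    q = unit_pressure(F, a)
    omega = surface_displacement(k, k_F, q, a, r=min(r, a))
    return ContactState(F=F, a=a, q=q, omega=omega, P=interface_pressure(F, a), r=min(r, a))


def pressure_ratio(inp: DeltaPInputs) -> PressureRatio:
    """Rigid-vs-soft pressure-diversity ratio dP with its factor ratios.

    dP = (w_r / w_s) * (k_s + k_F) / (k_r + k_F).  When both displacements
    come from :func:`surface_displacement` at the same (q, a), w is
    proportional to (k + k_F) and dP = 1 identically.
    """
    denom = inp.k_r + inp.k_F
    if denom == 0 or inp.w_s == 0:
        raise ZeroDivisionError("zero denominator in pressure ratio")
    w_ratio = inp.w_r / inp.w_s
    k_ratio = (inp.k_s + inp.k_F) / denom
    return PressureRatio(delta_p=w_ratio * k_ratio, w_ratio=w_ratio, k_ratio=k_ratio)
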
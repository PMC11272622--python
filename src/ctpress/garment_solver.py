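"""Quasi-static equilibrium of a stretched compression tube on a leg.

The stand-in for a full dynamic finite-element donning simulation: the worn
steady state is what pressure testing reads out, so the solver couples

* the hoop (course-direction) membrane law  T = E_F * eps * h,
* Laplace's law  P = T * kappa = T / radius  (per-radius, the dimensionally
  consistent reading of the membrane relation P = T / C), and
* a tissue-compliance foundation: the leg surface settles inward by
  w = lambda * P with lambda = (k_s + k_F) * pi * a0 / 4 (the Hertz
  surface-displacement at the contact-patch scale a0) or a Winkler bed
  w = P / K.

The coupled state is a damped fixed point on the worn girth C:
eps(C) -> T -> P -> w -> C = C0 - 2 pi w.  Rigid legs (mannequins, or any
tissue with E_s above 1 GPa) do not indent: the foundation is dropped and
the solve reduces to the closed-form Laplace pressure
P = 2 pi E_F h (1/C_F - 1/C0).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .leg_geometry import (
    CrossSection,
    LegModel,
    POSITION_ORDER,
    arc_positions,
    girth,
    local_radius,
)
from .materials import FabricSpec
from .units import pa_to_mmhg

__all__ = [
    "GarmentFit",
    "PressureResult",
    "SolverConfig",
    "GradientProfile",
    "wear_strain",
    "membrane_tension",
    "laplace_pressure",
    "laplace_pressure_from_girth",
    "closed_form_rigid_pressure",
    "local_pressure_profile",
    "foundation_compliance",
    "solve_equilibrium",
    "pressure_gradient_profile",
    "classify_compression",
    "RIGID_MODULUS_THRESHOLD",
    "DEFAULT_CLASS_BANDS",
    "MAX_DESIGN_STRAIN",
]

logger = logging.getLogger(__name__)

#: Tissue moduli at or above this (Pa) are treated as rigid: no indentation.
RIGID_MODULUS_THRESHOLD = 1e9

#: Upper end of the design stretch band for worn compression tubes; strains
#: above it draw a warning (the fabric law is linear only on 15%-80%).
MAX_DESIGN_STRAIN = 0.8

#: Ankle-pressure bands (mmHg, inclusive edges) of the RAL-GZ 387 medical
#: hosiery classes.
DEFAULT_CLASS_BANDS: dict[str, tuple[float, float]] = {
    "I": (18.0, 21.0),
    "II": (23.0, 32.0),
    "III": (34.0, 46.0),
    "IV": (49.0, math.inf),
}


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the equilibrium solve.

    ``foundation``: "hertz" uses lambda = (k_s + k_F) pi a0 / 4 with the
    contact-patch radius ``patch_radius`` (m); "winkler" uses
    w = P / ``winkler_modulus`` (Pa/m).  ``tol`` is the relative girth
    residual, ``damping`` the under-relaxation factor of the fixed point.
    """

    foundation: str = "hertz"
    patch_radius: float = 0.02
    winkler_modulus: float | None = None
    tol: float = 1e-8
    max_iter: int = 200
    damping: float = 0.35

    def __post_init__(self) -> None:
        if self.foundation not in ("hertz", "winkler"):
            raise ValueError("foundation must be 'hertz' or 'winkler'")
        if self.foundation == "winkler" and (
            self.winkler_modulus is None or self.winkler_modulus <= 0
        ):
            raise ValueError("winkler foundation needs a positive winkler_modulus")
        if self.patch_radius <= 0:
            raise ValueError("patch_radius must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class GarmentFit:
    """A fabric tube worn at one labelled position of a leg."""

    fabric: FabricSpec
    leg: LegModel
    position: str

    def __post_init__(self) -> None:
        if self.position not in POSITION_ORDER:
            raise ValueError(f"unknown position {self.position!r}")
        section = self.leg.section(self.position)  # raises if unlabelled
        if self.fabric.relaxed_girth >= girth(section):
            warnings.warn(
                f"garment at {self.position} is slack (tube girth "
                f"{self.fabric.relaxed_girth:.3f} m >= leg girth "
                f"{girth(section):.3f} m); it exerts no pressure",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PressureResult:
    """Equilibrium state at one position: pressure, tension, indentation."""

    position: str
    P_pa: float
    P_mmhg: float
    T: float
    strain: float
    w: float
    iterations: int
    converged: bool
    residual: float


@dataclass(frozen=True)
class GradientProfile:
    """Distal-to-proximal pressure profile with the degressive-gradient flag."""

    results: tuple[PressureResult, ...]
    degressive: bool
    violations: tuple[tuple[str, str], ...]


def wear_strain(C_leg: float, R_F: float) -> float:
    """Circumferential wear strain eps = (C_leg - 2 pi R_F) / (2 pi R_F).

    Floored at zero: a slack garment (tube girth at or above the leg girth)
    exerts nothing.
    """
    if C_leg <= 0 or R_F <= 0:
        raise ValueError("C_leg and R_F must be positive")
    C_F = 2.0 * math.pi * R_F
    eps = (C_leg - C_F) / C_F
    if eps < 0:
        warnings.warn("garment is slack (negative wear strain floored to 0)", stacklevel=2)
        return 0.0
    return eps


def membrane_tension(strain: float, fabric: FabricSpec, warn: bool = True) -> float:
    """Hoop tension per unit length T = E_F * strain * h, N/m."""
    if strain < 0:
        raise ValueError("strain must be non-negative")
    if warn and strain > MAX_DESIGN_STRAIN:
        warnings.warn(
            f"wear strain {strain:.2f} exceeds the {MAX_DESIGN_STRAIN:.0%} design "
            "stretch band; the linear fabric law extrapolates",
            stacklevel=2,
        )
    return fabric.E_F * strain * fabric.h


def laplace_pressure(T: float, radius: float) -> float:
    """Membrane pressure P = T / radius (tension times curvature), Pa."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if T < 0:
        raise ValueError("T must be non-negative")
    return T / radius


def laplace_pressure_from_girth(T: float, C: float) -> float:
    """Girth-accepting wrapper: converts C to the circular radius C / 2 pi."""
    if C <= 0:
        raise ValueError("girth must be positive")
    return laplace_pressure(T, C / (2.0 * math.pi))


def closed_form_rigid_pressure(fabric: FabricSpec, C_leg: float) -> float:
    """Laplace pressure on an unyielding leg: P = 2 pi E_F h (1/C_F - 1/C_leg)."""
    C_F = fabric.relaxed_girth
    if C_leg <= C_F:
        return 0.0
    return 2.0 * math.pi * fabric.E_F * fabric.h * (1.0 / C_F - 1.0 / C_leg)


def local_pressure_profile(
    section: CrossSection, T: float
) -> list[tuple[float, float]]:
    """Laplace pressure around an irregular section: P(s) = T * kappa(s).

    Returns (arc_position, pressure Pa) at every boundary vertex, with the
    curvature radius clipped as in :func:`~ctpress.leg_geometry.local_radius`.
    For near-circular sections the arc mean equals T / mean-radius within a
    few percent.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    fracs = arc_positions(section)
    return [(float(s), T / local_radius(section, float(s))) for s in fracs]


def _is_rigid(fit: GarmentFit) -> bool:
    if fit.leg.rigidity == "rigid":
        return True
    tissue = fit.leg.tissue
    return tissue is not None and tissue.E_s >= RIGID_MODULUS_THRESHOLD


def foundation_compliance(fit: GarmentFit, cfg: SolverConfig) -> float:
    """Foundation compliance lambda (m/Pa) such that w = lambda * P.

    Zero for rigid legs: a mannequin does not indent.  Hertz foundation:
    lambda = (k_s + k_F) pi a0 / 4, the surface displacement per unit
    pressure at the contact-patch scale.  Winkler: 1 / K.
    """
    if _is_rigid(fit):
        return 0.0
    if cfg.foundation == "winkler":
        return 1.0 / cfg.winkler_modulus
    tissue = fit.leg.tissue
    if tissue is None:
        raise ValueError("soft leg needs a TissueModel for the hertz foundation")
    return (tissue.k + fit.fabric.mismatch) * math.pi * cfg.patch_radius / 4.0


def solve_equilibrium(fit: GarmentFit, cfg: SolverConfig | None = None) -> PressureResult:
    """Damped fixed point on the worn girth; returns the converged state.

    Iterates eps = wear_strain(C), T = E_F eps h, P = 2 pi T / C,
    w = lambda P, C_target = C0 - 2 pi w until the relative girth update
    falls below ``cfg.tol``.  Non-convergence within ``cfg.max_iter`` is
    flagged, not raised.  A slack garment returns a zero-pressure result.
    """
    cfg = cfg or SolverConfig()
    fabric = fit.fabric
    section = fit.leg.section(fit.position)
    C0 = girth(section)
    C_F = fabric.relaxed_girth
    if C0 <= C_F:
        return PressureResult(
            position=fit.position, P_pa=0.0, P_mmhg=0.0, T=0.0, strain=0.0,
            w=0.0, iterations=0, converged=True, residual=0.0,
        )
    lam = foundation_compliance(fit, cfg)

    def pressure_at(C: float) -> tuple[float, float, float]:
        eps = max((C - C_F) / C_F, 0.0)
        T = membrane_tension(eps, fabric, warn=False)
        return eps, T, laplace_pressure_from_girth(T, C)

    C = C0
    residual = math.inf
    iterations = 0
    converged = False
    for iterations in range(1, cfg.max_iter + 1):
        _, _, P = pressure_at(C)
        C_target = C0 - 2.0 * math.pi * lam * P
        C_new = C + cfg.damping * (C_target - C)
        residual = abs(C_new - C) / C0
        C = C_new
        if residual < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "equilibrium at %s did not converge in %d iterations (residual %.2e)",
            fit.position, cfg.max_iter, residual,
        )
    eps, T, P = pressure_at(C)
    if eps > MAX_DESIGN_STRAIN:
        warnings.warn(
            f"worn strain {eps:.2f} exceeds the {MAX_DESIGN_STRAIN:.0%} design band",
            stacklevel=2,
        )
    return PressureResult(
        position=fit.position,
        P_pa=P,
        P_mmhg=pa_to_mmhg(P),
        T=T,
        strain=eps,
        w=lam * P,
        iterations=iterations,
        converged=converged,
        residual=residual,
    )


def pressure_gradient_profile(
    leg: LegModel,
    fits: list[GarmentFit],
    cfg: SolverConfig | None = None,
    tol_mmhg: float = 1.0,
) -> GradientProfile:
    """Solve every labelled position and flag the degressive gradient.

    Medical compression should decrease distal to proximal:
    P_B >= P_B1 >= P_C >= P_D within ``tol_mmhg``.  Violating adjacent pairs
    are named in the result.  Every labelled section of the leg must have a
    fit.
    """
    by_pos = {f.position: f for f in fits}
    labelled = [lab for lab in POSITION_ORDER if lab in leg.labels]
    missing = [lab for lab in labelled if lab not in by_pos]
    if missing:
        raise ValueError(f"missing garment fits for positions: {missing}")
    results = tuple(solve_equilibrium(by_pos[lab], cfg) for lab in labelled)
    violations = []
    for lo, hi in zip(results, results[1:]):
        if hi.P_mmhg > lo.P_mmhg + tol_mmhg:
            violations.append((lo.position, hi.position))
    return GradientProfile(
        results=results, degressive=not violations, violations=tuple(violations)
    )


def classify_compression(
    P_ankle_mmhg: float, bands: dict[str, tuple[float, float]] | None = None
) -> str:
    """RAL-style compression class of an ankle pressure (band edges inclusive).

    Returns "I"/"II"/"III"/"IV" or "none" when the pressure falls between or
    outside the configured bands.
    """
    if P_ankle_mmhg < 0:
        raise ValueError("pressure must be non-negative")
    bands = bands or DEFAULT_CLASS_BANDS
    for label, (lo, hi) in bands.items():
        if lo <= P_ankle_mmhg <= hi:
            return label
    return "none"
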
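"""Seeded generators that emulate a compression-textile pressure study.

Every stage of the pipeline is testable without measured data: parametric
legs (Fourier-perturbed ellipses with degressive girths at the B/B1/C/D
levels), knitted fabric batches drawn inside the measured property ranges
of the bundled reference samples, shear-wave elastography site readings,
and pneumatic pressure-sensor measurements with +/-3 mmHg instrument noise.

All generators are pure functions of (spec, seed): a single root seed is
fanned out by stable `numpy.random.SeedSequence` spawn keys per entity, so
adding a subject never perturbs earlier subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LinearRing

from .materials import MUSCLE_DENSITY, FabricSpec, SWERecord, TissueModel, swe_modulus
from .leg_geometry import POSITION_ORDER, CrossSection, LegModel, girth

__all__ = [
    "CohortSpec",
    "generate_leg",
    "generate_fabric",
    "generate_garment_set",
    "simulate_swe",
    "simulate_picopress",
    "swe_recovery_error",
    "with_tissue",
    "as_rigid",
    "STIFFNESS_LEVELS",
    "DEFAULT_GIRTH_RANGES",
    "DEFAULT_HEIGHTS",
    "FABRIC_RANGES",
    "STRAIN_TARGETS",
    "POSITION_STRAIN_FACTOR",
]

#: Named soft-tissue stiffness presets (Pa): the light / middle / strong
#: muscle stiffness levels compared by the study design.
STIFFNESS_LEVELS: dict[str, float] = {"LS-1": 1400.0, "LS-2": 2200.0, "LS-3": 3000.0}

#: Per-position girth ranges (m) of the synthetic cohort: ankle girths of
#: 20-24 cm rising to 33-38 cm calves, the usual adult lower-leg envelope.
DEFAULT_GIRTH_RANGES: dict[str, tuple[float, float]] = {
    "B": (0.20, 0.24),
    "B1": (0.26, 0.30),
    "C": (0.33, 0.38),
    "D": (0.32, 0.36),
}

#: Heights (m) of the measurement levels above the foot plane, spanning an
#: ankle-to-below-knee distance of ~35 cm.
DEFAULT_HEIGHTS: dict[str, float] = {"B": 0.04, "B1": 0.12, "C": 0.24, "D": 0.35}

#: Measured property envelopes of the reference fabric batch, SI units.
FABRIC_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "I": {"E_F": (0.33e6, 0.38e6), "E_Fy": (0.14e6, 0.22e6), "G_F": (0.14e6, 0.17e6)},
    "III": {"E_F": (0.33e6, 0.76e6), "E_Fy": (0.14e6, 0.27e6), "G_F": (0.14e6, 0.30e6)},
}
_COMMON_RANGES = {
    "h": (0.62e-3, 0.69e-3),
    "v_F": (0.19, 0.25),
    "MD": (468.2, 532.7),
    "L_F": (0.055, 0.075),
}

#: Wear-strain targets for standalone single-tube draws, inside the 15%-80%
#: design stretch band (class III tubes are worn at higher stretch).
STRAIN_TARGETS: dict[str, tuple[float, float]] = {"I": (0.30, 0.45), "III": (0.42, 0.58)}

#: Target ankle (B) pressure bands per compression class, mmHg.  Garment
#: sets are designed to a drawn ankle pressure inside the class band, the
#: way standardized graduated hosiery is knitted to a pressure, not to a
#: stretch.
PRESSURE_TARGETS_MMHG: dict[str, tuple[float, float]] = {"I": (18.0, 21.0), "III": (34.0, 40.0)}

#: Degressive design factors: the target pressure tapers from the ankle (B)
#: to the below-knee (D) level, mirroring the distal-to-proximal profile of
#: graduated compression (below-knee ~60% of ankle pressure).
POSITION_PRESSURE_FACTOR: dict[str, float] = {"B": 1.0, "B1": 0.82, "C": 0.70, "D": 0.62}

#: Worn-strain bounds the garment designer respects (the linear fabric law
#: holds on the 15%-80% stretch band).
_STRAIN_BOUNDS = (0.15, 0.78)

# spawn-key name spaces for the per-entity generator fan-out
_NS_LEG, _NS_FABRIC, _NS_GARMENT, _NS_MEASURE, _NS_SWE = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition envelope of a synthetic cohort."""

    n_subjects: int = 3
    seed: int = 0
    girth_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GIRTH_RANGES)
    )
    heights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HEIGHTS))
    stiffness_range: tuple[float, float] = (1400.0, 3000.0)
    irregularity: float = 0.1
    classes: tuple[str, ...] = ("I", "III")
    n_points: int = 128

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.stiffness_range
        if not 0 < lo <= hi:
            raise ValueError("stiffness_range must be positive and ordered")
        if hi > 1e4:
            warnings.warn(
                "stiffness_range extends beyond the physiological muscle band "
                "(<= 0.01 MPa)",
                stacklevel=2,
            )
        if not 0.0 <= self.irregularity <= 0.3:
            raise ValueError("irregularity must lie in [0, 0.3]")
        for cls in self.classes:
            if cls not in ("I", "III"):
                raise ValueError(f"unknown compression class {cls!r}")
        for pos, (a, b) in self.girth_ranges.items():
            if pos not in POSITION_ORDER or a <= 0 or b < a:
                raise ValueError(f"bad girth range for {pos!r}: {(a, b)}")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")


def _rng(root_seed: int, *key: int) -> np.random.Generator:
    """Stable per-entity stream: root seed plus a spawn-key name space."""
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=key))


def _perturbed_ellipse(
    rng: np.random.Generator,
    target_girth: float,
    aspect: float,
    irregularity: float,
    n_points: int,
    z: float,
    label: str,
) -> CrossSection:
    th = 2.0 * math.pi * np.arange(n_points) / n_points
    r = np.ones_like(th)
    if irregularity > 0.0:
        modes = (2, 3, 4)
        amps = rng.uniform(0.2, 1.0, size=len(modes))
        amps *= irregularity / amps.sum()  # total perturbation <= irregularity
        phases = rng.uniform(0.0, 2.0 * math.pi, size=len(modes))
        for m, c, phi in zip(modes, amps, phases):
            r += c * np.cos(m * th + phi)
    pts = np.column_stack([r * np.cos(th), aspect * r * np.sin(th)])
    ring = np.vstack([pts, pts[:1]])
    perimeter = float(np.sum(np.linalg.norm(np.diff(ring, axis=0), axis=1)))
    pts *= target_girth / perimeter  # perimeter is homogeneous of degree 1
    if not LinearRing(pts).is_simple:
        raise ValueError("generated section self-intersects; lower irregularity")
    return CrossSection(z=z, points=pts, label=label)


def generate_leg(
    spec: CohortSpec, subject_index: int, rigidity: str = "soft"
) -> LegModel:
    """One synthetic leg: labelled sections with degressive-compatible girths.

    Girths are drawn uniformly inside the per-position ranges with the ankle
    girth constrained at or below the calf girth.  Deterministic per
    (spec.seed, subject_index).
    """
    if not 0 <= subject_index:
        raise ValueError("subject_index must be >= 0")
    rng = _rng(spec.seed, _NS_LEG, subject_index)
    ranges = spec.girth_ranges
    if "B" in ranges and "C" in ranges and ranges["B"][0] > ranges["C"][1]:
        raise ValueError("infeasible girth ordering: min ankle girth exceeds max calf girth")
    for _ in range(100):
        girths = {pos: float(rng.uniform(*ranges[pos])) for pos in POSITION_ORDER if pos in ranges}
        if "B" not in girths or "C" not in girths or girths["B"] <= girths["C"]:
            break
    else:
        raise ValueError("could not draw a degressive-compatible girth set")
    if "D" in girths and "C" in girths:
        # the below-knee level sits just under the calf bulge: draw its girth
        # in [0.93, 1.0] x calf girth, intersected with the configured range
        lo = max(ranges["D"][0], 0.93 * girths["C"])
        hi = min(ranges["D"][1], girths["C"])
        girths["D"] = float(rng.uniform(lo, hi)) if lo < hi else min(hi, girths["C"])
    aspect = float(rng.uniform(0.78, 0.95))
    sections = []
    for pos in POSITION_ORDER:
        if pos not in girths:
            continue
        sections.append(
            _perturbed_ellipse(
                rng,
                target_girth=girths[pos],
                aspect=aspect,
                irregularity=spec.irregularity,
                n_points=spec.n_points,
                z=spec.heights[pos],
                label=pos,
            )
        )
    E_s = float(rng.uniform(*spec.stiffness_range))
    if rigidity == "rigid":
        tissue = TissueModel.from_modulus(3.0e9, nu=0.3)
    else:
        tissue = TissueModel.from_modulus(E_s, nu=0.5)
    return LegModel(sections=tuple(sections), rigidity=rigidity, tissue=tissue)


def with_tissue(leg: LegModel, E_s: float, nu: float = 0.5) -> LegModel:
    """The same geometry backed by a different soft-tissue stiffness."""
    return replace(leg, rigidity="soft", tissue=TissueModel.from_modulus(E_s, nu=nu))


def as_rigid(leg: LegModel, E: float = 3.0e9, nu: float = 0.3) -> LegModel:
    """The same geometry as a rigid mannequin (printed-polymer stiffness)."""
    return replace(leg, rigidity="rigid", tissue=TissueModel.from_modulus(E, nu=nu))


def generate_fabric(
    compression_class: str,
    seed: int,
    target_girth: float = 0.25,
    position: str = "B",
    strain_target: float | None = None,
    label: str | None = None,
) -> FabricSpec:
    """One synthetic tube drawn inside the reference property envelopes.

    The relaxed tube radius is scaled to the target leg girth so the wear
    strain lands in the design stretch band; class III tubes draw stiffer
    course moduli and higher strain targets than class I.
    """
    if compression_class not in FABRIC_RANGES:
        raise ValueError(f"unknown compression class {compression_class!r}")
    rng = _rng(seed, _NS_FABRIC, POSITION_ORDER.index(position))
    return _draw_fabric(rng, compression_class, target_girth, position, strain_target, label)


def _draw_fabric(
    rng: np.random.Generator,
    compression_class: str,
    target_girth: float,
    position: str,
    strain_target: float | None,
    label: str | None,
) -> FabricSpec:
    cls_ranges = FABRIC_RANGES[compression_class]
    if strain_target is None:
        strain_target = float(rng.uniform(*STRAIN_TARGETS[compression_class]))
    R_F = target_girth / (2.0 * math.pi * (1.0 + strain_target))
    return FabricSpec(
        label=label or f"synthetic/{compression_class}/{position}",
        R_F=R_F,
        L_F=float(rng.uniform(*_COMMON_RANGES["L_F"])),
        h=float(rng.uniform(*_COMMON_RANGES["h"])),
        MD=float(rng.uniform(*_COMMON_RANGES["MD"])),
        E_F=float(rng.uniform(*cls_ranges["E_F"])),
        E_Fy=float(rng.uniform(*cls_ranges["E_Fy"])),
        v_F=float(rng.uniform(*_COMMON_RANGES["v_F"])),
        G_F=float(rng.uniform(*cls_ranges["G_F"])),
        compression_class=compression_class,
    )


def generate_garment_set(
    compression_class: str, seed: int, leg: LegModel, subject_index: int = 0
) -> dict[str, FabricSpec]:
    """One graduated tube per labelled leg position, designed to pressure.

    A target ankle pressure is drawn inside the class band and tapered by
    the degressive position factors; one course modulus is drawn per
    garment (one yarn lot) from the feasible part of the class envelope,
    and the rigid Laplace law P = 2 pi E_F h eps / C is inverted for the
    per-position wear strain and relaxed tube radius.  If even the stiffest
    class fabric cannot reach the target inside the design stretch band,
    the whole target profile is scaled down, preserving its shape — so the
    generated set is degressive by construction.
    """
    from .units import mmhg_to_pa

    if compression_class not in FABRIC_RANGES:
        raise ValueError(f"unknown compression class {compression_class!r}")
    cls_idx = 0 if compression_class == "I" else 1
    rng = _rng(seed, _NS_GARMENT, subject_index, cls_idx)
    girths = leg.girths()
    positions = [p for p in POSITION_ORDER if p in girths]
    P_ankle = mmhg_to_pa(float(rng.uniform(*PRESSURE_TARGETS_MMHG[compression_class])))
    targets = {p: P_ankle * POSITION_PRESSURE_FACTOR[p] for p in positions}
    h = {p: float(rng.uniform(*_COMMON_RANGES["h"])) for p in positions}
    # modulus-strain product each position needs: E_F * eps = P C / (2 pi h)
    need = {p: targets[p] * girths[p] / (2.0 * math.pi * h[p]) for p in positions}
    eps_lo, eps_hi = _STRAIN_BOUNDS
    cls_lo, cls_hi = FABRIC_RANGES[compression_class]["E_F"]
    ef_lo = max(cls_lo, max(need.values()) / eps_hi)
    ef_hi = min(cls_hi, min(need.values()) / eps_lo)
    if ef_lo <= ef_hi:
        E_F = float(rng.uniform(ef_lo, ef_hi))
    else:
        # infeasible target on this leg: take the stiffest class fabric and
        # scale the whole profile down to the stretch band
        E_F = cls_hi
        scale = min(1.0, eps_hi * E_F / max(need.values()))
        targets = {p: v * scale for p, v in targets.items()}
        need = {p: v * scale for p, v in need.items()}
    cls_ranges = FABRIC_RANGES[compression_class]
    out = {}
    for pos in positions:
        eps = need[pos] / E_F
        out[pos] = FabricSpec(
            label=f"synthetic/S{subject_index}/{compression_class}/{pos}",
            R_F=girths[pos] / (2.0 * math.pi * (1.0 + eps)),
            L_F=float(rng.uniform(*_COMMON_RANGES["L_F"])),
            h=h[pos],
            MD=float(rng.uniform(*_COMMON_RANGES["MD"])),
            E_F=E_F,
            E_Fy=float(rng.uniform(*cls_ranges["E_Fy"])),
            v_F=float(rng.uniform(*_COMMON_RANGES["v_F"])),
            G_F=float(rng.uniform(*cls_ranges["G_F"])),
            compression_class=compression_class,
        )
    return out


def simulate_swe(
    E_true: float,
    n_sites: int = 8,
    noise_cv: float = 0.1,
    seed: int = 0,
    subject: str = "SYN",
) -> list[SWERecord]:
    """Shear-wave elastography site readings around a true tissue modulus.

    ``noise_cv`` is the coefficient of variation of the per-site modulus
    (the elasticity value the instrument maps); site velocities follow as
    v = sqrt(modulus / (3 rho_m)).  Sites alternate between the ankle (B)
    and calf (C) windows, mirroring a two-region, four-direction protocol.
    With cv = 0 every site converts back to exactly E_true.
    """
    if E_true <= 0:
        raise ValueError("E_true must be positive")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = _rng(seed, _NS_SWE)
    z = rng.standard_normal(n_sites)
    moduli = E_true * np.clip(1.0 + noise_cv * z, 0.05, None)
    records = []
    for i, m in enumerate(moduli):
        v = math.sqrt(m / (3.0 * MUSCLE_DENSITY))
        records.append(
            SWERecord(subject=subject, position="B" if i % 2 == 0 else "C", velocity=v)
        )
    return records


def swe_recovery_error(
    E_true: float = 2976.0,
    noise_cv: float = 0.1,
    n_sites: int = 8,
    n_seeds: int = 200,
    seed: int = 0,
) -> float:
    """Monte-Carlo mean absolute relative error of the SWE mean-modulus recovery."""
    from .materials import mean_swe_modulus

    errs = []
    for i in range(n_seeds):
        recs = simulate_swe(E_true, n_sites=n_sites, noise_cv=noise_cv, seed=seed * n_seeds + i)
        errs.append(abs(mean_swe_modulus(recs) - E_true) / E_true)
    return float(np.mean(errs))


def simulate_picopress(
    P_true_mmhg,
    seed: int = 0,
    noise_mmhg: float = 3.0,
    distribution: str = "uniform",
    rng: np.random.Generator | None = None,
):
    """Pneumatic pressure-sensor reading(s) of a true pressure, mmHg.

    Instrument noise is uniform over +/-``noise_mmhg`` (the stated sensor
    precision; a Gaussian alternative with sigma = noise/2 is available),
    the reading is floored at zero and rounded to the 1 mmHg instrument
    resolution.  ``noise_mmhg = 0`` disables the instrument model entirely
    (identity).  Accepts scalars or arrays.
    """
    P = np.asarray(P_true_mmhg, dtype=float)
    if np.any(P < 0):
        raise ValueError("true pressure must be non-negative")
    if noise_mmhg < 0:
        raise ValueError("noise_mmhg must be non-negative")
    if noise_mmhg == 0.0:
        return float(P) if P.ndim == 0 else P.copy()
    gen = rng if rng is not None else _rng(seed, _NS_MEASURE)
    if distribution == "uniform":
        noise = gen.uniform(-noise_mmhg, noise_mmhg, size=P.shape)
    elif distribution == "gaussian":
        noise = gen.normal(0.0, noise_mmhg / 2.0, size=P.shape)
    else:
        raise ValueError(f"unknown noise distribution {distribution!r}")
    out = np.round(np.clip(P + noise, 0.0, None))
    return float(out) if out.ndim == 0 else out
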
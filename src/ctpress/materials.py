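"""Constitutive conversions for compression fabrics and leg soft tissue.

The mechanical chain handled here:

* knitted compression fabrics characterised by uniaxial tension tests,
  ``E = F_T / (b h eps)`` averaged over the recorded stretch states;
* leg soft-tissue Young's modulus from shear-wave elastography (SWE),
  ``E_S = 3 rho_m v^2`` with muscle density 1000 kg/m^3;
* neo-Hookean hyperelastic constants for an isotropic, (nearly)
  incompressible tissue, ``C10 = S/2`` and ``D1 = B/2`` with the shear and
  bulk moduli from standard linear isotropic elasticity;
* the elastic mismatch factor ``k = (1 - nu^2) / (pi E)`` that enters the
  Hertz contact formulas.

A reference batch of measured compression-textile samples (three subjects,
compression classes I and III, leg positions B through D) and the matching
regional SWE moduli are bundled for worked examples and round-trip tests.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "FabricSpec",
    "TensileRecord",
    "SWERecord",
    "TissueModel",
    "fabric_modulus_from_tension",
    "swe_modulus",
    "mean_swe_modulus",
    "neo_hookean_params",
    "mismatch_factor",
    "reference_fabrics",
    "reference_fabric",
    "reference_swe_records",
    "read_fabric_csv",
    "write_fabric_csv",
    "read_swe_csv",
    "REFERENCE_SWE_PA",
    "REFERENCE_SWE_REPORTED_MEAN_PA",
    "MUSCLE_DENSITY",
    "MAX_SHEAR_WAVE_VELOCITY",
]

#: Default muscle density used by the SWE conversion, kg/m^3.
MUSCLE_DENSITY = 1000.0

#: Upper end of the physiological shear-wave velocity range, m/s.  Faster
#: readings are accepted with a warning (they usually indicate the probe
#: caught bone or fascia rather than muscle).
MAX_SHEAR_WAVE_VELOCITY = 7.7


@dataclass(frozen=True)
class FabricSpec:
    """One tubular compression-textile sample.

    Lengths in m, moduli in Pa, mass density in kg/m^3.  ``R_F`` is the
    relaxed circumferential radius of the tube, ``h`` the fabric thickness,
    ``E_F``/``E_Fy`` the course/wale tensile moduli, ``G_F`` the shear
    modulus from a pure-shear (KES-FB3 style) test.
    """

    label: str
    R_F: float
    L_F: float
    h: float
    MD: float
    E_F: float
    E_Fy: float
    v_F: float
    G_F: float
    compression_class: str = "I"

    def __post_init__(self) -> None:
        for name in ("R_F", "L_F", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.MD <= 0:
            raise ValueError("MD must be positive")
        for name in ("E_F", "E_Fy", "G_F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.v_F < 0.5:
            raise ValueError(f"v_F must lie in [0, 0.5), got {self.v_F!r}")
        if self.compression_class not in ("I", "III"):
            raise ValueError(f"unknown compression class {self.compression_class!r}")

    @property
    def relaxed_girth(self) -> float:
        """Tube circumference in the tension-free state, m."""
        return 2.0 * math.pi * self.R_F

    @property
    def mismatch(self) -> float:
        """Elastic mismatch factor k_F = (1 - v_F^2)/(pi E_F), Pa^-1."""
        return mismatch_factor(self.E_F, self.v_F)


@dataclass(frozen=True)
class TensileRecord:
    """One recorded state of a uniaxial fabric tension test.

    ``F_T`` clamp force in N, ``b`` sample width along the clamp in m,
    ``h`` fabric thickness in m, ``strain`` the engineering strain of the
    clamped length (dimensionless, > 0).
    """

    F_T: float
    b: float
    h: float
    strain: float

    def __post_init__(self) -> None:
        if self.F_T < 0:
            raise ValueError("F_T must be non-negative")
        if self.b <= 0 or self.h <= 0:
            raise ValueError("b and h must be positive")
        if self.strain <= 0:
            raise ValueError("strain must be positive")


@dataclass(frozen=True)
class SWERecord:
    """One shear-wave elastography site reading.

    Exactly one of ``velocity`` (m/s) or ``modulus`` (Pa) must be given;
    instruments report either the wave speed or the elasticity map value.
    """

    subject: str
    position: str
    velocity: float | None = None
    modulus: float | None = None
    rho_m: float = MUSCLE_DENSITY

    def __post_init__(self) -> None:
        if (self.velocity is None) == (self.modulus is None):
            raise ValueError("provide exactly one of velocity or modulus")
        if self.rho_m <= 0:
            raise ValueError("rho_m must be positive")
        if self.velocity is not None:
            if self.velocity < 0:
                raise ValueError("velocity must be non-negative")
            if self.velocity > MAX_SHEAR_WAVE_VELOCITY:
                warnings.warn(
                    f"shear-wave velocity {self.velocity:.2f} m/s exceeds the "
                    f"physiological range (0-{MAX_SHEAR_WAVE_VELOCITY} m/s)",
                    stacklevel=2,
                )
        if self.modulus is not None and self.modulus < 0:
            raise ValueError("modulus must be non-negative")


@dataclass(frozen=True)
class TissueModel:
    """Homogeneous isotropic soft-tissue model.

    ``E_s`` Young's modulus (Pa), ``nu`` Poisson ratio (0.5 = incompressible),
    ``C10``/``D1`` neo-Hookean constants (D1 = +inf for nu = 0.5), ``k`` the
    Hertz elastic mismatch factor (Pa^-1).
    """

    E_s: float
    nu: float
    C10: float
    D1: float
    k: float

    def __post_init__(self) -> None:
        if self.E_s <= 0:
            raise ValueError("E_s must be positive")
        if not 0.0 < self.nu <= 0.5:
            raise ValueError("nu must lie in (0, 0.5]")
        if self.C10 <= 0 or self.k <= 0:
            raise ValueError("C10 and k must be positive")

    @property
    def incompressible(self) -> bool:
        return math.isinf(self.D1)

    @classmethod
    def from_modulus(cls, E_s: float, nu: float = 0.5) -> "TissueModel":
        """Build the full model from (E_s, nu) alone."""
        C10, D1 = neo_hookean_params(E_s, nu)
        return cls(E_s=E_s, nu=nu, C10=C10, D1=D1, k=mismatch_factor(E_s, nu))


def fabric_modulus_from_tension(records: list[TensileRecord]) -> float:
    """Fabric Young's modulus from a set of tension-test states.

    Each state yields ``F_T / (b h strain)``; the modulus is the mean over
    the recorded stretch states, which averages out the mild non-linearity
    of the knitted stress-strain curve.
    """
    if not records:
        raise ValueError("need at least one tensile record")
    vals = []
    for rec in records:
        if rec.strain <= 0:
            raise ValueError("strain must be positive")
        vals.append(rec.F_T / (rec.b * rec.h * rec.strain))
    return sum(vals) / len(vals)


def swe_modulus(rec: SWERecord) -> float:
    """Young's modulus (Pa) of one SWE site: E_S = 3 rho_m v^2.

    If the record already carries a modulus it is returned as-is.
    """
    if rec.modulus is not None:
        return rec.modulus
    return 3.0 * rec.rho_m * rec.velocity**2


def mean_swe_modulus(records: list[SWERecord]) -> float:
    """Arithmetic mean modulus (Pa) over one subject's SWE sites.

    Mixing subjects in one call is an error: regional readings are only
    averaged within a subject.
    """
    if not records:
        raise ValueError("need at least one SWE record")
    subjects = {rec.subject for rec in records}
    if len(subjects) > 1:
        raise ValueError(f"records mix subjects: {sorted(subjects)}")
    vals = [swe_modulus(rec) for rec in records]
    return sum(vals) / len(vals)


def neo_hookean_params(E: float, nu: float) -> tuple[float, float]:
    """Neo-Hookean constants (C10, D1) from Young's modulus and Poisson ratio.

    Standard linear isotropic relations supply the shear and bulk moduli,
    S = E / (2 (1 + nu)) and B = E / (3 (1 - 2 nu)); then C10 = S/2 and
    D1 = B/2.  For nu = 0.5 the material is incompressible (the Jacobian of
    the deformation gradient is 1) and D1 is returned as +inf.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0.0 < nu <= 0.5:
        raise ValueError("nu must lie in (0, 0.5]")
    S = E / (2.0 * (1.0 + nu))
    C10 = S / 2.0
    if nu == 0.5:
        return C10, math.inf
    B = E / (3.0 * (1.0 - 2.0 * nu))
    return C10, B / 2.0


def mismatch_factor(E: float, nu: float) -> float:
    """Elastic mismatch factor k = (1 - nu^2) / (pi E), Pa^-1.

    Strictly decreasing in E; k -> 0 in the rigid-body limit.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must lie in [0, 1)")
    return (1.0 - nu**2) / (math.pi * E)


# --------------------------------------------------------------------------
# Bundled reference measurements
#
# One batch of knitted tubular samples: (subject, class, position,
# R_F [cm], L_F [cm], h [mm], MD [kg/m^3], E_F [MPa], E_Fy [MPa], v_F,
# G_F [MPa]).  Positions follow the standard hosiery levels: B ankle,
# B1 above-ankle, C calf, D below-knee.
_REFERENCE_FABRIC_ROWS: list[tuple] = [
    ("S1", "I", "B", 2.52, 6.0, 0.66, 479.3, 0.35, 0.16, 0.21, 0.14),
    ("S1", "I", "B1", 2.79, 6.5, 0.67, 468.2, 0.33, 0.15, 0.21, 0.14),
    ("S1", "I", "C", 3.57, 7.5, 0.68, 481.3, 0.37, 0.21, 0.20, 0.17),
    ("S1", "I", "D", 3.50, 7.0, 0.67, 480.6, 0.38, 0.20, 0.20, 0.16),
    ("S1", "III", "B", 2.42, 6.0, 0.62, 503.6, 0.42, 0.14, 0.22, 0.17),
    ("S1", "III", "B1", 2.79, 6.5, 0.64, 481.5, 0.41, 0.17, 0.23, 0.17),
    ("S1", "III", "C", 3.25, 7.5, 0.66, 479.3, 0.35, 0.16, 0.21, 0.14),
    ("S1", "III", "D", 3.22, 7.0, 0.68, 468.2, 0.33, 0.15, 0.21, 0.14),
    ("S2", "I", "B", 2.84, 5.5, 0.69, 484.7, 0.38, 0.21, 0.21, 0.14),
    ("S2", "I", "B1", 3.22, 6.0, 0.67, 468.2, 0.37, 0.15, 0.21, 0.15),
    ("S2", "I", "C", 3.57, 6.5, 0.67, 486.0, 0.38, 0.21, 0.20, 0.15),
    ("S2", "I", "D", 3.50, 6.0, 0.66, 485.4, 0.37, 0.20, 0.19, 0.14),
    ("S2", "III", "B", 2.83, 5.5, 0.62, 503.7, 0.45, 0.19, 0.23, 0.18),
    ("S2", "III", "B1", 2.87, 6.0, 0.67, 484.9, 0.38, 0.22, 0.20, 0.15),
    ("S2", "III", "C", 3.22, 6.5, 0.68, 468.2, 0.34, 0.15, 0.20, 0.14),
    ("S2", "III", "D", 3.25, 6.0, 0.66, 480.1, 0.33, 0.16, 0.20, 0.14),
    ("S3", "I", "B", 2.79, 5.5, 0.68, 468.2, 0.33, 0.15, 0.21, 0.14),
    ("S3", "I", "B1", 3.22, 6.0, 0.68, 484.4, 0.38, 0.21, 0.21, 0.15),
    ("S3", "I", "C", 3.50, 7.0, 0.67, 487.3, 0.38, 0.21, 0.20, 0.16),
    ("S3", "I", "D", 3.57, 6.5, 0.67, 486.3, 0.38, 0.21, 0.21, 0.15),
    ("S3", "III", "B", 2.80, 5.5, 0.64, 532.7, 0.76, 0.27, 0.25, 0.30),
    ("S3", "III", "B1", 2.83, 6.0, 0.62, 503.6, 0.42, 0.18, 0.22, 0.17),
    ("S3", "III", "C", 3.25, 7.0, 0.66, 479.3, 0.35, 0.16, 0.21, 0.14),
    ("S3", "III", "D", 3.22, 6.5, 0.68, 468.2, 0.33, 0.15, 0.21, 0.14),
]

#: Regional SWE moduli (Pa) for the reference subjects: ankle (B) and calf (C).
REFERENCE_SWE_PA: dict[str, dict[str, float]] = {
    "S1": {"B": 1975.0, "C": 2145.0},
    "S2": {"B": 2678.0, "C": 3273.0},
    "S3": {"B": 3700.0, "C": 1800.0},
}

#: Subject means as originally reported alongside the regional values.  Note
#: the S1 entry (2040 Pa) differs slightly from the plain arithmetic mean of
#: its two regional values (2060 Pa); `mean_swe_modulus` computes the plain
#: mean and does not special-case this row.
REFERENCE_SWE_REPORTED_MEAN_PA: dict[str, float] = {
    "S1": 2040.0,
    "S2": 2976.0,
    "S3": 2750.0,
}


def _row_to_spec(row: tuple) -> FabricSpec:
    subject, cls, pos, r_cm, l_cm, h_mm, md, ef, efy, vf, gf = row
    return FabricSpec(
        label=f"{subject}/{cls}/{pos}",
        R_F=r_cm / 100.0,
        L_F=l_cm / 100.0,
        h=h_mm / 1000.0,
        MD=md,
        E_F=ef * 1e6,
        E_Fy=efy * 1e6,
        v_F=vf,
        G_F=gf * 1e6,
        compression_class=cls,
    )


def reference_fabrics() -> dict[tuple[str, str, str], FabricSpec]:
    """The bundled reference fabric batch keyed by (subject, class, position)."""
    return {(r[0], r[1], r[2]): _row_to_spec(r) for r in _REFERENCE_FABRIC_ROWS}


def reference_fabric(subject: str, compression_class: str, position: str) -> FabricSpec:
    """One sample from the bundled reference batch."""
    try:
        return reference_fabrics()[(subject, compression_class, position)]
    except KeyError:
        raise KeyError(
            f"no reference fabric for {(subject, compression_class, position)}"
        ) from None


def reference_swe_records(subject: str) -> list[SWERecord]:
    """The bundled regional SWE readings for one reference subject."""
    if subject not in REFERENCE_SWE_PA:
        raise KeyError(f"unknown reference subject {subject!r}")
    return [
        SWERecord(subject=subject, position=pos, modulus=val)
        for pos, val in REFERENCE_SWE_PA[subject].items()
    ]


# --------------------------------------------------------------------------
# CSV interfaces (units carried in the headers, converted on read/write)

_FABRIC_COLUMNS = [
    "subject",
    "class",
    "position",
    "R_F_cm",
    "L_F_cm",
    "h_mm",
    "MD_kg_m3",
    "E_F_MPa",
    "E_Fy_MPa",
    "v_F",
    "G_F_MPa",
]


def read_fabric_csv(path: str | Path) -> dict[tuple[str, str, str], FabricSpec]:
    """Read a fabric-property CSV into specs keyed by (subject, class, position)."""
    out: dict[tuple[str, str, str], FabricSpec] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _FABRIC_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"fabric CSV missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["subject"], row["class"], row["position"])
                out[key] = _row_to_spec(
                    (
                        row["subject"],
                        row["class"],
                        row["position"],
                        float(row["R_F_cm"]),
                        float(row["L_F_cm"]),
                        float(row["h_mm"]),
                        float(row["MD_kg_m3"]),
                        float(row["E_F_MPa"]),
                        float(row["E_Fy_MPa"]),
                        float(row["v_F"]),
                        float(row["G_F_MPa"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed fabric CSV row {i}: {exc}") from exc
    return out


def write_fabric_csv(
    fabrics: dict[tuple[str, str, str], FabricSpec], path: str | Path
) -> None:
    """Write fabric specs to CSV in the same layout `read_fabric_csv` expects."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FABRIC_COLUMNS)
        for (subject, cls, pos), f in sorted(fabrics.items()):
            writer.writerow(
                [
                    subject,
                    cls,
                    pos,
                    f"{f.R_F * 100.0:.6g}",
                    f"{f.L_F * 100.0:.6g}",
                    f"{f.h * 1000.0:.6g}",
                    f"{f.MD:.6g}",
                    f"{f.E_F / 1e6:.6g}",
                    f"{f.E_Fy / 1e6:.6g}",
                    f"{f.v_F:.6g}",
                    f"{f.G_F / 1e6:.6g}",
                ]
            )


def read_swe_csv(path: str | Path) -> list[SWERecord]:
    """Read SWE readings: columns subject, position and velocity_m_s or modulus_MPa."""
    records: list[SWERecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        names = reader.fieldnames or []
        has_v = "velocity_m_s" in names
        has_e = "modulus_MPa" in names
        if not (has_v or has_e):
            raise ValueError("SWE CSV needs a velocity_m_s or modulus_MPa column")
        for i, row in enumerate(reader, start=2):
            try:
                if has_v and row.get("velocity_m_s"):
                    rec = SWERecord(
                        subject=row["subject"],
                        position=row["position"],
                        velocity=float(row["velocity_m_s"]),
                    )
                else:
                    rec = SWERecord(
                        subject=row["subject"],
                        position=row["position"],
                        modulus=float(row["modulus_MPa"]) * 1e6,
                    )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed SWE CSV row {i}: {exc}") from exc
            records.append(rec)
    return records
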
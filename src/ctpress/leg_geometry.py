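"""Leg cross-section geometry: girth, local curvature, radial indentation.

A leg is a stack of closed cross-section polylines along the vertical (z)
axis, optionally labelled with the standard hosiery measurement levels
(B ankle, B1 above-ankle, C calf, D below-knee).  The operations here are
the geometric bookkeeping behind the pressure analysis: perimeter (girth),
the local radius of curvature that converts membrane tension to pressure,
and the uniform inward radial displacement w whose circumferential
signature is dC = 2 pi w.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import LinearRing, Polygon

from .materials import TissueModel

__all__ = [
    "CrossSection",
    "LegModel",
    "girth",
    "local_radius",
    "apply_radial_displacement",
    "girth_change_from_displacement",
    "read_leg_csv",
    "write_leg_csv",
    "write_obj",
    "circle_section",
    "ellipse_section",
    "MIN_CURVATURE_RADIUS",
    "MAX_CURVATURE_RADIUS",
    "POSITION_ORDER",
]

logger = logging.getLogger(__name__)

#: Clipping bounds for the discrete radius of curvature, m.  The upper bound
#: keeps the Laplace pressure finite on locally flat boundary segments; the
#: lower bound guards against noise spikes at scan artefacts.
MIN_CURVATURE_RADIUS = 1e-4
MAX_CURVATURE_RADIUS = 10.0

#: Distal-to-proximal ordering of the standard measurement levels.
POSITION_ORDER = ("B", "B1", "C", "D")


def _as_ring(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 16:
        raise ValueError(f"a cross-section needs >= 16 points, got {len(pts)}")
    # shoelace signed area; store counter-clockwise
    x, y = pts[:, 0], pts[:, 1]
    area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area2 == 0.0:
        raise ValueError("degenerate cross-section (zero area)")
    if area2 < 0.0:
        pts = pts[::-1].copy()
    if not LinearRing(pts).is_simple:
        raise ValueError("cross-section polyline is self-intersecting")
    return pts


@dataclass(frozen=True)
class CrossSection:
    """A closed, simple, counter-clockwise cross-section at height z (m)."""

    z: float
    points: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", _as_ring(self.points))
        if self.label is not None and self.label not in POSITION_ORDER:
            raise ValueError(f"unknown position label {self.label!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class LegModel:
    """A stack of cross-sections ordered by z, with a rigidity flag.

    ``rigidity`` is "rigid" for mannequin-style models (printed PLA, wood)
    or "soft" for tissue-backed legs; soft legs should carry a
    :class:`~ctpress.materials.TissueModel`.
    """

    sections: tuple[CrossSection, ...]
    rigidity: str = "soft"
    tissue: TissueModel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sections", tuple(self.sections))
        if not self.sections:
            raise ValueError("a leg needs at least one cross-section")
        zs = [s.z for s in self.sections]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("section heights must be strictly increasing")
        if self.rigidity not in ("rigid", "soft"):
            raise ValueError(f"rigidity must be 'rigid' or 'soft', got {self.rigidity!r}")
        labels = {s.label for s in self.sections if s.label}
        if not {"B", "D"} <= labels:
            warnings.warn(
                "leg is missing labelled B and/or D sections; position-based "
                "solves will be limited",
                stacklevel=2,
            )

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sections if s.label]

    @property
    def height_span(self) -> float:
        return self.sections[-1].z - self.sections[0].z

    def section(self, label: str) -> CrossSection:
        for s in self.sections:
            if s.label == label:
                return s
        raise KeyError(f"leg has no section labelled {label!r}")

    def girths(self) -> dict[str, float]:
        """Girth (m) per labelled section, distal to proximal."""
        return {s.label: girth(s) for s in self.sections if s.label}


def girth(section: CrossSection) -> float:
    """Perimeter of the closed cross-section polyline, m."""
    pts = section.points
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a girth")
    closed = np.vstack([pts, pts[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def _circumradius(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    a = float(np.linalg.norm(p1 - p0))
    b = float(np.linalg.norm(p2 - p1))
    c = float(np.linalg.norm(p2 - p0))
    cross = float((p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0]))
    area2 = abs(cross)
    if area2 < 1e-16 * max(a * b, 1e-30):
        return math.inf
    return a * b * c / (2.0 * area2)


def local_radius(section: CrossSection, arc_position: float) -> float:
    """Discrete radius of curvature (m) at a fractional arc position in [0, 1).

    The radius of the circle through three consecutive boundary samples at
    the requested arc position, clipped to
    [:data:`MIN_CURVATURE_RADIUS`, :data:`MAX_CURVATURE_RADIUS`].  Collinear
    (locally flat) triples return the upper clip.
    """
    if not 0.0 <= arc_position < 1.0:
        raise ValueError("arc_position must lie in [0, 1)")
    pts = section.points
    n = len(pts)
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = arc_position * cum[-1]
    i = int(np.searchsorted(cum, target, side="right") - 1) % n
    r = _circumradius(pts[(i - 1) % n], pts[i], pts[(i + 1) % n])
    return float(min(max(r, MIN_CURVATURE_RADIUS), MAX_CURVATURE_RADIUS))


def arc_positions(section: CrossSection) -> np.ndarray:
    """Fractional arc position of every boundary vertex, in [0, 1)."""
    pts = section.points
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return cum / float(np.sum(seg))


def _outward_normals(pts: np.ndarray) -> np.ndarray:
    # central-difference tangents on the closed CCW ring
    t = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    n = np.column_stack([t[:, 1], -t[:, 0]])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def apply_radial_displacement(section: CrossSection, w: float) -> CrossSection:
    """Move every boundary point inward along the local normal by w (m).

    For a circular section the girth decreases by exactly 2 pi w.  Raises if
    the displacement exceeds the section's inscribed radius (the boundary
    would self-intersect).
    """
    if w < 0:
        raise ValueError("w must be non-negative")
    if w == 0.0:
        return replace(section)
    poly = Polygon(section.points)
    eroded = poly.buffer(-w)
    if eroded.is_empty or eroded.geom_type != "Polygon":
        raise ValueError(
            f"radial displacement w={w:.4g} m exceeds the section's inscribed radius"
        )
    new_pts = section.points - w * _outward_normals(section.points)
    if not LinearRing(new_pts).is_simple:
        raise ValueError(
            f"radial displacement w={w:.4g} m makes the section self-intersect"
        )
    return CrossSection(z=section.z, points=new_pts, label=section.label)


def girth_change_from_displacement(w: float) -> float:
    """Circumference decrease (m) of a uniform inward radial displacement w.

    The circular-section identity dC = 2 pi w; this is the bookkeeping that
    links reported indentation depths (mm) to circumference deltas (cm).
    """
    if w < 0:
        raise ValueError("w must be non-negative")
    return 2.0 * math.pi * w


# --------------------------------------------------------------------------
# constructors

def circle_section(
    radius: float, z: float = 0.0, n: int = 256, label: str | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> CrossSection:
    """A circular cross-section sampled at n points."""
    th = 2.0 * math.pi * np.arange(n) / n
    pts = np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])
    return CrossSection(z=z, points=pts, label=label)


def ellipse_section(
    a: float, b: float, z: float = 0.0, n: int = 256, label: str | None = None
) -> CrossSection:
    """An axis-aligned elliptic cross-section, semi-axes a (x) and b (y)."""
    th = 2.0 * math.pi * np.arange(n) / n
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    return CrossSection(z=z, points=pts, label=label)


# --------------------------------------------------------------------------
# I/O

_LEG_COLUMNS = ["z_m", "point_index", "x_m", "y_m", "label"]


def write_leg_csv(leg: LegModel, path: str | Path) -> None:
    """Write the section stack as rows of z_m, point_index, x_m, y_m, label."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LEG_COLUMNS)
        for s in leg.sections:
            for i, (x, y) in enumerate(s.points):
                writer.writerow([repr(s.z), i, repr(float(x)), repr(float(y)), s.label or ""])


def read_leg_csv(
    path: str | Path,
    rigidity: str = "rigid",
    tissue: TissueModel | None = None,
) -> LegModel:
    """Read a section-stack CSV back into a :class:`LegModel`.

    Sections must appear in ascending z order; malformed rows raise with the
    offending row number.  A missing ``label`` column is tolerated (labels
    stay unset, with a logged warning).
    """
    groups: list[tuple[float, list[tuple[float, float]], str | None]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        names = reader.fieldnames or []
        for col in ("z_m", "point_index", "x_m", "y_m"):
            if col not in names:
                raise ValueError(f"leg CSV missing column {col!r}")
        has_label = "label" in names
        if not has_label:
            logger.warning("leg CSV %s has no label column; labels left unset", path)
        for rownum, row in enumerate(reader, start=2):
            try:
                z = float(row["z_m"])
                x = float(row["x_m"])
                y = float(row["y_m"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed leg CSV row {rownum}: {exc}") from exc
            label = (row.get("label") or None) if has_label else None
            if groups and groups[-1][0] == z:
                groups[-1][1].append((x, y))
            else:
                if groups and z < groups[-1][0]:
                    raise ValueError(
                        f"leg CSV row {rownum}: section heights not sorted "
                        f"ascending (z={z} after z={groups[-1][0]})"
                    )
                groups.append((z, [(x, y)], label))
    sections = []
    for z, pts, label in groups:
        try:
            sections.append(CrossSection(z=z, points=np.array(pts), label=label))
        except ValueError as exc:
            raise ValueError(f"invalid section at z={z}: {exc}") from exc
    return LegModel(sections=tuple(sections), rigidity=rigidity, tissue=tissue)


def write_obj(leg: LegModel, path: str | Path) -> None:
    """Export the section stack as a Wavefront OBJ side-wall mesh (no caps).

    All sections must share the same point count; consecutive rings are
    joined by triangulated quads.  Intended for external viewers only.
    """
    counts = {s.n_points for s in leg.sections}
    if len(counts) != 1:
        raise ValueError("OBJ export needs equal point counts in every section")
    n = counts.pop()
    lines = ["# ctpress leg section stack"]
    for s in leg.sections:
        for x, y in s.points:
            lines.append(f"v {x:.6f} {y:.6f} {s.z:.6f}")
    for si in range(len(leg.sections) - 1):
        base0 = si * n
        base1 = (si + 1) * n
        for i in range(n):
            j = (i + 1) % n
            a, b = base0 + i + 1, base0 + j + 1
            c, d = base1 + i + 1, base1 + j + 1
            lines.append(f"f {a} {b} {d}")
            lines.append(f"f {a} {d} {c}")
    Path(path).write_text("\n".join(lines) + "\n")
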
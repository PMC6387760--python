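"""Muscle-force proxies: ilium lateral area and CFL cross-sectional area.

Two fossil-preservable proxies stand in for hind-limb muscle force.  The
lateral surface of the ilium dorsal to the supra-acetabular crest is the
origin field for knee extensors, hip flexors and femoral abductors, so its
planar area (cm^2) scales with their summed cross-section.  The major
femoral retractor, m. caudofemoralis longus (CFL), is reconstructed from the
tail's hypaxial depth (caudal-rib tip to chevron tip): one semicircular
cross-section of radius half that depth, minus the centrum cross-section,
optionally widened by the adult-crocodylian factor of 1.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "IliumOutline",
    "CFLSection",
    "GeometryError",
    "ModelInconsistencyError",
    "ilium_area",
    "cfl_cross_section",
    "depth_sensitivity",
]


class GeometryError(ValueError):
    """Raised for invalid outline polygons (self-intersection, too few vertices)."""


class ModelInconsistencyError(ValueError):
    """Raised when the CFL reconstruction yields a non-positive area."""


@dataclass
class IliumOutline:
    """Ordered planar polygon tracing the lateral ilium outline (cm)."""

    vertices: np.ndarray  # (n, 2)
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        pts = self.vertices
        if self.closed and pts.shape[0] > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if pts.shape[0] < 3:
            raise GeometryError("an outline needs at least 3 distinct vertices")
        self._polygon = Polygon(pts)
        if not self._polygon.is_valid or self._polygon.area == 0:
            raise GeometryError("outline polygon is self-intersecting or degenerate")

    @property
    def polygon(self) -> Polygon:
        return self._polygon


@dataclass(frozen=True)
class CFLSection:
    """Parameters of the reconstructed CFL cross-section at the deepest chevron.

    ``hypaxial_depth`` (cm) is the vertical distance from the caudal-rib tips
    to the chevron tips; ``centrum_area`` (cm^2) the vertebral centrum
    cross-section subtracted from the semicircle; ``width_factor`` widens the
    semicircle laterally (1.4 = adult-crocodylian upper bound).
    """

    hypaxial_depth: float
    centrum_area: float = 0.0
    width_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.hypaxial_depth <= 0:
            raise ValueError("hypaxial depth must be positive")
        if self.centrum_area < 0:
            raise ValueError("centrum area must be non-negative")
        if self.width_factor <= 0:
            raise ValueError("width factor must be positive")


def ilium_area(outline: IliumOutline, scale: float = 1.0) -> float:
    """Planar (shoelace) area of the outline in cm^2.

    ``scale`` converts outline units to cm (areas scale by ``scale**2``).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return float(outline.polygon.area) * scale * scale


def cfl_cross_section(section: CFLSection) -> float:
    """CFL cross-sectional area in cm^2 (one side of the tail).

        area = width_factor * (pi/2) (depth/2)^2 - centrum_area

    The semicircle has radius half the hypaxial depth; the centrum section
    is subtracted once per side.
    """
    semicircle = 0.5 * math.pi * (section.hypaxial_depth / 2.0) ** 2
    area = section.width_factor * semicircle - section.centrum_area
    if area <= 0:
        raise ModelInconsistencyError(
            "centrum cross-section exceeds the reconstructed CFL semicircle"
        )
    return float(area)


def depth_sensitivity(section: CFLSection, delta: float = 0.1) -> tuple[float, float, float]:
    """CFL area at depth scaled by (1 - delta), 1 and (1 + delta).

    All linear dimensions of the section scale together, so the centrum area
    scales by the square of the linear factor; the area ratios are then
    exactly ``(1 - delta)^2`` and ``(1 + delta)^2`` (e.g. -19% / +21% at
    delta = 0.1).
    """
    if not 0 <= delta < 1:
        raise ValueError("delta must be in [0, 1)")

    def scaled(factor: float) -> float:
        return cfl_cross_section(
            replace(
                section,
                hypaxial_depth=section.hypaxial_depth * factor,
                centrum_area=section.centrum_area * factor * factor,
            )
        )

    return scaled(1 - delta), scaled(1.0), scaled(1 + delta)
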
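"""Cross-section geometry of plain, concentric and tangent double-tube photobioreactors.

The culture cross-section is described in a single 2-D frame: a vertical
*depth axis* (positive toward the illuminated top of the outer tube, where
light enters) and a horizontal *lateral axis*.  The origin sits on the axis
of the outer tube.  Points are ``(depth_mm, lateral_mm)``.

Three layouts are supported:

``plain``
    A single tube; the culture region is the full outer disc.
``concentric``
    An inner aeration tube coaxial with the outer tube; the culture region
    is the annulus between them.
``tangent``
    The inner tube is internally tangent to the outer tube at the bottom.
    A configurable arc (default 60 deg) is removed at the bottom of the inner
    tube and replaced by a flat panel (modeled as the chord across the
    removed arc); the two cusp corners between inner and outer tube below
    the panel are excluded from the culture region.

Illumination comes from the top, travelling straight down the depth axis
(normal incidence), which splits the culture region into a *light* zone
above a horizontal interface line and a *dark* zone below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
from scipy import integrate


class Layout(str, Enum):
    PLAIN = "plain"
    CONCENTRIC = "concentric"
    TANGENT = "tangent"


class GeometryError(ValueError):
    """Invalid geometry specification (e.g. inner tube larger than outer)."""


class DomainError(ValueError):
    """A query point lies outside the domain the operation is defined on."""


def _as_layout(layout: "Layout | str") -> Layout:
    try:
        return Layout(layout)
    except ValueError as exc:
        raise GeometryError(f"unknown layout {layout!r}") from exc


@dataclass(frozen=True)
class CrossSectionGeometry:
    """Geometry of one reactor cross-section.

    Parameters
    ----------
    layout:
        One of ``plain``, ``concentric``, ``tangent``.
    outer_radius, inner_radius:
        Tube radii in mm (paper-scale defaults: 100 and 40 mm).
        ``inner_radius`` is ignored for the plain layout.
    removed_arc_deg:
        Arc removed at the bottom of the inner tube (tangent layout only).
    boundary_depth:
        Depth coordinate of the horizontal light/dark interface (mm);
        0 puts it through the outer-tube axis.
    fillet_enabled:
        Whether the removed-arc panel and cusp-corner exclusion are applied
        (tangent layout only).
    """

    layout: Layout = Layout.TANGENT
    outer_radius: float = 100.0
    inner_radius: float = 40.0
    removed_arc_deg: float = 60.0
    boundary_depth: float = 0.0
    fillet_enabled: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "layout", _as_layout(self.layout))
        if self.outer_radius <= 0:
            raise GeometryError("outer_radius must be positive")
        if self.layout is not Layout.PLAIN:
            if not 0 < self.inner_radius < self.outer_radius:
                raise GeometryError(
                    "inner_radius must satisfy 0 < inner_radius < outer_radius "
                    f"(got {self.inner_radius} vs {self.outer_radius})"
                )

    @property
    def has_inner_tube(self) -> bool:
        return self.layout is not Layout.PLAIN

    @property
    def inner_center_depth_offset(self) -> float:
        """Depth coordinate of the inner-tube axis.

        0 for the concentric layout; -(R - r) for the tangent layout, which
        makes the inner circle internally tangent to the outer circle at the
        bottom of the cross-section.
        """
        if self.layout is Layout.TANGENT:
            return -(self.outer_radius - self.inner_radius)
        return 0.0

    @property
    def fillet_chord_depth(self) -> float:
        """Depth of the flat panel closing the removed arc (tangent layout).

        The removed arc is centred on the lowest point of the inner tube;
        its closing chord is the horizontal line at
        ``inner_center - r*cos(arc/2)``.
        """
        half = math.radians(self.removed_arc_deg / 2.0)
        return self.inner_center_depth_offset - self.inner_radius * math.cos(half)

    # -- membership -----------------------------------------------------

    def in_culture(self, depth, lateral):
        """Vectorized membership test for the culture region."""
        depth = np.asarray(depth, dtype=float)
        lateral = np.asarray(lateral, dtype=float)
        r2 = depth * depth + lateral * lateral
        inside = r2 <= self.outer_radius**2
        if self.has_inner_tube:
            dc = depth - self.inner_center_depth_offset
            inside &= dc * dc + lateral * lateral >= self.inner_radius**2
            if self.layout is Layout.TANGENT and self.fillet_enabled:
                inside &= depth >= self.fillet_chord_depth
        if inside.ndim == 0:
            return bool(inside)
        return inside

    def in_culture_point(self, point: Iterable[float]) -> bool:
        d, l = point
        return bool(self.in_culture(d, l))

    # -- 1-D column reduction -------------------------------------------
    # Every area query reduces exactly to an integral over the lateral
    # coordinate of per-column interval lengths, so areas are computed by
    # adaptive quadrature rather than by cell counting.

    def _column_intervals(self, lateral: float) -> list[tuple[float, float]]:
        """Culture-region depth intervals of the vertical column at ``lateral``."""
        R = self.outer_radius
        if abs(lateral) >= R:
            return []
        h = math.sqrt(R * R - lateral * lateral)
        lo, hi = -h, h
        if self.layout is Layout.TANGENT and self.fillet_enabled:
            lo = max(lo, self.fillet_chord_depth)
        if lo >= hi:
            return []
        if not self.has_inner_tube or abs(lateral) >= self.inner_radius:
            return [(lo, hi)]
        g = math.sqrt(self.inner_radius**2 - lateral * lateral)
        c = self.inner_center_depth_offset
        ilo, ihi = c - g, c + g
        out: list[tuple[float, float]] = []
        if ilo > lo:
            out.append((lo, min(ilo, hi)))
        if ihi < hi:
            out.append((max(ihi, lo), hi))
        return [(a, b) for a, b in out if b > a]

    def _column_length(self, lateral: float, max_depth_below: float | None = None) -> float:
        """Total culture length of a column, optionally clipped to the
        sub-column whose light path from the top surface is < ``max_depth_below``."""
        iv = self._column_intervals(lateral)
        if not iv:
            return 0.0
        if max_depth_below is None:
            return sum(b - a for a, b in iv)
        surface = math.sqrt(self.outer_radius**2 - lateral * lateral)
        cut = surface - max_depth_below  # keep depth > cut
        return sum(max(0.0, b - max(a, cut)) for a, b in iv)

    def culture_area(self) -> float:
        """Area of the culture region in mm^2 (adaptive quadrature)."""
        val, _ = integrate.quad(
            self._column_length, -self.outer_radius, self.outer_radius, limit=200
        )
        return val

    # -- light path ------------------------------------------------------

    def depth_below_surface(self, point: Iterable[float]) -> float:
        """Light-path length (mm) from the illuminated top surface to ``point``.

        Light travels straight down the depth axis; the path length is the
        distance from the outer circle (at the same lateral coordinate) down
        to the point.
        """
        d, l = float(point[0]), float(point[1])
        if d * d + l * l > self.outer_radius**2 * (1 + 1e-12):
            raise DomainError(f"point {point!r} outside the outer tube")
        return math.sqrt(max(self.outer_radius**2 - l * l, 0.0)) - d

    def zone_of(self, point: Iterable[float]) -> str:
        """``"light"`` if the point lies above the light/dark interface, else ``"dark"``."""
        if not self.in_culture_point(point):
            raise DomainError(f"point {point!r} outside the culture region")
        return "light" if point[0] > self.boundary_depth else "dark"

    def light_dark_area_ratio(self, penetration_depth: float) -> float:
        """Ratio light-zone area / dark-zone area for a given light
        penetration depth (mm).

        The light zone is the part of the culture region whose light path
        from the top surface is shorter than ``penetration_depth``.  Returns
        ``math.inf`` when the dark area is numerically zero.
        """
        if penetration_depth <= 0:
            raise ValueError("penetration_depth must be positive")
        total = self.culture_area()
        light, _ = integrate.quad(
            lambda y: self._column_length(y, penetration_depth),
            -self.outer_radius,
            self.outer_radius,
            limit=200,
        )
        dark = total - light
        if dark <= total * 1e-9:
            return math.inf
        return light / dark


def make_geometry(
    layout: "Layout | str",
    outer_radius: float = 100.0,
    inner_radius: float = 40.0,
    removed_arc_deg: float = 60.0,
    boundary_depth: float = 0.0,
    fillet_enabled: bool = True,
) -> CrossSectionGeometry:
    """Construct a :class:`CrossSectionGeometry`, validating the layout."""
    return CrossSectionGeometry(
        layout=_as_layout(layout),
        outer_radius=outer_radius,
        inner_radius=inner_radius,
        removed_arc_deg=removed_arc_deg,
        boundary_depth=boundary_depth,
        fillet_enabled=fillet_enabled,
    )
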
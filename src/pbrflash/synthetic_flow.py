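"""Synthetic divergence-free cross-sectional flow and turbulence fields.

This module is the data stage of the pipeline.  The reference flow fields in
this problem come from 3-D two-phase CFD solutions; the metrics layer,
however, only needs a 2-D cross-sectional liquid velocity field plus
turbulence quantities.  Fields here are generated parametrically from a
scalar streamfunction so they are exactly divergence-free on the grid:
velocities are obtained by central differencing of the streamfunction, and
the discrete central-difference divergence of such a field vanishes
identically at interior cells.

Two kernel families mimic the structures seen in aerated double-tube
reactors: Gaussian-core (Lamb--Oseen-type) vortices, and dipole "jet plume"
kernels aligned with an aeration-pore direction.  :func:`default_scenario`
assembles a counter-rotating vortex pair (plus pore jets) whose placement
and dark-zone strength depend on the aeration direction, and calibrates the
result so the peak monitoring-line velocity and the culture-average
turbulent kinetic energy hit requested targets.

Gridded fields round-trip through a delimited text table so externally
produced CFD exports can enter the same pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import CrossSectionGeometry, GeometryError, Layout

FIELD_COLUMNS = [
    "depth_mm",
    "lateral_mm",
    "u_depth_m_s",
    "u_lateral_m_s",
    "k_cm2_s2",
    "eps_cm2_s3",
]


class FieldFormatError(ValueError):
    """A gridded field table violates the declared format."""


class CalibrationError(ValueError):
    """A requested field calibration target cannot be reached."""


class ResolutionError(ValueError):
    """Grid spacing too coarse to resolve the geometry."""


@dataclass(frozen=True)
class AerationSpec:
    """Aeration configuration of the inner tube.

    ``direction_deg`` is the jet angle from the horizontal, positive upward
    (so -30 is the 30-degree-downward case).  ``rate_vvm`` is gas volume per
    culture volume per minute.  Pore geometry defaults follow the package's
    own choice of 4 pores per row along a 1 m tube (one pore row every
    250 mm), 5 mm pore diameter; the tangent layout carries two symmetric
    pore rows on the inner-tube sides, the concentric layout one row canted
    45 degrees downward.
    """

    direction_deg: float = -30.0
    rate_vvm: float = 0.7
    pore_diameter_mm: float = 5.0
    pores_per_row: int = 4
    n_rows: int = 2
    tube_length_mm: float = 1000.0

    def __post_init__(self) -> None:
        if self.rate_vvm < 0:
            raise ValueError("rate_vvm must be >= 0")
        if self.pore_diameter_mm <= 0:
            raise ValueError("pore_diameter_mm must be positive")
        if self.pores_per_row < 1 or self.n_rows < 1:
            raise ValueError("pore counts must be >= 1")


@dataclass(frozen=True)
class FlowComponentSpec:
    """One parametric flow structure: a vortex or a jet plume.

    ``strength`` is a velocity scale in m/s (for a vortex, the azimuthal
    speed scale of the Gaussian core; for a jet, the centreline speed).
    ``core_radius`` is in mm; ``orientation_deg`` (jets only) is the jet
    direction from the horizontal, positive upward.
    """

    kind: str  # "vortex" | "jet_plume"
    center: tuple[float, float]  # (depth_mm, lateral_mm)
    strength: float
    core_radius: float
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("vortex", "jet_plume"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be positive")

    def streamfunction(self, depth: np.ndarray, lateral: np.ndarray) -> np.ndarray:
        """Streamfunction contribution, in (m/s)*mm, on the given coordinates."""
        dd = depth - self.center[0]
        dl = lateral - self.center[1]
        r2 = dd * dd + dl * dl
        sig = self.core_radius
        g = np.exp(-r2 / (2.0 * sig * sig))
        if self.kind == "vortex":
            return self.strength * sig * g
        # jet plume: dipole whose centre velocity points along the jet axis
        th = math.radians(self.orientation_deg)
        j_depth, j_lat = math.sin(th), math.cos(th)
        # with u_depth = dpsi/dlat, u_lateral = -dpsi/ddepth the choice
        # psi = S * (-j_lat*dd + j_depth*dl) * g yields u(center) = S*(j_depth, j_lat)
        return self.strength * (-j_lat * dd + j_depth * dl) * g


@dataclass
class GriddedFlowField:
    """Uniform Cartesian cross-sectional field of liquid velocity and turbulence.

    Arrays are indexed ``[i_depth, j_lateral]``.  Velocities are in m/s,
    turbulent kinetic energy ``k`` in cm^2/s^2, dissipation ``eps`` in
    cm^2/s^3, coordinates in mm.  Cells outside the culture mask carry zero
    velocity.
    """

    depth_coords: np.ndarray
    lateral_coords: np.ndarray
    mask: np.ndarray
    u_depth: np.ndarray
    u_lateral: np.ndarray
    k: np.ndarray
    eps: np.ndarray
    gas_fraction: np.ndarray | None = None
    geometry: CrossSectionGeometry | None = None

    @property
    def spacing(self) -> float:
        return float(self.depth_coords[1] - self.depth_coords[0])

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u_depth, self.u_lateral)

    def interior_mask(self) -> np.ndarray:
        """Masked cells whose four neighbours are also masked."""
        m = self.mask
        inner = np.zeros_like(m)
        inner[1:-1, 1:-1] = (
            m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
        )
        return inner

    def max_interior_divergence(self) -> float:
        """Max |central-difference divergence| over interior cells, in 1/s-ish
        grid units (m/s per mm); used relative to the peak speed."""
        h = self.spacing
        div = np.zeros_like(self.u_depth)
        div[1:-1, :] += (self.u_depth[2:, :] - self.u_depth[:-2, :]) / (2 * h)
        div[:, 1:-1] += (self.u_lateral[:, 2:] - self.u_lateral[:, :-2]) / (2 * h)
        inner = self.interior_mask()
        if not inner.any():
            return 0.0
        return float(np.abs(div[inner]).max())

    def _bilinear(self, values: np.ndarray, depth, lateral) -> np.ndarray:
        """Bilinear interpolation of one or more stacked channel arrays.

        ``values`` has shape ``(..., n_depth, n_lateral)``; points outside
        the grid are clamped to the border cell.
        """
        d = np.asarray(depth, dtype=float)
        l = np.asarray(lateral, dtype=float)
        dc, lc = self.depth_coords, self.lateral_coords
        h = self.spacing
        fi = np.minimum(np.maximum((d - dc[0]) / h, 0.0), len(dc) - 1.0)
        fj = np.minimum(np.maximum((l - lc[0]) / h, 0.0), len(lc) - 1.0)
        i0 = np.minimum(fi.astype(int), len(dc) - 2)
        j0 = np.minimum(fj.astype(int), len(lc) - 2)
        wi = fi - i0
        wj = fj - j0
        v00 = values[..., i0, j0]
        v10 = values[..., i0 + 1, j0]
        v01 = values[..., i0, j0 + 1]
        v11 = values[..., i0 + 1, j0 + 1]
        return (
            v00 * (1 - wi) * (1 - wj)
            + v10 * wi * (1 - wj)
            + v01 * (1 - wi) * wj
            + v11 * wi * wj
        )

    def velocity_at(self, depth, lateral) -> np.ndarray:
        """Liquid velocity (m/s) at arbitrary points; shape (2, ...)."""
        return self._bilinear(np.stack([self.u_depth, self.u_lateral]), depth, lateral)

    def turbulence_at(self, depth, lateral) -> np.ndarray:
        """(k, eps) at arbitrary points; shape (2, ...)."""
        return self._bilinear(np.stack([self.k, self.eps]), depth, lateral)

    def monitoring_line_samples(
        self, lateral_offset: float, n_samples: int = 400
    ) -> tuple[np.ndarray, np.ndarray]:
        """Depth coordinates (inside the culture region) and interpolated
        depth-velocity along the vertical line at ``lateral_offset``."""
        geom = self.geometry
        dmin, dmax = float(self.depth_coords[0]), float(self.depth_coords[-1])
        depths = np.linspace(dmin, dmax, n_samples)
        lats = np.full_like(depths, lateral_offset)
        if geom is not None:
            keep = geom.in_culture(depths, lats)
            depths, lats = depths[keep], lats[keep]
        if depths.size == 0:
            return depths, depths
        u = self.velocity_at(depths, lats)
        return depths, u[0]


def make_grid(
    geom: CrossSectionGeometry, spacing: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-centre coordinates and culture mask covering the outer tube.

    The lateral coordinates are symmetric about 0 so mirror-symmetric
    scenarios are exactly mirror-symmetric on the grid.
    """
    R = geom.outer_radius
    if 2 * R / spacing < 20:
        raise ResolutionError(
            f"spacing {spacing} mm too coarse for outer diameter {2 * R} mm"
        )
    n = int(round(2 * R / spacing))
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing
    depth = coords.copy()
    lateral = coords.copy()
    D, L = np.meshgrid(depth, lateral, indexing="ij")
    mask = geom.in_culture(D, L)
    return depth, lateral, mask


def _wall_distance(geom: CrossSectionGeometry, D: np.ndarray, L: np.ndarray) -> np.ndarray:
    R = geom.outer_radius
    d = R - np.hypot(D, L)
    if geom.has_inner_tube:
        dc = D - geom.inner_center_depth_offset
        d = np.minimum(d, np.hypot(dc, L) - geom.inner_radius)
        if geom.layout is Layout.TANGENT and geom.fillet_enabled:
            d = np.minimum(d, D - geom.fillet_chord_depth)
    return d


def field_from_streamfunction(
    geom: CrossSectionGeometry,
    psi: np.ndarray,
    depth_coords: np.ndarray,
    lateral_coords: np.ndarray,
    mask: np.ndarray,
    k: np.ndarray | None = None,
    eps: np.ndarray | None = None,
) -> GriddedFlowField:
    """Differentiate a streamfunction (units (m/s)*mm) into a divergence-free
    velocity field: ``u_depth = dpsi/dlateral``, ``u_lateral = -dpsi/ddepth``."""
    h = float(depth_coords[1] - depth_coords[0])
    u_depth = np.gradient(psi, h, axis=1)
    u_lateral = -np.gradient(psi, h, axis=0)
    u_depth = np.where(mask, u_depth, 0.0)
    u_lateral = np.where(mask, u_lateral, 0.0)
    if k is None:
        k = np.zeros_like(psi)
    if eps is None:
        eps = np.full_like(psi, 1e-6)
    return GriddedFlowField(
        depth_coords=np.asarray(depth_coords, float),
        lateral_coords=np.asarray(lateral_coords, float),
        mask=mask,
        u_depth=u_depth,
        u_lateral=u_lateral,
        k=np.where(mask, k, 0.0),
        eps=np.where(mask, eps, 1e-6),
        geometry=geom,
    )


def compose_field(
    geom: CrossSectionGeometry,
    components: Sequence[FlowComponentSpec],
    spacing: float = 2.0,
    taper_width: float = 12.0,
    dark_zone_weakening: float = 1.0,
    dark_transition_width: float = 35.0,
) -> GriddedFlowField:
    """Superpose component streamfunctions on a grid and differentiate.

    The summed streamfunction is multiplied by a smoothstep taper that
    vanishes at the walls (no-penetration: the wall is a streamline) and,
    optionally, by a smooth factor that reduces to ``dark_zone_weakening``
    below the light/dark interface — emulating the sparse, disordered
    dark-zone flow of upward-aerated scenarios.  Both factors multiply the
    streamfunction, so the result remains exactly divergence-free.
    """
    if not components:
        raise ValueError("at least one flow component is required")
    depth, lateral, mask = make_grid(geom, spacing)
    D, L = np.meshgrid(depth, lateral, indexing="ij")
    psi = np.zeros_like(D)
    for comp in components:
        psi += comp.streamfunction(D, L)
    if taper_width > 0:
        s = np.clip(_wall_distance(geom, D, L) / taper_width, 0.0, 1.0)
        psi *= s * s * (3.0 - 2.0 * s)
    if dark_zone_weakening < 1.0:
        t = np.clip(
            (geom.boundary_depth - D) / dark_transition_width, 0.0, 1.0
        )
        t = t * t * (3.0 - 2.0 * t)
        psi *= 1.0 - (1.0 - dark_zone_weakening) * t
    return field_from_streamfunction(geom, psi, depth, lateral, mask)


# -- aeration ----------------------------------------------------------


def pore_layout(
    geom: CrossSectionGeometry, spec: AerationSpec
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Pore sites and unit jet directions on the inner-tube surface.

    Tangent layout: two sites mirror-symmetric about the vertical plane on
    the sides of the inner tube, jets at ``spec.direction_deg`` from the
    horizontal pointing away from the tube.  Concentric layout: a single
    site on one side, canted 45 degrees downward.
    """
    if not geom.has_inner_tube:
        raise GeometryError("plain layout has no inner aeration tube")
    c = geom.inner_center_depth_offset
    r = geom.inner_radius
    if geom.layout is Layout.TANGENT:
        th = math.radians(spec.direction_deg)
        jd, jl = math.sin(th), math.cos(th)
        right = ((c, r), (jd, jl))
        left = ((c, -r), (jd, -jl))
        return [left, right]
    # concentric: one row canted downward by 45 deg, on the lateral<0 side
    n = (-math.sqrt(0.5), -math.sqrt(0.5))
    site = (c + r * n[0], r * n[1])
    return [(site, n)]


def vvm_to_jet_speed(
    spec: AerationSpec, culture_area_mm2: float, tube_length_mm: float | None = None
) -> float:
    """Superficial gas jet speed (m/s) through the aeration pores.

    The volumetric gas flow is ``rate_vvm x culture volume / 60 s``; the jet
    speed is that flow divided by the total pore cross-sectional area.
    """
    if culture_area_mm2 <= 0:
        raise ValueError("culture_area must be positive")
    length = spec.tube_length_mm if tube_length_mm is None else tube_length_mm
    n_pores = spec.pores_per_row * spec.n_rows
    pore_area = n_pores * math.pi * (spec.pore_diameter_mm / 2.0) ** 2
    if pore_area <= 0:
        raise ValueError("total pore area must be positive")
    volume_mm3 = culture_area_mm2 * length
    flow_mm3_s = spec.rate_vvm * volume_mm3 / 60.0
    return flow_mm3_s / pore_area / 1000.0  # mm/s -> m/s


# -- scenario assembly -------------------------------------------------

#: fraction of the pore jet speed transferred to the liquid circulation
MOMENTUM_TRANSFER_COEFF = 0.05

_SIN_M30 = math.sin(math.radians(-30.0))


def _upwardness(direction_deg: float) -> float:
    """0 for 30-degree-downward (or lower) aeration, approaching 1 as the
    jets rotate toward vertical-up; sub-linear so small rotations away from
    the optimum already register."""
    s = math.sin(math.radians(direction_deg))
    x = max(0.0, (s - _SIN_M30) / (1.0 - _SIN_M30))
    return x**0.25


def _direction_lift_fraction(direction_deg: float) -> float:
    """How far (fraction of R) the vortex pair sits above the light/dark
    interface.  0 for 30-degree-downward aeration (vortices straddle the
    interface); grows as the jets rotate toward upward (quadratically, so
    near-optimal directions keep boundary-straddling vortices)."""
    return 0.55 * _upwardness(direction_deg) ** 3


def _direction_dark_weakening(direction_deg: float) -> float:
    """Multiplier on the dark-zone streamfunction and turbulence: 1 at
    -30 deg, smaller as the aeration rotates upward (sparse, disordered
    dark-zone flow)."""
    return 1.0 - 0.75 * _upwardness(direction_deg)


def default_scenario(
    geom: CrossSectionGeometry,
    aeration: AerationSpec,
    peak_vr_target: float = 0.045,
    mean_tke_target: float = 80.0,
    spacing: float = 2.0,
    monitoring_offsets: tuple[float, float] = (-40.0, 40.0),
) -> GriddedFlowField:
    """Assemble and calibrate the default synthetic scenario for an
    aeration configuration.

    A counter-rotating vortex pair is placed symmetrically about the
    vertical plane; for downward 30-degree aeration the pair straddles the
    light/dark interface, while more upward directions lift it into the
    light zone and weaken the dark-zone flow.  Pore jets at the aeration
    sites are added with strength proportional to the vvm-derived jet
    speed.  The velocity field is linearly rescaled so the peak |u_depth|
    on the monitoring lines equals ``peak_vr_target``, and the turbulent
    kinetic energy field (Gaussian blobs on pores and vortex cores) is
    rescaled so its culture-average equals ``mean_tke_target``.
    """
    if peak_vr_target < 0 or mean_tke_target < 0:
        raise CalibrationError("calibration targets must be non-negative")
    area = geom.culture_area()
    jet_speed = vvm_to_jet_speed(aeration, area)
    u_jet = MOMENTUM_TRANSFER_COEFF * jet_speed

    upw = _upwardness(aeration.direction_deg)
    lift = _direction_lift_fraction(aeration.direction_deg)
    weak = _direction_dark_weakening(aeration.direction_deg)
    R = geom.outer_radius
    core = 0.22 * R
    center_depth = geom.boundary_depth + lift * R
    x_c = 0.20 * R

    comps = [
        FlowComponentSpec("vortex", (center_depth, -x_c), +1.0, core),
        FlowComponentSpec("vortex", (center_depth, +x_c), -1.0, core),
    ]
    sites = pore_layout(geom, aeration) if geom.has_inner_tube else []
    for (pos, direction) in sites:
        orientation = math.degrees(math.atan2(direction[0], direction[1]))
        comps.append(
            FlowComponentSpec(
                "jet_plume",
                (pos[0] + 6.0 * direction[0], pos[1] + 6.0 * direction[1]),
                0.5 * max(u_jet, 1e-6),
                0.35 * core,
                orientation_deg=orientation,
            )
        )

    depth_c, lateral_c, mask = make_grid(geom, spacing)
    D, L = np.meshgrid(depth_c, lateral_c, indexing="ij")
    psi = np.zeros_like(D)
    for comp in comps:
        psi += comp.streamfunction(D, L)
    if weak < 1.0:
        # the slowdown acts on the deep dark zone only, with a gentle
        # spatial transition: shallow excursions below the interface keep
        # their geometry in every scenario, while the deep legs of dark
        # orbits are traversed more slowly
        t = np.clip((geom.boundary_depth - 25.0 - D) / 55.0, 0.0, 1.0)
        t = t * t * (3.0 - 2.0 * t)
        psi *= 1.0 - (1.0 - weak) * t
    # settling recirculation: with upward aeration, cells that cross into
    # the dark zone are drawn slowly downward toward the dead zone
    # (sedimentation) instead of being flung back; a weak counter-rotating
    # pair deep in the dark zone produces that downward sweep at the
    # midline.  It is added after the dark-zone weakening so its slow loop
    # is not weakened away.
    if upw > 0:
        # closed dark-zone recirculation cells: cells that dip below the
        # interface are captured by jitter into these closed eddies, where
        # the weak dark turbulence releases them only slowly -- the
        # settling/dead-zone behaviour of upward-aerated scenarios
        dark_depth = geom.boundary_depth - 0.45 * R
        extra = [
            FlowComponentSpec("vortex", (dark_depth, -0.30 * R), +0.35 * upw, 0.30 * R),
            FlowComponentSpec("vortex", (dark_depth, +0.30 * R), -0.35 * upw, 0.30 * R),
        ]
        for comp in extra:
            psi += comp.streamfunction(D, L)
    s = np.clip(_wall_distance(geom, D, L) / 25.0, 0.0, 1.0)
    psi *= s * s * (3.0 - 2.0 * s)
    field = field_from_streamfunction(geom, psi, depth_c, lateral_c, mask)

    # velocity calibration: exact by linearity
    peak = 0.0
    for off in monitoring_offsets:
        _, vr = field.monitoring_line_samples(off)
        if vr.size:
            peak = max(peak, float(np.abs(vr).max()))
    if peak_vr_target > 0:
        if peak <= 0:
            raise CalibrationError(
                "zero-strength field cannot be scaled to a nonzero peak target"
            )
        scale = peak_vr_target / peak
        field.u_depth *= scale
        field.u_lateral *= scale

    # turbulence: Gaussian blobs at pore sites and vortex cores, rescaled
    # turbulent kinetic energy rides with the energetic structures: strong
    # Gaussian blobs on the (direction-dependent) vortex cores, weaker ones
    # on the aeration pores, over a low ambient level.  When upward aeration
    # lifts the vortex pair into the light zone, the boundary region goes
    # quiet along with it.
    D, L = np.meshgrid(field.depth_coords, field.lateral_coords, indexing="ij")
    base_shape = np.full_like(D, 0.15)
    for comp in comps[:2]:
        bd, bl = comp.center
        r2 = (D - bd) ** 2 + (L - bl) ** 2
        base_shape += np.exp(-r2 / (2.0 * (0.8 * core) ** 2))
    for (pos, _) in sites:
        r2 = (D - pos[0]) ** 2 + (L - pos[1]) ** 2
        base_shape += 0.5 * np.exp(-r2 / (2.0 * (0.8 * core) ** 2))
    shape = base_shape
    if weak < 1.0:
        # upward aeration leaves the dark zone weakly turbulent as well
        t = np.clip((geom.boundary_depth - D) / 35.0, 0.0, 1.0)
        t = t * t * (3.0 - 2.0 * t)
        shape = base_shape * (1.0 - (1.0 - weak) * t)
    m = field.mask
    if mean_tke_target > 0:
        k = mean_tke_target * shape / float(shape[m].mean())
        k_ref = mean_tke_target * base_shape / float(base_shape[m].mean())
    else:
        k = np.zeros_like(shape)
        k_ref = k
    # dissipation follows the aeration-driven energetic scales (unweakened
    # profile): where upward aeration depresses k, eddies are short-lived
    # and small, so turbulent transport drops sharply.  The dissipation
    # length is the aeration-pore scale -- bubble-injected turbulence is
    # fine-grained jitter, while cross-section transport is carried by the
    # resolved vortices.
    mixing_length_cm = aeration.pore_diameter_mm / 2.0 / 10.0
    eps = 0.09**0.75 * np.maximum(k_ref, 1e-9) ** 1.5 / mixing_length_cm
    field.k = np.where(m, k, 0.0)
    field.eps = np.where(m, eps, 1e-6)
    return field


# -- table I/O ---------------------------------------------------------


def write_field_table(field: GriddedFlowField, path) -> None:
    """Write a gridded field as the delimited text table the pipeline reads.

    Row-major, lateral-fastest ordering; full float precision so a
    write-then-read round trip is bit-exact.
    """
    D, L = np.meshgrid(field.depth_coords, field.lateral_coords, indexing="ij")
    data = {
        "depth_mm": D.ravel(),
        "lateral_mm": L.ravel(),
        "u_depth_m_s": field.u_depth.ravel(),
        "u_lateral_m_s": field.u_lateral.ravel(),
        "k_cm2_s2": field.k.ravel(),
        "eps_cm2_s3": field.eps.ravel(),
    }
    if field.gas_fraction is not None:
        data["gas_fraction"] = field.gas_fraction.ravel()
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_field_table(path, geom: CrossSectionGeometry | None = None) -> GriddedFlowField:
    """Read a gridded field table (see :func:`write_field_table`).

    The table must contain a complete rectangular grid.  If ``geom`` is
    given, the culture mask is rebuilt from it; otherwise every cell is
    treated as culture.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:
        raise FieldFormatError(f"cannot parse field table {path}: {exc}") from exc
    missing = [c for c in FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise FieldFormatError(f"field table missing column(s): {', '.join(missing)}")
    for col in FIELD_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.argmax((df[col].isna() | bad).to_numpy()))
            raise FieldFormatError(
                f"non-numeric or missing value in column {col!r} at data row {row}"
            )
        df[col] = vals.astype(float)
    depth = np.unique(df["depth_mm"].to_numpy())
    lateral = np.unique(df["lateral_mm"].to_numpy())
    nd, nl = len(depth), len(lateral)
    if nd * nl != len(df):
        raise FieldFormatError(
            f"ragged grid: {len(df)} rows cannot form a {nd} x {nl} rectangle"
        )
    order = np.lexsort((df["lateral_mm"].to_numpy(), df["depth_mm"].to_numpy()))
    sorted_df = df.iloc[order]
    exp_d = np.repeat(depth, nl)
    exp_l = np.tile(lateral, nd)
    if not (
        np.array_equal(sorted_df["depth_mm"].to_numpy(), exp_d)
        and np.array_equal(sorted_df["lateral_mm"].to_numpy(), exp_l)
    ):
        raise FieldFormatError("incomplete grid: coordinate pairs do not tile a rectangle")

    def grid(col: str) -> np.ndarray:
        return sorted_df[col].to_numpy().reshape(nd, nl)

    if geom is not None:
        D, L = np.meshgrid(depth, lateral, indexing="ij")
        mask = geom.in_culture(D, L)
    else:
        mask = np.ones((nd, nl), dtype=bool)
    gas = grid("gas_fraction") if "gas_fraction" in df.columns else None
    return GriddedFlowField(
        depth_coords=depth,
        lateral_coords=lateral,
        mask=mask,
        u_depth=grid("u_depth_m_s"),
        u_lateral=grid("u_lateral_m_s"),
        k=grid("k_cm2_s2"),
        eps=grid("eps_cm2_s3"),
        gas_fraction=gas,
        geometry=geom,
    )
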
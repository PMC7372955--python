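"""Lagrangian tracking of neutrally buoyant algal-cell surrogate particles.

Particles (spheres, default 10 um, 1000 kg/m^3 — density-matched to the
medium) are advanced through a steady 2-D liquid velocity field under two
forces per unit particle mass:

* quadratic drag, ``(3 C_D rho_f)/(4 d rho_d) |v_f - v_p| (v_f - v_p)``
  with a constant Newton-regime drag coefficient ``C_D = 0.44``;
* the pressure-gradient force, ``(rho_f/rho_d) Dv_f/Dt``, evaluated from
  the material acceleration ``(u . grad) u`` of the steady field.

Turbulent dispersion uses the discrete random walk (eddy interaction)
model: the fluid velocity seen by a particle is the mean field plus a
Gaussian fluctuation with per-component variance ``2k/3``, held for an
eddy lifetime ``tau_e = 2 T_L`` with ``T_L = 0.15 k/eps`` and then
resampled.

Integration is explicit 4th-order Runge-Kutta on (position, velocity)
with specular wall reflection; positions and light/dark zone labels are
recorded on a fixed schedule (default every 0.1 s up to 60 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CrossSectionGeometry, DomainError, Layout
from .synthetic_flow import GriddedFlowField


class IntegrationError(RuntimeError):
    """Particle integration produced a non-finite state."""


@dataclass(frozen=True)
class ParticleParams:
    """Physical and numerical parameters of the particle tracker."""

    n_particles: int = 20
    diameter: float = 1e-5  # m
    density: float = 1000.0  # particle density, kg/m^3
    drag_coefficient: float = 0.44
    fluid_density: float = 1000.0  # kg/m^3
    record_interval: float = 0.1  # s
    max_time: float = 60.0  # s
    integrator_step: float = 0.01  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0 or self.fluid_density <= 0:
            raise ValueError("diameter and densities must be positive")
        if self.integrator_step > self.record_interval:
            raise ValueError("integrator_step must not exceed record_interval")
        if self.max_time < self.record_interval:
            raise ValueError("max_time must be at least one record_interval")

    @property
    def drag_factor(self) -> float:
        """Per-unit-mass quadratic drag prefactor, 1/m."""
        return (
            3.0
            * self.drag_coefficient
            * self.fluid_density
            / (4.0 * self.diameter * self.density)
        )


@dataclass
class Trajectory:
    """Recorded path of one particle: times (s), positions (mm), zone labels."""

    particle_id: int
    times: np.ndarray
    positions: np.ndarray  # (n_samples, 2) = (depth_mm, lateral_mm)
    zones: np.ndarray  # (n_samples,) of "light" / "dark"


def drag_accel(
    v_fluid: np.ndarray, v_particle: np.ndarray, params: ParticleParams
) -> np.ndarray:
    """Quadratic drag acceleration (m/s^2) on the particle."""
    dv = np.asarray(v_fluid, float) - np.asarray(v_particle, float)
    slip = np.linalg.norm(dv, axis=-1, keepdims=True)
    return params.drag_factor * slip * dv


class _FieldDerivatives:
    """Cached central-difference velocity gradients of a steady field.

    Gradients are stored in 1/s (velocity in m/s differentiated with
    respect to position in metres) so the material acceleration
    ``(u . grad) u`` comes out in m/s^2.
    """

    def __init__(self, field: GriddedFlowField):
        self.field = field
        h_m = field.spacing / 1000.0
        ud, ul = field.u_depth, field.u_lateral
        self.stack = np.stack(
            [
                ud,
                ul,
                np.gradient(ud, h_m, axis=0),
                np.gradient(ud, h_m, axis=1),
                np.gradient(ul, h_m, axis=0),
                np.gradient(ul, h_m, axis=1),
            ]
        )

    def velocity_and_accel(self, depth, lateral) -> tuple[np.ndarray, np.ndarray]:
        """Mean velocity (m/s) and material acceleration (m/s^2) at points."""
        v = self.field._bilinear(self.stack, depth, lateral)
        ud, ul, dud_dd, dud_dl, dul_dd, dul_dl = v
        u = np.empty(ud.shape + (2,))
        u[..., 0] = ud
        u[..., 1] = ul
        acc = np.empty_like(u)
        acc[..., 0] = ud * dud_dd + ul * dud_dl
        acc[..., 1] = ud * dul_dd + ul * dul_dl
        return u, acc


def fluid_accel(field: GriddedFlowField, point) -> np.ndarray:
    """Material acceleration ``(u . grad) u`` of the steady field, m/s^2."""
    geom = field.geometry
    if geom is not None and not geom.in_culture_point(point):
        raise DomainError(f"point {point!r} outside the culture region")
    _, acc = _FieldDerivatives(field).velocity_and_accel(point[0], point[1])
    return acc


def pressure_gradient_accel(
    field: GriddedFlowField, point, params: ParticleParams
) -> np.ndarray:
    """Pressure-gradient force per unit particle mass, m/s^2."""
    return (params.fluid_density / params.density) * fluid_accel(field, point)


def drw_fluctuation(
    k_cm2_s2, eps_cm2_s3, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a discrete-random-walk velocity fluctuation and eddy lifetime.

    Each component is ``zeta * sqrt(2k/3)`` (zeta standard normal, k
    converted to m^2/s^2); the eddy lifetime is ``2 T_L`` with
    ``T_L = 0.15 k/eps``.  Vectorized over particles.
    """
    k = np.atleast_1d(np.asarray(k_cm2_s2, float))
    eps = np.atleast_1d(np.asarray(eps_cm2_s3, float))
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    if np.any(eps <= 0):
        raise ValueError("eps must be positive")
    sigma = np.sqrt(2.0 * k * 1e-4 / 3.0)  # m/s
    zeta = rng.standard_normal(size=(k.size, 2))
    fluct = zeta * sigma[:, None]
    lifetime = 2.0 * 0.15 * k / eps
    return fluct, lifetime


def _reflect(
    geom: CrossSectionGeometry, pos: np.ndarray, vel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Specular reflection of escaped particles back into the culture region.

    Handles the outer wall, the inner tube and the tangent-layout panel;
    applied iteratively since a single reflection can land in another
    excluded region.  Reflection preserves speed.
    """
    pos = pos.copy()
    vel = vel.copy()
    R = geom.outer_radius
    for _ in range(8):
        outside = ~np.atleast_1d(geom.in_culture(pos[:, 0], pos[:, 1]))
        if not outside.any():
            break
        idx = np.where(outside)[0]
        p = pos[idx]
        v = vel[idx]
        rho = np.hypot(p[:, 0], p[:, 1])
        out_outer = rho > R
        # outer wall: fold radially
        if out_outer.any():
            j = out_outer
            n = p[j] / rho[j, None]
            p[j] -= 2.0 * (rho[j] - R)[:, None] * n
            vn = (v[j] * n).sum(axis=1)
            v[j] -= 2.0 * vn[:, None] * n
        if geom.has_inner_tube:
            c = geom.inner_center_depth_offset
            r_in = geom.inner_radius
            dc = p[:, 0] - c
            rin = np.hypot(dc, p[:, 1])
            in_inner = (~out_outer) & (rin < r_in)
            if in_inner.any():
                j = in_inner
                safe = np.maximum(rin[j], 1e-9)
                n = np.stack([dc[j], p[j, 1]], axis=1) / safe[:, None]
                p[j] += 2.0 * (r_in - rin[j])[:, None] * n
                vn = (v[j] * n).sum(axis=1)
                v[j] -= 2.0 * vn[:, None] * n
            if geom.layout is Layout.TANGENT and geom.fillet_enabled:
                chord = geom.fillet_chord_depth
                below = (~out_outer) & (~in_inner) & (p[:, 0] < chord)
                if below.any():
                    j = below
                    p[j, 0] = 2.0 * chord - p[j, 0]
                    v[j, 0] = -v[j, 0]
        pos[idx] = p
        vel[idx] = v
    return pos, vel


def stratified_release_positions(geom: CrossSectionGeometry, n: int) -> np.ndarray:
    """Deterministic, evenly spread release positions over the culture region.

    Scenario comparisons release the same cells in every scenario; a
    stratified deterministic release removes release-position sampling
    noise from paired comparisons.  Points are taken from a regular grid
    restricted to the culture region, thinned evenly to ``n``.
    """
    R = geom.outer_radius
    m = max(8, int(math.ceil(2.5 * math.sqrt(n))))
    while True:
        coords = (np.arange(m) + 0.5) / m * 2 * R - R
        D, L = np.meshgrid(coords, coords, indexing="ij")
        keep = np.atleast_1d(geom.in_culture(D.ravel(), L.ravel()))
        pts = np.stack([D.ravel()[keep], L.ravel()[keep]], axis=1)
        if len(pts) >= n:
            break
        m *= 2
    idx = np.round(np.linspace(0, len(pts) - 1, n)).astype(int)
    return pts[idx]


def sample_release_positions(
    geom: CrossSectionGeometry, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random release positions (mm) over the culture region."""
    R = geom.outer_radius
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-R, R, size=(4 * n, 2))
        keep = cand[np.atleast_1d(geom.in_culture(cand[:, 0], cand[:, 1]))]
        take = min(n - filled, len(keep))
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def track(
    field: GriddedFlowField,
    geom: CrossSectionGeometry,
    params: ParticleParams,
    initial_positions: np.ndarray | None = None,
    initial_velocities: np.ndarray | None = None,
) -> list[Trajectory]:
    """Track particles through the field and record sampled trajectories.

    Particles are released at ``initial_positions`` (mm) or, if absent, at
    seeded uniform random positions over the culture region.  The initial
    velocity defaults to the local mean fluid velocity (an equilibrated
    release); pass ``initial_velocities`` (m/s) to override, e.g. zeros for
    a release from rest.  Positions are recorded every
    ``params.record_interval`` up to ``params.max_time`` (the release
    position itself is not recorded).
    """
    rng = np.random.default_rng(params.seed)
    if initial_positions is None:
        pos = sample_release_positions(geom, params.n_particles, rng)
    else:
        pos = np.atleast_2d(np.asarray(initial_positions, float)).copy()
        inside = np.atleast_1d(geom.in_culture(pos[:, 0], pos[:, 1]))
        if not inside.all():
            raise DomainError("initial positions must lie inside the culture region")
    n = len(pos)
    deriv = _FieldDerivatives(field)
    if initial_velocities is None:
        vel, _ = deriv.velocity_and_accel(pos[:, 0], pos[:, 1])
        vel = vel.copy()
    else:
        vel = np.atleast_2d(np.asarray(initial_velocities, float)).copy()
        if vel.shape != pos.shape:
            raise ValueError("initial_velocities must match initial_positions")

    dt = params.integrator_step
    steps_per_record = int(round(params.record_interval / dt))
    n_records = int(round(params.max_time / params.record_interval))
    drag_f = params.drag_factor
    rho_ratio = params.fluid_density / params.density

    fluct = np.zeros((n, 2))
    eddy_left = np.zeros(n)
    has_turb = bool(np.any(field.k[field.mask] > 0))

    times = (np.arange(n_records) + 1) * params.record_interval
    rec_pos = np.empty((n_records, n, 2))

    def rhs(p: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        u_mean, acc = deriv.velocity_and_accel(p[:, 0], p[:, 1])
        dv = u_mean + fluct - v
        slip = np.sqrt(dv[:, 0] ** 2 + dv[:, 1] ** 2)[:, None]
        a = drag_f * slip * dv + rho_ratio * acc
        return v * 1000.0, a, float(slip.max())  # dx/dt in mm/s

    step_count = 0
    for rec in range(n_records):
        for _ in range(steps_per_record):
            if has_turb:
                expired = eddy_left <= 0.0
                if expired.any():
                    kk, ee = field.turbulence_at(pos[:, 0], pos[:, 1])
                    new_f, life = drw_fluctuation(kk, np.maximum(ee, 1e-12), rng)
                    fluct[expired] = new_f[expired]
                    eddy_left[expired] = np.maximum(life[expired], dt)
                eddy_left -= dt
            # RK4 with internal stability sub-stepping: the quadratic-drag
            # relaxation rate 2*A*slip can exceed 1/dt by orders of magnitude
            # right after an eddy resampling, so the step is subdivided until
            # the drag rate per substep is small.
            t_done = 0.0
            while t_done < dt - 1e-15:
                k1p, k1v, max_slip = rhs(pos, vel)
                h = dt - t_done
                if max_slip > 0:
                    h = min(h, 0.8 / (drag_f * max_slip))
                k2p, k2v, _ = rhs(pos + 0.5 * h * k1p, vel + 0.5 * h * k1v)
                k3p, k3v, _ = rhs(pos + 0.5 * h * k2p, vel + 0.5 * h * k2v)
                k4p, k4v, _ = rhs(pos + h * k3p, vel + h * k3v)
                pos = pos + (h / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p)
                vel = vel + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
                t_done += h
            step_count += 1
            if not (np.isfinite(pos).all() and np.isfinite(vel).all()):
                raise IntegrationError(f"non-finite particle state at step {step_count}")
            pos, vel = _reflect(geom, pos, vel)
        rec_pos[rec] = pos

    inside = geom.in_culture(rec_pos[:, :, 0], rec_pos[:, :, 1])
    if not inside.all():
        raise DomainError("particle escaped the culture region after reflection")
    zones = np.where(rec_pos[:, :, 0] > geom.boundary_depth, "light", "dark")
    return [
        Trajectory(
            particle_id=i,
            times=times.copy(),
            positions=rec_pos[:, i, :].copy(),
            zones=zones[:, i].copy(),
        )
        for i in range(n)
    ]
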
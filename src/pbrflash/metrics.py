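"""Evaluation metrics: field synergy |cos a|, monitoring-line profiles,
mean turbulent kinetic energy, dead-zone fraction, and light/dark cycle
statistics.

The field synergy angle ``a`` is the angle between the local liquid
velocity and the light propagation direction (illumination from the top,
normal incidence, travelling straight down the depth axis).  ``|cos a|``
near 1 means the flow carries cells along the light path — across the
light gradient — which is what drives the flashing-light effect.

Light/dark cycle statistics follow the crossing definition: a cycle is the
time for a cell to cross the light/dark interface twice; the population
cycle period T averages per-particle mean cycle durations, the cycle
frequency is f = 1/T, and the light-time ratio phi is the per-particle
fraction of cycle time spent in the light zone, averaged over particles
that cross at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import CrossSectionGeometry
from .particle_tracking import Trajectory
from .synthetic_flow import GriddedFlowField

#: speed below which the synergy angle is undefined (stagnant fluid), m/s
STAGNANT_SPEED = 1e-9


@dataclass
class SynergyStats:
    region: str
    mean_abs_cos_alpha: float
    undefined_fraction: float


@dataclass
class ProfileSeries:
    lateral_offset: float
    depth_coords: np.ndarray
    v_r: np.ndarray
    abs_cos_alpha: np.ndarray


@dataclass
class LDCycleStats:
    per_particle_T: dict[int, float]
    mean_T: float
    frequency: float
    light_time_ratio: float
    n_cycles: dict[int, int]
    n_noncrossing: int


def cos_alpha_field(
    flow: GriddedFlowField, light_direction: tuple[float, float] = (-1.0, 0.0)
) -> np.ndarray:
    """Per-cell |cos a| between velocity and the light direction.

    ``light_direction`` is a unit vector in (depth, lateral) components;
    the default points straight down the depth axis (light entering from
    the illuminated top).  Cells with speed below ``STAGNANT_SPEED`` are
    NaN (undefined).
    """
    g = np.asarray(light_direction, float)
    norm = np.linalg.norm(g)
    if norm < 1e-12:
        raise ValueError("light_direction must be a nonzero vector")
    if abs(norm - 1.0) > 1e-9:
        g = g / norm
    speed = flow.speed
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.abs(flow.u_depth * g[0] + flow.u_lateral * g[1]) / speed
    cos[speed < STAGNANT_SPEED] = np.nan
    cos[~flow.mask] = np.nan
    return cos


def mean_abs_cos_alpha(
    flow: GriddedFlowField,
    region: str = "culture",
    lateral_offset: float | None = None,
    light_direction: tuple[float, float] = (-1.0, 0.0),
) -> SynergyStats:
    """Area- (or line-) weighted mean |cos a| over defined cells.

    ``region="culture"`` averages over all culture cells with uniform cell
    weights; ``region="line"`` averages along the vertical monitoring line
    at ``lateral_offset`` with uniform sample weights.  Stagnant (undefined)
    cells are excluded and their fraction reported.
    """
    if region == "line":
        if lateral_offset is None:
            raise ValueError("lateral_offset required for region='line'")
        prof = vr_profile(flow, lateral_offset, light_direction=light_direction)
        vals = prof.abs_cos_alpha
    elif region == "culture":
        cos = cos_alpha_field(flow, light_direction)
        vals = cos[flow.mask]
    else:
        raise ValueError(f"unknown region {region!r}")
    if vals.size == 0:
        raise ValueError("region contains no cells")
    defined = np.isfinite(vals)
    undef_frac = 1.0 - defined.mean()
    mean = float(np.nan) if not defined.any() else float(vals[defined].mean())
    name = region if region == "culture" else f"line@{lateral_offset:g}mm"
    return SynergyStats(name, mean, float(undef_frac))


def vr_profile(
    flow: GriddedFlowField,
    lateral_offset: float,
    n_samples: int = 400,
    light_direction: tuple[float, float] = (-1.0, 0.0),
) -> ProfileSeries:
    """V_r and |cos a| sampled along a vertical monitoring line.

    V_r is the depth-axis velocity component — the component that carries
    cells across the light/dark interface.  Sampling is bilinear,
    restricted to points inside the culture region.
    """
    geom = flow.geometry
    if geom is not None and abs(lateral_offset) >= geom.outer_radius:
        raise ValueError("monitoring line lies outside the outer tube")
    depths, _ = flow.monitoring_line_samples(lateral_offset, n_samples)
    if depths.size == 0:
        return ProfileSeries(lateral_offset, depths, depths, depths)
    lats = np.full_like(depths, lateral_offset)
    u = flow.velocity_at(depths, lats)
    g = np.asarray(light_direction, float)
    g = g / np.linalg.norm(g)
    speed = np.hypot(u[0], u[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.abs(u[0] * g[0] + u[1] * g[1]) / speed
    cos[speed < STAGNANT_SPEED] = np.nan
    return ProfileSeries(lateral_offset, depths, u[0], cos)


def tke_mean(flow: GriddedFlowField, region_mask: np.ndarray | None = None) -> float:
    """Area-weighted mean turbulent kinetic energy over culture cells, cm^2/s^2."""
    m = flow.mask if region_mask is None else (flow.mask & region_mask)
    if not m.any():
        raise ValueError("region contains no culture cells")
    return float(flow.k[m].mean())


def dead_zone_fraction(flow: GriddedFlowField, speed_threshold: float = 1e-3) -> float:
    """Fraction of the culture area where the liquid is effectively stagnant."""
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    m = flow.mask
    return float((flow.speed[m] < speed_threshold).mean())


# -- light/dark cycle statistics ---------------------------------------


def _crossing_times(
    times: np.ndarray, depth: np.ndarray, boundary: float
) -> np.ndarray:
    """Interface crossing times by sign change with linear interpolation."""
    s = depth - boundary
    sign = np.sign(s)
    # treat exact zeros as belonging to the previous side so a grazing
    # touch does not double-count
    for i in range(len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1] if i > 0 else 1.0
    idx = np.where(sign[1:] * sign[:-1] < 0)[0]
    frac = s[idx] / (s[idx] - s[idx + 1])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def _light_fraction_between(
    times: np.ndarray, depth: np.ndarray, boundary: float, t0: float, t1: float
) -> float:
    """Fraction of [t0, t1] spent in the light zone, with linear
    interpolation of the depth coordinate between samples."""
    if t1 <= t0:
        return float("nan")
    fine_t = np.union1d(times[(times > t0) & (times < t1)], [t0, t1])
    fine_d = np.interp(fine_t, times, depth)
    light = 0.0
    for a, b, da, db in zip(fine_t[:-1], fine_t[1:], fine_d[:-1], fine_d[1:]):
        seg = b - a
        sa, sb = da - boundary, db - boundary
        if sa >= 0 and sb >= 0:
            light += seg
        elif sa < 0 and sb < 0:
            pass
        else:
            tc = a + seg * sa / (sa - sb)
            if sa >= 0:
                light += tc - a
            else:
                light += b - tc
    return light / (t1 - t0)


def ld_cycle_stats(
    trajectories: list[Trajectory],
    geom: CrossSectionGeometry,
    per_particle: bool = False,
) -> LDCycleStats:
    """Population light/dark cycle statistics from recorded trajectories.

    A cycle is the time between alternate interface crossings (crossing i
    to crossing i+2), containing one light and one dark interval.  The
    population period T averages over all observed cycles (the limit sum
    runs over cycles); with ``per_particle=True`` it instead averages
    per-particle mean cycle durations with equal particle weights.  phi is
    the light-time fraction over the complete-cycle span (first to last
    crossing), pooled over particles by time (or averaged per particle).
    Particles that never cross are excluded and counted in
    ``n_noncrossing``; a particle needs at least three crossings to hold a
    complete cycle.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    boundary = geom.boundary_depth
    per_T: dict[int, float] = {}
    n_cycles: dict[int, int] = {}
    phis: list[float] = []
    spans: list[float] = []
    total_cycle_time = 0.0
    total_cycles = 0
    n_noncrossing = 0
    for tr in trajectories:
        depth = tr.positions[:, 0]
        cross = _crossing_times(tr.times, depth, boundary)
        if cross.size == 0:
            n_noncrossing += 1
            continue
        if cross.size >= 3:
            cycles = cross[2:] - cross[:-2]
            per_T[tr.particle_id] = float(cycles.mean())
            n_cycles[tr.particle_id] = int(cycles.size)
            total_cycle_time += float(cycles.sum())
            total_cycles += int(cycles.size)
            # phi over the complete-cycle span only: between the first and
            # last crossing the trajectory holds whole light and dark
            # intervals, so t_l/(t_l+t_d) is well defined; a particle with
            # fewer than three crossings has no complete cycle and would
            # contribute a span that is entirely one zone.
            phis.append(
                _light_fraction_between(
                    tr.times, depth, boundary, cross[0], cross[-1]
                )
            )
            spans.append(float(cross[-1] - cross[0]))
        else:
            n_cycles[tr.particle_id] = 0
    if not per_T:
        mean_T = math.inf
        phi = float("nan")
    elif per_particle:
        mean_T = float(np.mean(list(per_T.values())))
        phi = float(np.mean(phis))
    else:
        mean_T = total_cycle_time / total_cycles
        phi = float(np.average(phis, weights=spans))
    freq = 1.0 / mean_T if math.isfinite(mean_T) and mean_T > 0 else 0.0
    return LDCycleStats(
        per_particle_T=per_T,
        mean_T=mean_T,
        frequency=freq,
        light_time_ratio=phi,
        n_cycles=n_cycles,
        n_noncrossing=n_noncrossing,
    )
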
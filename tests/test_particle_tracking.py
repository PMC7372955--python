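"""Particle tracker: force model oracles, DRW statistics, wall handling,
and integration accuracy."""

import numpy as np
import pytest

import pbrflash as pf
from pbrflash.geometry import DomainError
from pbrflash.particle_tracking import sample_release_positions
from pbrflash.synthetic_flow import make_grid


def uniform_field(geom, u_depth, u_lateral, k=0.0, eps=1.0):
    depth, lateral, mask = make_grid(geom, spacing=2.0)
    nd, nl = len(depth), len(lateral)
    return pf.GriddedFlowField(
        depth_coords=depth,
        lateral_coords=lateral,
        mask=mask,
        u_depth=np.where(mask, u_depth, 0.0),
        u_lateral=np.where(mask, u_lateral, 0.0),
        k=np.full((nd, nl), k),
        eps=np.full((nd, nl), eps),
        geometry=geom,
    )


class TestForceModel:
    def test_drag_zero_slip(self):
        p = pf.ParticleParams()
        a = pf.drag_accel(np.array([0.02, 0.01]), np.array([0.02, 0.01]), p)
        np.testing.assert_array_equal(a, [0.0, 0.0])

    def test_drag_hand_oracle(self):
        # (3*0.44*1000)/(4*1e-5*1000) * (0.01)^2 = 3.3 m/s^2
        p = pf.ParticleParams()
        a = pf.drag_accel(np.array([0.01, 0.0]), np.array([0.0, 0.0]), p)
        assert np.linalg.norm(a) == pytest.approx(3.3, rel=1e-12)

    def test_drag_quadratic_scaling(self):
        p = pf.ParticleParams()
        a1 = pf.drag_accel(np.array([0.01, 0.0]), np.zeros(2), p)
        a2 = pf.drag_accel(np.array([0.02, 0.0]), np.zeros(2), p)
        assert np.linalg.norm(a2) == pytest.approx(4 * np.linalg.norm(a1), rel=1e-12)

    def test_fluid_accel_uniform_field_zero(self, plain_geom):
        fld = uniform_field(plain_geom, 0.02, 0.01)
        a = pf.fluid_accel(fld, (0.0, 0.0))
        np.testing.assert_allclose(a, [0.0, 0.0], atol=1e-15)

    def test_fluid_accel_solid_body_centripetal(self, solid_body_field):
        # (u.grad)u for solid-body rotation is -omega^2 r toward the centre
        fld = solid_body_field
        omega_si = fld.omega * 1000.0  # rad/s
        for pt in [(30.0, 0.0), (0.0, 40.0), (20.0, -20.0)]:
            a = pf.fluid_accel(fld, pt)
            r_m = np.hypot(*pt) / 1000.0
            expected = omega_si**2 * r_m
            assert np.linalg.norm(a) == pytest.approx(expected, rel=0.02)
            # directed toward the axis
            inward = -np.array(pt) / np.hypot(*pt)
            assert float(a @ inward) > 0

    def test_fluid_accel_shear_hand_oracle(self, plain_geom):
        # u_depth = c * lateral, u_lateral = 0:
        # (u.grad)u = (u_l * du_d/dlat, 0) = (0, 0) since u_lateral = 0
        depth, lateral, mask = make_grid(plain_geom, spacing=2.0)
        L = np.meshgrid(depth, lateral, indexing="ij")[1]
        c = 2e-4  # (m/s)/mm
        fld = pf.GriddedFlowField(
            depth_coords=depth,
            lateral_coords=lateral,
            mask=mask,
            u_depth=c * L,
            u_lateral=np.zeros_like(L),
            k=np.zeros_like(L),
            eps=np.ones_like(L),
            geometry=plain_geom,
        )
        a = pf.fluid_accel(fld, (10.0, 20.0))
        np.testing.assert_allclose(a, [0.0, 0.0], atol=1e-15)

    def test_pressure_gradient_density_ratio(self, solid_body_field):
        pt = (30.0, 0.0)
        base = pf.fluid_accel(solid_body_field, pt)
        equal = pf.ParticleParams()  # rho_f = rho_d
        np.testing.assert_allclose(
            pf.pressure_gradient_accel(solid_body_field, pt, equal), base
        )
        heavy = pf.ParticleParams(density=1e9)
        assert np.linalg.norm(
            pf.pressure_gradient_accel(solid_body_field, pt, heavy)
        ) == pytest.approx(0.0, abs=1e-9 * np.linalg.norm(base) * 1e9)

    def test_fluid_accel_outside_mask_rejected(self, tangent_geom, tangent_field):
        with pytest.raises(DomainError):
            pf.fluid_accel(tangent_field, (-60.0, 0.0))


class TestDRW:
    def test_zero_k_zero_fluctuation(self):
        rng = np.random.default_rng(0)
        fluct, _ = pf.drw_fluctuation(0.0, 10.0, rng)
        np.testing.assert_array_equal(fluct, 0.0)

    def test_component_variance_is_two_thirds_k(self):
        rng = np.random.default_rng(42)
        k = 80.0  # cm^2/s^2
        fluct, _ = pf.drw_fluctuation(np.full(100_000, k), np.full(100_000, 50.0), rng)
        var = fluct.var(axis=0)  # (m/s)^2
        expected = 2.0 * k * 1e-4 / 3.0
        np.testing.assert_allclose(var, expected, rtol=0.02)

    def test_eddy_lifetime_formula(self):
        rng = np.random.default_rng(0)
        _, life = pf.drw_fluctuation(50.0, 25.0, rng)
        assert life[0] == pytest.approx(2.0 * 0.15 * 50.0 / 25.0)

    def test_fixed_seed_reproducible(self):
        a, _ = pf.drw_fluctuation(np.full(10, 30.0), np.full(10, 10.0), np.random.default_rng(9))
        b, _ = pf.drw_fluctuation(np.full(10, 30.0), np.full(10, 10.0), np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            pf.drw_fluctuation(10.0, 0.0, np.random.default_rng(0))


class TestTrack:
    def test_zero_field_particles_stationary(self, plain_geom):
        fld = uniform_field(plain_geom, 0.0, 0.0)
        params = pf.ParticleParams(n_particles=3, seed=1)
        trajs = pf.track(fld, plain_geom, params)
        assert len(trajs) == 3
        for tr in trajs:
            assert len(tr.times) == 600
            assert np.ptp(tr.positions, axis=0) == pytest.approx([0.0, 0.0])

    def test_drag_relaxation_matches_closed_form(self, plain_geom):
        # dv/dt = A (u - v)|u - v| with v(0)=0 has slip s(t) = s0/(1 + A s0 t)
        u = 0.02
        fld = uniform_field(plain_geom, 0.0, u)
        params = pf.ParticleParams(
            n_particles=1, seed=0, max_time=2.0, record_interval=0.1
        )
        A = params.drag_factor
        start = np.array([[0.0, -40.0]])
        trajs = pf.track(
            fld, plain_geom, params, initial_positions=start,
            initial_velocities=np.zeros((1, 2)),
        )
        # velocity not recorded; compare travelled distance against the
        # integral of v(t) = u - s0/(1 + A s0 t):
        # x(t) = u t - ln(1 + A s0 t)/A   (in m)
        t = trajs[0].times
        expected_mm = (u * t - np.log(1.0 + A * u * t) / A) * 1000.0
        got_mm = trajs[0].positions[:, 1] - start[0, 1]
        np.testing.assert_allclose(got_mm, expected_mm, rtol=0.01, atol=1e-4)
        # monotone approach: displacement increments increase toward u*dt
        inc = np.diff(got_mm)
        assert (np.diff(inc) > -1e-9).all()

    def test_tracer_follows_solid_body_orbit(self, solid_body_field, plain_geom):
        # 10 revolutions: orbit radius conserved within 1%
        omega_si = solid_body_field.omega * 1000.0  # 0.5 rad/s
        period = 2 * np.pi / omega_si
        params = pf.ParticleParams(
            n_particles=1, seed=0, max_time=60.0, record_interval=0.1
        )
        assert 10 * period < 130.0
        params = pf.ParticleParams(
            n_particles=1, seed=0, max_time=float(np.ceil(10 * period)),
            record_interval=0.1,
        )
        trajs = pf.track(
            solid_body_field, plain_geom, params, initial_positions=[[0.0, 50.0]]
        )
        radii = np.hypot(*trajs[0].positions.T)
        assert np.abs(radii - 50.0).max() < 0.01 * 50.0

    def test_tracer_limit_deviation_from_streamline(self, solid_body_field, plain_geom):
        # analytic streamline of solid-body rotation: a circle traversed at
        # omega; compare the tracked particle against it pointwise
        omega_si = solid_body_field.omega * 1000.0
        params = pf.ParticleParams(n_particles=1, seed=0, max_time=60.0)
        trajs = pf.track(
            solid_body_field, plain_geom, params, initial_positions=[[0.0, 50.0]]
        )
        t = trajs[0].times
        # velocity (u_d, u_l) = (-omega*L, omega*D) rotates (depth, lateral)
        # clockwise from (0, 50): depth(t) = -50 sin(wt), lateral = 50 cos(wt)
        expected = np.stack(
            [-50.0 * np.sin(omega_si * t), 50.0 * np.cos(omega_si * t)], axis=1
        )
        dev = np.linalg.norm(trajs[0].positions - expected, axis=1)
        assert dev.max() < 0.01 * plain_geom.outer_radius

    def test_step_halving_convergence(self, solid_body_field, plain_geom):
        kw = dict(n_particles=1, seed=0, max_time=20.0)
        p1 = pf.ParticleParams(integrator_step=0.01, **kw)
        p2 = pf.ParticleParams(integrator_step=0.005, **kw)
        t1 = pf.track(solid_body_field, plain_geom, p1, initial_positions=[[0.0, 50.0]])
        t2 = pf.track(solid_body_field, plain_geom, p2, initial_positions=[[0.0, 50.0]])
        diff = np.linalg.norm(t1[0].positions[-1] - t2[0].positions[-1])
        assert diff < 0.001 * plain_geom.outer_radius

    def test_bit_reproducible_with_seed(self, tangent_geom, tangent_field):
        params = pf.ParticleParams(n_particles=4, seed=77, max_time=5.0)
        a = pf.track(tangent_field, tangent_geom, params)
        b = pf.track(tangent_field, tangent_geom, params)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_recorded_positions_stay_in_culture(self, tangent_geom, tangent_field):
        params = pf.ParticleParams(n_particles=6, seed=3, max_time=10.0)
        trajs = pf.track(tangent_field, tangent_geom, params)
        for tr in trajs:
            inside = tangent_geom.in_culture(tr.positions[:, 0], tr.positions[:, 1])
            assert inside.all()
            assert (np.diff(tr.times) > 0).all()
            np.testing.assert_allclose(np.diff(tr.times), 0.1)

    def test_release_outside_culture_rejected(self, tangent_geom, tangent_field):
        params = pf.ParticleParams(n_particles=1, seed=0)
        with pytest.raises(DomainError):
            pf.track(
                tangent_field, tangent_geom, params, initial_positions=[[-60.0, 0.0]]
            )

    def test_release_sampling_uniform_inside(self, tangent_geom):
        rng = np.random.default_rng(5)
        pts = sample_release_positions(tangent_geom, 500, rng)
        assert tangent_geom.in_culture(pts[:, 0], pts[:, 1]).all()
        # both zones populated
        assert (pts[:, 0] > 0).any() and (pts[:, 0] < 0).any()
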
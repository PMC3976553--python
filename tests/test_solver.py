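"""Explicit solver: masses, element forces, integration, boundary tracking."""

import numpy as np
import pytest

from mvsim import contact as ct
from mvsim import geometry as geo
from mvsim import materials as mat
from mvsim import solver as sv
from mvsim.errors import InvalidParameterError


@pytest.fixture
def materials():
    return mat.representative_materials()


@pytest.fixture
def small_valve():
    return geo.build_valve(
        geo.AnnulusProfile(n_samples=32),
        geo.LeafletSpec(),
        geo.ChordaeSpec(n_marginal_anterior=6, n_marginal_posterior=6, n_strut=2),
        target_edge_length=4.0,
    )


def single_triangle_problem(materials, nodes=None):
    """One anterior membrane triangle with unit-free scale (mm geometry)."""
    if nodes is None:
        nodes = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
    g = geo.MVGeometry(
        nodes=nodes,
        triangles=np.array([[0, 1, 2]]),
        truss_segments=np.empty((0, 2), np.int64),
        truss_type=np.empty(0, np.int64),
        truss_chord_id=np.empty(0, np.int64),
        truss_rest_length=np.empty(0),
        node_sets={
            "annulus": np.empty(0, np.int64),
            "anterior_leaflet": np.arange(3),
            "posterior_leaflet": np.empty(0, np.int64),
            "free_edge_anterior": np.empty(0, np.int64),
            "free_edge_posterior": np.empty(0, np.int64),
            "pm_tips": np.empty(0, np.int64),
            "chordae_internal": np.empty(0, np.int64),
        },
        node_region=np.zeros(3, np.int64),
        node_param_s=np.zeros(3),
        node_param_t=np.zeros(3),
        tri_region=np.zeros(1, np.int64),
    )
    cfg = sv.SolverConfig(T_end=0.0, mass_scale=1.0, chordae_mass_scale=1.0)
    return sv.build_problem(g, materials, cfg)


def truss_problem(materials, L0_mm=10.0, pos_mm=None):
    nodes = np.array([[0.0, 0.0, 0.0], [L0_mm, 0.0, 0.0]]) if pos_mm is None else pos_mm
    g = geo.MVGeometry(
        nodes=nodes,
        triangles=np.empty((0, 3), np.int64),
        truss_segments=np.array([[0, 1]]),
        truss_type=np.array([1]),
        truss_chord_id=np.array([0]),
        truss_rest_length=np.array([L0_mm]),
        node_sets={
            "annulus": np.empty(0, np.int64),
            "anterior_leaflet": np.empty(0, np.int64),
            "posterior_leaflet": np.empty(0, np.int64),
            "free_edge_anterior": np.empty(0, np.int64),
            "free_edge_posterior": np.empty(0, np.int64),
            "pm_tips": np.array([0]),
            "chordae_internal": np.array([1]),
        },
        node_region=np.array([geo.REGION_PM, geo.REGION_CHORDAE]),
        node_param_s=np.array([0.0, 1.0]),
        node_param_t=np.zeros(2),
        tri_region=np.empty(0, np.int64),
    )
    cfg = sv.SolverConfig(T_end=0.0, mass_scale=1.0, chordae_mass_scale=1.0)
    return sv.build_problem(g, materials, cfg)


class TestLoadCurve:
    def test_linear_interpolation(self):
        c = sv.LoadCurve(((0.0, 0.0), (1.0, 10.0)), interpolation="linear")
        assert c(0.5) == pytest.approx(5.0)

    def test_smoothstep_endpoints_and_midpoint(self):
        c = sv.LoadCurve(((0.0, 0.0), (1.0, 10.0)))
        assert c(0.0) == 0.0 and c(1.0) == 10.0
        assert c(0.5) == pytest.approx(5.0)
        assert c(2.0) == 10.0  # clamped beyond the last knot

    def test_ramp_hold_holds_peak(self):
        c = sv.LoadCurve.ramp_hold(1.0, 7.0, ramp_fraction=0.6)
        assert c(0.6) == pytest.approx(7.0)
        assert c(0.9) == pytest.approx(7.0)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(InvalidParameterError):
            sv.LoadCurve(((0.0, 0.0), (0.0, 1.0)))


class TestLumpedMass:
    def test_single_triangle_closed_form(self, materials):
        # A = 1 mm^2, t = 0.69 mm, rho = 1100 kg/m^3 -> 7.59e-7 kg total
        nodes = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        g = single_triangle_problem(materials, nodes).geometry
        m = sv.lumped_mass(g, materials.props)
        assert m.sum() == pytest.approx(7.59e-7, rel=1e-12)
        np.testing.assert_allclose(m, 7.59e-7 / 3.0, rtol=1e-12)

    def test_total_mass_matches_integral(self, small_valve, materials):
        m = sv.lumped_mass(small_valve, materials.props)
        areas = geo.triangle_areas(small_valve.nodes, small_valve.triangles) * 1e-6
        th = np.where(
            small_valve.tri_region == geo.REGION_ANTERIOR, 0.69e-3, 0.51e-3
        )
        seg = small_valve.nodes[small_valve.truss_segments] * 1e-3
        L = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
        ca = np.array([0.27, 0.29, 0.61])[small_valve.truss_type] * 1e-6
        expect = 1100.0 * ((areas * th).sum() + (ca * L).sum())
        assert m.sum() == pytest.approx(expect, rel=1e-12)

    def test_thickness_linearity(self, materials):
        g = single_triangle_problem(materials).geometry
        m1 = sv.lumped_mass(g, materials.props).sum()
        props2 = mat.TissueProps(thickness_anterior=2 * 0.69)
        m2 = sv.lumped_mass(g, props2).sum()
        assert m2 == pytest.approx(2 * m1, rel=1e-12)


class TestMembraneForces:
    def test_undeformed_zero(self, materials):
        p = single_triangle_problem(materials)
        f = sv.membrane_forces(p.X0, p)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_forces_are_energy_gradient(self, materials, rng):
        p = single_triangle_problem(materials)

        def energy(x):
            cache = {}
            sv.membrane_forces(x, p, cache=cache)
            W = mat.fung_energy(
                mat.PlanarStrain(cache["E11"], cache["E22"], cache["E12"]),
                materials.fung_anterior,
            ) * 1e3  # kPa -> Pa
            return float(np.sum(W * p.tri_area0 * p.tri_thickness))

        for _ in range(10):
            x = p.X0 + 2e-4 * rng.standard_normal(p.X0.shape)
            g = sv.membrane_forces(x, p)
            h = 1e-9
            for i in range(3):
                for d in range(3):
                    xp = x.copy()
                    xp[i, d] += h
                    xm = x.copy()
                    xm[i, d] -= h
                    num = (energy(xp) - energy(xm)) / (2 * h)
                    assert num == pytest.approx(g[i, d], rel=2e-5, abs=1e-10)

    def test_per_element_equilibrium(self, materials, rng):
        p = single_triangle_problem(materials)
        x = p.X0 + 3e-4 * rng.standard_normal(p.X0.shape)
        f = sv.membrane_forces(x, p)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12 * np.abs(f).max())
        torque = np.cross(x, f).sum(axis=0)
        assert np.abs(torque).max() < 1e-10 * max(np.abs(f).max(), 1e-30)

    def test_rotation_equivariance(self, materials, rng):
        from scipy.spatial.transform import Rotation

        p = single_triangle_problem(materials)
        x = p.X0 * np.array([1.15, 1.05, 1.0])  # stretched state
        f = sv.membrane_forces(x, p)
        R = Rotation.random(random_state=7).as_matrix()
        fR = sv.membrane_forces(x @ R.T, p)
        np.testing.assert_allclose(fR, f @ R.T, rtol=1e-9, atol=1e-12)


class TestTrussForces:
    def test_reference_zero(self, materials):
        p = truss_problem(materials)
        np.testing.assert_allclose(sv.truss_forces(p.X0, p), 0.0)

    def test_matches_constitutive_force(self, materials):
        p = truss_problem(materials, L0_mm=10.0)
        x = p.X0.copy()
        x[1, 0] *= 1.25
        f = sv.truss_forces(x, p)
        expect = mat.ogden_axial_force(
            1.25, materials.ogden["anterior_marginal"], 0.29
        )
        assert f[1, 0] == pytest.approx(expect, rel=1e-12)
        np.testing.assert_allclose(f[0], -f[1], rtol=1e-14)

    def test_slack_chord_carries_nothing(self, materials):
        p = truss_problem(materials)
        x = p.X0.copy()
        x[1, 0] *= 0.9
        np.testing.assert_allclose(sv.truss_forces(x, p), 0.0)


class TestPressure:
    def test_zero_pressure(self, materials):
        p = single_triangle_problem(materials)
        np.testing.assert_allclose(sv.pressure_forces(p.X0, p, 0.0), 0.0)

    def test_flat_plate_net_force(self, materials):
        nodes = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
        p = single_triangle_problem(materials, nodes)
        pr = 1000.0
        f = sv.pressure_forces(p.X0, p, pr)
        area = 0.5 * (10e-3) ** 2
        net = f.sum(axis=0)
        assert abs(net[2]) == pytest.approx(pr * area, rel=1e-12)
        assert np.allclose(net[:2], 0.0, atol=1e-15)

    def test_closed_sphere_nets_zero(self, materials):
        trimesh = pytest.importorskip("trimesh")
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        g = geo.MVGeometry(
            nodes=np.asarray(sphere.vertices, float),
            triangles=np.asarray(sphere.faces, np.int64),
            truss_segments=np.empty((0, 2), np.int64),
            truss_type=np.empty(0, np.int64),
            truss_chord_id=np.empty(0, np.int64),
            truss_rest_length=np.empty(0),
            node_sets={
                "annulus": np.empty(0, np.int64),
                "anterior_leaflet": np.arange(len(sphere.vertices)),
                "posterior_leaflet": np.empty(0, np.int64),
                "free_edge_anterior": np.empty(0, np.int64),
                "free_edge_posterior": np.empty(0, np.int64),
                "pm_tips": np.empty(0, np.int64),
                "chordae_internal": np.empty(0, np.int64),
            },
            node_region=np.zeros(len(sphere.vertices), np.int64),
            node_param_s=np.zeros(len(sphere.vertices)),
            node_param_t=np.zeros(len(sphere.vertices)),
            tri_region=np.zeros(len(sphere.faces), np.int64),
        )
        cfg = sv.SolverConfig(T_end=0.0, mass_scale=1.0, chordae_mass_scale=1.0)
        prob = sv.build_problem(g, mat.representative_materials(), cfg)
        pr = 5000.0
        f = sv.pressure_forces(prob.X0, prob, pr)
        area = 4 * np.pi * (8e-3) ** 2
        assert np.linalg.norm(f.sum(axis=0)) < 1e-10 * pr * area


class TestStableDt:
    def test_positive(self, small_valve, materials):
        prob = sv.build_problem(small_valve, materials, sv.SolverConfig())
        assert sv.stable_dt(prob) > 0

    def test_stiffer_material_smaller_dt(self, small_valve):
        base = mat.representative_materials()
        stiff = mat.MaterialSet(
            fung_anterior=mat.FungParams(
                c=4 * base.fung_anterior.c,
                a1=base.fung_anterior.a1,
                a2=base.fung_anterior.a2,
                a3=base.fung_anterior.a3,
                a4=base.fung_anterior.a4,
            ),
            fung_posterior=mat.FungParams(
                c=4 * base.fung_posterior.c,
                a1=base.fung_posterior.a1,
                a2=base.fung_posterior.a2,
                a3=base.fung_posterior.a3,
                a4=base.fung_posterior.a4,
            ),
            ogden={
                k: mat.OgdenParams(order=v.order, mu=tuple(4 * m for m in v.mu), alpha=v.alpha)
                for k, v in base.ogden.items()
            },
        )
        cfg = sv.SolverConfig()
        dt1 = sv.stable_dt(sv.build_problem(small_valve, base, cfg))
        dt4 = sv.stable_dt(sv.build_problem(small_valve, stiff, cfg))
        assert dt4 == pytest.approx(dt1 / 2, rel=1e-6)


class TestStepAndRun:
    def test_free_flight_uniform_motion(self, materials):
        p = truss_problem(materials)
        p.damping_alpha = 0.0
        state = sv.SimState(
            time=0.0,
            positions=p.X0.copy(),
            velocities=np.tile([0.01, 0.0, 0.0], (2, 1)),
        )
        dt = 1e-5
        new = sv.step(state, dt, p)
        np.testing.assert_allclose(
            new.positions, p.X0 + 0.01 * dt * np.array([[1, 0, 0], [1, 0, 0]]), rtol=1e-12
        )

    def test_oscillator_period(self, materials):
        """2-node truss oscillator: measured period vs 2*pi*sqrt(m/k)."""
        p = truss_problem(materials, L0_mm=10.0)
        p.damping_alpha = 0.0
        p.tension_only = False  # linear two-sided spring about lam = 1
        p.boundary = [
            sv.BoundaryMotion(
                node_ids=np.array([0]),
                start=p.X0[:1].copy(),
                target=p.X0[:1].copy(),
                profile=sv.LoadCurve(((0.0, 0.0), (1.0, 0.0))),
            )
        ]
        par = materials.ogden["anterior_marginal"]
        k = 3.0 * sum(par.mu) * 1e3 * (0.29e-6) / 10e-3  # tangent dP/dlam(1)*A/L
        m = p.masses[1]
        T_expect = 2 * np.pi * np.sqrt(m / k)
        dt = sv.stable_dt(p) / 10.0
        amp = 1e-6
        state = sv.SimState(time=0.0, positions=p.X0.copy(), velocities=np.zeros((2, 3)))
        state.positions[1, 0] += amp
        crossings = []
        x_prev = amp
        for i in range(200000):
            state = sv.step(state, dt, p)
            x = state.positions[1, 0] - p.X0[1, 0]
            if x_prev > 0 >= x:
                # linear interpolation of the downward zero crossing
                crossings.append(state.time - dt * x / (x - x_prev + 1e-300))
                if len(crossings) >= 6:
                    break
            x_prev = x
        T_meas = np.mean(np.diff(crossings))
        assert T_meas == pytest.approx(T_expect, rel=0.01)

    def test_damping_dissipates_kinetic_energy(self, materials):
        p = truss_problem(materials)
        p.damping_alpha = 50.0
        v0 = np.tile([0.05, 0.0, 0.0], (2, 1))
        state = sv.SimState(time=0.0, positions=p.X0.copy(), velocities=v0.copy())
        e = [sv.kinetic_energy(state, p)]
        for _ in range(50):
            state = sv.step(state, 1e-5, p)
            e.append(sv.kinetic_energy(state, p))
        assert all(b < a for a, b in zip(e, e[1:]))

    def test_zero_Tend_returns_initial_only(self, small_valve, materials):
        cfg = sv.SolverConfig(T_end=0.0)
        traj = sv.run(small_valve, materials, cfg)
        assert len(traj.states) == 1
        assert traj.final.time == 0.0

    def test_null_load_stays_at_rest(self, small_valve, materials):
        cfg = sv.SolverConfig(
            T_end=0.01,
            pressure_curve=sv.LoadCurve(((0.0, 0.0), (1.0, 0.0))),
            damping_alpha=50.0,
        )
        traj = sv.run(small_valve, materials, cfg)  # no boundary motion, no pressure
        disp = np.abs(traj.final.positions - traj.initial.positions).max()
        assert disp < 1e-6

    def test_boundary_nodes_track_prescribed_motion(self, small_valve, materials):
        cfg = sv.SolverConfig(T_end=0.004, output_stride=100, mass_scale=20.0)
        closure = geo.ClosureSpec(annular_area_contraction=0.1)
        traj = sv.run(small_valve, materials, cfg, closure=closure)
        prob = sv.build_problem(small_valve, materials, cfg, closure=closure)
        for snap in traj.states[1:]:
            for bm in prob.boundary:
                np.testing.assert_allclose(
                    snap.positions[bm.node_ids], bm.positions(snap.time), atol=1e-12
                )
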
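"""Coaptation metrics: contact maps, gap distance, edge lengths, orifice
area, principal stresses, run comparison."""

import json

import numpy as np
import pytest

from mvsim import coaptation as co
from mvsim import contact as ct
from mvsim import geometry as geo
from mvsim import materials as mat
from mvsim import solver as sv
from mvsim.errors import InputError


@pytest.fixture
def valve():
    return geo.build_valve(
        geo.AnnulusProfile(n_samples=32), geo.LeafletSpec(), geo.ChordaeSpec()
    )


def fake_contact_state(n, pressures_ll=None):
    z = np.zeros((n, 3))
    p = np.zeros(n) if pressures_ll is None else np.asarray(pressures_ll, float)
    return ct.ContactState(
        force=z.copy(), force_leaflet=z.copy(), pressure=p.copy(), pressure_leaflet=p
    )


class TestContactMap:
    def test_zero_pressures_empty_map(self, valve):
        cs = fake_contact_state(valve.n_nodes)
        mask, area = co.contact_map(cs, valve, 50e3)
        assert not mask.any() and area == 0.0

    def test_threshold_above_max_empty(self, valve):
        p = np.full(valve.n_nodes, 40e3)
        mask, area = co.contact_map(fake_contact_state(valve.n_nodes, p), valve, 40e3 + 1.0)
        assert not mask.any()

    def test_uniform_patch_area_matches_tributary(self, valve):
        ant = valve.node_sets["anterior_leaflet"]
        patch = ant[:20]
        p = np.zeros(valve.n_nodes)
        p[patch] = 60e3
        trib = geo.tributary_areas(valve.nodes, valve.triangles, valve.n_nodes)
        mask, area = co.contact_map(fake_contact_state(valve.n_nodes, p), valve, 50e3)
        assert set(np.flatnonzero(mask)) == set(patch.tolist())
        assert area == pytest.approx(trib[patch].sum(), rel=1e-12)

    def test_missing_pressure_field_raises(self, valve):
        with pytest.raises(InputError):
            co.contact_map(None, valve, 50e3)

    def test_chordal_pressure_excluded(self, valve):
        cs = fake_contact_state(valve.n_nodes)
        cs.pressure = np.full(valve.n_nodes, 100e3)  # total incl. chordae
        cs.pressure_leaflet[:] = 0.0  # but no leaflet-leaflet component
        mask, area = co.contact_map(cs, valve, 50e3)
        assert not mask.any()


class TestNoncoaptationEdge:
    def test_all_marked_zero_length(self, valve):
        mask = np.zeros(valve.n_nodes, bool)
        mask[valve.node_sets["free_edge_anterior"]] = True
        assert co.noncoaptation_edge_length(mask, valve, valve.nodes) == 0.0

    def test_none_marked_full_length(self, valve):
        edge = valve.node_sets["free_edge_anterior"]
        full = np.sum(
            np.linalg.norm(np.diff(valve.nodes[edge], axis=0), axis=1)
        )
        mask = np.zeros(valve.n_nodes, bool)
        assert co.noncoaptation_edge_length(mask, valve, valve.nodes) == pytest.approx(full)

    def test_alternating_marks_zero(self, valve):
        edge = valve.node_sets["free_edge_anterior"]
        mask = np.zeros(valve.n_nodes, bool)
        mask[edge[::2]] = True  # no segment has both endpoints unmarked
        assert co.noncoaptation_edge_length(mask, valve, valve.nodes) == 0.0


class TestGapDistance:
    def test_parallel_lines_exact(self):
        d = 2.5
        a = np.array([[0.0, 0.0, 0.0]])
        segs = np.array([[[-5.0, d, 0.0], [5.0, d, 0.0]]])
        assert co.point_to_segments_distance(a[0], segs) == pytest.approx(d, abs=1e-12)

    def test_translation_properties(self, valve):
        pos = valve.nodes.copy()
        plane = co.default_cut_plane(valve, pos)
        g0 = co.max_gap_distance(pos, valve, plane)
        post = valve.node_sets["posterior_leaflet"]
        # 1-Lipschitz: a 1 mm rigid shift changes the gap by at most 1 mm
        shifted = pos.copy()
        shifted[post] += [0.0, 0.0, -1.0]
        g1 = co.max_gap_distance(shifted, valve, plane)
        assert abs(g1 - g0) <= 1.0 + 1e-9
        # translating the posterior leaflet along the gap direction (away
        # from the anterior free edge) raises the result by the shift length
        p_a = co._polyline_crossings(pos, valve.node_sets["free_edge_anterior"], *plane)[0]
        post_tris = valve.triangles[valve.tri_region == geo.REGION_POSTERIOR]
        cut = co._plane_cut_segments(pos, post_tris, *plane)
        # nearest posterior cut point to p_a defines the gap direction
        seg_pts = cut.reshape(-1, 3)
        q = seg_pts[np.argmin(np.linalg.norm(seg_pts - p_a, axis=1))]
        u = (q - p_a) / np.linalg.norm(q - p_a)
        away = pos.copy()
        away[post] += 1.0 * u
        g2 = co.max_gap_distance(away, valve, plane)
        assert g2 == pytest.approx(g0 + 1.0, abs=0.3)

    def test_plane_missing_valve_raises(self, valve):
        plane = (np.array([0.0, 0.0, 500.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(InputError):
            co.max_gap_distance(valve.nodes, valve, plane)

    def test_coincident_polylines_zero(self):
        segs = np.array([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]])
        assert co.point_to_segments_distance(np.array([0.5, 0.0, 0.0]), segs) == 0.0


class TestOrificeArea:
    def test_lens_between_two_arcs(self):
        # symmetric lens between two circular arcs of radius R, half-angle a
        R, a = 10.0, 0.8
        t = np.linspace(-a, a, 200)
        upper = np.stack([R * np.sin(t), R * np.cos(t) - R * np.cos(a)], axis=1)
        lower = np.stack([R * np.sin(t), -(R * np.cos(t) - R * np.cos(a))], axis=1)
        area = co.orifice_area_from_chains(upper, lower)
        expect = 2 * (R**2 * (a - np.sin(a) * np.cos(a)) )  # 2 circular segments
        expect = 2 * R**2 * (a - 0.5 * np.sin(2 * a))
        assert area == pytest.approx(expect, rel=0.02)

    def test_scaling_quadratic(self):
        t = np.linspace(0, np.pi, 50)
        a = np.stack([np.cos(t), 0.3 * np.sin(t)], axis=1)
        b = np.stack([np.cos(t), -0.3 * np.sin(t)], axis=1)[::-1]
        s1 = co.orifice_area_from_chains(a, b)
        s2 = co.orifice_area_from_chains(2 * a, 2 * b)
        assert s2 == pytest.approx(4 * s1, rel=1e-9)

    def test_fully_coapted_zero(self, valve):
        mask = np.zeros(valve.n_nodes, bool)
        mask[valve.node_sets["free_edge_anterior"]] = True
        mask[valve.node_sets["free_edge_posterior"]] = True
        assert co.regurgitant_orifice_area(valve.nodes, valve, mask, mask) == 0.0

    def test_degenerate_chain_zero(self):
        assert co.orifice_area_from_chains(np.zeros((1, 2)), np.zeros((1, 2))) == 0.0


class TestPrincipalStress:
    def _stretched_state(self, lam1, lam2, shear=0.0):
        materials = mat.representative_materials()
        nodes = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
        import test_solver

        prob = test_solver.single_triangle_problem(materials, nodes)
        # material frame: e1 along circumferential = z x r from the element
        # centroid; for this flat element in the xy plane find it explicitly
        x = prob.X0.copy()
        F = np.array([[lam1, shear], [0.0, lam2]])
        # apply in the element's material frame
        e1, e2 = sv._material_frames(prob.geometry)
        E = np.stack([e1[0], e2[0]], axis=1)  # 3x2
        for i in range(3):
            local = E.T @ prob.X0[i]
            x[i] = E @ (F @ local) + (prob.X0[i] - E @ local)
        cache = {}
        sv.membrane_forces(x, prob, cache=cache)
        state = sv.SimState(time=0.0, positions=x, velocities=np.zeros_like(x), strain=cache)
        return state, prob, materials

    def test_unstrained_zero(self):
        state, prob, _ = self._stretched_state(1.0, 1.0)
        field, gmax = co.max_principal_stress_field(state, prob)
        np.testing.assert_allclose(field, 0.0, atol=1e-8)

    def test_equibiaxial_closed_form(self):
        lam = 1.12
        state, prob, materials = self._stretched_state(lam, lam)
        _, gmax = co.max_principal_stress_field(state, prob)
        E = 0.5 * (lam**2 - 1.0)
        p = materials.fung_anterior
        S = p.c * 1e3 * np.exp((p.a1 + p.a2 + 2 * p.a3) * E**2) * ((p.a1 + p.a3) * E)
        nu = materials.props.poisson
        lam3 = (lam**2) ** (-nu / (1 - nu))
        sigma = S / lam3  # eig(SC)/(J2*lam3) with S,C isotropic: S*lam^2/(lam^2*lam3)
        assert gmax == pytest.approx(sigma, rel=1e-6)

    def test_uniaxial_principal_direction(self):
        state, prob, _ = self._stretched_state(1.25, 1.0)
        cache = state.strain
        # principal direction of F S F^T should align with the circumferential axis
        p = state.positions[prob.tris][0]
        D = np.stack([p[1] - p[0], p[2] - p[0]], axis=1)
        F = D @ prob.tri_Bm[0]
        S = np.array(
            [
                [cache["S11"][0], 0.5 * cache["S12"][0]],
                [0.5 * cache["S12"][0], cache["S22"][0]],
            ]
        )
        M = F @ S @ F.T
        w, v = np.linalg.eigh(M)
        direction = v[:, np.argmax(w)]
        e1, _ = sv._material_frames(prob.geometry)
        # current circumferential direction = F applied to (1, 0)
        circ = F[:, 0] / np.linalg.norm(F[:, 0])
        angle = np.degrees(np.arccos(np.clip(abs(direction @ circ), 0, 1)))
        assert angle < 1.0


class TestCompareRuns:
    def _report(self, **kw):
        base = dict(
            threshold=50e3,
            contact_map=[1, 2],
            contact_map_posterior=[7],
            max_contact_pressure=60e3,
            max_gap_distance=1.0,
            noncoaptation_edge_length=5.0,
            regurgitant_orifice_area=4.0,
            total_contact_area=100.0,
            total_contact_fraction=0.2,
            max_principal_stress=3e5,
            max_chordal_penetration=0.1,
            penalty_bound=0.2,
            geometry_hash="abc",
        )
        base.update(kw)
        return co.CoaptationReport(**base)

    def test_identical_reports_zero_deltas(self):
        rec = co.compare_runs(self._report(), self._report())
        assert all(v == 0 for v in rec.delta.values())

    def test_mismatched_geometry_rejected(self):
        with pytest.raises(InputError):
            co.compare_runs(self._report(), self._report(geometry_hash="zzz"))

    def test_findings_panel_directions(self):
        full = self._report(
            max_contact_pressure=55e3,
            noncoaptation_edge_length=7.0,
            total_contact_area=90.0,
            max_chordal_penetration=0.05,
            penalty_bound=0.2,
        )
        lo = self._report(
            max_contact_pressure=70e3,
            noncoaptation_edge_length=3.0,
            total_contact_area=120.0,
            max_chordal_penetration=1.5,
        )
        rec = co.compare_runs(full, lo, leaflet_thickness_mm=0.69)
        assert rec.all_findings_hold

    def test_json_round_trip_lossless(self, tmp_path):
        rec = co.compare_runs(self._report(), self._report())
        path = tmp_path / "cmp.json"
        rec.to_json(path)
        back = co.ComparisonRecord.from_dict(json.loads(path.read_text()))
        assert back.to_dict() == rec.to_dict()

    def test_report_json_round_trip(self, tmp_path):
        r = self._report()
        path = tmp_path / "report.json"
        r.to_json(path)
        assert co.CoaptationReport.from_json(path).to_dict() == r.to_dict()


class TestChordalPenetration:
    def test_no_chordae_zero(self):
        g = geo.build_valve(
            geo.AnnulusProfile(n_samples=32),
            geo.LeafletSpec(),
            geo.ChordaeSpec(n_marginal_anterior=0, n_marginal_posterior=0, n_strut=0),
        )
        assert co.chordal_penetration(g.nodes, g) == 0.0

    def test_reference_valve_no_crossing(self, valve):
        # chords hang below the leaflets in the open reference state
        assert co.chordal_penetration(valve.nodes, valve) == 0.0

    def test_constructed_pass_through_detected(self, valve):
        pos = valve.nodes.copy()
        # place two consecutive chordal nodes on opposite sides of an anterior
        # belly triangle: the segment between them pierces its interior
        chored = valve.node_sets["chordae_internal"]
        seg_idx = np.flatnonzero(
            np.isin(valve.truss_segments, chored).all(axis=1)
        )[0]
        n0, n1 = valve.truss_segments[seg_idx]
        tris_a = valve.triangles[valve.tri_region == geo.REGION_ANTERIOR]
        tri = tris_a[len(tris_a) // 2]
        cen = pos[tri].mean(axis=0)
        normal = geo.triangle_normals(pos, tri[None, :])[0]
        pos[n0] = cen - 2.0 * normal
        pos[n1] = cen + 2.0 * normal
        depth = co.chordal_penetration(pos, valve)
        # at least the constructed 2 mm overhang (adjacent displaced segments
        # may cross with an even larger overhang)
        assert depth >= 2.0 - 1e-9
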
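"""Parametric synthetic mitral valve geometry.

Generates normal and pathologic valve models (saddle annulus, anterior and
posterior leaflet membranes meshed with triangles, chordae tendineae as
subdivided truss lines from two papillary-muscle tips) that stand in for
patient-derived echocardiographic reconstructions.  All coordinates are in
millimetres; the annular best-fit plane is z ~ 0 with the left atrium at
z > 0 and the ventricle at z < 0.

The leaflet surfaces are analytic annulus-to-free-edge sweeps on a structured
grid (deterministic triangulation), not spline fits: the downstream solver
only needs the mesh class, not an image-fitting pipeline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidParameterError, MeshError

__all__ = [
    "AnnulusProfile",
    "LeafletSpec",
    "ChordaeSpec",
    "ClosureSpec",
    "MVGeometry",
    "annulus_point",
    "build_annulus",
    "build_valve",
    "make_pathologic_variant",
    "keyframe_boundary_targets",
    "triangle_areas",
    "triangle_normals",
    "boundary_edges",
    "tributary_areas",
    "geometry_hash",
]

TRUSS_TYPE_NAMES = ("posterior_marginal", "anterior_marginal", "strut")

REGION_ANTERIOR = 0
REGION_POSTERIOR = 1
REGION_CHORDAE = 2
REGION_PM = 3


@dataclass(frozen=True)
class AnnulusProfile:
    """Saddle annulus: elliptic in-plane projection, cos(2t) out-of-plane term."""

    ap_diameter: float = 30.0
    cc_diameter: float = 36.0
    saddle_height: float = 4.0
    n_samples: int = 64

    def __post_init__(self) -> None:
        if not (self.ap_diameter > 0 and self.cc_diameter > 0):
            raise InvalidParameterError("annulus diameters must be > 0")
        if self.saddle_height < 0:
            raise InvalidParameterError("saddle_height must be >= 0")
        if self.n_samples < 8:
            raise InvalidParameterError("n_samples must be >= 8")


@dataclass(frozen=True)
class LeafletSpec:
    """Leaflet sweep heights (mm) and shape modifiers.

    ``commissural_overlap`` boosts the posterior height near the commissures
    so the posterior free edge extends beyond the anterior one there; ``billow``
    is an atrial-ward mid-surface bow in mm.
    """

    anterior_height: float = 23.0
    posterior_height: float = 14.0
    commissural_overlap: float = 0.08
    billow: float = 1.5

    def __post_init__(self) -> None:
        if not (self.anterior_height > 0 and self.posterior_height > 0):
            raise InvalidParameterError("leaflet heights must be > 0")
        if self.commissural_overlap < 0:
            raise InvalidParameterError("commissural_overlap must be >= 0")


@dataclass(frozen=True)
class ChordaeSpec:
    """Chordal counts and papillary tip placement.

    ``pm_positions`` may be two explicit 3D points (mm); by default tips are
    placed below and inward of the commissures.  With all counts zero the
    valve has no chordae.
    """

    n_marginal_anterior: int = 12
    n_marginal_posterior: int = 12
    n_strut: int = 2
    pm_positions: tuple[tuple[float, float, float], ...] | None = None
    branching: bool = False

    def __post_init__(self) -> None:
        if min(self.n_marginal_anterior, self.n_marginal_posterior, self.n_strut) < 0:
            raise InvalidParameterError("chordal counts must be >= 0")
        if self.pm_positions is not None and len(self.pm_positions) != 2:
            raise InvalidParameterError("pm_positions must contain exactly two tips")


@dataclass(frozen=True)
class ClosureSpec:
    """End-systolic boundary kinematics: annular area contraction fraction and
    a translation applied to both papillary tips (mm)."""

    annular_area_contraction: float = 0.2
    pm_displacement: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.annular_area_contraction < 1.0):
            raise InvalidParameterError("annular_area_contraction must be in [0, 1)")


@dataclass
class MVGeometry:
    """Triangulated valve with truss chordae and named node sets (mm units).

    ``node_sets`` keys: annulus, anterior_leaflet, posterior_leaflet,
    free_edge_anterior, free_edge_posterior, pm_tips, chordae_internal.
    Free-edge sets are ordered along the edge.  ``truss_rest_length`` holds
    per-segment unloaded lengths (chordae are slack in the open reference
    state and become taut near closure).
    """

    nodes: np.ndarray  # (N, 3) mm
    triangles: np.ndarray  # (T, 3) int
    truss_segments: np.ndarray  # (S, 2) int
    truss_type: np.ndarray  # (S,) int codes into TRUSS_TYPE_NAMES
    truss_chord_id: np.ndarray  # (S,) int physical chord index
    truss_rest_length: np.ndarray  # (S,) mm
    node_sets: dict[str, np.ndarray]
    node_region: np.ndarray  # (N,) int region codes
    node_param_s: np.ndarray  # (N,) annulus->free-edge (or PM->leaflet) fraction
    node_param_t: np.ndarray  # (N,) annular angle parameter
    tri_region: np.ndarray  # (T,) int region codes
    annulus_profile: AnnulusProfile | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def copy(self) -> "MVGeometry":
        return MVGeometry(
            nodes=self.nodes.copy(),
            triangles=self.triangles.copy(),
            truss_segments=self.truss_segments.copy(),
            truss_type=self.truss_type.copy(),
            truss_chord_id=self.truss_chord_id.copy(),
            truss_rest_length=self.truss_rest_length.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            node_region=self.node_region.copy(),
            node_param_s=self.node_param_s.copy(),
            node_param_t=self.node_param_t.copy(),
            tri_region=self.tri_region.copy(),
            annulus_profile=self.annulus_profile,
        )

    def validate(self) -> None:
        """Raise :class:`MeshError` on any violated mesh invariant."""
        n = self.n_nodes
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= n):
            raise MeshError("triangle index out of range")
        if self.truss_segments.size and (
            self.truss_segments.min() < 0 or self.truss_segments.max() >= n
        ):
            raise MeshError("truss index out of range")
        for name, ids in self.node_sets.items():
            if ids.size and (ids.min() < 0 or ids.max() >= n):
                raise MeshError(f"node set {name!r} index out of range")
        if self.triangles.size:
            areas = triangle_areas(self.nodes, self.triangles)
            if np.any(areas <= 1e-12):
                raise MeshError("zero-area triangle present")
            # manifoldness: every edge shared by at most two triangles
            e = np.sort(
                np.concatenate(
                    [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
                ),
                axis=1,
            )
            _, counts = np.unique(e, axis=0, return_counts=True)
            if np.any(counts > 2):
                raise MeshError("non-manifold edge (shared by >2 triangles)")
        if self.truss_segments.size:
            seg = self.nodes[self.truss_segments]
            lengths = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
            if np.any(lengths <= 1e-12):
                raise MeshError("zero-length truss segment present")
        if self.annulus_profile is not None and "annulus" in self.node_sets:
            ids = self.node_sets["annulus"]
            ref = annulus_point(self.annulus_profile, self.node_param_t[ids])
            if ids.size and np.max(np.linalg.norm(self.nodes[ids] - ref, axis=1)) > 1e-6:
                raise MeshError("annulus nodes do not lie on the annulus curve")


# ---------------------------------------------------------------------------
# Annulus
# ---------------------------------------------------------------------------


def annulus_point(profile: AnnulusProfile, t) -> np.ndarray:
    """Point(s) on the saddle annulus at angle parameter ``t``.

    x along the commissure-commissure axis, y along the anteroposterior axis
    (anterior at y > 0, t = pi/2), z = -(saddle/2) cos(2t): anterior and
    posterior annulus high (atrial), commissures low.
    """
    t = np.asarray(t, float)
    x = 0.5 * profile.cc_diameter * np.cos(t)
    y = 0.5 * profile.ap_diameter * np.sin(t)
    z = -0.5 * profile.saddle_height * np.cos(2.0 * t)
    return np.stack([x, y, z], axis=-1)


def build_annulus(profile: AnnulusProfile) -> np.ndarray:
    """Sampled closed saddle curve, shape (n_samples + 1, 3); last point equals the first."""
    t = np.linspace(0.0, 2.0 * np.pi, profile.n_samples + 1)
    pts = annulus_point(profile, t)
    pts[-1] = pts[0]
    return pts


def _arc_length_params(profile: AnnulusProfile, t0: float, t1: float, n: int) -> np.ndarray:
    """n parameter values in [t0, t1] equally spaced in annular arc length."""
    tf = np.linspace(t0, t1, 2048)
    pts = annulus_point(profile, tf)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return np.interp(np.linspace(0.0, s[-1], n), s, tf)


def _arc_length(profile: AnnulusProfile, t0: float, t1: float) -> float:
    tf = np.linspace(t0, t1, 2048)
    pts = annulus_point(profile, tf)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# Valve construction
# ---------------------------------------------------------------------------


def _leaflet_grid(
    profile: AnnulusProfile,
    t_cols: np.ndarray,
    heights: np.ndarray,
    funnel_angle_rad: float,
    billow: float,
    n_rows: int,
):
    """Structured (n_rows, n_cols, 3) surface swept from annulus to free edge."""
    a = annulus_point(profile, t_cols)  # (C, 3)
    r_in = -a.copy()
    r_in[:, 2] = 0.0
    r_in /= np.linalg.norm(r_in, axis=1, keepdims=True)
    sweep = np.sin(funnel_angle_rad) * r_in + np.cos(funnel_angle_rad) * np.array([0.0, 0.0, -1.0])
    s = np.linspace(0.0, 1.0, n_rows)[:, None, None]
    pts = a[None] + s * heights[None, :, None] * sweep[None]
    pts[..., 2] += billow * np.sin(np.pi * s[..., 0]) * (heights[None, :] / max(heights.max(), 1e-9))
    return pts


def _grid_triangles(n_rows: int, n_cols: int, offset: int) -> np.ndarray:
    tris = []
    for i in range(n_rows - 1):
        for j in range(n_cols - 1):
            v00 = offset + i * n_cols + j
            v01 = v00 + 1
            v10 = v00 + n_cols
            v11 = v10 + 1
            if (i + j) % 2 == 0:
                tris.append((v00, v01, v11))
                tris.append((v00, v11, v10))
            else:
                tris.append((v00, v01, v10))
                tris.append((v01, v11, v10))
    return np.asarray(tris, dtype=np.int64)


def _orient_triangles(nodes: np.ndarray, tris: np.ndarray, funnel_angle_rad: float) -> np.ndarray:
    """Flip winding so normals point to the atrial (funnel-interior) side."""
    p = nodes[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    cen = p.mean(axis=1)
    r_out = cen.copy()
    r_out[:, 2] = 0.0
    nr = np.linalg.norm(r_out, axis=1, keepdims=True)
    r_out = np.divide(r_out, nr, out=np.zeros_like(r_out), where=nr > 1e-12)
    probe = -np.cos(funnel_angle_rad) * r_out
    probe[:, 2] += np.sin(funnel_angle_rad)
    flip = np.einsum("ij,ij->i", n, probe) < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def build_valve(
    annulus: AnnulusProfile,
    leaflet_spec: LeafletSpec,
    chordae_spec: ChordaeSpec,
    target_edge_length: float = 2.5,
    seed: int = 0,
    *,
    anterior_half_arc_deg: float = 75.0,
    commissure_gap_deg: float = 2.5,
    funnel_angle_anterior_deg: float = 28.0,
    funnel_angle_posterior_deg: float = 42.0,
    chord_segment_length: float = 3.0,
    coapt_depth_frac: float = 0.45,
    coapt_inplane_frac: float = 0.30,
    rest_scale: float = 1.0,
) -> MVGeometry:
    """Mesh a complete valve: two leaflet membranes plus subdivided chordae.

    ``target_edge_length`` (mm) controls grid resolution.  Chordal unloaded
    lengths are sized from an estimated coapted end-systolic position of their
    insertions (scaled by ``rest_scale``): chords are slack in the open
    reference state and become taut as the leaflets close, which is the
    physiologic condition.  Generation is a pure deterministic function of the
    arguments; ``seed`` is accepted for interface symmetry with stochastic
    generators.
    """
    if target_edge_length <= 0:
        raise InvalidParameterError("target_edge_length must be > 0")
    del seed  # structured deterministic meshing; kept for interface stability

    phi = np.deg2rad(anterior_half_arc_deg)
    gap = np.deg2rad(commissure_gap_deg)  # keeps the leaflets initially separated
    th_a = np.deg2rad(funnel_angle_anterior_deg)
    th_p = np.deg2rad(funnel_angle_posterior_deg)
    t_c1 = np.pi / 2 - phi  # anterolateral commissure
    t_c2 = np.pi / 2 + phi  # posteromedial commissure

    H_a, H_p = leaflet_spec.anterior_height, leaflet_spec.posterior_height
    end_frac_a = 0.40
    end_frac_p = (1.0 + leaflet_spec.commissural_overlap) * end_frac_a * H_a / H_p
    if end_frac_p > 1.0:
        raise InvalidParameterError(
            "infeasible leaflet spec: posterior leaflet too short to cover the "
            "commissures (posterior_height too small relative to anterior_height)"
        )

    def h_ant(u):
        return H_a * (end_frac_a + (1.0 - end_frac_a) * np.sin(np.pi * u))

    def h_post(u):
        return H_p * (end_frac_p + (1.0 - end_frac_p) * np.sin(np.pi * u))

    if h_post(0.0) + 1e-9 < h_ant(0.0):
        raise InvalidParameterError("posterior commissural height below anterior")

    # column counts from annular arc length, row counts from mean height
    arc_a = _arc_length(annulus, t_c1 + gap, t_c2 - gap)
    arc_p = _arc_length(annulus, t_c2 + gap, t_c1 + 2 * np.pi - gap)
    nca = max(6, int(round(arc_a / target_edge_length)) + 1)
    ncp = max(8, int(round(arc_p / target_edge_length)) + 1)
    nra = max(4, int(round(0.8 * H_a / target_edge_length)) + 1)
    nrp = max(4, int(round(0.8 * H_p / target_edge_length)) + 1)

    t_a = _arc_length_params(annulus, t_c1 + gap, t_c2 - gap, nca)
    t_p = _arc_length_params(annulus, t_c2 + gap, t_c1 + 2 * np.pi - gap, ncp)
    u_a = (t_a - t_c1 - gap) / (2 * phi - 2 * gap)
    u_p = (t_p - t_c2 - gap) / (2 * np.pi - 2 * phi - 2 * gap)

    grid_a = _leaflet_grid(annulus, t_a, h_ant(u_a), th_a, leaflet_spec.billow, nra)
    grid_p = _leaflet_grid(annulus, t_p, h_post(u_p), th_p, leaflet_spec.billow, nrp)

    nodes = [grid_a.reshape(-1, 3), grid_p.reshape(-1, 3)]
    n_a = nra * nca
    n_p = nrp * ncp
    off_p = n_a

    tris_a = _orient_triangles(np.vstack(nodes), _grid_triangles(nra, nca, 0), th_a)
    tris_p = _orient_triangles(np.vstack(nodes), _grid_triangles(nrp, ncp, off_p), th_p)

    s_a = np.repeat(np.linspace(0, 1, nra), nca)
    s_p = np.repeat(np.linspace(0, 1, nrp), ncp)
    t_all = [np.tile(t_a, nra), np.tile(t_p, nrp)]
    s_all = [s_a, s_p]
    region = [np.full(n_a, REGION_ANTERIOR), np.full(n_p, REGION_POSTERIOR)]

    ids_a = np.arange(n_a)
    ids_p = off_p + np.arange(n_p)
    free_a = ids_a[-nca:]  # ordered last row
    free_p = ids_p[-ncp:]
    annulus_ids = np.concatenate([ids_a[:nca], ids_p[:ncp]])

    # ---------------- papillary tips ----------------
    if chordae_spec.pm_positions is not None:
        pm = np.asarray(chordae_spec.pm_positions, float)
    else:
        # tips below and inward of the commissures, offset toward the
        # posterior ventricular wall where the papillary muscles arise; the
        # posterior offset routes anterior marginal chords beneath the
        # posterior leaflet's distal strip, as in the closing valve
        pm = []
        for t_c in (t_c1, t_c2):
            a_c = annulus_point(annulus, t_c)
            tip = np.array(
                [
                    0.60 * a_c[0],
                    0.60 * a_c[1] - 0.15 * annulus.ap_diameter,
                    a_c[2] - (0.9 * H_a + 4.0),
                ]
            )
            pm.append(tip)
        pm = np.asarray(pm)

    # ---------------- chordae ----------------
    xyz = np.vstack(nodes)

    def closed_estimate(node_id: int, height: float) -> np.ndarray:
        """Estimated end-systolic position of a leaflet insertion node."""
        t_n = np.concatenate(t_all)[node_id]
        a_n = annulus_point(annulus, t_n)
        est = a_n.copy()
        est[:2] *= coapt_inplane_frac
        est[2] = a_n[2] - coapt_depth_frac * height
        return est

    chord_rows = []  # (leaflet_node, pm_index, type_code, height)
    if chordae_spec.n_marginal_anterior > 0:
        uu = (np.arange(chordae_spec.n_marginal_anterior) + 0.5) / chordae_spec.n_marginal_anterior
        cols = np.unique(np.clip(np.round(uu * (nca - 1)).astype(int), 0, nca - 1))
        for j in cols:
            nid = int(free_a[j])
            pm_i = int(np.argmin(np.linalg.norm(pm - xyz[nid], axis=1)))
            chord_rows.append((nid, pm_i, 1, float(h_ant(u_a[j]))))
    if chordae_spec.n_marginal_posterior > 0:
        uu = (np.arange(chordae_spec.n_marginal_posterior) + 0.5) / chordae_spec.n_marginal_posterior
        cols = np.unique(np.clip(np.round(uu * (ncp - 1)).astype(int), 0, ncp - 1))
        for j in cols:
            nid = int(free_p[j])
            pm_i = int(np.argmin(np.linalg.norm(pm - xyz[nid], axis=1)))
            chord_rows.append((nid, pm_i, 0, float(h_post(u_p[j]))))
    if chordae_spec.n_strut > 0:
        row = int(round(0.65 * (nra - 1)))
        uu = (np.arange(chordae_spec.n_strut) + 0.5) / chordae_spec.n_strut
        cols = np.unique(np.clip(np.round(uu * (nca - 1)).astype(int), 0, nca - 1))
        for j in cols:
            nid = int(ids_a[row * nca + j])
            pm_i = int(np.argmin(np.linalg.norm(pm - xyz[nid], axis=1)))
            chord_rows.append((nid, pm_i, 2, float(0.65 * h_ant(u_a[j]))))

    chord_nodes = []
    chord_s = []
    chord_t = []
    segs = []
    seg_type = []
    seg_chord = []
    seg_rest = []
    pm_ids = np.array([n_a + n_p, n_a + n_p + 1], dtype=np.int64)
    next_id = n_a + n_p + 2

    for cid, (nid, pm_i, tcode, height) in enumerate(chord_rows):
        attach = xyz[nid]
        tip = pm[pm_i]
        L_geom = float(np.linalg.norm(attach - tip))
        est = closed_estimate(nid, height)
        L_rest = rest_scale * float(np.linalg.norm(est - tip))
        n_seg = max(3, int(round(L_geom / chord_segment_length)))
        # internal nodes on the straight reference line
        fr = np.linspace(0.0, 1.0, n_seg + 1)[1:-1]
        ids_int = np.arange(next_id, next_id + len(fr))
        next_id += len(fr)
        chord_nodes.append(tip[None] * (1 - fr[:, None]) + attach[None] * fr[:, None])
        chord_s.append(fr)
        chord_t.append(np.full(len(fr), np.concatenate(t_all)[nid]))
        path = np.concatenate([[pm_ids[pm_i]], ids_int, [nid]])
        for k in range(len(path) - 1):
            segs.append((path[k], path[k + 1]))
            seg_type.append(tcode)
            seg_chord.append(cid)
            seg_rest.append(L_rest / n_seg)

    all_nodes = [xyz, pm]
    s_all.append(np.zeros(2))
    t_all.append(np.array([t_c1, t_c2]))
    region.append(np.full(2, REGION_PM))
    chordae_internal = np.arange(n_a + n_p + 2, next_id)
    if chord_nodes:
        all_nodes.append(np.vstack(chord_nodes))
        s_all.append(np.concatenate(chord_s))
        t_all.append(np.concatenate(chord_t))
        region.append(np.full(len(chordae_internal), REGION_CHORDAE))

    geom = MVGeometry(
        nodes=np.ascontiguousarray(np.vstack(all_nodes)),
        triangles=np.vstack([tris_a, tris_p]),
        truss_segments=np.asarray(segs, dtype=np.int64).reshape(-1, 2),
        truss_type=np.asarray(seg_type, dtype=np.int64),
        truss_chord_id=np.asarray(seg_chord, dtype=np.int64),
        truss_rest_length=np.asarray(seg_rest, float),
        node_sets={
            "annulus": annulus_ids,
            "anterior_leaflet": ids_a,
            "posterior_leaflet": ids_p,
            "free_edge_anterior": free_a,
            "free_edge_posterior": free_p,
            "pm_tips": pm_ids,
            "chordae_internal": chordae_internal,
        },
        node_region=np.concatenate(region),
        node_param_s=np.concatenate(s_all),
        node_param_t=np.concatenate(t_all),
        tri_region=np.concatenate(
            [np.full(len(tris_a), REGION_ANTERIOR), np.full(len(tris_p), REGION_POSTERIOR)]
        ),
        annulus_profile=annulus,
    )
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# Pathologic variant and boundary keyframes
# ---------------------------------------------------------------------------


def make_pathologic_variant(
    geom: MVGeometry,
    annular_dilation: float,
    pm_displacement=(0.0, 0.0, 0.0),
) -> MVGeometry:
    """Dilate the annulus in-plane and translate the papillary tips.

    Leaflet nodes follow the annular dilation with a weight (1 - s)^2 that
    decays from the annulus to the free edge, so the free edges (and chordal
    unloaded lengths) are unchanged: a dilated annulus with normal-size
    leaflets, the substrate of functional regurgitation.
    """
    if annular_dilation < 1.0:
        raise InvalidParameterError("annular dilation factor must be >= 1")
    pm_displacement = np.asarray(pm_displacement, float)
    out = geom.copy()
    if annular_dilation == 1.0 and not np.any(pm_displacement):
        return out

    ann = geom.node_sets["annulus"]
    centroid_xy = geom.nodes[ann][:, :2].mean(axis=0)

    leaflet = np.isin(geom.node_region, (REGION_ANTERIOR, REGION_POSTERIOR))
    w = (1.0 - geom.node_param_s[leaflet]) ** 2
    out.nodes[leaflet, :2] += (
        (annular_dilation - 1.0) * w[:, None] * (geom.nodes[leaflet, :2] - centroid_xy)
    )

    pm = geom.node_sets["pm_tips"]
    out.nodes[pm] += pm_displacement
    chords = geom.node_region == REGION_CHORDAE
    out.nodes[chords] += (1.0 - geom.node_param_s[chords])[:, None] * pm_displacement

    out.annulus_profile = None  # annulus no longer on the analytic curve
    out.validate()
    return out


def keyframe_boundary_targets(geom: MVGeometry, closure: ClosureSpec):
    """End-systolic target positions for the prescribed boundary node sets.

    Annular nodes contract in-plane about the annular centroid by
    sqrt(1 - annular_area_contraction) (projected area scales by the stated
    fraction); papillary tips translate rigidly.  Returns a dict
    ``{set_name: (node_ids, targets)}``.
    """
    for required in ("annulus", "pm_tips"):
        if required not in geom.node_sets:
            raise ConfigurationError(f"geometry lacks required node set {required!r}")
    ann = geom.node_sets["annulus"]
    pm = geom.node_sets["pm_tips"]
    centroid_xy = geom.nodes[ann][:, :2].mean(axis=0)
    scale = float(np.sqrt(1.0 - closure.annular_area_contraction))
    targets_ann = geom.nodes[ann].copy()
    targets_ann[:, :2] = centroid_xy + scale * (targets_ann[:, :2] - centroid_xy)
    targets_pm = geom.nodes[pm] + np.asarray(closure.pm_displacement, float)
    return {"annulus": (ann.copy(), targets_ann), "pm_tips": (pm.copy(), targets_pm)}


# ---------------------------------------------------------------------------
# Mesh utilities
# ---------------------------------------------------------------------------


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def triangle_normals(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def boundary_edges(tris: np.ndarray) -> np.ndarray:
    """Edges belonging to exactly one triangle, as sorted index pairs."""
    if not len(tris):
        return np.empty((0, 2), dtype=np.int64)
    e = np.sort(
        np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq[counts == 1]


def tributary_areas(nodes: np.ndarray, tris: np.ndarray, n_nodes: int) -> np.ndarray:
    """Per-node tributary area: one third of each incident triangle."""
    areas = triangle_areas(nodes, tris)
    trib = np.zeros(n_nodes)
    for k in range(3):
        np.add.at(trib, tris[:, k], areas / 3.0)
    return trib


def geometry_hash(geom: MVGeometry) -> str:
    """SHA-256 over the geometry's defining arrays (platform-stable for
    identical inputs)."""
    h = hashlib.sha256()
    for arr in (
        geom.nodes,
        geom.triangles,
        geom.truss_segments,
        geom.truss_type,
        geom.truss_rest_length,
        geom.node_region,
        geom.node_param_s,
        geom.node_param_t,
        geom.tri_region,
    ):
        h.update(np.ascontiguousarray(arr).tobytes())
        h.update(b"|")
    for name in sorted(geom.node_sets):
        h.update(name.encode())
        h.update(np.ascontiguousarray(geom.node_sets[name]).tobytes())
    return h.hexdigest()
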
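"""Coaptation quantitation at peak systole.

Post-processes a closed-valve snapshot into the standard leaflet-apposition
metrics: a thresholded leaflet-to-leaflet contact-pressure map (default
threshold 50 kPa), maximum gap distance on a commissural cut plane, length of
free (marginal) edge with no coaptation, geometric regurgitant orifice area
by annular-plane projection of the non-coapted edges, total contact area, and
the maximum in-plane principal Cauchy stress.  Lengths/areas are reported in
mm / mm^2, pressures and stresses in Pa.

All operators are pure functions of the snapshot: re-running them on a saved
state reproduces the report bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
import shapely.ops
from shapely.geometry import Polygon

from . import contact as ct
from . import geometry as geo
from . import solver as sv
from .errors import InputError

__all__ = [
    "CoaptationReport",
    "ComparisonRecord",
    "contact_map",
    "max_gap_distance",
    "noncoaptation_edge_length",
    "regurgitant_orifice_area",
    "max_principal_stress_field",
    "chordal_penetration",
    "build_report",
    "compare_runs",
    "default_cut_plane",
]

DEFAULT_THRESHOLD_PA = 50e3


@dataclass
class CoaptationReport:
    """Scalar coaptation metrics plus the anterior-leaflet contact map."""

    threshold: float = DEFAULT_THRESHOLD_PA  # Pa
    contact_map: list[int] = field(default_factory=list)  # coapted anterior node ids
    contact_map_posterior: list[int] = field(default_factory=list)
    max_contact_pressure: float = 0.0  # Pa, leaflet-leaflet
    max_gap_distance: float = 0.0  # mm
    noncoaptation_edge_length: float = 0.0  # mm, anterior free edge
    regurgitant_orifice_area: float = 0.0  # mm^2
    total_contact_area: float = 0.0  # mm^2
    total_contact_fraction: float = 0.0  # of anterior leaflet area
    max_principal_stress: float = 0.0  # Pa
    max_chordal_penetration: float = 0.0  # mm beyond the leaflet mid-surface
    penalty_bound: float = 0.0  # mm, 2*max_fn/kn penalty-consistency scale
    geometry_hash: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CoaptationReport":
        return cls(**d)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "CoaptationReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Contact map and edge metrics
# ---------------------------------------------------------------------------


def contact_map(
    cstate: ct.ContactState,
    geom: geo.MVGeometry,
    threshold: float = DEFAULT_THRESHOLD_PA,
    *,
    tributary_mm2: np.ndarray | None = None,
    positions_mm: np.ndarray | None = None,
    leaflet: str = "anterior_leaflet",
):
    """Thresholded coaptation map on one leaflet.

    A node is coapted iff its leaflet-to-leaflet contact pressure (chordal
    contributions excluded) reaches ``threshold``.  Returns ``(mask, area)``
    with mask boolean over all nodes (True only on the chosen leaflet) and
    the total tributary contact area in mm^2.
    """
    if cstate is None or cstate.pressure_leaflet is None:
        raise InputError("contact pressure field missing from the state")
    field = (
        cstate.interface_pressure_leaflet
        if cstate.interface_pressure_leaflet is not None
        else cstate.pressure_leaflet
    )
    ids = geom.node_sets[leaflet]
    mask = np.zeros(geom.n_nodes, bool)
    mask[ids] = field[ids] >= threshold
    if tributary_mm2 is None:
        pos = geom.nodes if positions_mm is None else positions_mm
        tributary_mm2 = geo.tributary_areas(pos, geom.triangles, geom.n_nodes)
    area = float(tributary_mm2[mask].sum())
    return mask, area


def noncoaptation_edge_length(
    mask: np.ndarray,
    geom: geo.MVGeometry,
    positions_mm: np.ndarray,
    leaflet: str = "anterior_leaflet",
) -> float:
    """Summed length (mm) of free-edge segments whose both endpoints are
    not coapted.  The free-edge node set is ordered along the edge."""
    edge = geom.node_sets[
        "free_edge_anterior" if leaflet == "anterior_leaflet" else "free_edge_posterior"
    ]
    a, b = edge[:-1], edge[1:]
    seg_len = np.linalg.norm(positions_mm[b] - positions_mm[a], axis=1)
    open_seg = (~mask[a]) & (~mask[b])
    return float(seg_len[open_seg].sum())


# ---------------------------------------------------------------------------
# Gap distance on a cut plane
# ---------------------------------------------------------------------------


def default_cut_plane(geom: geo.MVGeometry, positions_mm: np.ndarray):
    """Vertical plane through the annular centroid and the anterolateral
    commissure (the first anterior free-edge column)."""
    ann = geom.node_sets["annulus"]
    centroid = positions_mm[ann].mean(axis=0)
    edge = geom.node_sets["free_edge_anterior"]
    # a station ~15% along the free edge from the anterolateral commissure:
    # "near" the commissure but inside the leaflet, away from the cleft
    comm = positions_mm[edge[max(1, int(round(0.15 * (len(edge) - 1))))]]
    d = comm - centroid
    d[2] = 0.0
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise InputError("degenerate commissure direction for the cut plane")
    d /= nd
    normal = np.cross(np.array([0.0, 0.0, 1.0]), d)
    return centroid, normal


def _plane_cut_segments(positions, tris, point, normal):
    """Intersect a triangle mesh with a plane; returns (k, 2, 3) segments."""
    s = (positions - point) @ normal
    sv_ = s[tris]
    pos = sv_ > 0
    crossing = ~(pos.all(axis=1) | (~pos).all(axis=1))
    segs = []
    for tri, sd in zip(tris[crossing], sv_[crossing]):
        pts = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            if (sd[i] > 0) != (sd[j] > 0):
                w = sd[i] / (sd[i] - sd[j])
                pts.append(positions[tri[i]] + w * (positions[tri[j]] - positions[tri[i]]))
        if len(pts) >= 2:
            segs.append((pts[0], pts[1]))
    return np.asarray(segs).reshape(-1, 2, 3)


def _polyline_crossings(positions, ordered_ids, point, normal):
    """Points where an ordered polyline crosses the plane."""
    s = (positions[ordered_ids] - point) @ normal
    out = []
    for k in range(len(ordered_ids) - 1):
        if (s[k] > 0) != (s[k + 1] > 0):
            w = s[k] / (s[k] - s[k + 1])
            out.append(
                positions[ordered_ids[k]]
                + w * (positions[ordered_ids[k + 1]] - positions[ordered_ids[k]])
            )
    return np.asarray(out).reshape(-1, 3)


def point_to_segments_distance(p: np.ndarray, segs: np.ndarray) -> float:
    """Minimum distance from a point to a set of 3D segments."""
    if not len(segs):
        raise InputError("empty segment set")
    a, b = segs[:, 0], segs[:, 1]
    d = b - a
    L2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / np.maximum(L2, 1e-30), 0.0, 1.0)
    proj = a + t[:, None] * d
    return float(np.linalg.norm(proj - p, axis=1).min())


def max_gap_distance(
    positions_mm: np.ndarray,
    geom: geo.MVGeometry,
    cut_plane=None,
) -> float:
    """Maximum gap (mm) between the leaflets on a cut plane.

    The anterior free edge's crossing points of the plane are measured against
    the posterior surface's cut polyline; the largest of the minimum distances
    is the gap (0 when the edges touch)."""
    if cut_plane is None:
        cut_plane = default_cut_plane(geom, positions_mm)
    point, normal = cut_plane
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    ant_pts = _polyline_crossings(
        positions_mm, geom.node_sets["free_edge_anterior"], point, normal
    )
    post_tris = geom.triangles[geom.tri_region == geo.REGION_POSTERIOR]
    post_cut = _plane_cut_segments(positions_mm, post_tris, point, normal)
    if not len(ant_pts) or not len(post_cut):
        raise InputError("cut plane misses the anterior free edge or posterior leaflet")
    return float(max(point_to_segments_distance(p, post_cut) for p in ant_pts))


# ---------------------------------------------------------------------------
# Regurgitant orifice area
# ---------------------------------------------------------------------------


def _open_chains(mask: np.ndarray, ordered_ids: np.ndarray):
    """Maximal runs of consecutive free-edge nodes that are all un-coapted."""
    open_nodes = ~mask[ordered_ids]
    chains, cur = [], []
    for nid, is_open in zip(ordered_ids, open_nodes):
        if is_open:
            cur.append(int(nid))
        else:
            if len(cur) >= 2:
                chains.append(cur)
            cur = []
    if len(cur) >= 2:
        chains.append(cur)
    return chains


def orifice_area_from_chains(chain_a_xy: np.ndarray, chain_b_xy: np.ndarray) -> float:
    """Planar area (same units^2) enclosed between two open curves.

    Where the projected curves cross each other, the orifice is the union of
    the faces bounded between consecutive crossings (two nearly coincident
    curves therefore enclose almost nothing).  If the curves never cross, the
    polygon is closed by joining their endpoints.  Self-intersections are
    repaired by summing simple parts; degenerate inputs (< 3 distinct points)
    give 0."""
    if len(chain_a_xy) < 2 or len(chain_b_xy) < 2:
        return 0.0
    la = shapely.LineString(np.asarray(chain_a_xy, float))
    lb = shapely.LineString(np.asarray(chain_b_xy, float))
    if la.length == 0 or lb.length == 0:
        return 0.0
    if la.crosses(lb) or la.touches(lb):
        faces = list(shapely.ops.polygonize(shapely.unary_union([la, lb])))
        if faces:
            return float(sum(f.area for f in faces))
    pts = np.vstack([chain_a_xy, np.asarray(chain_b_xy)[::-1]])
    if len(pts) < 3:
        return 0.0
    poly = Polygon(pts)
    if poly.is_empty:
        return 0.0
    fixed = poly.buffer(0)
    if fixed.is_empty or fixed.area == 0.0:
        faces = list(shapely.ops.polygonize(shapely.unary_union([shapely.LineString(np.vstack([pts, pts[:1]]))])))
        return float(sum(p.area for p in faces))
    return float(fixed.area)


def regurgitant_orifice_area(
    positions_mm: np.ndarray,
    geom: geo.MVGeometry,
    mask_anterior: np.ndarray,
    mask_posterior: np.ndarray,
) -> float:
    """Geometric orifice area (mm^2): project the non-coapted free-edge chains
    of both leaflets onto the annular plane and measure the enclosed polygon.
    A fully coapted valve gives 0."""
    chains_a = _open_chains(mask_anterior, geom.node_sets["free_edge_anterior"])
    chains_p = _open_chains(mask_posterior, geom.node_sets["free_edge_posterior"])
    if not chains_a or not chains_p:
        return 0.0
    # largest chain of each leaflet, projected in-plane (annular plane ~ z=0)
    chain_a = max(chains_a, key=len)
    chain_p = max(chains_p, key=len)
    return orifice_area_from_chains(
        positions_mm[chain_a][:, :2], positions_mm[chain_p][:, :2]
    )


# ---------------------------------------------------------------------------
# Stress and chordal penetration
# ---------------------------------------------------------------------------


def max_principal_stress_field(state: sv.SimState, problem: sv.SimProblem):
    """Per-element in-plane maximum principal Cauchy stress (Pa) and its
    global maximum over the leaflets.

    The PK2 stress is pushed forward through the in-plane deformation
    gradient; the through-thickness stretch follows the near-incompressibility
    rule lam3 = (lam1*lam2)^(-nu/(1-nu))."""
    if state.strain is None:
        raise InputError("strain cache missing; recompute forces on the state first")
    c = state.strain
    S11, S22 = c["S11"], c["S22"]
    S12 = 0.5 * c["S12"]  # tensor component (law's S12 is conjugate to the stored shear)
    C11, C22, C12 = c["C11"], c["C22"], c["C12"]
    detC = np.maximum(C11 * C22 - C12**2, 1e-30)
    J2 = np.sqrt(detC)
    nu = problem.materials.props.poisson
    lam3 = J2 ** (-nu / (1.0 - nu))
    # nonzero eigenvalues of F S F^T equal those of (S C); scale to Cauchy
    M11 = S11 * C11 + S12 * C12
    M12 = S11 * C12 + S12 * C22
    M21 = S12 * C11 + S22 * C12
    M22 = S12 * C12 + S22 * C22
    tr = M11 + M22
    det = M11 * M22 - M12 * M21
    disc = np.sqrt(np.maximum(tr**2 - 4.0 * det, 0.0))
    sig_max = 0.5 * (tr + disc) / (J2 * lam3)
    return sig_max, float(sig_max.max()) if len(sig_max) else 0.0


def chordal_penetration(positions_mm: np.ndarray, geom: geo.MVGeometry) -> float:
    """Worst chordal pass-through depth beyond a leaflet mid-surface, in mm.

    Every chordal truss segment is intersected with the leaflet triangles
    (attachment triangles sharing a node with the segment are skipped).  For
    each genuine crossing the depth is how far the segment's end extends past
    the surface on the atrial side — chordae belong on the ventricular side,
    so depths of the order of the leaflet thickness or more mean the chord
    passed through the leaflet.  Insertion segments (those ending on a
    leaflet node) are skipped: at coaptation an insertion lies inside the
    opposing leaflet's contact slab and its terminal segment grazes that
    mid-surface by construction.  Returns 0 when no interior segment crosses
    a leaflet.
    """
    if not len(geom.truss_segments) or not len(geom.triangles):
        return 0.0
    from scipy.spatial import cKDTree

    tris = geom.triangles
    p = positions_mm[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-30)
    cen = p.mean(axis=1)
    rad = np.linalg.norm(p - cen[:, None], axis=2).max()

    seg = positions_mm[geom.truss_segments]
    a, b = seg[:, 0], seg[:, 1]
    mids = 0.5 * (a + b)
    half = 0.5 * np.linalg.norm(b - a, axis=1)
    leaflet_node = np.isin(
        geom.node_region, (geo.REGION_ANTERIOR, geo.REGION_POSTERIOR)
    )
    interior_seg = ~leaflet_node[geom.truss_segments].any(axis=1)
    # ordered node chains per chord (by arc fraction) for depth walking
    chains: dict[int, np.ndarray] = {}
    for cid in np.unique(geom.truss_chord_id):
        nodes = np.unique(geom.truss_segments[geom.truss_chord_id == cid].ravel())
        chains[int(cid)] = nodes[np.argsort(geom.node_param_s[nodes])]
    tree = cKDTree(cen)
    lists = tree.query_ball_point(mids, r=half.max() + rad + 1e-9)
    worst = 0.0
    for si, cand in enumerate(lists):
        if not cand or not interior_seg[si]:
            continue
        cand = np.asarray(cand)
        # skip triangles touching the segment's own nodes (chord insertions)
        own = (tris[cand][:, :, None] == geom.truss_segments[si][None, None, :]).any(axis=(1, 2))
        cand = cand[~own]
        if not len(cand):
            continue
        d0 = np.einsum("kj,kj->k", a[si] - p[cand, 0], n[cand])
        d1 = np.einsum("kj,kj->k", b[si] - p[cand, 0], n[cand])
        crossing = (d0 > 0) != (d1 > 0)
        if not crossing.any():
            continue
        cand, d0, d1 = cand[crossing], d0[crossing], d1[crossing]
        w = d0 / (d0 - d1)
        hit = a[si] + w[:, None] * (b[si] - a[si])
        e0 = p[cand, 1] - p[cand, 0]
        e1 = p[cand, 2] - p[cand, 0]
        wv = hit - p[cand, 0]
        d00 = np.einsum("kj,kj->k", e0, e0)
        d01 = np.einsum("kj,kj->k", e0, e1)
        d11 = np.einsum("kj,kj->k", e1, e1)
        dw0 = np.einsum("kj,kj->k", wv, e0)
        dw1 = np.einsum("kj,kj->k", wv, e1)
        det = np.maximum(d00 * d11 - d01 * d01, 1e-30)
        wb = (d11 * dw0 - d01 * dw1) / det
        wc = (d00 * dw1 - d01 * dw0) / det
        inside = (wb >= -1e-9) & (wc >= -1e-9) & (wb + wc <= 1 + 1e-9)
        if not inside.any():
            continue
        # atrial-side overhang: follow the chord past the crossing while it
        # stays on the atrial side of the crossed triangle's plane (normals
        # face atrial), so a chord passing far through reports its full reach
        chain = chains[int(geom.truss_chord_id[si])]
        n0, n1 = geom.truss_segments[si]
        for tloc, dd0, dd1 in zip(cand[inside], d0[inside], d1[inside]):
            depth = max(dd0, dd1)
            far = n1 if dd1 > dd0 else n0
            near = n0 if far == n1 else n1
            k = int(np.flatnonzero(chain == far)[0])
            if k > 0 and chain[k - 1] == near:
                step_dir = 1
            elif k + 1 < len(chain) and chain[k + 1] == near:
                step_dir = -1
            else:
                step_dir = 0
            j = k + step_dir
            while step_dir and 0 <= j < len(chain):
                dj = float(np.dot(positions_mm[chain[j]] - p[tloc, 0], n[tloc]))
                if dj <= 0:
                    break
                depth = max(depth, dj)
                j += step_dir
            worst = max(worst, float(depth))
    return worst


# ---------------------------------------------------------------------------
# Report assembly and two-arm comparison
# ---------------------------------------------------------------------------


def build_report(
    state: sv.SimState,
    problem: sv.SimProblem,
    threshold: float = DEFAULT_THRESHOLD_PA,
    cut_plane=None,
) -> CoaptationReport:
    """Evaluate the full metric panel on a peak-systole snapshot."""
    geom = problem.geometry
    pos_mm = state.positions * 1e3
    trib_mm2 = (
        problem.scene.tributary_area * 1e6
        if problem.scene is not None
        else geo.tributary_areas(pos_mm, geom.triangles, geom.n_nodes)
    )
    mask_a, area_a = contact_map(
        state.contact, geom, threshold, tributary_mm2=trib_mm2, leaflet="anterior_leaflet"
    )
    mask_p, _ = contact_map(
        state.contact, geom, threshold, tributary_mm2=trib_mm2, leaflet="posterior_leaflet"
    )
    ant_ids = geom.node_sets["anterior_leaflet"]
    ant_area = float(trib_mm2[ant_ids].sum())
    _, sig_max = max_principal_stress_field(state, problem)
    kn = problem.contact_params.kn if problem.contact_params else np.inf
    max_fn = state.contact.max_fn if state.contact else 0.0
    report = CoaptationReport(
        threshold=threshold,
        contact_map=[int(i) for i in np.flatnonzero(mask_a)],
        contact_map_posterior=[int(i) for i in np.flatnonzero(mask_p)],
        max_contact_pressure=float(
            (
                state.contact.interface_pressure_leaflet
                if state.contact.interface_pressure_leaflet is not None
                else state.contact.pressure_leaflet
            ).max()
        )
        if state.contact
        else 0.0,
        max_gap_distance=max_gap_distance(pos_mm, geom, cut_plane),
        noncoaptation_edge_length=noncoaptation_edge_length(mask_a, geom, pos_mm),
        regurgitant_orifice_area=regurgitant_orifice_area(pos_mm, geom, mask_a, mask_p),
        total_contact_area=area_a,
        total_contact_fraction=area_a / ant_area if ant_area > 0 else 0.0,
        max_principal_stress=sig_max,
        max_chordal_penetration=chordal_penetration(pos_mm, geom),
        penalty_bound=float(2.0 * max_fn / kn * 1e3) if np.isfinite(kn) else 0.0,
        geometry_hash=geo.geometry_hash(geom),
    )
    return report


@dataclass
class ComparisonRecord:
    """Field-by-field deltas/ratios (full minus/over leaflets-only) plus the
    directional-findings panel of the leaflet-to-chordae contact experiment."""

    delta: dict
    ratio: dict
    findings: dict

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonRecord":
        return cls(**d)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @property
    def all_findings_hold(self) -> bool:
        return all(self.findings.values())


_NUMERIC_FIELDS = (
    "max_contact_pressure",
    "max_gap_distance",
    "noncoaptation_edge_length",
    "regurgitant_orifice_area",
    "total_contact_area",
    "total_contact_fraction",
    "max_principal_stress",
    "max_chordal_penetration",
)


def compare_runs(
    report_full: CoaptationReport,
    report_leaflets_only: CoaptationReport,
    leaflet_thickness_mm: float = 0.69,
) -> ComparisonRecord:
    """Compare the two contact-domain arms run on the same geometry.

    The findings panel asserts the directional effects of including
    leaflet-to-chordae contact: chordal pass-through only without it, lower
    peak leaflet contact pressure, longer non-coapted edge, and smaller total
    contact area with it."""
    if (
        report_full.geometry_hash
        and report_leaflets_only.geometry_hash
        and report_full.geometry_hash != report_leaflets_only.geometry_hash
    ):
        raise InputError("reports come from different geometries")
    delta, ratio = {}, {}
    for f in _NUMERIC_FIELDS:
        a = getattr(report_full, f)
        b = getattr(report_leaflets_only, f)
        delta[f] = a - b
        ratio[f] = a / b if b not in (0, 0.0) else float("inf") if a else 1.0
    findings = {
        "pass_through_without_chordae_contact": bool(
            report_leaflets_only.max_chordal_penetration > leaflet_thickness_mm
        ),
        "penetration_bounded_with_full_contact": bool(
            report_full.max_chordal_penetration
            <= max(report_full.penalty_bound, 0.5 * leaflet_thickness_mm)
        ),
        "lower_contact_pressure_with_full_contact": bool(
            report_full.max_contact_pressure < report_leaflets_only.max_contact_pressure
        ),
        "longer_noncoaptation_edge_with_full_contact": bool(
            report_full.noncoaptation_edge_length
            > report_leaflets_only.noncoaptation_edge_length
        ),
        "smaller_contact_area_with_full_contact": bool(
            report_full.total_contact_area < report_leaflets_only.total_contact_area
        ),
    }
    return ComparisonRecord(delta=delta, ratio=ratio, findings=findings)
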
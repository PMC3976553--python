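"""Penalty-method contact between leaflets and chordae.

The engine detects node-to-triangle penetrations and edge-to-edge proximities
(shell perimeter edges and chordal truss edges), applies a linear penalty
normal force fn = kn * gn, a kinetic friction force |ft| = mu_d * fn opposing
the slip increment, and assembles equal-and-opposite nodal forces so the net
contact force is zero.

The *contact domain* selects which body pairs may interact: ``full`` includes
every pair among {anterior_leaflet, posterior_leaflet, chordae} (including
chordae-chordae), ``leaflets_only`` restricts detection to the
anterior-posterior leaflet pair — the two arms of the simulated experiment.

Detection is double-sided (a membrane has two contact faces): a slave node
within the clearance of either side of a master triangle is active and is
pushed back out on the side it currently occupies.  Geometry here is
unit-agnostic; the solver feeds SI coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InvalidParameterError
from . import geometry as geo

__all__ = [
    "BODIES",
    "PenaltyParams",
    "ContactDomain",
    "ContactPair",
    "ContactScene",
    "ContactSet",
    "ContactState",
    "ContactEngine",
    "configure_domain",
    "detect",
    "penalty_normal_force",
    "friction_force",
    "assemble",
    "auto_penalty_stiffness",
]

BODIES = ("anterior_leaflet", "posterior_leaflet", "chordae")
_BARY_TOL = 1e-12


@dataclass(frozen=True)
class PenaltyParams:
    """Penalty stiffnesses (N/m), kinetic friction coefficient, and detection
    clearance (same length unit as the coordinates; ``None`` uses the scene's
    per-element half-thickness sums)."""

    kn: float
    kt: float | None = None
    mu_d: float = 0.05
    clearance: float | None = None
    eps_slip: float = 1e-6  # slip regularization scale used by the solver

    def __post_init__(self) -> None:
        if not self.kn > 0:
            raise InvalidParameterError("kn must be > 0")
        kt = self.kn if self.kt is None else self.kt
        if kt < 0:
            raise InvalidParameterError("kt must be >= 0")
        if not (0.0 <= self.mu_d < 1.0):
            raise InvalidParameterError("mu_d must be in [0, 1)")
        if self.clearance is not None and self.clearance < 0:
            raise InvalidParameterError("clearance must be >= 0")


@dataclass(frozen=True)
class ContactDomain:
    mode: Literal["full", "leaflets_only"]
    included_pairs: frozenset

    def includes(self, body_a: str, body_b: str) -> bool:
        return tuple(sorted((body_a, body_b))) in self.included_pairs


def configure_domain(
    mode: Literal["full", "leaflets_only"], bodies: Sequence[str] = BODIES
) -> ContactDomain:
    """Build the contact domain for one experiment arm."""
    for b in bodies:
        if b not in BODIES:
            raise ConfigurationError(f"unknown body label {b!r}; expected one of {BODIES}")
    if mode == "leaflets_only":
        pairs = set()
        if "anterior_leaflet" in bodies and "posterior_leaflet" in bodies:
            pairs.add(("anterior_leaflet", "posterior_leaflet"))
        return ContactDomain(mode=mode, included_pairs=frozenset(pairs))
    if mode == "full":
        pairs = {
            tuple(sorted((a, b)))
            for i, a in enumerate(bodies)
            for b in bodies[i:]
        }
        return ContactDomain(mode=mode, included_pairs=frozenset(pairs))
    raise ConfigurationError(f"unknown contact mode {mode!r}")


@dataclass(frozen=True)
class ContactPair:
    """One active contact: penetration gn >= 0, slip increment gt, unit normal
    (push-out direction on the slave), and the force magnitudes assigned at
    assembly time."""

    kind: Literal["node_triangle", "edge_edge"]
    slave: tuple
    master: tuple
    gn: float
    gt: float
    normal: np.ndarray
    fn: float = 0.0
    ft: float = 0.0


@dataclass
class ContactScene:
    """Static contact topology: body membership of nodes, triangles and edges,
    per-entity contact half-thicknesses, and tributary areas for pressure."""

    node_body: np.ndarray  # (N,) int index into `bodies`, -1 = not in contact
    triangles: np.ndarray  # (T, 3)
    tri_body: np.ndarray  # (T,)
    edges: np.ndarray  # (E, 2)
    edge_body: np.ndarray  # (E,)
    edge_group: np.ndarray  # (E,) same-group edges never contact (e.g. one chord)
    node_half: np.ndarray  # (N,)
    tri_half: np.ndarray  # (T,)
    edge_half: np.ndarray  # (E,)
    tributary_area: np.ndarray  # (N,)
    bodies: tuple[str, ...] = BODIES
    # sorted int64 keys i*N+j of topologically-near node pairs; same-body
    # candidates touching these pairs are skipped (a smooth surface is always
    # within clearance of its own neighboring elements)
    ring_keys: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_body)

    def build_ring_exclusions(self, rings: int = 3) -> None:
        """Precompute node pairs within ``rings`` mesh edges of each other."""
        from scipy import sparse

        n = self.n_nodes
        rows, cols = [], []
        for conn in (self.triangles, self.edges):
            for k in range(conn.shape[1]):
                for l in range(conn.shape[1]):
                    if k != l:
                        rows.append(conn[:, k])
                        cols.append(conn[:, l])
        if not rows:
            self.ring_keys = np.empty(0, np.int64)
            return
        A = sparse.csr_matrix(
            (np.ones(sum(len(r) for r in rows), bool), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        reach = A + sparse.eye(n, dtype=bool, format="csr")
        total = reach.copy()
        for _ in range(rings - 1):
            reach = (reach @ A).astype(bool)
            total = (total + reach).astype(bool)
        coo = total.tocoo()
        self.ring_keys = np.sort(coo.row.astype(np.int64) * n + coo.col.astype(np.int64))

    @classmethod
    def from_geometry(cls, geom: geo.MVGeometry, props, scale: float = 1e-3) -> "ContactScene":
        """Build the SI contact scene of a valve: leaflet triangles + boundary
        edges, chordal truss edges, half-thicknesses from the tissue
        properties (leaflets: t/2; chordae: fiber radius)."""
        nodes = geom.nodes * scale
        n = len(nodes)
        node_body = np.full(n, -1, dtype=np.int64)
        node_body[geom.node_sets["anterior_leaflet"]] = 0
        node_body[geom.node_sets["posterior_leaflet"]] = 1
        node_body[geom.node_sets["pm_tips"]] = 2
        node_body[geom.node_sets["chordae_internal"]] = 2

        tri_body = np.where(geom.tri_region == geo.REGION_ANTERIOR, 0, 1)
        half_t = np.array([props.thickness_anterior, props.thickness_posterior]) * scale / 2.0
        tri_half = half_t[tri_body]
        node_half = np.zeros(n)
        node_half[node_body == 0] = half_t[0]
        node_half[node_body == 1] = half_t[1]
        chord_radius = np.sqrt(
            np.array(
                [props.area_posterior_marginal, props.area_anterior_marginal, props.area_strut]
            )
            / np.pi
        ) * scale
        node_half[node_body == 2] = float(chord_radius.max())

        # edges: per-leaflet boundary edges + truss segments
        edge_list, edge_body, edge_group = [], [], []
        for body, reg in ((0, geo.REGION_ANTERIOR), (1, geo.REGION_POSTERIOR)):
            be = geo.boundary_edges(geom.triangles[geom.tri_region == reg])
            edge_list.append(be)
            edge_body.append(np.full(len(be), body))
            edge_group.append(np.full(len(be), -1))
        edge_list.append(geom.truss_segments)
        edge_body.append(np.full(len(geom.truss_segments), 2))
        edge_group.append(geom.truss_chord_id)
        edges = np.vstack([e.reshape(-1, 2) for e in edge_list]).astype(np.int64)
        edge_body = np.concatenate(edge_body).astype(np.int64)
        edge_group = np.concatenate(edge_group).astype(np.int64)
        edge_half = np.where(
            edge_body < 2, half_t[np.clip(edge_body, 0, 1)], float(chord_radius.max())
        )

        trib = geo.tributary_areas(nodes, geom.triangles, n)
        # chordal nodes: tributary length * diameter as an effective strip area
        if len(geom.truss_segments):
            seg = nodes[geom.truss_segments]
            L = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
            dia = 2.0 * float(chord_radius.max())
            for k in range(2):
                np.add.at(trib, geom.truss_segments[:, k], 0.5 * L * dia)
        scene = cls(
            node_body=node_body,
            triangles=geom.triangles,
            tri_body=tri_body.astype(np.int64),
            edges=edges,
            edge_body=edge_body,
            edge_group=edge_group,
            node_half=node_half,
            tri_half=tri_half,
            edge_half=edge_half,
            tributary_area=trib,
        )
        scene.build_ring_exclusions()
        return scene


@dataclass
class ContactSet:
    """Vectorized active-pair arrays produced by :func:`detect`."""

    # node-triangle arrays
    nt_node: np.ndarray
    nt_tri: np.ndarray
    nt_gn: np.ndarray
    nt_normal: np.ndarray  # (k,3) push-out direction on the slave node
    nt_bary: np.ndarray  # (k,3)
    nt_gt_vec: np.ndarray  # (k,3) tangential slip increment
    nt_weight: np.ndarray  # 0.5 per pass (two-pass symmetric treatment)
    # edge-edge arrays
    ee_i: np.ndarray
    ee_j: np.ndarray
    ee_gn: np.ndarray
    ee_normal: np.ndarray  # pushes edge i
    ee_params: np.ndarray  # (k,2) closest-point parameters (s on i, t on j)
    ee_gt_vec: np.ndarray
    scene: ContactScene | None = None

    @property
    def n_active(self) -> int:
        return len(self.nt_node) + len(self.ee_i)

    def pairs(self, params: PenaltyParams | None = None) -> list[ContactPair]:
        """Materialize ContactPair records (forces filled if params given)."""
        out = []
        for k in range(len(self.nt_node)):
            gt = float(np.linalg.norm(self.nt_gt_vec[k]))
            fn = params.kn * self.nt_gn[k] if params else 0.0
            ft = params.mu_d * fn if (params and gt > 0) else 0.0
            out.append(
                ContactPair(
                    kind="node_triangle",
                    slave=(int(self.nt_node[k]),),
                    master=tuple(int(v) for v in self.scene.triangles[self.nt_tri[k]]),
                    gn=float(self.nt_gn[k]),
                    gt=gt,
                    normal=self.nt_normal[k].copy(),
                    fn=float(fn),
                    ft=float(ft),
                )
            )
        for k in range(len(self.ee_i)):
            gt = float(np.linalg.norm(self.ee_gt_vec[k]))
            fn = params.kn * self.ee_gn[k] if params else 0.0
            ft = params.mu_d * fn if (params and gt > 0) else 0.0
            out.append(
                ContactPair(
                    kind="edge_edge",
                    slave=tuple(int(v) for v in self.scene.edges[self.ee_i[k]]),
                    master=tuple(int(v) for v in self.scene.edges[self.ee_j[k]]),
                    gn=float(self.ee_gn[k]),
                    gt=gt,
                    normal=self.ee_normal[k].copy(),
                    fn=float(fn),
                    ft=float(ft),
                )
            )
        return out


@dataclass
class ContactState:
    """Assembled per-node contact forces and pressures for one configuration."""

    force: np.ndarray  # (N,3) total contact force
    force_leaflet: np.ndarray  # (N,3) leaflet-leaflet pairs only
    pressure: np.ndarray  # (N,) |force| / tributary area
    pressure_leaflet: np.ndarray  # (N,) leaflet-leaflet pressure
    # interface pressure: fn over the slave patch area, painted onto BOTH
    # sides of each leaflet-leaflet contact (the contact-pressure field of a
    # coaptation map is a property of the interface, not of one body)
    interface_pressure_leaflet: np.ndarray | None = None
    pairs: list = field(default_factory=list)
    max_fn: float = 0.0


def penalty_normal_force(gn, kn: float):
    """Linear penalty law fn = kn * gn (gn >= 0)."""
    gn = np.asarray(gn, float)
    if np.any(gn < 0):
        raise InvalidParameterError("gn must be >= 0 for an active pair")
    fn = kn * gn
    return fn if fn.ndim else float(fn)


def friction_force(gn, gt, kn: float, mu_d: float):
    """Kinetic friction ft = -sgn(gt) * mu_d * kn * gn (signed, opposes slip)."""
    gn = np.asarray(gn, float)
    if np.any(gn < 0):
        raise InvalidParameterError("gn must be >= 0 for an active pair")
    ft = -np.sign(gt) * mu_d * kn * gn
    return ft if ft.ndim else float(ft)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _apply_override(cl, keys, override):
    """Shrink clearances for pairs carrying an initial-overclosure adjustment."""
    if override is None or not len(override[0]):
        return cl
    okeys, ovals = override
    pos = np.searchsorted(okeys, keys)
    pos = np.clip(pos, 0, len(okeys) - 1)
    hit = okeys[pos] == keys
    cl = cl.copy()
    cl[hit] = np.minimum(cl[hit], ovals[pos[hit]])
    return cl


def _clearance_nt(scene: ContactScene, params: PenaltyParams, nodes_idx, tris_idx,
                  override=None):
    if params.clearance is not None:
        cl = np.full(len(nodes_idx), params.clearance)
    else:
        cl = scene.node_half[nodes_idx] + scene.tri_half[tris_idx]
    keys = nodes_idx * np.int64(max(len(scene.triangles), 1)) + tris_idx
    return _apply_override(cl, keys, override)


def _clearance_ee(scene: ContactScene, params: PenaltyParams, ei, ej, override=None):
    if params.clearance is not None:
        cl = np.full(len(ei), params.clearance)
    else:
        cl = scene.edge_half[ei] + scene.edge_half[ej]
    keys = ei * np.int64(max(len(scene.edges), 1)) + ej
    return _apply_override(cl, keys, override)


def _node_triangle_candidates(positions, scene, domain, params, max_move=0.0):
    """Broad phase: KD-tree on triangle centroids; returns (node_idx, tri_idx)."""
    if not len(scene.triangles):
        return np.empty(0, np.int64), np.empty(0, np.int64)
    tri_pts = positions[scene.triangles]
    centroids = tri_pts.mean(axis=1)
    circum = np.linalg.norm(tri_pts - centroids[:, None, :], axis=2).max(axis=1)
    cl_max = (
        params.clearance
        if params.clearance is not None
        else float(scene.node_half.max() + scene.tri_half.max())
    )
    radius = float(circum.max()) + cl_max + max_move
    active_nodes = np.flatnonzero(scene.node_body >= 0)
    if not len(active_nodes):
        return np.empty(0, np.int64), np.empty(0, np.int64)
    tree = cKDTree(centroids)
    lists = tree.query_ball_point(positions[active_nodes], r=radius)
    ni, ti = [], []
    for node, cand in zip(active_nodes, lists):
        if cand:
            ni.extend([node] * len(cand))
            ti.extend(cand)
    ni = np.asarray(ni, np.int64)
    ti = np.asarray(ti, np.int64)
    if not len(ni):
        return ni, ti
    keep = _pair_included(scene.node_body[ni], scene.tri_body[ti], domain)
    # never contact a triangle the node belongs to
    own = (scene.triangles[ti] == ni[:, None]).any(axis=1)
    keep &= ~own
    # same-body pairs: skip topologically-near neighbors
    if scene.ring_keys is not None and len(scene.ring_keys):
        same = scene.node_body[ni] == scene.tri_body[ti]
        if same.any():
            n = scene.n_nodes
            near = np.zeros(len(ni), bool)
            for k in range(3):
                near |= np.isin(ni * n + scene.triangles[ti][:, k], scene.ring_keys)
            keep &= ~(same & near)
    return ni[keep], ti[keep]


def _pair_included(body_a, body_b, domain: ContactDomain):
    keep = np.zeros(len(body_a), bool)
    for pair in domain.included_pairs:
        ia, ib = BODIES.index(pair[0]), BODIES.index(pair[1])
        keep |= (body_a == ia) & (body_b == ib)
        keep |= (body_a == ib) & (body_b == ia)
    return keep


def _edge_candidates(positions, scene, domain, params, max_move=0.0):
    if not len(scene.edges):
        return np.empty(0, np.int64), np.empty(0, np.int64)
    seg = positions[scene.edges]
    mids = seg.mean(axis=1)
    half_len = 0.5 * np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
    cl_max = (
        params.clearance if params.clearance is not None else 2.0 * float(scene.edge_half.max())
    )
    radius = 2.0 * float(half_len.max()) + cl_max + max_move
    tree = cKDTree(mids)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if not len(pairs):
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ei, ej = pairs[:, 0], pairs[:, 1]
    keep = _pair_included(scene.edge_body[ei], scene.edge_body[ej], domain)
    same_group = (
        (scene.edge_group[ei] >= 0)
        & (scene.edge_group[ei] == scene.edge_group[ej])
    )
    keep &= ~same_group
    shared = (
        (scene.edges[ei][:, :, None] == scene.edges[ej][:, None, :]).any(axis=(1, 2))
    )
    keep &= ~shared
    if scene.ring_keys is not None and len(scene.ring_keys):
        same = scene.edge_body[ei] == scene.edge_body[ej]
        if same.any():
            n = scene.n_nodes
            near = np.zeros(len(ei), bool)
            for k in range(2):
                for l in range(2):
                    near |= np.isin(
                        scene.edges[ei][:, k] * n + scene.edges[ej][:, l], scene.ring_keys
                    )
            keep &= ~(same & near)
    return ei[keep], ej[keep]


def _segment_segment(p1, q1, p2, q2):
    """Vectorized closest points of segment pairs (Ericson).  Returns s, t, c1, c2."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    s = np.where(denom > 1e-30, np.clip((b * f - c * e) / np.where(denom > 1e-30, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > 1e-30, (b * s + f) / np.where(e > 1e-30, e, 1.0), 0.0)
    low = t < 0
    high = t > 1
    t = np.clip(t, 0, 1)
    s = np.where(low, np.clip(-c / np.where(a > 1e-30, a, 1.0), 0, 1), s)
    s = np.where(high, np.clip((b - c) / np.where(a > 1e-30, a, 1.0), 0, 1), s)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    return s, t, c1, c2


def _narrow_node_triangle(positions, scene, params, ni, ti, prev_positions, tie_break=True,
                          override=None):
    empty = (
        np.empty(0, np.int64),
        np.empty(0, np.int64),
        np.empty(0),
        np.empty((0, 3)),
        np.empty((0, 3)),
        np.empty((0, 3)),
    )
    if not len(ni):
        return empty
    p = positions[ni]
    tri = scene.triangles[ti]
    v0, v1, v2 = positions[tri[:, 0]], positions[tri[:, 1]], positions[tri[:, 2]]
    n = np.cross(v1 - v0, v2 - v0)
    nn = np.linalg.norm(n, axis=1)
    ok = nn > 1e-30  # degenerate master triangles are skipped
    n = n[ok] / nn[ok, None]
    p, tri, ti_k, ni_k = p[ok], tri[ok], ti[ok], ni[ok]
    v0, v1, v2 = v0[ok], v1[ok], v2[ok]
    d = np.einsum("ij,ij->i", p - v0, n)
    cl = _clearance_nt(scene, params, ni_k, ti_k, override)
    # side continuity: a node that crossed the mid-plane since the last step
    # keeps being pushed back toward the side it came from (penetration may
    # then exceed the clearance) instead of being ejected through the shell
    if prev_positions is not None:
        d_prev = np.einsum("ij,ij->i", prev_positions[ni_k] - v0, n)
        side = np.where(np.abs(d_prev) > 1e-15, np.sign(d_prev), np.sign(d))
    else:
        side = np.sign(d)
    side = np.where(side == 0, 1.0, side)
    within = side * d < cl
    if not within.any():
        return empty
    p, tri, ti_k, ni_k = p[within], tri[within], ti_k[within], ni_k[within]
    v0, v1, v2 = v0[within], v1[within], v2[within]
    n, d, cl, side = n[within], d[within], cl[within], side[within]
    # barycentric coordinates of the in-plane projection
    q = p - d[:, None] * n
    e0, e1 = v1 - v0, v2 - v0
    w = q - v0
    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    dw0 = np.einsum("ij,ij->i", w, e0)
    dw1 = np.einsum("ij,ij->i", w, e1)
    det = d00 * d11 - d01 * d01
    wb = (d11 * dw0 - d01 * dw1) / det
    wc = (d00 * dw1 - d01 * dw0) / det
    wa = 1.0 - wb - wc
    inside = (wa >= -_BARY_TOL) & (wb >= -_BARY_TOL) & (wc >= -_BARY_TOL)
    if not inside.any():
        return empty
    sel = inside
    ni_k, ti_k, tri = ni_k[sel], ti_k[sel], tri[sel]
    n, d, cl, side = n[sel], d[sel], cl[sel], side[sel]
    bary = np.stack([wa[sel], wb[sel], wc[sel]], axis=1)
    gn = cl - side * d
    normal = side[:, None] * n  # push-out direction on the slave

    if tie_break:
        # keep the deepest pair per (slave node, master body)
        key = ni_k * 8 + scene.tri_body[ti_k]
        order = np.lexsort((-gn, key))
        key_sorted = key[order]
        first = np.ones(len(order), bool)
        first[1:] = key_sorted[1:] != key_sorted[:-1]
        sel2 = order[first]
        ni_k, ti_k, gn, normal, bary = ni_k[sel2], ti_k[sel2], gn[sel2], normal[sel2], bary[sel2]
        tri = tri[sel2]

    if prev_positions is not None:
        rel = (positions[ni_k] - prev_positions[ni_k]) - np.einsum(
            "kj,kjd->kd", bary, positions[tri] - prev_positions[tri]
        )
        gt_vec = rel - np.einsum("kd,kd->k", rel, normal)[:, None] * normal
    else:
        gt_vec = np.zeros((len(ni_k), 3))
    return ni_k, ti_k, gn, normal, bary, gt_vec


def _narrow_edge_edge(positions, scene, params, ei, ej, prev_positions, override=None):
    empty = (
        np.empty(0, np.int64),
        np.empty(0, np.int64),
        np.empty(0),
        np.empty((0, 3)),
        np.empty((0, 2)),
        np.empty((0, 3)),
    )
    if not len(ei):
        return empty
    a = scene.edges[ei]
    b = scene.edges[ej]
    s, t, c1, c2 = _segment_segment(
        positions[a[:, 0]], positions[a[:, 1]], positions[b[:, 0]], positions[b[:, 1]]
    )
    diff = c1 - c2
    dist = np.linalg.norm(diff, axis=1)
    cl = _clearance_ee(scene, params, ei, ej, override)
    crossed = np.zeros(len(ei), bool)
    if prev_positions is not None:
        ap = scene.edges[ei]
        bp = scene.edges[ej]
        c1p = (1 - s)[:, None] * prev_positions[ap[:, 0]] + s[:, None] * prev_positions[ap[:, 1]]
        c2p = (1 - t)[:, None] * prev_positions[bp[:, 0]] + t[:, None] * prev_positions[bp[:, 1]]
        crossed = np.einsum("kd,kd->k", diff, c1p - c2p) < 0
    active = ((dist < cl) | crossed) & (dist > 1e-30)
    if not active.any():
        return empty
    ei, ej, s, t = ei[active], ej[active], s[active], t[active]
    dist, diff, crossed = dist[active], diff[active], crossed[active]
    # edges that crossed since the last step are pushed back through
    gn = np.where(crossed, cl[active] + dist, cl[active] - dist)
    normal = np.where(crossed[:, None], -diff, diff) / dist[:, None]
    if prev_positions is not None:
        a, b = scene.edges[ei], scene.edges[ej]
        disp = positions - prev_positions
        rel = (1 - s)[:, None] * disp[a[:, 0]] + s[:, None] * disp[a[:, 1]]
        rel -= (1 - t)[:, None] * disp[b[:, 0]] + t[:, None] * disp[b[:, 1]]
        gt_vec = rel - np.einsum("kd,kd->k", rel, normal)[:, None] * normal
    else:
        gt_vec = np.zeros((len(ei), 3))
    return ei, ej, gn, normal, np.stack([s, t], axis=1), gt_vec


def detect(
    positions: np.ndarray,
    scene: ContactScene,
    domain: ContactDomain,
    params: PenaltyParams,
    prev_positions: np.ndarray | None = None,
    candidates=None,
    tie_break: bool = True,
    overrides=None,
) -> ContactSet:
    """Find all active contact pairs for the included body pairs.

    ``overrides`` optionally carries per-pair adjusted clearances (sorted-key,
    value array pairs) for initial-overclosure treatment."""
    if candidates is None:
        ni, ti = _node_triangle_candidates(positions, scene, domain, params)
        ei, ej = _edge_candidates(positions, scene, domain, params)
    else:
        (ni, ti), (ei, ej) = candidates
    ov_nt, ov_ee = overrides if overrides is not None else (None, None)
    nt = _narrow_node_triangle(positions, scene, params, ni, ti, prev_positions, tie_break,
                               override=ov_nt)
    ee = _narrow_edge_edge(positions, scene, params, ei, ej, prev_positions, override=ov_ee)
    return ContactSet(
        nt_node=nt[0],
        nt_tri=nt[1],
        nt_gn=nt[2],
        nt_normal=nt[3],
        nt_bary=nt[4],
        nt_gt_vec=nt[5],
        nt_weight=np.full(len(nt[0]), 0.5),
        ee_i=ee[0],
        ee_j=ee[1],
        ee_gn=ee[2],
        ee_normal=ee[3],
        ee_params=ee[4],
        ee_gt_vec=ee[5],
        scene=scene,
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble(
    contacts: ContactSet,
    params: PenaltyParams,
    positions: np.ndarray,
    *,
    collect_pairs: bool = False,
) -> tuple[np.ndarray, ContactState]:
    """Turn active pairs into per-node forces; returns (forces, ContactState).

    Normal forces follow fn = kn * gn; tangential forces use the regularized
    kinetic law -mu_d * fn * tanh(|gt|/eps) * t_hat (exact sign law recovered
    as eps -> 0).  Slave and master sides receive equal and opposite loads
    (barycentric / segment-parameter weights), so the global sum is zero.
    """
    scene = contacts.scene
    n = scene.n_nodes
    force = np.zeros((n, 3))
    force_ll = np.zeros((n, 3))
    iface = np.zeros(n)
    max_fn = 0.0

    if len(contacts.nt_node):
        fn = params.kn * contacts.nt_gn
        max_fn = max(max_fn, float(fn.max()))
        fvec = fn[:, None] * contacts.nt_normal
        gt_mag = np.linalg.norm(contacts.nt_gt_vec, axis=1)
        sliding = gt_mag > 0
        if sliding.any():
            that = np.zeros_like(contacts.nt_gt_vec)
            that[sliding] = contacts.nt_gt_vec[sliding] / gt_mag[sliding, None]
            fvec -= (params.mu_d * fn * np.tanh(gt_mag / params.eps_slip))[:, None] * that
        fvec *= contacts.nt_weight[:, None]
        tri = scene.triangles[contacts.nt_tri]
        is_ll = (scene.node_body[contacts.nt_node] < 2) & (scene.tri_body[contacts.nt_tri] < 2)
        if is_ll.any():
            trib = np.maximum(scene.tributary_area, 1e-30)
            p_pair = fn[is_ll] / trib[contacts.nt_node[is_ll]]
            np.maximum.at(iface, contacts.nt_node[is_ll], p_pair)
            for k in range(3):
                np.maximum.at(iface, tri[is_ll, k], p_pair)
        for dest, mask in ((force, np.ones(len(fvec), bool)), (force_ll, is_ll)):
            if not mask.any():
                continue
            np.add.at(dest, contacts.nt_node[mask], fvec[mask])
            for k in range(3):
                np.add.at(
                    dest,
                    tri[mask, k],
                    -contacts.nt_bary[mask, k, None] * fvec[mask],
                )

    if len(contacts.ee_i):
        fn = params.kn * contacts.ee_gn
        max_fn = max(max_fn, float(fn.max()))
        fvec = fn[:, None] * contacts.ee_normal
        gt_mag = np.linalg.norm(contacts.ee_gt_vec, axis=1)
        sliding = gt_mag > 0
        if sliding.any():
            that = np.zeros_like(contacts.ee_gt_vec)
            that[sliding] = contacts.ee_gt_vec[sliding] / gt_mag[sliding, None]
            fvec -= (params.mu_d * fn * np.tanh(gt_mag / params.eps_slip))[:, None] * that
        a = scene.edges[contacts.ee_i]
        b = scene.edges[contacts.ee_j]
        s = contacts.ee_params[:, 0]
        t = contacts.ee_params[:, 1]
        is_ll = (scene.edge_body[contacts.ee_i] < 2) & (scene.edge_body[contacts.ee_j] < 2)
        if is_ll.any():
            trib = np.maximum(scene.tributary_area, 1e-30)
            p_pair = fn[is_ll] / (0.5 * (trib[a[is_ll, 0]] + trib[a[is_ll, 1]]))
            for arr, cols in ((a, (0, 1)), (b, (0, 1))):
                for k in cols:
                    np.maximum.at(iface, arr[is_ll, k], p_pair)
        for dest, mask in ((force, np.ones(len(fvec), bool)), (force_ll, is_ll)):
            if not mask.any():
                continue
            np.add.at(dest, a[mask, 0], (1 - s[mask, None]) * fvec[mask])
            np.add.at(dest, a[mask, 1], s[mask, None] * fvec[mask])
            np.add.at(dest, b[mask, 0], -(1 - t[mask, None]) * fvec[mask])
            np.add.at(dest, b[mask, 1], -t[mask, None] * fvec[mask])

    trib = np.maximum(scene.tributary_area, 1e-30)
    state = ContactState(
        force=force,
        force_leaflet=force_ll,
        pressure=np.linalg.norm(force, axis=1) / trib,
        pressure_leaflet=np.linalg.norm(force_ll, axis=1) / trib,
        interface_pressure_leaflet=iface,
        pairs=contacts.pairs(params) if collect_pairs else [],
        max_fn=max_fn,
    )
    return force, state


def auto_penalty_stiffness(masses: np.ndarray, dt: float, safety: float = 4.0):
    """Largest penalty stiffness stable for the explicit integrator:
    kn = m_min * (pi / dt)^2 / safety, kt = kn."""
    m_min = float(np.min(masses[masses > 0]))
    kn = m_min * (np.pi / dt) ** 2 / safety
    return kn, kn


# ---------------------------------------------------------------------------
# Cached-broad-phase engine for the time stepper
# ---------------------------------------------------------------------------


class ContactEngine:
    """detect() with a lazily refreshed broad phase.

    Candidates are regenerated with an inflated search radius and reused until
    any node has moved more than a third of the inflation margin, which keeps
    the candidate set conservative between rebuilds.
    """

    def __init__(
        self,
        scene: ContactScene,
        domain: ContactDomain,
        params: PenaltyParams,
        margin: float = 1e-3,
    ):
        self.scene = scene
        self.domain = domain
        self.params = params
        self.margin = margin
        self._cand = None
        self._build_pos = None
        self._override_nt = (np.empty(0, np.int64), np.empty(0))
        self._override_ee = (np.empty(0, np.int64), np.empty(0))

    def _needs_rebuild(self, positions) -> bool:
        if self._cand is None:
            return True
        move = np.abs(positions - self._build_pos).max()
        return bool(move > self.margin / 3.0)

    def freeze_initial_overlaps(self, positions) -> int:
        """Adjust clearances for pairs already within clearance at the
        reference configuration (chords converging on a shared papillary tip,
        chordal insertions grazing their own leaflet): each such pair gets its
        clearance shrunk to its initial separation, so the reference state is
        force-free but any FURTHER approach is still penalized.  Returns the
        number of adjusted pairs."""
        ni, ti = _node_triangle_candidates(
            positions, self.scene, self.domain, self.params, max_move=self.margin
        )
        ei, ej = _edge_candidates(
            positions, self.scene, self.domain, self.params, max_move=self.margin
        )
        cs = detect(
            positions,
            self.scene,
            self.domain,
            self.params,
            candidates=((ni, ti), (ei, ej)),
            tie_break=False,
        )
        nT = np.int64(max(len(self.scene.triangles), 1))
        nE = np.int64(max(len(self.scene.edges), 1))
        keys_nt = cs.nt_node * nT + cs.nt_tri
        # initial separation |d0| = clearance - gn
        vals_nt = _clearance_nt(self.scene, self.params, cs.nt_node, cs.nt_tri) - cs.nt_gn
        keys_ee = cs.ee_i * nE + cs.ee_j
        vals_ee = _clearance_ee(self.scene, self.params, cs.ee_i, cs.ee_j) - cs.ee_gn
        o = np.argsort(keys_nt)
        self._override_nt = (keys_nt[o], np.maximum(vals_nt[o], 0.0))
        o = np.argsort(keys_ee)
        self._override_ee = (keys_ee[o], np.maximum(vals_ee[o], 0.0))
        self._cand = None
        return len(keys_nt) + len(keys_ee)

    def detect(self, positions, prev_positions=None) -> ContactSet:
        if self._needs_rebuild(positions):
            ni, ti = _node_triangle_candidates(
                positions, self.scene, self.domain, self.params, max_move=self.margin
            )
            ei, ej = _edge_candidates(
                positions, self.scene, self.domain, self.params, max_move=self.margin
            )
            self._cand = ((ni, ti), (ei, ej))
            self._build_pos = positions.copy()
        return detect(
            positions,
            self.scene,
            self.domain,
            self.params,
            prev_positions=prev_positions,
            candidates=self._cand,
            overrides=(self._override_nt, self._override_ee),
        )
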
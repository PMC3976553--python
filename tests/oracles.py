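"""Independent brute-force oracles for contact detection.

These re-implement the detection geometry with simple per-pair loops and
different numerical routes (least-squares projection, parametric grid +
bounded optimization) so they can cross-check the vectorized engine.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def point_triangle_signed(p, v0, v1, v2):
    """(signed distance along unit normal, inside_projection) via lstsq."""
    n = np.cross(v1 - v0, v2 - v0)
    nn = np.linalg.norm(n)
    if nn < 1e-30:
        return None
    n = n / nn
    d = float(np.dot(p - v0, n))
    # least-squares barycentric solve of p - d*n = v0 + b*(v1-v0) + c*(v2-v0)
    A = np.stack([v1 - v0, v2 - v0], axis=1)
    bc, *_ = np.linalg.lstsq(A, (p - d * n) - v0, rcond=None)
    b, c = float(bc[0]), float(bc[1])
    inside = b >= -1e-12 and c >= -1e-12 and (1.0 - b - c) >= -1e-12
    return d, inside


def segment_segment_distance(p1, q1, p2, q2, refine=True):
    """Min distance between two segments by dense grid + bounded polish."""

    def dist(st):
        s, t = st
        return np.linalg.norm((p1 + s * (q1 - p1)) - (p2 + t * (q2 - p2)))

    grid = np.linspace(0.0, 1.0, 41)
    best, best_st = np.inf, (0.0, 0.0)
    for s in grid:
        for t in grid:
            v = dist((s, t))
            if v < best:
                best, best_st = v, (s, t)
    if not refine:
        return best
    res = minimize(
        dist,
        best_st,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        options={"ftol": 1e-18, "gtol": 1e-14},
    )
    return float(min(best, res.fun))


def brute_force_pairs(positions, scene, domain, params):
    """All active pairs via exhaustive loops; mirrors the engine's rules
    (double-sided slab, clearance, shared-node and same-body-ring exclusions,
    deepest-per-(node, master-body) tie-break)."""
    from mvsim.contact import BODIES

    def included(a, b):
        return tuple(sorted((BODIES[a], BODIES[b]))) in domain.included_pairs

    n = scene.n_nodes
    ring = set(scene.ring_keys.tolist()) if scene.ring_keys is not None else set()

    nt_best = {}
    for i in range(n):
        if scene.node_body[i] < 0:
            continue
        for t in range(len(scene.triangles)):
            tri = scene.triangles[t]
            if i in tri:
                continue
            if not included(scene.node_body[i], scene.tri_body[t]):
                continue
            if scene.node_body[i] == scene.tri_body[t] and ring:
                if any((i * n + int(v)) in ring for v in tri):
                    continue
            res = point_triangle_signed(
                positions[i], positions[tri[0]], positions[tri[1]], positions[tri[2]]
            )
            if res is None:
                continue
            d, inside = res
            cl = (
                params.clearance
                if params.clearance is not None
                else scene.node_half[i] + scene.tri_half[t]
            )
            if inside and abs(d) < cl:
                gn = cl - abs(d)
                key = (i, scene.tri_body[t])
                if key not in nt_best or gn > nt_best[key][1]:
                    nt_best[key] = (t, gn)
    nt = {(i, t): gn for (i, _), (t, gn) in nt_best.items()}

    ee = {}
    E = len(scene.edges)
    for i in range(E):
        for j in range(i + 1, E):
            a, b = scene.edges[i], scene.edges[j]
            if set(a.tolist()) & set(b.tolist()):
                continue
            if not included(scene.edge_body[i], scene.edge_body[j]):
                continue
            if (
                scene.edge_group[i] >= 0
                and scene.edge_group[i] == scene.edge_group[j]
            ):
                continue
            if scene.edge_body[i] == scene.edge_body[j] and ring:
                if any(
                    (int(u) * n + int(v)) in ring for u in a for v in b
                ):
                    continue
            cl = (
                params.clearance
                if params.clearance is not None
                else scene.edge_half[i] + scene.edge_half[j]
            )
            d = segment_segment_distance(
                positions[a[0]], positions[a[1]], positions[b[0]], positions[b[1]]
            )
            if 0 < d < cl:
                ee[(i, j)] = cl - d
    return nt, ee
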
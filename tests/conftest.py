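import numpy as np
import pytest

from mvsim import contact as ct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scene(
    positions,
    triangles=(),
    edges=(),
    node_body=None,
    tri_body=None,
    edge_body=None,
    tributary=None,
    rings=False,
):
    """Minimal ContactScene for constructed test scenes (unit half-thickness
    semantics are bypassed by passing explicit clearances in PenaltyParams)."""
    positions = np.asarray(positions, float)
    n = len(positions)
    triangles = np.asarray(triangles, np.int64).reshape(-1, 3)
    edges = np.asarray(edges, np.int64).reshape(-1, 2)
    scene = ct.ContactScene(
        node_body=np.zeros(n, np.int64) if node_body is None else np.asarray(node_body, np.int64),
        triangles=triangles,
        tri_body=np.ones(len(triangles), np.int64) if tri_body is None else np.asarray(tri_body, np.int64),
        edges=edges,
        edge_body=np.zeros(len(edges), np.int64) if edge_body is None else np.asarray(edge_body, np.int64),
        edge_group=np.full(len(edges), -1, np.int64),
        node_half=np.zeros(n),
        tri_half=np.zeros(len(triangles)),
        edge_half=np.zeros(len(edges)),
        tributary_area=np.ones(n) if tributary is None else np.asarray(tributary, float),
    )
    if rings:
        scene.build_ring_exclusions()
    scene.positions_init = positions
    return scene


def random_scene(rng, n_tri=10, n_seg=6, box=1.0):
    """Random triangle soup (body anterior/posterior alternating) plus truss
    segments (chordae body) for oracle-equivalence scenes."""
    pts = []
    tris = []
    tri_body = []
    for k in range(n_tri):
        c = rng.uniform(-box, box, 3)
        tri = c + rng.uniform(-0.25 * box, 0.25 * box, (3, 3))
        base = len(pts)
        pts.extend(tri)
        tris.append((base, base + 1, base + 2))
        tri_body.append(k % 2)
    segs = []
    edge_body = []
    for k in range(n_seg):
        c = rng.uniform(-box, box, 3)
        seg = c + rng.uniform(-0.3 * box, 0.3 * box, (2, 3))
        base = len(pts)
        pts.extend(seg)
        segs.append((base, base + 1))
        edge_body.append(2)
    pts = np.asarray(pts)
    n = len(pts)
    node_body = np.concatenate(
        [np.repeat(tri_body, 3), np.repeat(edge_body, 2)]
    ).astype(np.int64)
    tris = np.asarray(tris, np.int64)
    # perimeter edges of every triangle participate in edge-edge contact
    tri_edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    tri_edge_body = np.concatenate([tri_body, tri_body, tri_body])
    edges = np.vstack([tri_edges, np.asarray(segs, np.int64)])
    edge_bodies = np.concatenate([tri_edge_body, edge_body]).astype(np.int64)
    return make_scene(
        pts,
        triangles=tris,
        edges=edges,
        node_body=node_body,
        tri_body=np.asarray(tri_body, np.int64),
        edge_body=edge_bodies,
    )
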
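"""Explicit dynamic finite-element closure solver.

Constant-strain membrane triangles (anisotropic Fung law in a per-element
circumferential/radial material frame), Ogden truss chordae, follower
pressure loading on the leaflets, prescribed annulus / papillary-tip motion,
mass-proportional damping, and a central-difference (symplectic Euler) time
integrator.  Internal units are SI; geometry enters in millimetres and is
converted when the problem is assembled.

Closure is driven quasi-statically: transvalvular pressure ramps from zero to
its systolic peak while the annulus contracts, with damping heavy enough that
the end state is an equilibrium.  Selective mass scaling (global and
chordae-specific) enlarges the stable timestep; it changes the transient, not
the damped end state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import contact as ct
from . import geometry as geo
from . import materials as mat
from .errors import ConfigurationError, InvalidParameterError, MeshError, SimulationError

__all__ = [
    "LoadCurve",
    "BoundaryMotion",
    "SolverConfig",
    "SimState",
    "Trajectory",
    "SimProblem",
    "lumped_mass",
    "membrane_forces",
    "truss_forces",
    "pressure_forces",
    "stable_dt",
    "build_problem",
    "step",
    "run",
]

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class LoadCurve:
    """Piecewise curve over time; ``smoothstep`` uses 3u^2 - 2u^3 blending
    between consecutive knots (C1 at knots with zero end slopes)."""

    knots: tuple[tuple[float, float], ...]
    interpolation: str = "smoothstep"

    def __post_init__(self) -> None:
        times = [t for t, _ in self.knots]
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidParameterError("LoadCurve needs strictly increasing knot times")
        if self.interpolation not in ("linear", "smoothstep"):
            raise InvalidParameterError("interpolation must be 'linear' or 'smoothstep'")

    def __call__(self, t):
        t = np.asarray(t, float)
        times = np.array([k[0] for k in self.knots])
        vals = np.array([k[1] for k in self.knots])
        if self.interpolation == "linear":
            out = np.interp(t, times, vals)
        else:
            idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2)
            t0, t1 = times[idx], times[idx + 1]
            u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
            u = u * u * (3.0 - 2.0 * u)
            out = vals[idx] + u * (vals[idx + 1] - vals[idx])
            out = np.where(t <= times[0], vals[0], np.where(t >= times[-1], vals[-1], out))
        return out if out.ndim else float(out)

    @classmethod
    def ramp(cls, T_end: float, peak: float, interpolation: str = "smoothstep") -> "LoadCurve":
        return cls(knots=((0.0, 0.0), (max(T_end, 1e-9), peak)), interpolation=interpolation)

    @classmethod
    def ramp_hold(
        cls,
        T_end: float,
        peak: float,
        ramp_fraction: float = 0.65,
        interpolation: str = "smoothstep",
    ) -> "LoadCurve":
        """Ramp to the peak over the first part of the interval, then hold it
        (the hold lets the damped system settle to quasi-static equilibrium)."""
        T = max(T_end, 1e-9)
        return cls(
            knots=((0.0, 0.0), (ramp_fraction * T, peak), (T, peak)),
            interpolation=interpolation,
        )


@dataclass
class BoundaryMotion:
    """Prescribed positions for one node set, blended start -> target by a
    [0, 1]-valued time profile."""

    node_ids: np.ndarray
    start: np.ndarray  # (k, 3) m
    target: np.ndarray  # (k, 3) m
    profile: LoadCurve

    def __post_init__(self) -> None:
        if len(self.start) != len(self.target) or len(self.start) != len(self.node_ids):
            raise InvalidParameterError("start/target/node_ids lengths must match")

    def positions(self, t: float) -> np.ndarray:
        w = float(np.clip(self.profile(t), 0.0, 1.0))
        return self.start + w * (self.target - self.start)


@dataclass(frozen=True)
class SolverConfig:
    """Integrator settings.  ``dt=None`` selects the stable timestep
    automatically; ``mass_scale`` multiplies tissue density (quasi-static
    speed-up) and ``chordae_mass_scale`` additionally scales chordal nodal
    masses so subdivided chords do not control the timestep."""

    dt: float | None = None
    T_end: float = 0.25
    damping_alpha: float = 300.0  # 1/s, mass-proportional
    peak_pressure: float = 100.0 * MMHG_TO_PA  # Pa at peak systole
    pressure_curve: LoadCurve | None = None
    output_stride: int = 2000
    mass_scale: float = 6.0
    chordae_mass_scale: float = 40.0
    dt_safety: float = 0.5
    strain_cap: float = 0.30  # strain level used for tangent-stiffness dt estimate
    contact_stiffness_safety: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.damping_alpha < 0:
            raise InvalidParameterError("damping_alpha must be >= 0")
        if self.T_end < 0:
            raise InvalidParameterError("T_end must be >= 0")


@dataclass
class SimState:
    """Snapshot of the dynamic system (SI units)."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray | None = None
    contact: ct.ContactState | None = None
    strain: dict | None = None  # per-triangle E11/E22/E12 and PK2 caches

    def check_finite(self) -> None:
        if not (np.isfinite(self.positions).all() and np.isfinite(self.velocities).all()):
            raise SimulationError(f"non-finite state at t={self.time:.6g}s")


@dataclass
class Trajectory:
    states: list[SimState] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def initial(self) -> SimState:
        return self.states[0]

    @property
    def final(self) -> SimState:
        return self.states[-1]


# ---------------------------------------------------------------------------
# Problem assembly
# ---------------------------------------------------------------------------


@dataclass
class SimProblem:
    """Precomputed arrays for the time stepper (all SI)."""

    geometry: geo.MVGeometry
    materials: mat.MaterialSet
    X0: np.ndarray  # (N,3) reference positions, m
    masses: np.ndarray  # (N,)
    # membrane elements
    tris: np.ndarray
    tri_Bm: np.ndarray  # (T,2,2) inverse reference in-plane edge matrix
    tri_area0: np.ndarray  # (T,)
    tri_thickness: np.ndarray  # (T,)
    tri_fung: dict  # arrays c, a1..a4 per triangle (Pa)
    leaflet_tris: np.ndarray  # mask for pressure loading
    # truss elements
    segs: np.ndarray
    seg_L0: np.ndarray  # unloaded lengths, m
    seg_area: np.ndarray  # m^2
    seg_type: np.ndarray
    ogden_by_type: dict
    tension_only: bool
    # loading and boundaries
    pressure_curve: LoadCurve
    boundary: list[BoundaryMotion]
    damping_alpha: float
    # contact
    scene: ct.ContactScene | None = None
    engine: ct.ContactEngine | None = None
    contact_params: ct.PenaltyParams | None = None


def lumped_mass(geom: geo.MVGeometry, props: mat.TissueProps) -> np.ndarray:
    """Per-node lumped mass in kg: rho*A*t/3 per triangle vertex plus
    rho*A_c*L/2 per truss end (geometry in mm)."""
    n = geom.n_nodes
    m = np.zeros(n)
    if len(geom.triangles):
        areas = geo.triangle_areas(geom.nodes, geom.triangles) * 1e-6  # m^2
        if np.any(areas <= 0):
            raise MeshError("zero-area triangle in mass computation")
        th = np.where(
            geom.tri_region == geo.REGION_ANTERIOR, props.thickness_anterior, props.thickness_posterior
        ) * 1e-3
        contrib = props.density * areas * th / 3.0
        for k in range(3):
            np.add.at(m, geom.triangles[:, k], contrib)
    if len(geom.truss_segments):
        seg = geom.nodes[geom.truss_segments] * 1e-3
        L = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
        if np.any(L <= 0):
            raise MeshError("zero-length truss in mass computation")
        areas_c = np.array(
            [props.area_posterior_marginal, props.area_anterior_marginal, props.area_strut]
        ) * 1e-6
        contrib = props.density * areas_c[geom.truss_type] * L / 2.0
        for k in range(2):
            np.add.at(m, geom.truss_segments[:, k], contrib)
    return m


def _material_frames(geom: geo.MVGeometry):
    """Per-triangle orthonormal (e1, e2) with e1 along the local
    circumferential direction projected into the element plane."""
    X = geom.nodes
    tris = geom.triangles
    p = X[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    cen = p.mean(axis=1)
    # circumferential = z x r_hat (horizontal tangent around the annulus axis)
    circ = np.stack([-cen[:, 1], cen[:, 0], np.zeros(len(cen))], axis=1)
    circ /= np.maximum(np.linalg.norm(circ, axis=1, keepdims=True), 1e-12)
    e1 = circ - np.einsum("ij,ij->i", circ, n)[:, None] * n
    norm1 = np.linalg.norm(e1, axis=1, keepdims=True)
    # fall back to an arbitrary in-plane axis where circ ~ parallel to n
    bad = norm1[:, 0] < 1e-8
    if bad.any():
        alt = np.cross(n[bad], np.array([1.0, 0.0, 0.0]))
        alt_n = np.linalg.norm(alt, axis=1, keepdims=True)
        small = alt_n[:, 0] < 1e-8
        alt[small] = np.cross(n[bad][small], np.array([0.0, 1.0, 0.0]))
        e1[bad] = alt
        norm1 = np.linalg.norm(e1, axis=1, keepdims=True)
    e1 /= norm1
    e2 = np.cross(n, e1)
    return e1, e2


def build_problem(
    geom: geo.MVGeometry,
    materials: mat.MaterialSet,
    config: SolverConfig,
    domain: ct.ContactDomain | None = None,
    contact_params: ct.PenaltyParams | None = None,
    closure: geo.ClosureSpec | None = None,
) -> SimProblem:
    """Convert a millimetre geometry plus materials/config into SI arrays."""
    X0 = geom.nodes * 1e-3
    props = materials.props

    masses = lumped_mass(geom, props) * config.mass_scale
    chordal = np.isin(geom.node_region, (geo.REGION_CHORDAE, geo.REGION_PM))
    masses[chordal] *= config.chordae_mass_scale
    if np.any(masses <= 0):
        raise MeshError("isolated node with zero mass")

    e1, e2 = _material_frames(geom)
    p = X0[geom.triangles]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    Dm = np.stack(
        [
            np.stack([np.einsum("ij,ij->i", d1, e1), np.einsum("ij,ij->i", d2, e1)], axis=1),
            np.stack([np.einsum("ij,ij->i", d1, e2), np.einsum("ij,ij->i", d2, e2)], axis=1),
        ],
        axis=1,
    )  # (T,2,2) rows = frame axes
    det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
    if np.any(np.abs(det) < 1e-18):
        raise MeshError("degenerate reference triangle")
    Bm = np.empty_like(Dm)
    Bm[:, 0, 0] = Dm[:, 1, 1] / det
    Bm[:, 0, 1] = -Dm[:, 0, 1] / det
    Bm[:, 1, 0] = -Dm[:, 1, 0] / det
    Bm[:, 1, 1] = Dm[:, 0, 0] / det

    area0 = geo.triangle_areas(X0, geom.triangles)
    thick = np.where(
        geom.tri_region == geo.REGION_ANTERIOR,
        props.thickness_anterior,
        props.thickness_posterior,
    ) * 1e-3

    def fung_arrays():
        pa, pp = materials.fung_anterior, materials.fung_posterior
        sel = geom.tri_region == geo.REGION_ANTERIOR
        out = {}
        for name in ("c", "a1", "a2", "a3", "a4"):
            va, vp = getattr(pa, name), getattr(pp, name)
            arr = np.where(sel, va, vp).astype(float)
            if name == "c":
                arr *= 1e3  # kPa -> Pa
            out[name] = arr
        return out

    areas_c = np.array(
        [props.area_posterior_marginal, props.area_anterior_marginal, props.area_strut]
    ) * 1e-6

    pressure_curve = config.pressure_curve or LoadCurve.ramp_hold(config.T_end, config.peak_pressure)

    boundary = []
    if closure is not None:
        targets = geo.keyframe_boundary_targets(geom, closure)
        profile = LoadCurve.ramp_hold(config.T_end, 1.0)
        for name, (ids, tgt) in targets.items():
            boundary.append(
                BoundaryMotion(
                    node_ids=ids, start=X0[ids].copy(), target=tgt * 1e-3, profile=profile
                )
            )

    problem = SimProblem(
        geometry=geom,
        materials=materials,
        X0=X0,
        masses=masses,
        tris=geom.triangles,
        tri_Bm=Bm,
        tri_area0=area0,
        tri_thickness=thick,
        tri_fung=fung_arrays(),
        leaflet_tris=np.ones(len(geom.triangles), bool),
        segs=geom.truss_segments,
        seg_L0=geom.truss_rest_length * 1e-3,
        seg_area=areas_c[geom.truss_type] if len(geom.truss_segments) else np.empty(0),
        seg_type=geom.truss_type,
        ogden_by_type=materials.ogden,
        tension_only=materials.tension_only,
        pressure_curve=pressure_curve,
        boundary=boundary,
        damping_alpha=config.damping_alpha,
    )

    if domain is not None:
        scene = ct.ContactScene.from_geometry(geom, props)
        if contact_params is None:
            dt = config.dt or stable_dt(problem, safety=config.dt_safety, strain_cap=config.strain_cap)
            # large safety: keeps fresh rim-catching contacts from shocking the
            # membrane while still holding penetrations to ~1% of thickness
            kn, kt = ct.auto_penalty_stiffness(masses, dt, safety=config.contact_stiffness_safety)
            contact_params = ct.PenaltyParams(kn=kn, kt=kt)
        margin = 3.0 * float(scene.node_half.max() + scene.tri_half.max())
        problem.scene = scene
        problem.engine = ct.ContactEngine(scene, domain, contact_params, margin=margin)
        problem.engine.freeze_initial_overlaps(X0)
        problem.contact_params = contact_params
    return problem


# ---------------------------------------------------------------------------
# Force contributions
# ---------------------------------------------------------------------------


def _fung_stress_arrays(E11, E22, E12, fp):
    Q = fp["a1"] * E11**2 + fp["a2"] * E22**2 + 2 * fp["a3"] * E11 * E22 + fp["a4"] * E12**2
    ceQ = fp["c"] * np.exp(np.minimum(Q, 80.0))
    S11 = ceQ * (fp["a1"] * E11 + fp["a3"] * E22)
    S22 = ceQ * (fp["a3"] * E11 + fp["a2"] * E22)
    S12 = ceQ * (fp["a4"] * E12)
    return S11, S22, S12


def membrane_forces(positions: np.ndarray, problem: SimProblem, cache: dict | None = None):
    """Internal force array dPi/dx of the membrane elements (N, 3).

    The deformation gradient is evaluated in each element's material frame;
    forces are the exact gradient of the total Fung energy, so each element's
    three nodal forces sum to zero and carry no net torque."""
    if not len(problem.tris):
        return np.zeros_like(positions)
    p = positions[problem.tris]
    D = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # (T,3,2)
    F = D @ problem.tri_Bm  # (T,3,2)
    C11 = np.einsum("ti,ti->t", F[:, :, 0], F[:, :, 0])
    C22 = np.einsum("ti,ti->t", F[:, :, 1], F[:, :, 1])
    C12 = np.einsum("ti,ti->t", F[:, :, 0], F[:, :, 1])
    E11 = 0.5 * (C11 - 1.0)
    E22 = 0.5 * (C22 - 1.0)
    E12 = 0.5 * C12
    S11, S22, S12 = _fung_stress_arrays(E11, E22, E12, problem.tri_fung)
    if cache is not None:
        cache.update(
            E11=E11, E22=E22, E12=E12, S11=S11, S22=S22, S12=S12, C11=C11, C22=C22, C12=C12
        )
    S = np.empty((len(S11), 2, 2))
    S[:, 0, 0] = S11
    S[:, 1, 1] = S22
    # Q counts the stored shear strain once, so the work-conjugate of each of
    # the two symmetric tensor slots is half the S12 returned by the law
    S[:, 0, 1] = S[:, 1, 0] = 0.5 * S12
    Vol = (problem.tri_area0 * problem.tri_thickness)[:, None, None]
    G = Vol * (F @ S @ np.transpose(problem.tri_Bm, (0, 2, 1)))  # (T,3,2)
    forces = np.zeros_like(positions)
    np.add.at(forces, problem.tris[:, 1], G[:, :, 0])
    np.add.at(forces, problem.tris[:, 2], G[:, :, 1])
    np.add.at(forces, problem.tris[:, 0], -G[:, :, 0] - G[:, :, 1])
    return forces


def truss_forces(positions: np.ndarray, problem: SimProblem):
    """Internal force array of the Ogden truss chordae (N, 3); slack chords
    carry no force when the material set is tension-only."""
    forces = np.zeros_like(positions)
    if not len(problem.segs):
        return forces
    seg = positions[problem.segs]
    d = seg[:, 1] - seg[:, 0]
    L = np.linalg.norm(d, axis=1)
    if np.any(L <= 1e-14):
        raise SimulationError("zero-length chordal segment during integration")
    lam = L / problem.seg_L0
    P = np.zeros_like(lam)
    for code, name in enumerate(geo.TRUSS_TYPE_NAMES):
        sel = problem.seg_type == code
        if sel.any():
            P[sel] = mat.ogden_nominal_stress(lam[sel], problem.ogden_by_type[name]) * 1e3  # Pa
    if problem.tension_only:
        P = np.maximum(P, 0.0)
    fmag = P * problem.seg_area  # N, along the segment on node b
    dirv = d / L[:, None]
    fv = fmag[:, None] * dirv
    np.add.at(forces, problem.segs[:, 1], fv)
    np.add.at(forces, problem.segs[:, 0], -fv)
    return forces


def pressure_forces(positions: np.ndarray, problem: SimProblem, p: float):
    """Follower pressure on leaflet triangles: p * current area * current
    normal (atrial-facing orientation), split equally to the vertices."""
    forces = np.zeros_like(positions)
    if p == 0.0 or not len(problem.tris):
        return forces
    tris = problem.tris[problem.leaflet_tris]
    pts = positions[tris]
    an = 0.5 * np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0])  # area-weighted normal
    f = (p / 3.0) * an
    for k in range(3):
        np.add.at(forces, tris[:, k], f)
    return forces


def _fung_tangent_modulus(fung_arrays, strain: float) -> np.ndarray:
    """Upper-bound in-plane tangent modulus (Pa) at an equibiaxial strain."""
    E = strain
    a_sum = fung_arrays["a1"] + fung_arrays["a3"]
    Q = (fung_arrays["a1"] + fung_arrays["a2"] + 2 * fung_arrays["a3"]) * E**2
    ceQ = fung_arrays["c"] * np.exp(Q)
    return ceQ * (np.maximum(fung_arrays["a1"], fung_arrays["a2"]) + 2 * (a_sum * E) ** 2)


def stable_dt(problem: SimProblem, safety: float = 0.5, strain_cap: float = 0.30) -> float:
    """Conservative explicit timestep from per-element spring estimates,
    dt = safety * min_e sqrt(m_node / k_est), with tangent stiffnesses
    evaluated at a capped working strain."""
    dts = []
    rho_eff = problem.materials.props.density  # mass scaling enters via masses below
    if len(problem.tris):
        Et = _fung_tangent_modulus(problem.tri_fung, strain_cap)
        pts = problem.X0[problem.tris]
        e = np.stack(
            [
                np.linalg.norm(pts[:, 1] - pts[:, 0], axis=1),
                np.linalg.norm(pts[:, 2] - pts[:, 1], axis=1),
                np.linalg.norm(pts[:, 0] - pts[:, 2], axis=1),
            ],
            axis=1,
        )
        h = 2.0 * problem.tri_area0 / e.max(axis=1)  # min altitude
        k_est = Et * problem.tri_thickness * problem.tri_area0 / h**2
        m_node = problem.masses[problem.tris].min(axis=1)
        dts.append(np.sqrt(m_node / k_est).min())
    if len(problem.segs):
        lam_cap = 1.0 + strain_cap
        Pt = np.zeros(len(problem.segs))
        for code, name in enumerate(geo.TRUSS_TYPE_NAMES):
            sel = problem.seg_type == code
            if sel.any():
                par = problem.ogden_by_type[name]
                lam_grid = np.linspace(1.0, lam_cap, 16)
                dP = np.gradient(mat.ogden_nominal_stress(lam_grid, par), lam_grid)
                Pt[sel] = dP.max() * 1e3  # Pa
        seg = problem.X0[problem.segs]
        L = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
        k_est = Pt * problem.seg_area / np.minimum(L, problem.seg_L0)
        m_node = problem.masses[problem.segs].min(axis=1)
        dts.append(np.sqrt(m_node / np.maximum(k_est, 1e-30)).min())
    if not dts:
        raise ConfigurationError("no elements to size a timestep from")
    return float(safety * min(dts))


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------


def total_forces(positions: np.ndarray, problem: SimProblem, t: float, prev_positions=None,
                 cache: dict | None = None):
    """(F_ext + F_contact - F_int) and the contact state at ``positions``."""
    f = -membrane_forces(positions, problem, cache=cache)
    f -= truss_forces(positions, problem)
    f += pressure_forces(positions, problem, float(problem.pressure_curve(t)))
    cstate = None
    if problem.engine is not None:
        contacts = problem.engine.detect(positions, prev_positions)
        fc, cstate = ct.assemble(contacts, problem.contact_params, positions)
        f += fc
    return f, cstate


def step(state: SimState, dt: float, problem: SimProblem) -> SimState:
    """One central-difference update; boundary nodes are overwritten with their
    prescribed positions (velocities set consistently)."""
    x, v = state.positions, state.velocities
    cache: dict = {}
    f, cstate = total_forces(x, problem, state.time, prev_positions=getattr(state, "_prev", None),
                             cache=cache)
    a = f / problem.masses[:, None] - problem.damping_alpha * v
    v_new = v + a * dt
    x_new = x + v_new * dt
    t_new = state.time + dt
    for bm in problem.boundary:
        xb = bm.positions(t_new)
        v_new[bm.node_ids] = (xb - x[bm.node_ids]) / dt
        x_new[bm.node_ids] = xb
    new = SimState(time=t_new, positions=x_new, velocities=v_new, forces=f, contact=cstate,
                   strain=cache or None)
    new._prev = x  # type: ignore[attr-defined]
    return new


def run(
    geom: geo.MVGeometry,
    materials: mat.MaterialSet,
    config: SolverConfig,
    domain: ct.ContactDomain | None = None,
    closure: geo.ClosureSpec | None = None,
    contact_params: ct.PenaltyParams | None = None,
    problem: SimProblem | None = None,
) -> Trajectory:
    """Integrate from end diastole (t=0) to peak systole (t=T_end).

    Deterministic: there is no randomness in the solve.  Snapshots are stored
    every ``output_stride`` steps plus the initial and final states."""
    if problem is None:
        problem = build_problem(
            geom, materials, config, domain=domain, contact_params=contact_params, closure=closure
        )
    dt = config.dt or stable_dt(problem, safety=config.dt_safety, strain_cap=config.strain_cap)
    n_steps = int(np.ceil(config.T_end / dt)) if config.T_end > 0 else 0

    state = SimState(
        time=0.0, positions=problem.X0.copy(), velocities=np.zeros_like(problem.X0)
    )
    traj = Trajectory(states=[state])
    for i in range(n_steps):
        h = min(dt, config.T_end - state.time)
        state = step(state, h, problem)
        if (i + 1) % config.output_stride == 0 and i + 1 < n_steps:
            state.check_finite()
            traj.states.append(state)
    if n_steps:
        # final state with refreshed force/contact caches at peak systole
        cache: dict = {}
        f, cstate = total_forces(state.positions, problem, state.time,
                                 prev_positions=getattr(state, "_prev", None), cache=cache)
        state.forces = f
        state.contact = cstate
        state.strain = cache or None
        state.check_finite()
        traj.states.append(state)
    return traj


def kinetic_energy(state: SimState, problem: SimProblem) -> float:
    return 0.5 * float(np.sum(problem.masses[:, None] * state.velocities**2))
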
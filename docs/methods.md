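# Methods

`mvsim` simulates systolic closure of the mitral valve with an explicit
dynamic membrane finite-element model and quantifies leaflet coaptation.  Its
central experimental contrast is the *contact domain*: the same valve is
closed once with every contact interaction active (leaflets with each other,
leaflets with chordae, chordae with chordae) and once with leaflet-to-leaflet
contact only, and the coaptation metrics of the two arms are compared.

## Model

**Leaflets.**  Each leaflet is a membrane of constant-strain triangles
(no bending stiffness).  The in-plane response is an anisotropic Fung-type
hyperelastic law,

    W = (c/2) (exp(Q) - 1),
    Q = a1 E11^2 + a2 E22^2 + 2 a3 E11 E22 + a4 E12^2,

with Green–Lagrange strain components in a per-element material frame whose
first axis is the local circumferential direction (horizontal tangent around
the valve axis, projected into the element plane) and whose second axis is
radial.  Nodal forces are the exact gradient of the total element energy, so
every element's force system is self-equilibrated and torque-free; this is
verified against finite differences in the test suite.  Note that `Q` counts
the stored shear strain once, so the work conjugate of each of the two
symmetric shear slots of the PK2 tensor is half the `S12` returned by the
constitutive function.

**Chordae.**  Chordae tendineae are lines of truss segments from two
papillary-muscle (PM) tips to leaflet insertion nodes, with an incompressible
uniaxial Ogden response

    W(λ) = Σ_i (2 μ_i / α_i^2) (λ^{α_i} + 2 λ^{-α_i/2} - 3)

and tension-only behavior by default (slack chords buckle; config
`materials.tension_only`).  Chords are subdivided (target segment length
3 mm) so their interior nodes participate in contact along the whole span.

**Membrane thickness.**  Uniform per leaflet (anterior 0.69 mm, posterior
0.51 mm).  The Poisson ratio 0.48 enters only through the through-thickness
stretch λ3 = (λ1 λ2)^{-ν/(1-ν)} used when pushing PK2 stress forward to
Cauchy stress for reporting.

**Loading and boundary conditions.**  A follower pressure acts on the
leaflets along their current atrial-facing normals, ramping smoothly from
zero to the systolic peak (default 13.33 kPa ≈ 100 mmHg) over the first 65 %
of the simulated interval and holding the peak thereafter, so the heavily
damped system settles toward a quasi-static closed equilibrium.  Annular
nodes and PM tips follow prescribed displacements on the same schedule
(annular in-plane contraction scaling projected area by the configured
fraction; rigid PM translation); all other degrees of freedom are free, and
since nodes carry no rotational degrees of freedom, insertion rotations are
naturally unconstrained.

**Contact.**  Penalty contact with fn = kn·gn and kinetic friction
|ft| = μd·fn (μd = 0.05) opposing the slip increment, regularized by
tanh(gt/ε) with ε = 1e-6 m to avoid chatter at stick; the exact sign law is
recovered as ε → 0.  Detection finds node-to-triangle penetrations (two
symmetric passes with half weight each, keeping the deepest pair per slave
node and master body) and edge-to-edge proximities among shell perimeter
edges and chordal segments.  Shells are double-sided: a node within the
clearance of either face is active, and a *side-continuity* rule keeps
pushing a node back toward the side it occupied on the previous step even if
it crosses the mid-plane, which prevents fast approaches from being ejected
through the membrane.  Clearances default to the sum of the two bodies' half
thicknesses (leaflet t/2; chordal fiber radius).  Pairs already within
clearance in the reference state (chords fanning from a shared PM tip,
insertions grazing their own leaflet) have their clearance shrunk to the
initial separation, so the reference is force-free but further approach is
still resisted.  Same-body contact skips pairs within three mesh edges of
each other — a smooth surface is always inside the clearance slab of its own
neighbors.  The broad phase uses KD-tree radius queries with an inflated
margin, cached until any node moves a third of the margin.

**Penalty stiffness.**  kn = m_min (π/dt)^2 / safety.  The solver default
safety of 1000 keeps kn two to three orders below the explicit stability
limit: the limit-scaled value turns fresh rim-catching contacts into shocks
that destabilize the strain-stiffening membrane, while the softer value still
holds equilibrium penetrations to microns (contact nodal loads are ~0.1 N, so
penetration ≈ fn/kn stays far below the tissue thickness).

**Integration.**  Symplectic (semi-implicit) Euler — the central-difference
family — with dt = 0.5 · min over elements of sqrt(m/k_est), tangent
stiffnesses evaluated at a capped working strain (default 0.30).
Mass-proportional damping α = 300 s⁻¹ makes closure quasi-static.  Density
is mass-scaled (default ×6 globally; chordal nodes a further ×40) to enlarge
the stable timestep; with the ramp-and-hold loading the damped end state is
an equilibrium and is insensitive to the inertia scaling, which is why the
scaling is admissible.

## Synthetic valve generator

No patient geometries are distributed, so the generator emulates the *class*
of reconstructed valves: a saddle annulus (elliptic projection with the
configured anteroposterior and commissural diameters; out-of-plane term
−(s/2)·cos 2t with peak-to-peak saddle height s, anterior and posterior
annulus high), two leaflet membranes swept from their annular arcs toward the
ventricle on a structured, deterministically triangulated grid, and chordae
attached by even arc-length sampling of the free edges (marginal) and to
anterior belly nodes (strut).  The anterior leaflet spans a 150° arc; a 2.5°
cleft at each commissure keeps the two meshes initially separated.  Height
profiles taper toward the commissures with the posterior leaflet longer than
the anterior there, reproducing the commissural overhang of real valves.  PM
tips sit below and inward of the commissures, offset toward the posterior
ventricular wall; this routes the anterior marginal chords underneath the
posterior leaflet's distal strip, which is what makes leaflet-to-chordae
contact (or its absence) consequential during closure.

Chordal unloaded lengths are sized from an estimated coapted position of each
insertion (in-plane contraction toward the annular centroid, depth a fixed
fraction of the local leaflet height), so chords are slack in the open state
and become taut near closure — the physiologic condition.  The pathologic
variant dilates the annulus in-plane about its centroid with a weight
(1−s)² decaying toward the free edges, translates the PM tips, and leaves
free edges and chordal rest lengths unchanged: a dilated annulus with
normal-size leaflets, the substrate of functional regurgitation.

Generation is a pure function of its parameters; the `seed` argument is
accepted for interface stability but the structured mesher uses no
randomness.

What the generator does *not* emulate: patient-specific scallop anatomy
(P1/P2/P3 clefts), chordal branching trees, regional thickness variation, and
image-derived annular irregularity.  Passing tests on these geometries shows
the machinery is correct and the directional physics is reproduced; it does
not certify patient-specific accuracy.

## Coaptation metrics

All metrics are pure functions of a peak-systole snapshot.

- **Contact map / total contact area** — a leaflet node is coapted iff its
  leaflet-to-leaflet *interface* contact pressure reaches the threshold
  (default 50 kPa).  The interface pressure paints fn over the slave patch
  area onto both faces of each contact, because a coaptation map is a
  property of the interface, not of one body; chordal contributions are
  excluded.  Total contact area sums tributary areas of coapted anterior
  nodes and is also reported as a fraction of the anterior leaflet area.
- **Maximum gap distance** — on a vertical cut plane through the annular
  centroid and a station 15 % along the anterior free edge from the
  anterolateral commissure ("near" the commissure but clear of the cleft):
  the anterior free edge's plane crossings are measured against the
  posterior surface's cut polyline; the largest minimum distance is the gap.
- **Non-coaptation edge length** — summed length of anterior free-edge
  segments with both endpoints below the threshold.
- **Regurgitant orifice area** — the non-coapted free-edge chains of both
  leaflets are projected onto the annular plane; where the curves cross, the
  orifice is the union of the faces enclosed between crossings (nearly
  coincident curves enclose almost nothing); if they never cross the polygon
  is closed through the chain endpoints.
- **Maximum principal stress** — per element, the larger eigenvalue of the
  in-plane Cauchy stress from the PK2 push-forward (eigenvalues of S·C
  scaled by 1/(J₂ λ₃)).
- **Chordal pass-through** — interior chord segments are intersected with
  the leaflet triangles; the depth of a crossing is how far the chord
  extends past the mid-surface on the atrial side, following the chord past
  the crossing while it remains on the far side.  Insertion segments are
  excluded (a coapted insertion sits within the opposing leaflet's contact
  slab by construction).  Depths of the order of the leaflet thickness or
  more indicate a chord passing through a leaflet — the unphysical artifact
  that omitting leaflet-to-chordae contact produces.  The experiment harness
  evaluates this metric over *every stored frame* of the closure, not only
  peak systole: without chordal contact a leaflet can sweep straight through
  the chords and leave no crossing in the final state, so the transient is
  where the violation lives.

## Default parameters

| parameter | default | why |
| --- | --- | --- |
| annulus AP × CC diameter | 30 × 36 mm | mid-range adult dimensions |
| saddle height | 4 mm | ~15 % of the AP diameter keeps the in-plane/3D perimeter distinction mild |
| leaflet heights (ant/post) | 23 / 16.5 mm | anterior dominant; combined height exceeds the closure span so a coaptation reserve exists |
| Fung anterior | c=5 kPa, a1=20, a2=14, a3=6, a4=10 | ~100 kPa membrane stress near 18 % biaxial strain, circumferential-dominant |
| Fung posterior | c=3 kPa, a1=16, a2=12, a3=5, a4=8 | softer than anterior |
| Ogden marginal / strut | μ=1.8 MPa, α=12 / μ=2.6 MPa, α=13 | low-strain tangent of a few MPa with strong stiffening beyond ~10 % stretch, so loaded chords operate near λ ≈ 1.1 |
| thicknesses, chordal areas, density, Poisson | 0.69/0.51 mm; 0.27/0.29/0.61 mm²; 1100 kg/m³; 0.48 | standard tissue values |
| peak transvalvular pressure | 13.33 kPa (100 mmHg) | physiologic systolic load |
| annular area contraction | 30 % (normal) / 5 % (pathologic) | sphincteric contraction vs hypokinetic dilated annulus |
| friction μd | 0.05 | wet-tissue kinetic friction |
| coaptation threshold | 50 kPa | the mapping threshold of the contact-pressure panel |

The constitutive families are standard; the numerical constants above are
*representative*, chosen once for a physiologically closing desk-scale valve,
and are config inputs.  `fit_params` exists so users can fit digitized
experimental stress–strain curves instead (biaxial protocols at several
strain ratios for the planar Fung constants — a single 2-column curve cannot
identify all four — and uniaxial curves for the Ogden constants).

## Problem sizes

The shipped presets mesh the valve at a 3 mm target edge length
(≈ 450 triangles, ≈ 500 nodes including chordal subdivisions) and integrate
0.2 s of closure, which runs each contact arm in minutes on one CPU.  Finer
meshes sharpen the contact-pressure concentration along the coaptation line
(nodal pressure is force over tributary area) and are config-reachable;
the directional contrasts between the contact arms already express at the
preset resolution.

## Known limitations

- No bending stiffness: leaflets can wrinkle at scales the membrane model
  does not penalize; heavy damping controls, but does not eliminate,
  free-edge flutter in unconstrained regions.
- No fluid–structure interaction: pressure is a prescribed follower load;
  regurgitant orifice area is geometric, not hemodynamic.
- Kinetic friction only — no stick states; penalty contact admits
  penetrations of order fn/kn.
- Patient-reported magnitudes (gap distances, orifice areas, pressures of a
  specific valve) are not reproducible on synthetic geometry; the package's
  claims are the directional effects of the contact domain and the verified
  correctness of its components.
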
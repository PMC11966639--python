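# Methods

## Model

The package implements a Laplace–Dirichlet rule-based method (LDRBM) for
bi-atrial fiber architecture. The myocardium is treated as a volumetric
tetrahedral domain whose boundary is partitioned into labeled sets
(endocardial bands, epicardium with top bands, vein/valve rings, landmark
patches). Harmonic "distance" fields between chosen boundary sets provide
smooth coordinates adapted to the anatomy; their gradients provide the
transmural and normal directions from which an orthonormal frame is built
per node, and per-bundle rotation angles turn the flat longitudinal axis
into the fiber direction. Two volumetric layers (sub-endocardial /
sub-epicardial) carry independent angles, so transmurally crossing fiber
systems (e.g. the crista terminalis over the lateral wall) are representable.

Assumptions worth stating explicitly:

- fibers are **axial** (f ≡ −f) everywhere; all statistics and comparisons
  respect this invariance;
- within one bundle and one layer the rotation angle is constant — the
  model prescribes piecewise-constant fiber obliquity, not a continuous
  transmural ramp;
- the rule cascade is an ordered if/else-if chain: earlier branches win,
  and permuting branches changes the output. The order is therefore pinned
  by a regression test on a frozen fixture.

### The boundary-data table

Every harmonic field is defined by (value, boundary-set) pairs; both
chamber ψ-sets are solved on the full domain in the bi-atrial case (the
Dirichlet data only touches the owning side; fields extend harmonically
across the septum, which is what the inter-atrial connection windows probe).
Where two prescribed sets share junction nodes the conflict is resolved by
a fixed priority (landmark patches > rings > bands > endo/epi), then by
row order; conflicts are counted and reported.

The printed layer rule ("endocardial for |φ|>0") is degenerate as stated,
since φ is signed across chambers; we use the chamber transmural coordinate
(φ_la on the left, φ_ra on the right, both in [0,1] across the wall) and a
configurable split `τ_layer` (default 0.5): endocardial where
φ_chamber < τ_layer, the boundary value going to the epicardial layer. The
same coordinate resolves the layer-dependent normal sources in the
posterior-wall and Bachmann-bundle rules.

The landmark boundary sets (appendage apices, fossa ovalis center,
coronary-sinus apex) have no stated geometric extent; they are realized as
the landmark node plus its k-ring on the boundary surface (default k = 1,
configurable), i.e. point-like Dirichlet patches whose harmonic footprint
decays over a few elements. Thresholds on those fields (e.g. the appendage
cutoffs) must therefore sit close to the patch value; the shipped defaults
do.

## Parameters

- **Bundle thresholds (`BundleParams`).** All dimensionless, each
  constrained to the Dirichlet range of the field it thresholds. The
  shipped defaults are mid-range values calibrated once on the idealized
  fixtures in this repository — they are NOT values from any publication
  (per-geometry threshold tables for real anatomies are user config). The
  pectinate-muscle layout uses intervals of the appendage distance:
  `PM_i = τ_raa + (n−1)(pm_tk + pm_rg)`, `PM_f = PM_i + pm_tk`, with
  `pm_tk = pm_rg = 0.1`, `N_pm = 5`, `pm_end = 0.8` by default.
- **Rotation angles (`AngleTable`).** Per-bundle (endo, epi) degrees in
  (−90°, 90°]. Defaults have anatomical flavour (circumferential rings and
  venous sleeves, longitudinal crista terminalis at 80°, pectinates
  transverse at −70°, distinct endo/epi values where transmural crossing is
  typical) but are likewise fixture defaults, not published measurements.
  The printed cascade lists only an epicardial angle for the Bachmann
  connection and reuses the inter-caval angles for the septal fallback and
  the endocardial angle twice for the crista and pectinates; both angles
  are exposed for every bundle, with defaults equal where the source lists
  one value.
- **Electrophysiology (`EPParams`).** `c_f = 100 s^(−1/2)`,
  `σ_f = 1×10⁻⁴ m²/s`, `σ_s = σ_n = 0.16×10⁻⁴ m²/s` — calibrated to give
  1 m/s conduction along the fiber and 0.4 m/s across it; spherical
  stimulus radius 2 mm. A `dt` field is kept for interface compatibility
  with pseudo-time formulations but the shipped solver is a fixed-point
  scheme and does not use it.
- **Measurement.** Histogram bin width 10° (bins centered on multiples of
  the width so constant samples report their own angle; the ±90° bin wraps
  axially), minimum group size 50, "good agreement" threshold
  `1 − cos 30° ≈ 0.134`. All configurable; the agreement threshold behind
  published agreement percentages is not stated in the literature this
  package follows, so 30° is this package's documented default.

## Numerics

- **FEM.** P1 tetrahedra with exact element stiffness; Dirichlet imposition
  by symmetric elimination; diagonally preconditioned conjugate gradients.
  The distance-set driver solves at relative residual 1e−10 so that the
  discrete maximum principle holds within the 1e−8 band asserted by the
  tests (at 1e−8 the CG residual itself can overshoot the bound).
  Nodal gradients are tet-volume-weighted averages of the per-tet constant
  gradients; gradients below 1e−10 × (field range / bounding-box diagonal)
  are flagged degenerate, and such nodes inherit the full assignment of
  their nearest non-degenerate neighbour (breadth-first over mesh edges) —
  harmonic extrema produce isolated zero-gradient points and this keeps the
  frame field total.
- **Eikonal solver.** The activation time is the geodesic distance in the
  metric `M = Σ⁻¹/c_f²`. A vectorized fixed-point (fast-iterative style)
  scheme updates each vertex from the opposite faces of its incident tets:
  the planar-wave quadratic for the new vertex value, accepted only when
  the characteristic `Σ∇u` decomposes with non-negative weights on the
  face (causality), with exact minimization over the face's edges and
  vertices as fallback. Updates are monotone non-increasing from a BIG
  sentinel; the edge objective is evaluated in convex-combination form so
  the sentinel cannot absorb finite times. Iteration stops when no node
  improves by more than `tol` (1e−10 s). The scheme is first order; near a
  point source the front-curvature error is O(h/d), so an optional
  analytic source factorization seeds the exact metric distance in a small
  ball around point stimuli. The slab conduction-velocity calibration uses
  planar stimuli and no factorization. Element conductivity tensors are
  the mean of the four nodal tensors — averaging tensors is well defined
  under the axial symmetry f ≡ −f, unlike averaging frames.
- **Comparison indices.** Relative activation errors are normalized by the
  reference map's total activation time (consistent with how maximal local
  errors and the >10 % volume index are reported in the atrial EP
  literature); the volumetric index is
  `100 × (N_tot − N_≤10%)/N_tot` over solution nodes.
- **Ties.** Threshold comparisons are exactly as printed (≥, ≤, >, <), so
  equality belongs to the branch whose operator is inclusive. Histogram
  ties break toward the bin nearest 0°, negative first. The layer boundary
  φ_chamber = τ_layer is epicardial.

## Synthetic fixtures: what they emulate and what they do not

- The **slab** provides closed-form oracles (linear harmonic fields,
  planar eikonal fronts) and carries a complete left-atrial tag set so
  label validation and single-bundle round trips run on it.
- The **idealized atria** are single-chart dome shells (spherical caps of
  realistic size: 2 cm radius, 2.5 mm wall) with through-wall vein
  orifices, ring sectors along the rim, endo/epi bands and landmark nodes.
  They exercise every branch of the cascades, but their harmonic fields
  are smoother and more symmetric than on patient anatomies: passing tests
  demonstrates correctness of the rules and solvers, not that the shipped
  thresholds segment a real atrium.
- The **bi-atrial fixture** joins two dome chambers through a flat septal
  wall generated from one structured chart (conforming by construction).
  Both septal surfaces are tagged epicardial so the separator ξ
  interpolates freely across the wall; construction truth labels the
  septum as belonging to neither chamber. Inter-atrial connection windows,
  the flip rule and the left/right dispatch are all exercised; the septum's
  geometry (a ruled wall, not a fossa-ovalis-shaped rim) is not anatomical.
- The **measured-fiber generator** perturbs the configured truth angles by
  axial von Mises noise (2δ ~ VM(0, κ), so the axial SD follows
  √(2(1−I₁/I₀(κ)))/2) and applies random sign flips. It emulates axial
  noise and sign ambiguity of tensor-imaging data, but not spatially
  correlated disarray, partial-volume artifacts or regional dropout — so
  round-trip accuracy here is an upper bound on what real measured data
  would give.

Problem sizes used throughout (fixture defaults): slab 1.2k nodes / 4.8k
tets; domes ≈ 4.8k nodes / 18k tets; bi-atrial ≈ 7.6k nodes / 28k tets.
The full bi-atrial pipeline (11+ harmonic solves, cascade, frames) runs in
a few seconds on one core at these sizes.

## Known limitations

- Exactly two transmural layers; no continuous rotation across the wall.
- Automatic threshold estimation from geometry is out of scope; real
  meshes must arrive pre-labeled (no orifice detection).
- The eikonal model omits the diffusion (front-curvature) correction of
  reaction–diffusion models; bath loading, wall-thickness-dependent
  slowing and ionic dynamics are out of scope.
- The fixed-point eikonal scheme is first order; expect O(h) velocity
  error on unstructured anisotropic meshes away from the axis-aligned
  benchmark configuration.
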
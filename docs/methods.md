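# Methods

This note documents the models, numerical choices and synthetic-data design
behind `ieegcoverage`, and what the test suite does and does not establish
about real patient data.

## Coverage model

A contact's recording volume is idealized as a sphere of radius r (the
radius of influence) around its centroid; there is no amplitude decay
inside the sphere and nothing outside it. Because no single radius is
defensible across signal types — gamma-band activity dies off within a few
millimetres while low-frequency rhythms correlate across centimetres — the
radius is swept from 1 to 15 mm in 0.5 mm steps and every result is a curve
over r, with 2.5, 5, 10 and 15 mm reported as named radii.

Per patient, coverage at radius r is the probability-weighted volume of the
**union** of all contact spheres: each voxel counts once, weighted by its
gray- (or white-) matter probability and by the voxel volume. The union is
what encodes redundancy — two contacts 5 mm apart at r = 5 share a large
lens of tissue that must not be double-counted, and that redundancy is the
mechanism behind the depth/surface crossover. Per-contact coverage divides
the union total by the patient's full contact count (not only contacts
with nonzero coverage).

Voxel membership is by voxel-center distance with no anti-aliasing: the
probability maps already encode partial volume, so sub-voxel sphere
geometry would add a second, redundant smoothing. The cost is lattice
noise of order (h/r); binary voxelization of a 2.5 mm sphere on a 1 mm
grid is wrong by 10–25 % no matter where the center falls (a center-aligned
sphere contains 81 lattice points against an ideal 65.45 mm³), so oracle
checks at 2 % tolerance use voxels ≤ r/10. The sweep is computed from one
min-distance field per contact group (a voxel's distance to its nearest
contact), so all 29 radii are thresholdings of the same field and masks are
nested by construction.

Gray and white matter inside subcortical (accumbens/caudate/pallidum-like)
and cerebellar parcels is excluded from the totals; region-specific
coverage is reported for six analysis parcels (frontal, temporal,
hippocampus, amygdala, insula, cingulate) using gray matter only. A patient
counts for a region only if coverage there is nonzero at the 5 mm reference
radius — regions outside the clinical localization hypothesis would
otherwise dilute group comparisons with structural zeros. Exclusion masks
are applied by masking, not by re-normalizing probabilities.

## Brain-shift correction

Subdural contacts localized from postoperative CT typically sit several
millimetres inside the preoperative brain surface (the cortex sags once the
skull is open; shifts beyond 1 cm occur). The correction surface is the
gray-matter mask (threshold 0.5, configurable) morphologically closed with
a spherical element of 24 mm diameter — large enough to bridge sulci and
holes smaller than the kernel — then hole-filled and iso-surfaced into a
watertight triangle mesh. The volume is padded before closing so the
operation behaves as in an unbounded field of view; a closed surface still
sags r − sqrt(r² − w²/4) into a slit of width w (about 1 voxel for a 10 mm
slit), which is geometrically correct behavior, not an artifact.

Every strip/grid contact is moved to its exactly-closest point on that
mesh. Closest-point projection coincides with the foot of the
perpendicular for the dominant displacement mode (inward along the local
surface normal), is idempotent, and never increases the contact–surface
distance. An earlier variant cast rays along a plane fitted to grid-lead
neighbors; it was dropped because closest-point projection meets every
postcondition without a ray engine and is exact in the planar and
spherical limits. Closest-point queries run on a kd-tree over triangle
centroids with an exact point–triangle distance pass, widened by the
largest triangle circumradius so the result is exact rather than
approximate. Contacts farther than 25 mm (configurable) from the surface
are flagged, logged and left unmoved. Depth contacts are never touched.

Interhemispheric surface contacts record from one bank of the fissure
only, so their spheres are clipped to the hemisphere of their centroid
(tie at the midline goes to a configured side, default left, and is
logged). Hemisphere masks are thresholded gray matter split at the
midline plane, hole-filled per side; the nominal 0.1 mm Gaussian
mean-filter is smaller than any voxel and therefore effectively the
identity — it is kept configurable and documented as such. The clip is
applied to white matter as well as gray by default (`restrict_wm=False`
restores gray-only clipping), since a fissure contact is no better coupled
to contralateral white matter than to contralateral gray.

## Synthetic phantom

No patient imaging ships with the package, so every stage runs on a
phantom whose geometry is closed-form and therefore auditable:

- **Tissue layers.** A gray-matter ribbon of constant cortical thickness
  (3 mm) follows the folded sheet
  `z_top(x,y) = z0 + A · sin(2πx/λ) · cos(2πy/λ)`, with white matter below,
  CSF above and in the 4 mm interhemispheric gap. Defaults λ = 15 mm,
  A = 10 mm give gyral crowns ~15 mm apart and sulci ~20 mm deep
  peak-to-trough, in the anatomical range. The folding is a product
  sinusoid ("egg-crate") rather than a one-axis ridge: a one-axis fold
  leaves translation-invariant white-matter walls under every crest, which
  lets surface-contact spheres harvest unrealistically much white matter at
  large radii; the egg-crate bounds gyral white-matter cores in both
  lateral axes, as in a real cortex, and reproduces the clinical direction
  (depth ≈ 2× strip white-matter coverage at r = 15 mm).
- **Partial volume.** Probabilities are logistic in the signed distance to
  each tissue boundary with width `softness` (default 1 mm ≈ one MRI
  voxel); softness 0 gives hard binary tissue, for which total tissue
  volumes match slab geometry within one voxel layer (tested).
- **Atlas.** Parcels are axis-aligned blocks intersected with the tissue
  they occupy: cortical bands along the anterior–posterior axis for
  frontal/cingulate/insula/temporal, deep gray boxes per hemisphere for
  hippocampus and amygdala (18 mm tall — several 5 mm-spaced contacts fit
  inside, as in real hippocampal implants), an excluded subcortical box and
  an excluded cerebellar block.
- **Electrodes.** Strips (6 × 1, 10 mm pitch) and grids (4 × 6) lie on the
  smooth envelope tangent to the gyral crowns; half their contacts sit
  above sulci with gray matter ≥ 8 mm away, which is the geometric source
  of the small-radius depth advantage. Depth leads (10 contacts, 5 mm
  pitch) run obliquely from crown entries to clinically motivated targets:
  hippocampus and amygdala plus temporal and frontal white-matter
  trajectories, bilaterally. Cohorts draw per-patient layout jitter
  (±2 mm) from a seeded generator; subdural contacts are then displaced
  10 mm inward to emulate brain shift, and the pipeline must undo it.

What the phantom does **not** emulate: real MRI intensities or
segmentation error, curved lead trajectories, variable gyral width,
per-patient anatomy, electrode-count variance across patients at the
clinical scale (desk-scale cohorts use ~24–80 contacts per patient versus
~75–93 in clinical series). Passing tests therefore establish that the
*pipeline* is correct and that the folding-plus-spacing mechanism produces
the qualitative modality contrast; they do not reproduce any clinical
effect size, p-value or the ≈4 mm clinical crossover radius (the phantom's
crossover lands near 11 mm — its folding is still coarser than a real
cortex).

## FEM recording volumes

To probe the spherical idealization, the quasi-static potential
∇·(σ∇V) = 0 is solved per contact with σ_CSF = 1.79, σ_GM = 0.33,
σ_WM = 0.142 S/m and I = 1 mA. Discretization is linear (P1) tetrahedral
FEM on a structured lattice at the target edge length (default 1.5 mm, a
single-contact solve in well under a minute on one CPU): each hexahedral
cell splits into six Kuhn tetrahedra, which conform across faces without
parity bookkeeping, and each element takes the conductivity of the
majority tissue at its centroid. Coordinates are mm, so conductivities are
converted to S/mm and voltages come out in volts.

Current is injected as nodal loads distributed over the mesh nodes inside
the contact's physical footprint — a 2.3 mm disc for subdural contacts, a
0.86 × 2.29 mm cylinder for depth contacts — dilated by half an edge so
coarse meshes still catch a node ring (an isolated point source would make
the near-field mesh-dependent). The return electrode is the top 5 % of the
outer boundary by facet area, taken in descending superior coordinate,
held at V = 0 — the numerical analogue of scalp screws at the vertex. The
reduced system is solved by Jacobi-preconditioned conjugate gradients to
rtol 1e-9; discrete current conservation (reaction sum at the ground equals
−I) holds to solver tolerance and is asserted in tests, as is linearity in
I and < 5 % change at probe points under one uniform refinement.

The FEM recording volume at nominal radius r thresholds |V| at its mean
over the r-sphere around the contact (500 near-uniform Fibonacci
directions; samples outside the mesh are dropped with a warning above
20 %). The magnitude |V| rather than signed V is averaged — the monopolar
field changes sign nowhere, but the magnitude convention stays correct if
a bipolar configuration is ever added; both are available. In homogeneous
tissue this volume is nearly the sphere itself (Dice ≥ 0.9 when the mesh
resolves the radius, roughly h ≤ r/3); next to a high-conductivity CSF
layer it elongates and Dice drops, which is the physical point of the
comparison.

Solver verification against the infinite-medium point source
V = I/(4πσr) uses an exact far-field Dirichlet boundary (the analytic
solution imposed on the whole outer boundary). With the small vertex
ground instead, the finite box adds a constant access-resistance offset to
the far field that no mesh refinement removes — that configuration is kept
for production runs and validated via conservation and Dice, not via the
point-source formula.

Pipeline FEM runs solve a configurable subset of contacts per patient
(default 2) on a sub-box mesh around the contact that always extends to
the top of the head, keeping the physical ground patch in the model.

## Statistics

Group comparisons across implant classes use the Kruskal–Wallis rank test
(tie-corrected, chi-squared approximation) — coverage distributions are
skewed and cohorts small, so no normality is assumed. All-identical data
across groups carries no rank information and is reported as H = 0, p = 1
by convention. Families of pairwise class contrasts at one radius and
tissue are Bonferroni-corrected over the pair count (p·m clamped at 1);
classes with fewer than two patients are excluded and logged. Empirical
type-I error of the test is verified at 2000 null replicates to sit in
[0.04, 0.06] at α = 0.05.

Dice distributions are compared with Pearson's chi-squared on binned
values: pooled deciles, adjacent bins merged until every expected cell
count reaches 5, no continuity correction. Binning a continuous overlap
score is one defensible reading of a chi-squared test on Dice
coefficients; a Kruskal–Wallis alternative is available behind
`method="kruskal"`. Summaries report median and IQR, matching the
non-parametric tests.

The crossover radius between two classes is the smallest swept radius at
which the sign of the mean per-contact difference flips relative to its
initial sign — measured from the curves, never assumed. It is symmetric in
its arguments and `None` when the ordering never reverses.

## Problem sizes

Default analysis resolutions: phantom voxels 1 mm (cohort tests and the
acceptance script use 2 mm), FEM edges 1.5 mm, sweep 29 radii. A full
8-patient cohort run at 2 mm voxels with FEM off completes in a few
seconds on one CPU; the FEM validation battery (≈ 160 k nodes at 1.5 mm
plus smaller solves) runs in about ten seconds.

## Known limitations

- The RoI model is binary by design; no signal-amplitude weighting.
- Phantom folding is periodic and the atlas blocky; absolute coverage
  numbers are phantom properties, not clinical estimates.
- The FEM model has CSF/GM/WM only (no skull or skin compartments) with
  isotropic, frequency-independent conductivities.
- Depth-lead trajectories are straight lines; no vessel or sulcus
  avoidance beyond target placement.
- Coverage is computed on the phantom grid; anisotropic voxels are
  supported in the grid machinery but untested against an oracle.
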
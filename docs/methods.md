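# Methods

This note documents the models and algorithms implemented in `retractx`,
the synthetic study conditions and why they were chosen, and the numerical
decisions a user should know before trusting or changing the defaults.

## 1. Geometry and discretization

**Volumes.** All images are 3-D scalar grids with a voxel-to-world affine in
the NIfTI convention: `world = affine @ [i, j, k, 1]`, voxel centers at
integer indices, world units millimetres. Meshing requires an axis-aligned
affine with positive spacing.

**Mesh.** The tissue label is tiled with uniform axis-aligned hexahedra
whose edge length must be an integer multiple of the voxel size (default
5 mm on 1 mm voxels; at phantom scale this yields ≈3,100 elements and
≈4,000 nodes, i.e. ≈12,000 standard DOFs). A cell is kept when at least
half of its voxels are in-mask (`occupancy_threshold = 0.5`); the rule is
deliberately simple and is verified against a brute-force recount in the
tests.

**Crack.** The retraction corridor is a planar rectangle: mouth edge at the
cortical surface, interior front edge at depth `depth_mm`, lateral extent
`width_mm`. Two level sets describe any point: ψ, the signed distance to
the plane (positive along the outward normal; the tie ψ = 0 resolves to the
positive side everywhere in the package), and φ = (in-plane depth) − depth,
negative over the open crack and zero on the front. In the correction stage
the plane is least-squares fitted to the probe-digitized blade corners; the
rectangle dimensions come from configuration.

**Node classification.** For each element the plane–hexahedron intersection
points are computed from edge sign changes of nodal ψ. If the intersection
(clipped to the rectangle laterally) lies entirely behind the front the
element is *completely cut* and its nodes join set J (3 extra Heaviside
DOFs each); if the front passes through, the element is a *front element*
and its nodes join set M (12 extra tip DOFs each). M takes precedence on
overlap, so J ∩ M = ∅ by construction. A crack touching no element is a
warning, not an error.

## 2. Enriched elastic solver

The displacement ansatz uses *shifted* enrichment — the enrichment function
value at the owning node is subtracted — so standard nodal DOFs keep their
physical meaning and Dirichlet data can be imposed at nodes directly. The
span is identical to the unshifted form. Consequences used throughout:

* the displacement trace at a J node approached from side s is
  `u_j + (s − H_j) a_j`; prescribing both faces gives `a_j = (u⁺ − u⁻)/2`
  and pins `u_j` to the trace from the node's own side;
* tip enrichment vanishes at nodes, so nodal displacements never involve
  `c_m^l`.

The crack-tip branch functions use the standard fracture-mechanics polar
frame in the plane normal to the front: θ = 0 on the crack-plane extension
ahead of the front, θ = ±π on the faces; only the first branch
(√r sin θ/2) is discontinuous across the faces, jumping by 2√r.

**Integration.** Uncut elements share one 2×2×2-Gauss stiffness (the mesh is
uniform), computed once and scattered. Cut and front elements are
integrated on a uniform 4³ sub-cell refinement with 2-point Gauss per
sub-cell and the step/tip functions evaluated per point; when the crack
lies on element faces this is exact, which the duplicated-node oracle test
exploits. At ν = 0.45 trilinear hexahedra lock volumetrically, so a mean-
dilatation (B-bar) treatment of the volumetric strain is applied
everywhere, averaged separately on each side of the crack in cut elements.
The patch test passes to machine precision with B-bar, and the
duplicated-node FEM oracle in the tests uses the same element technology so
the equivalence check is exact.

**Constraints and solve.** Dirichlet data (side-resolved crack-face values,
zero-displacement base region, and automatically detected zero-stiffness
enriched DOFs) are imposed by exact elimination through a sparse reduction
operator; the reduced symmetric system is factorized with SuperLU. A
singular reduced matrix (unconstrained rigid modes) and a relative residual
above 1e-8 both raise errors rather than returning bad fields.

## 3. Retractor tracking

**Template.** From ≥3 non-collinear probe points the blade frame is fitted
(plane + principal axes) and both blade faces are sampled on a regular grid
at the configured pitch. The per-blade *contact template* used by the
pipeline is the on-plane grid with contact-direction normals.

**Rigid augmentation.** The full template is fitted to the partially
occluded scan to complete it. Point-to-point ICP on regularly sampled flat
blades is surprisingly treacherous: lattice-aliased local minima, centroid
bias from the occluded sector, and in-plane rotation aliasing all produce
multi-millimetre pose errors from naive starts. The implemented fit is a
symmetric trimmed ICP — scan→template correspondences untrimmed (every scan
point truly lies on the surface), template→scan correspondences trimmed at
the expected occlusion fraction — preceded by principal-axis rotation
seeding and a coarse in-plane translation grid search, followed by a
one-lattice-pitch multistart and an untrimmed polish that is asymptotically
exact for full-overlap data. Because the rectangular template has a 180°
symmetry group, exactly equivalent poses are tie-broken toward the least
motion (retraction moves blades modestly). A cost-landscape analysis shows
that the pose component *along* an occluded edge is only weakly
identifiable for a flat blade — trimmed-RMS differences between aliased
poses fall below the scan noise floor; the surface-normal component — the one that carries the retraction
displacement — is recovered to ≈0.02 mm under 30 % occlusion and 0.3 mm
noise.

**Nonrigid registration.** Coherent point drift with the dense template as
Gaussian-mixture centroids and the (completed) scan as data. The EM
iteration is seeded with the rigid pre-alignment (without a seed, centroid
alignment); bandwidth β is expressed in units of the template RMS scale
(default 2), regularization λ = 3, outlier weight w = 0.05 when the
occluded patch has been filled. The negative log-likelihood (with the
Gaussian normalization, since σ² evolves) is tracked and tested to be
non-increasing up to tolerance.

**Aperture projection.** The recovered per-point displacement is projected
onto the blade surface normal by default: a featureless flat face cannot
observe tangential motion, and a low-friction blade constrains the tissue
only along its normal, so the tangential estimate is registration noise
(measured ≈1 mm) and is discarded. This is an observability statement about
the instrument, not a tuning choice.

**Boundary conditions.** Each tracked point's displacement is offset by the
blade thickness along its normal (scanned inner surface → tissue contact
surface) and snapped to the nearest crack-adjacent node on the matching
side of the plane (nearest neighbour, capped at one element size). Only
nodes whose in-plane position falls inside the measured cloud footprint
(+0.5 mm) are eligible — tissue outside the contact area is not touching a
retractor and remains free. Points reaching no node are dropped with a log
entry; incompatible prescriptions from different source faces at one
(node, side) raise an error rather than being averaged. The zero-
displacement region is the bottom slab of the phantom (default 8 mm),
standing in for the fixed base / brainstem attachment.

## 4. Synthetic phantom and ground truth

The generator emulates a PVA-C brain phantom experiment: a smoothed
ellipsoid of tissue (default semiaxes 55 × 45 × 38 mm in a 128³ grid of
1 mm voxels), 23 beads of 1.5 mm rendered as anti-aliased spheres with
exact continuous centers stored separately, and an analytic crack-opening
displacement field

    u(x) = ± d_side · (1 − |ψ|/R)₊ · clip((depth − dd)/τ_f, 0, 1)
                    · clip((W/2 − |w|)/τ_e, 0, 1) · n̂

with d_right = 7.0 mm, d_left = 6.3 mm. The lateral taper τ_e closes the
jump at the rectangle's lateral edges (without it the field would be
discontinuous outside the crack polygon, contradicting its own support).
The post-retraction volume is produced by exact backward resampling of this
field (fixed-point inversion per crack side, analytic gap fill with
background), which gives the same image as forward pushing without splat
or hole artifacts; bead centers are displaced exactly.

Default study conditions and their rationale, chosen from geometric
consistency arguments:

* two 14-mm blades back-to-back at the fissure center (bilateral
  retraction), inserted 22 mm of the 30 mm crack depth so the blade covers
  the full-opening plateau (front taper τ_f = 8 mm);
* crack width 54 mm = blade span + 2×τ_e with τ_e = 20 mm, so the truth
  plateau coincides with the instrumented (bladed) region — a truth field
  claiming full opening where no blade pushes would validate nothing;
* decay radius R = 65 mm, the crack-to-anchored-base distance at which the
  phantom's motion must vanish;
* beads placed in the retraction-affected region (5–25 mm from the plane,
  ±20 mm along the crack, upper tissue) so their true motions span
  ≈2–6.4 mm, mirroring the 1.4–5.4 mm range reported for embedded beads in
  a physical phantom; two deep beads near the base have zero true motion
  and are excluded from accuracy means.

Scanner simulation: Bernoulli subsampling, one contiguous angular patch
removed (laser obstruction), isotropic Gaussian noise; defaults keep 80 %,
occlude 30 %, noise 0.3 mm. All randomness flows from one seed.

**What the generator does not model** — CT physics (noise spectra, beam
hardening, partial-volume streaks), material inhomogeneity or
nonlinearity, curved or wedge-shaped retraction corridors, brain-shift
prior to retraction, and any tangential tissue motion along the blades
(the truth field is purely plane-normal). Passing the end-to-end tests
therefore demonstrates that the tracking → XFEM → warping chain recovers a
discontinuity-dominated displacement field from realistic sparse, noisy
surface data; it does not certify accuracy on real CT of real tissue.

The residual bead error in the end-to-end run is dominated by the *shape*
difference between the analytic truth (linear decay) and a genuine elastic
response (St-Venant decay from the loaded patch): with error-free
boundary conditions sampled from the truth itself the mean accuracy is
≈73 %, and the full tracked pipeline reaches ≈72 %, i.e. tracking costs
only ≈1 accuracy point at the default noise levels.

## 5. Model-updated images

Backward interpolation with crack awareness. Per output voxel: the two
displaced face positions above the voxel's plane projection decide whether
it lies in the opened corridor (→ background fill), on the + or − side;
the material point is then found by fixed-point inversion of the
side-consistent displacement field (per-side trilinear interpolation of
nodal values on the uniform lattice, off-mesh lattice sites filled from
their nearest mesh node), clamped to its own side of the plane, and the
intensity is pulled from the pre-retraction image (trilinear by default,
nearest for labels). Voxels whose material point leaves the mesh are copied
through unchanged so un-modeled surroundings survive. Continuous indices
within 1e-6 voxel of an integer are snapped, which makes the zero-
displacement warp bit-identical and integer translations exact. The
inter-node variation of tip enrichment is not rendered by the warp (nodal
values carry no tip contribution under shifting); its effect is confined to
front-element interiors and is below voxel scale for these openings. A
crack-blind `warp_traditional` is provided; it differs from the modified
algorithm exactly in crack-adjacent voxels, which the tests assert.

## 6. Evaluation

Forecast error `‖C_model − C_post‖₂` and correction accuracy
`(1 − ‖C_model − C_post‖/‖C_post − C_pre‖)·100 %` per bead; beads with zero
true motion are excluded and logged. The accuracy numerator follows the
motion-recapture reading (model vs post); the alternative definition with
`‖C_model − C_pre‖` in the numerator — which reads 100 % when *nothing* is
corrected — is available behind `printed_form=True` for comparison studies.
Edge comparison: Canny (σ = 1, hysteresis 0.1/0.2 of the slice intensity
range) on 19 evenly spaced slices through the crack depth region, scored
with the modified Hausdorff distance — mean-of-minima directed distances,
symmetrized by the max; the classical max-of-minima form is available
behind a flag. The KD-tree implementation is tested against a brute-force
double loop to 1e-12.

Model bead positions are computed by evaluating the solved field at the
exact stored pre-retraction centers (side-resolved); an intensity-weighted
centroid localizer is provided for evaluating from voxelized images
instead, with sub-voxel accuracy on rendered beads.

## 7. Reproducibility, sizes, limitations

Every stochastic operation takes a seed derived from the single pipeline
seed; rerunning a stage with unchanged configuration and inputs is skipped
via a fingerprint file, and rerunning from scratch is bit-identical for
all tabular outputs. The reference problem size (128³ voxels, ≈3,100
elements, ≈13,000 enriched DOFs) runs the full pipeline in well under a
minute on one CPU; the test suite and the acceptance script together stay
within a few minutes.

Known limitations: linear elasticity is inappropriate for retractions much
beyond ≈13 mm (nonlinear/viscoelastic models would be needed); the crack is
a single planar rectangle (no curved or multiple corridors, no
propagation); tip enrichment is topological (front-containing elements
only), accepting standard blending error; contact between the crack faces
is not modeled (faces may interpenetrate if driven to); and the evaluation
against an analytic truth field bounds, but does not equal, accuracy
against a physical phantom.
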
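# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `cephaloplane`, and what the synthetic generator
does and does not emulate.

## Coordinate frame and plane representation

All coordinates are millimetres in a right-handed subject frame: X lateral
(positive toward the subject's right), Y vertical (positive superior), Z
antero-posterior (positive anterior). Nothing downstream depends on the
absolute frame — every metric is either invariant under rigid motion of the
whole landmark set (unsigned distances, bilateral differences) or pinned by
an explicit orientation convention — but the sign conventions below are
stated in this frame.

Planes are kept in Hesse normal form `{p : n·p = d}` with `‖n‖ = 1`, so the
signed distance of a point is a single dot product. Horizontal-plane normals
are flipped, if needed, to have a positive Y component (pointing
superiorly); midsagittal normals to have a positive X component (pointing to
the subject's right). The latter makes "positive offset = landmark right of
the midline" hold by construction, which is the convention clinical
symmetry tables use.

## Reference planes

The five horizontal planes are each built from exactly three landmarks
(FHP-P: PoA/OrR/OrL; FHP-O: OrA/PoR/PoL; FHP-L: PoL/OrR/OrL; FHP-R:
PoR/OrR/OrL; LSP: LsR/LsL/N), with the average porion/orbitale midpoints
derived internally and never read from input files. Three points closer to
collinear than a triangle area of 1e-6 mm² raise `DegenerateGeometryError`
naming the offending landmarks; with landmark coordinates at the 0.4 mm
voxel scale of CBCT imaging this threshold is orders of magnitude below
data precision, so it only fires on genuinely broken input. Constructed
planes contain their defining points to better than 1e-9 mm (verified
property, not an approximation knob).

The midsagittal plane derived from a horizontal plane is the unique plane
(up to normal sign) containing nasion and basion and perpendicular to it:
`n_ms ∝ n_h × (Ba − N)`. The construction degenerates when the
basion-nasion axis is parallel to the horizontal normal; the angle guard is
1e-6 rad, far beyond any anatomically possible configuration, and the error
is raised loudly rather than producing a garbage plane. One midsagittal
plane is derived per horizontal plane; symmetry reports cover the four
FHP-derived ones by default (the LSP-derived plane is available via
`parents=HORIZONTAL_PLANES`), matching how such comparisons are usually
tabulated.

## Asymmetry metrics

Bilateral metrics use unsigned point-plane distances and then the absolute
difference between sides (`U3 = |d(UL3) − d(UR3)|`, analogously U6/L3/L6);
a signed variant (left minus right) is available behind a flag for
exploratory work but excluded from the standard report shape. Midline
offsets are signed distances with the positive-right convention. Cohort
summaries report the sample mean and SD with the n−1 denominator. The
clinical classification helper calls a face asymmetric when |Me offset|
exceeds 4.0 mm, the conventional chin-deviation threshold.

## Observer-reliability statistics

Repeated digitisations pair off as: intraobserver — trial 1 vs trial 2
within each observer; interobserver — observer 1 vs observer 2 at matched
trials. How two observers × two trials collapse into pairs is genuinely
open; trial-matched inter pairs were chosen and both pairings are
parameters (`trial_pair`, `observer_pair`). Per landmark and axis the report
carries the mean absolute coordinate difference and Pearson's r computed
from its raw-sum formula, with a two-sided p from the exact t transform
`t = r√((n−2)/(1−r²))`. A zero-variance coordinate yields r = NaN with a
warning — a constant vector carries no correlation information and
reporting r = 1 there would silently inflate reliability. No
multiple-testing correction is applied by default (each landmark/axis is
reported marginally, as is conventional for these tables); a Bonferroni
option exists.

Expected values under the noise model: if both digitisations carry
independent N(0, σ²) placement error per axis, the coordinate difference is
N(0, 2σ²) and the mean absolute difference is `E|diff| = 2σ/√π` (≈ 0.226 mm
at σ = 0.2 mm). If one digitisation is error-free the expectation drops to
`σ√(2/π)` (≈ 0.160 mm). The test suite checks both constructions against
the simulation. High r additionally requires between-subject anatomical
spread much larger than σ; see the generator section.

## Friedman test

Within-block midranks, the statistic
`Q = [12/(n k (k+1))] Σ_j R_j² − 3n(k+1)` divided by the tie correction
`1 − Σ(t³−t)/(n k (k²−1))`, and p from χ² with k−1 dof. Fully tied data
(every block constant) return Q = 0, p = 1 rather than 0/0. Both the
Pearson and Friedman statistics are implemented from their formulas; SciPy
supplies only the t/χ² tail probabilities, and `scipy.stats` implementations
serve as independent cross-checks in the tests. Under the null the χ²
approximation at n = 10 blocks, k = 5 treatments is slightly conservative
(observed rejection rates a little under 0.05), which is the documented
behaviour of the approximation, not an implementation artifact.

## Volumetric pipeline

Rigid pre/post superimposition uses the Kabsch closed-form SVD solution
with reflection correction (smallest singular direction negated if the
determinant is −1), over the cranial-base landmarks N, Ba, PoR, PoL, LsR,
LsL by default — structures unaffected by orthognathic surgery. Fewer than
three or (near-)collinear correspondences raise an error rather than
returning an ill-conditioned fit.

Regions are intersections of half-spaces, each plane given directly, via a
reference plane plus an offset along its normal, or through named
landmarks; the named facial regions (chin, right/left mandible, lower lip)
have no canonical published borders, so region YAML files are package
conventions supplied by the user. Clipping slices the watertight mesh with
each plane and closes the cross-section with a triangle fan around each
boundary loop's centroid. The fan cap is exact for convex and star-shaped
cross-sections, which covers plane-bounded facial regions of skin/bone
shells; strongly non-star-shaped cross-sections would need a general
polygon triangulator and are out of scope.

Voxelization casts one ray per (y, z) voxel column and assigns inside/
outside by crossing parity, with duplicate crossings from shared triangle
edges deduplicated at 1e-9 mm and grazing (odd-count) columns dropped. The
default voxel is 0.4 mm, matching common CBCT acquisition; the voxel count
is capped (80M cells) with an error advising a coarser grid. The unsigned
volume difference counts voxels covered by exactly one of the two clipped
models (a movement magnitude, symmetric in pre/post); the signed net change
(post − pre) is reported alongside.

Average movement is ΔV divided by the region's surface area. The area is
measured on the *original pre-op* surface as the summed area of faces whose
three vertices all lie inside every half-space (tolerance 1e-6 mm): clip
caps are artifacts of region cutting and never contribute, and faces
straddling the region border are excluded whole — a deliberate
discretisation that under-counts by at most one face ring, negligible
against typical region sizes. Dividing by the pre-op (rather than post-op
or averaged) area is a choice, exposed as a parameter. The soft-to-hard
ratio divides the soft- by the hard-tissue average movement and refuses to
divide by hard movements below 1e-6 mm.

Surface-distance colour maps classify per-vertex distances into 0.4 mm bins
(green ≤ 0.4, yellow ≤ 0.8, orange ≤ 1.2, red ≤ 1.6, purple ≤ 2.0 mm,
larger = out of range). Vertex-to-surface distance is approximated by
nearest neighbour against a dense random sampling of the reference surface
(KD-tree), accurate to the sampling density.

## Synthetic generator

The generator stands in for patient CBCT landmark data, which cannot be
distributed. The template is a bilaterally symmetric adult skull at
realistic scale: inter-porion width 110 mm, orbitale ±32 mm lateral and
90 mm anterior of the porions, lower face extending ~70 mm below, mirror
plane X = 0. All horizontal-plane landmarks (Or, Po, Ls, N) are placed
exactly coplanar at Y = 0, so the undeformed template is the idealized null
in which all five horizontal planes coincide and every asymmetry metric is
exactly zero — the cleanest possible baseline for recovery tests. (Real
nasions sit near but not exactly on the Frankfort plane; relaxing that
coplanarity tilts the LSP slightly against the FHPs, which is precisely the
between-plane variation the cross-plane comparison measures on real data.)

Deformations compose in a fixed order (they do not commute): occlusal cant
(rotation of the eight paired dental cusps about the anterior axis through
the arch midline; UI/LI stay on the midline so chin-deviation ground truth
stays exact), then chin deviation (lateral translation of Me/Pog/LI,
positive right, clinical magnitudes roughly 4–12 mm), then per-side
mandibular setback along −Z. Because the cranial landmarks never move, the
true midsagittal plane remains X = 0 and ground truths are closed-form:
cant θ over cusp half-width w gives a bilateral metric of 2w·sin θ; chin
deviation d gives Me/Pog/LI offsets of exactly d.

Observer noise is isotropic Gaussian, default σ = 0.2 mm per axis —
consistent with reported repeated-digitisation differences of a few tenths
of a millimetre — and deterministic per (seed, observer, trial). Cohorts
can add per-subject anatomical variation (`anatomy_sigma_mm`, default 0):
independent Gaussian offsets per landmark, fixed across that subject's
digitisations. The reliability study uses 3 mm, a modest stand-in for
inter-individual anatomy, which is what makes cross-subject correlations
meaningful (spread ≫ σ). With nonzero anatomical variation the closed-form
deformation truths no longer hold exactly; analyses needing exact truth use
the per-subject `*_exact` outputs.

Mesh phantoms are watertight trimesh solids: a slab pair (cube with one
face offset outward — ΔV, moved area and average movement known exactly)
and an ellipsoid pair (axis-scaled icospheres — volumes analytic in the
refinement limit). The soft/hard phantom pair (offsets 1.6 and 2.0 mm)
fixes a ground-truth movement ratio of 0.80.

What the generator does **not** emulate: realistic skull-shape population
variation (no morphable model), correlated or observer-biased landmark
error, soft-tissue draping physics, imaging artifacts, or non-rigid
surgical remodelling. Tests passing on these phantoms validate the
geometry, statistics and bookkeeping of the pipeline — not clinical
accuracy on real CBCT data.

## Problem sizes and determinism

Default analysis sizes were chosen to exercise every code path at
interactive speed: 1000 randomized skulls for plane-containment sweeps,
10-subject × 2-observer × 2-trial reliability studies, 2000 simulations for
the Friedman null calibration, and 20 mm slab phantoms at 0.4–0.2 mm
voxels. Every stochastic entry point takes an explicit seed; identical
seeds reproduce byte-identical cohort files and reports (timestamps are
confined to log files), and output tables embed the package version and a
hash of the effective configuration.

## Known limitations

- Fan caps restrict region clipping to star-shaped cross-sections.
- Voxel parity assumes closed, consistently oriented meshes; open meshes
  are rejected rather than repaired.
- Region surface area excludes border-straddling faces whole (small
  negative bias at coarse mesh resolution).
- The Friedman χ² reference is asymptotic; exact permutation p-values are
  not implemented.
- Landmark files are trusted to be in millimetres; no unit detection.
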
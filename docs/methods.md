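# Methods

## Problem and model

`orbitcut` segments extraocular muscle, intraorbital fat and bone/dense
structures (including hydroxyapatite sphere prostheses) in an orbital CT
region of interest from sparse user strokes, then quantifies per-tissue
volumes. The segmentation is an interactive graph-cut of the lazy-snapping
family, adapted to the single scalar channel of CT:

For a labeling *L* over graph nodes (voxels, or watershed superpixels):

E(L) = Σ_i |R_i| · D_i(L_i) + λ Σ_(i,j)∈N w_ij · [L_i ≠ L_j]

* **Intensity models.** Per label, k-means cluster centers (at most K per
  label, fewer when the seeds hold fewer distinct values) fitted to the
  seeded voxels' HU. Lloyd iterations start from quantile-spread centers,
  so the fit is deterministic. CT being scalar, the color distance of the
  original formulation reduces to |HU − center|.
* **Data term.** D_i(l) = d_l / Σ_m d_m with d_l the minimum distance to
  label *l*'s centers; if every distance is zero the costs are zero for the
  tying labels and one for the rest. Costs lie in [0, 1] and, for two
  labels, sum to one. Node costs scale with the member-voxel count |R_i|.
* **Smoothness.** Contrast-sensitive Potts, w_ij = λ / (ε + (I_i − I_j)²),
  symmetric and strictly decreasing in contrast. ε > 0 keeps the weight
  finite at zero contrast.
* **Hard constraints.** Seeded nodes carry a large finite penalty
  (`hard_seed_cost`) against any label other than their seed label. The
  automatic default exceeds both 10⁶ × the maximum data cost and 100 × the
  initial labeling's energy, which provably dominates any cut the expansion
  can prefer while keeping capacities small enough for the integer solver
  (below). Infinities are never used.
* **Implicit background.** The three interactive brushes cover the tissues
  of interest, but an orbital ROI also contains air. Unless background
  strokes are given, voxels below −500 HU and the eight ROI corner voxels
  are auto-seeded as background (label 0). At the node level a background
  auto-seed pins a superpixel only when air voxels are the outright
  majority of its members; boundary superpixels containing a few air voxels
  stay free, otherwise thin tissues erode into the background. Voxel-level
  auto-seeds and user strokes always override the broadcast node label in
  the output.

## Minimisation

Alpha-expansion over the seeded labels in ascending id order, starting from
the per-node data-term argmin (ties to the lowest label id). Each expansion
is one binary min-cut: the Potts pairwise terms are reparameterised into
two t-links plus a single directed arc of capacity
θ01 + θ10 − θ00 − θ11 (non-negative because Potts is a metric), so no
auxiliary nodes are needed. A candidate labeling is accepted only if its
exactly recomputed (floating-point) energy strictly decreases, hence energy
is monotonically non-increasing; sweeps repeat until one full pass yields
no decrease (cap `max_sweeps`, default 10). With exactly two labels this
local optimum is the global one (sub-/superset expansion optimality on a
submodular binary energy), which the tests verify by exhaustive enumeration
on tiny volumes.

**Min-cut solver.** `solve_min_cut` wraps `scipy.sparse.csgraph.maximum_flow`
(Dinic) and recovers the source side by BFS on the residual graph. The
solver is integer-only and every capacity must fit int32, so float
capacities are quantised: the scale is the largest power-of-two step up to
2¹⁶ that keeps the maximum capacity below 2³⁰ (already-integral inputs are
solved exactly at scale 1). Quantisation can make an expansion miss an
improvement smaller than the step; the float-energy acceptance check means
this only affects move quality, never monotonicity or the hard constraints.

## Graph construction

* **Voxel mode** (`use_superpixels=False`): one node per voxel,
  6-connectivity by default (26 available). Exact but larger; used for the
  noiseless-recovery validation.
* **Superpixel mode** (default): watershed on the Gaussian gradient
  magnitude (σ = 0.7 voxels) with the connected local minima of the
  gradient as markers — a constant volume is one region, two constant
  half-spaces are two. Regions smaller than `min_region_voxels` (default 8)
  merge into their most similar-intensity neighbour (smallest-first greedy
  with union-find). Node intensity is the mean member HU; adjacency is
  6-connected region contact. Granularity matters: coarser superpixels cap
  the achievable Dice of thin structures (muscle strips are only a few
  voxels across), which is why the defaults are finer than a generic
  watershed preset.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lambda_smooth` | 50 | smoothness multiplier (HU²-scaled by the contrast denominator) |
| `K` | 16 | max k-means centers per label |
| `neighborhood` | 6 | 3-D voxel connectivity (6 or 26) |
| `use_superpixels` | on | watershed pre-segmentation for speed |
| `min_region_voxels` | 8 | minimum superpixel size before merging |
| `superpixel_smoothing_sigma` | 0.7 | Gaussian σ (voxels) for the gradient |
| `epsilon_contrast` | 1 | contrast-weight regulariser (HU²) |
| `hard_seed_cost` | auto | seed-pinning cost (see above) |
| `air_threshold_hu` | −500 | auto-background threshold |

Deterministic tie-breaking throughout: lowest label id wins ties, label
sweep order is ascending, k-means init is quantile-based, auto-seed
sampling uses an explicit generator seed.

## Synthetic phantom

The generator emulates a physical validation phantom: a skull-like bone
shell (ellipsoid shell, 3 mm thick, with an anterior opening), a centered
HA sphere (radius 6 mm, labeled with the bone/dense label but at its own
HU), four tapered muscle strips diverging from the orbital apex, and a fat
fill, the rest air. Defaults: 64×128×128 voxels at (1.0, 0.5, 0.5) mm —
the scale of a unilateral orbital ROI — muscle total 3.8 cm³, fat 2.5 cm³
(series preset: 2.0 … 2.5 cm³ in 0.1 cm³ steps across six phantoms), HU
means air −1000 / fat −100 / muscle +55 / bone +1000 / prosthesis +700
(textbook values, all configurable), noise σ = 15 HU.

Muscle and fat voxel sets are rank-selected from continuous priority
fields (normalised tube distance for the strips; apex distance for fat),
so ground-truth volumes hit the requested figure to within one voxel
volume, and a growing fat series is exactly nested. Noise is i.i.d.
Gaussian, drawn per phantom from a seed derived from (`rng_seed`, index).

**What the phantom does not model:** partial-volume averaging at tissue
boundaries, beam hardening and streak artifacts, anatomical orbit shape,
spatially correlated noise. Passing the phantom battery therefore
demonstrates the correctness of the energy, solver, calibration and
statistics — not clinical-grade accuracy on patient scans, where boundary
voxels are genuinely mixed and tissue HU distributions overlap more.

## Evaluation statistics

Jaccard and Dice are plain set overlaps with the convention that two empty
masks are identical (JS = DC = 1); the identity DC = 2·JS/(1+JS) is
property-tested. The ICC is the two-way mixed-effects, single-measure
variant computed from the explicit ANOVA mean squares; consistency
(ICC(3,1) = (MS_R − MS_E)/(MS_R + (k−1)·MS_E)) is the default reading for
a fixed rater panel, with absolute agreement behind `kind="agreement"`, and
reports name the variant. t tests are the classical paired (df = n−1) and
pooled-variance independent (df = n₁+n₂−2) forms with two-sided p-values;
zero-variance inputs are rejected rather than returning infinities.
Percentage difference is |truth − measured| / truth × 100 against a known
volume. No multiple-testing correction is applied.

Volumes are voxel counts × voxel volume (cm³, reported to 4 decimals);
sub-voxel boundary treatment is deliberately out of scope. Surface meshes
come from marching cubes on the 0.5-level of the binary mask, padded by
one background voxel so boundary-touching tissues still close; a single
interior voxel meshes to the octahedron through its face midpoints
(enclosed volume 1/6 of a voxel), and solid shapes ≥ 3 voxels thick agree
with the voxel-count volume to within 5%.

## Problem sizes used in validation

The automated battery runs the full default phantom (64×128×128 ≈ 1.05 M
voxels) for the noiseless exact-recovery, noisy-accuracy and six-phantom
sensitivity checks, and a geometrically similar 32×64×64 phantom for unit
and property tests. The min-cut solver is audited against exhaustive
enumeration of all 2ⁿ partitions on graphs of up to 8 non-terminal nodes,
and the expansion against exhaustive labelings of 2×2×2 volumes.

## Known limitations

* One 3-D cut over the whole ROI (no slice-wise mode); very large volumes
  should be cropped with `clip_roi` first.
* DICOM support covers axis-aligned single-frame axial CT series only;
  oblique orientations are rejected, never resampled.
* The solver's integer quantisation (≤ 1.5e-5 relative steps in the usual
  regime) makes near-degenerate energy ties resolve by rounding rather
  than exactly; determinism is unaffected.
* Superpixel mode trades boundary fidelity for speed; the exact voxel mode
  is the reference.
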
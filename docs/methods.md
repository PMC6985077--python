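# Methods

## Planning model

A trajectory is the straight segment from a scalp entry point to an
intracerebral target point. All geometry is computed on a voxel grid:
binary masks (scalp, brain, gray matter, sulci, vessels) share one
voxel-to-world affine (mm, 0-based indices, voxel-center convention).
Distance queries go through exact Euclidean distance transforms
(`scipy.ndimage.distance_transform_edt`, anisotropic spacing
respected) with trilinear interpolation for off-grid points —
nearest-neighbor lookups would quantize node distances by half a voxel
and propagate into the risk score.

### Risk score

Each trajectory is sampled at N = 128 equally spaced nodes including
both endpoints. Node distances to the vessel mask feed a two-branch
score (see README for the formula) with safety margin d_safe = 3 mm
and outer range d_max = 10 mm. The branch condition is ambiguous when
nodes straddle the margin (the condition is per-node but the leading
"1 +" is per-trajectory); we adopt the **whole-trajectory switch**: if
any node is ≤ d_safe the score is 1 plus the normalized penalty summed
over offending nodes only. This reproduces all the closed-form
anchors (bounds 0 and 2, boundary value 1, R > 1 iff a node breaches
the margin) and makes R continuous as an all-equal distance vector
crosses the margin. The alternative per-node-continuous reading —
each node contributes its own branch's term — is available via
`RiskParams(branch="node")`; both agree on all-equal vectors.

Risk nodes span the full scalp-entry→target segment by default
(`RiskParams(node_span="intracerebral")` restricts to the portion
inside the brain). Distance fields are ≥ 0 by construction; values
above d_max contribute zero risk.

When a critical-structure mask is empty the distance field degenerates
to a sentinel uniformly equal to the grid diagonal (the largest
distance representable on the grid), with a warning. Metrics stay
total: minimum vessel distance reports the cap, risk is 0.

### Other metrics

* **Minimum vessel distance**: min over nodes of the interpolated
  vessel distance field. It therefore shares discretization with the
  risk score — the flag R > 1 and the condition min distance < 3 mm
  agree exactly.
* **GM sampling ratio**: fraction of intracerebral nodes (interpolated
  brain-mask value > 0.5) inside gray matter. Node counting rather
  than arc length; identical under the uniform node spacing used
  everywhere.
* **Intracerebral length**: distance from the first node inside the
  brain mask to the target, resolved to one node spacing.
* **Drilling angle**: arccos of |direction · normal| at the entry,
  in degrees; 0° is orthogonal drilling. Scalp normals are gradients
  of a Gaussian-smoothed (σ = 2 mm) signed distance field of the scalp
  mask — smoothing suppresses the voxel staircase; on a sphere the
  estimator stays within 5° of the analytic radial direction.

## Constraints and ranking

Hard constraints, checked in order with *all* violations reported:
minimum vessel distance ≥ 3 mm, entry→target length < 90 mm (the
conservative reading — the full segment is never shorter than the
intracerebral portion, and both lengths are reported), drilling angle
< 30°, and no sulcal crossing (any node interpolating the sulci mask
above 0.5). Sulcal avoidance can be disabled, reflecting the
variability in surgical practice.

Feasible trajectories are ranked by a composite score

    w_r·R/2 + w_g·(1 − GM) + w_l·(length/90) + w_a·(angle/30)

with default weights (1, 0.5, 0.25, 0.25): risk-dominant, gray-matter
sampling next, length and angle as mild tie-shapers. The qualitative
preference order is established practice; the specific weights are
this package's choice and are exposed in `PlanningConstraints`. Ties
break deterministically on (risk, −GM, length, angle, candidate
order). Per-entry and per-target tables of best achievable risk (the
"risk maps") support risk-stratified iteration.

## Candidate generation

Target candidates are target-ROI voxel centers subsampled by a
deterministic per-axis stride anchored at the region's bounding box.
Entry candidates are entry-region voxels projected outward along the
local surface-normal direction onto the scalp surface (bracketing +
bisection of the signed distance zero crossing). The entry-region
construction is a stand-in: clinical systems project through gyral
anatomy from a whole-brain parcellation, whose details are not
reproducible from masks alone.

## Multi-electrode planning

Electrodes are planned sequentially, most-constrained first (fewest
feasible candidates). After each selection, alternatives of the
remaining electrodes that come within 10 mm (exact closed-form
segment–segment distance, full entry→target segments — the
conservative reading of "trajectory spacing") are skipped. If a later
electrode becomes unplannable, one round of backtracking advances a
single earlier electrode to its next compatible alternative. The
greedy-with-backtracking planner is this package's concrete strategy;
on two-to-three-electrode problems its summed composite score is
verified against exhaustive combination search to be within a factor
of 1.5 (in the test runs it is usually optimal), and feasibility of
every emitted plan is asserted unconditionally.

`next_target` advances one electrode to the next-ranked alternative
sharing its current entry; `next_entry` jumps to the best trajectory
of the next-best entry in the risk map. Both skip alternatives that
would violate spacing against the other current selections and wrap
past the end with an explicit flag (the clinical UI's buttons have no
stated end behavior). Automated output is provenance `plan2`;
iteration marks `plan3`; a clean manual override is `plan4`; an
override violating any constraint is demoted to `manual` with the
violations (including the names of conflicting electrodes) attached —
never silently accepted.

## Synthetic phantom

The generator emulates the structure of real planning inputs on a
160 mm³ grid at 1 mm isotropic spacing (default): a spherical head
(75 mm) containing a brain (65 mm) with a 3 mm cortical gray-matter
ribbon; six 2 mm-wide radial sulcal folds reaching 10 mm deep,
localized to hemispheric caps; two vessel trees grown by a seeded
branching random walk (2 mm steps, direction diffusion, branching
probability 0.08 per step) rasterized as 1.5 mm-radius tubes; four
6 mm spherical target ROIs placed with a head-size-scaled minimum
separation; and per-ROI entry regions, the cortical patch within a 15°
cap about the ROI's radial direction. A brute-force feasibility probe
re-draws an ROI/entry pair (bounded retries) until every schema
electrode admits at least one feasible trajectory. One seeded
generator per phantom; identical (seed, config) gives bit-identical
volumes.

What the phantom does **not** emulate: vascular anatomy (no
arterial/venous topology, no cortical surface vessels), MRI intensity
or segmentation noise, gyral/sulcal geometry beyond thin radial slabs,
and non-spherical head shape. Tests passing on phantoms therefore
validate the *planning machinery* — distances, constraints,
optimization, determinism — not clinical performance on patient
anatomy.

## Statistics

Paired risk-score comparisons cluster within patients (~10 electrodes
per plan). The sample size uses the two-group normal approximation
n = round(4·(z₁₋α/₂ + z_power)²·σ²/δ²), rounded to nearest for the
unadjusted total and ceiling after multiplying by the design effect
1 + (m − 1)·ρ — the convention pair that reproduces both printed
design numbers (42 comparisons; 118 electrodes at m = 10, ρ = 0.2).
Rounding conventions differ across texts, hence this explicit note.

`compare_plans` reports per-metric mean paired differences with a
cluster bootstrap: patients (plan pairs) are resampled with
replacement, keeping each cluster's electrodes together. With few
clusters the naive equal-tailed percentile interval is systematically
narrow, so the percentile levels are widened the standard small-sample
way (Hesterberg's *expanded percentile* interval: the nominal z
quantile is replaced by t_{G−1}·√(G/(G−1)) for G clusters). Measured
by simulation at G = 13, m = 10, ICC 0.2, this lifts coverage of the
nominal 95% interval from ≈ 0.90 to ≈ 0.93. The output is labeled
descriptive; mixed-effects regression is deliberately out of scope.

## Numerical choices

* Trilinear interpolation everywhere off-grid; edge handling by
  nearest-edge extension.
* Masks binarize as value > 0 on load (tolerates probabilistic
  segmentations).
* NIfTI volumes are written uncompressed by default: gzip embeds a
  timestamp in its header, which would break byte-identical
  reproducibility of repeated runs; `.nii.gz` is accepted on read.
* Segment–segment distance is the standard clamped closed-form
  quadratic minimization, robust to (near-)parallel segments.
* Degenerate inputs fail loudly: coincident endpoints, singular
  affines, zero-gradient normals, empty regions, empty plans.

## Problem sizes in the test suite

Unit and end-to-end tests run on reduced phantoms — 64³–96³ grids,
24–38 mm brains, 2–3 electrodes — chosen so the suite exercises every
code path (sulci, vessels, conflicts, backtracking, wrapping) at
interactive speed; the oracle-equivalence suites sweep 100+ seeded
phantoms at the 64³ scale. The default `PhantomConfig` remains the
full 160³ head described above.

## Known limitations

* Straight trajectories only; no curved or multi-segment paths.
* Candidate entry projection assumes a star-shaped scalp around each
  entry region (true for head-like shapes; not for arbitrary masks).
* The risk score is a surrogate: proximity to segmented vasculature,
  not hemorrhage probability.
* Electrode contacts (count, spacing along the shaft) are not
  modeled; the trajectory is the unit of planning.
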
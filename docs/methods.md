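# Methods

This note documents the models, algorithms and numerical choices behind
`cstract`, what the synthetic phantoms do and do not emulate, and the
parameters that matter.

## Streamline propagation model

The tracker operates on a crossing-fibre orientation field: each voxel hosts
up to three fibre populations, each with an axial (sign-free) unit mean
direction, a volume fraction, and S unit orientation samples emulating
posterior draws from a crossing-fibre model fit. Propagation per streamline:

1. **Initialisation.** At the seed voxel, a population is chosen with
   probability proportional to its volume fraction among populations at or
   above the fraction threshold; one of its samples is drawn and assigned a
   random sign.
2. **Stepping.** At each step the field is looked up at the *nearest voxel*
   of the current position. Candidates are the populations at or above the
   fraction threshold; the candidate whose sign-aligned mean direction makes
   the smallest angle with the current direction is selected (ties break to
   the lowest population index), one of its S samples is drawn and
   sign-aligned, and the step is rejected — the streamline terminates as a
   curvature dead end — if the turning angle exceeds the curvature limit.
   Curvature is evaluated between successive step directions only, not over
   a window.
3. **Termination and constraints.** The streamline advances a fixed step in
   world millimetres; the new point is tested against the grid (exit ⇒
   lost), the exclusion mask (⇒ the whole streamline is invalidated),
   waypoint masks (recorded; an ordered flag additionally requires first-hit
   order) and the stop mask (entry point kept, propagation halts). A
   position with no supra-threshold population also ends the streamline.

A streamline is **valid** iff it hits every waypoint (in order where
required) and never enters the exclusion mask, regardless of how propagation
ended. The path distribution counts each valid streamline at most once per
voxel and divides by the number of valid streamlines, so voxel values lie in
[0, 1] and `value × n_valid` is integral for single runs (the
reverse-and-averaged anterior commissure map is a mean of two runs and
integrality does not apply to it).

Directions are **not** interpolated between voxels: axial vectors do not
interpolate linearly without sign bookkeeping, and nearest-voxel lookup keeps
the propagation rule exactly enumerable, which the test suite exploits
(empirical visit frequencies on micro-corridors are checked against full
enumeration of all draw sequences).

Mask membership of a continuous point uses nearest-voxel rounding with .5
ties rounding toward −∞; voxel indexing is 0-based with integer coordinates
at voxel centres.

**Parameters** (defaults): step 0.5 mm on the full-scale phantom and 0.2 mm
on the half-scale one (roughly half a voxel); curvature limit 80° per step;
at most 2000 steps; subsidiary-fibre volume fraction threshold 1%; 200 seeds
per seed voxel by default, reduced to 15–40 in the test suites where many
repetitions are run — the Monte-Carlo properties tested are insensitive to
this beyond sampling noise.

**Determinism.** Every random draw is a pure SplitMix64-based function of
(rng seed, seed-voxel index, streamline index, step, draw slot). Results are
therefore bit-identical across batch sizes and execution orders, and raw
visit counts are additive over any partition of the seed mask. A pipeline
seed fans out to stage-specific substreams keyed by stage-name strings, so
adding a stage never perturbs another stage's randomness.

## Tract protocols

A protocol is a declarative combination of seed, waypoint (target), optional
stop and exclusion masks plus two flags (reverse-and-average; ordered
waypoints). The shipped library expands to 23 reconstructions: 11 bilateral
tracts × 2 hemispheres + 1 commissural. Nine bilateral bundles are new
(AMF, StBf, StBm, StBp, StBt, MB, EmCf, EmCp, EmCt; 18 protocols) and three
protocols are revised (UF, FX bilateral; AC commissural; 5 protocols).
Protocol semantics follow the standardised-protocol conventions:

* each striatal-bundle part targets the putamen and excludes a midsagittal
  plane, the subcortex except the putamen, the occipital lobe, and the seeds
  of every sibling StB part; extreme-capsule parts share the StB seeds,
  target the insula, and exclude sibling EmC seeds;
* the Muratoff bundle seeds in white matter adjacent to the caudate head,
  targets white matter adjacent to the tail, and carries a stop mask beyond
  the target — stop masks terminate but never invalidate;
* the amygdalofugal seed is *derived from the field*: voxels inside a
  sub-commissural slab whose dominant population lies within 25° of the
  anterior–posterior axis with volume fraction ≥ 0.5 — an orientation-based
  operationalisation of a "high anterior–posterior anisotropy" seed rule;
* the anterior commissure seeds one temporal pole, requires the midline AC
  body *before* the contralateral pole (the only ordered-waypoint protocol),
  and averages the two flipped seed/target runs voxelwise;
* the fornix adds an amygdala exclusion; the revised uncinate uses an
  anterior temporal seed with a genu-level target plane and basal-ganglia,
  posterior-plane and dorsal exclusions.

Waypoints are unordered AND-logic everywhere except the AC. Group averaging
of path distributions thresholds strictly (`value > level`) before the
voxelwise mean, consistent with single-map thresholding.

The phantom-space masks realise the *logic* of these rules, not anatomical
geometry; protocol masks from any other source load through the same
directory schema (`protocol.json` + mask NIfTIs, one directory per tract).
A separate reference set (a thalamic radiation ATR plus four
cortico-cortical association bundles CING, SLF, IFO, ILF per hemisphere)
widens the blueprint columns and provides the cortico-cortical contrast
subset; it is deliberately not part of the 23-tract library.

## Connectivity blueprints

Cortical rows are built through an intermediary whole-brain matrix: each
cortical element (a ribbon voxel adjacent to white matter, decimated to a
sparse lattice as a voxel-based stand-in for a downsampled surface) seeds
unconstrained tracking whose validity is simply "entered the white-matter
mask"; binary per-streamline visits are accumulated per block-mean
downsampled WM voxel (factor 2 here), and the GM×WM matrix is multiplied by
a WM×Tracts matrix of collated path distributions, downsampled the same way
and thresholded at 0.1%. This construction exists because raw near-cortex
path distributions are dominated by geometric bias at the grey–white
boundary.

Subcortical rows intersect each tract's downsampled, thresholded path
distribution directly with the binary nucleus masks — one row per coarse
in-nucleus voxel. The order of operations is fixed as downsample → threshold
and recorded in metadata. The intermediary-matrix construction is also
implemented for the subcortex (seeding one representative fine voxel per
coarse nucleus voxel so rows correspond one-to-one) purely for comparison:
on the phantom the direct variant is at least as nucleus-specific for every
assigned tract, and markedly more specific for bundles passing close to
other tracts' territories.

Rows are concatenated cortex-first and sum-normalised; rows that are
all-zero *before* normalisation are flagged and excluded from divergence
rather than δ-filled — a zero row carries no connectivity evidence and
δ-filling would make it spuriously uniform. Group averaging is the
element-wise mean followed by re-normalisation. On disk a blueprint is a TSV
matrix plus a JSON sidecar carrying row identities, tract classes, the
normalisation flag and the flagged-row vector.

## Divergence mapping

Patterns are compared with the symmetric KL divergence in bits. Both
patterns are shifted by δ = 10⁻⁶ and re-normalised to sum to one before the
divergence; the shift avoids degeneracies at zeros, and the re-normalisation
makes the compared patterns proper distributions (recorded in output
metadata). The reference pattern of a region is the *mean* of its unflagged
normalised rows. Best-match identification takes the candidate region with
the lowest median divergence (median of an even-sized region is the mean of
the two central values); the specificity contrast is the best non-matching
median minus the matching median. Tract subsets (all / cortico-cortical /
cortico-subcortical) select columns before the δ-shift, so a subset
restriction changes values only through the selected columns. Percentile
thresholding of divergence maps uses the nearest-rank definition (with an
epsilon guard so that exact multiples are not pushed up a rank by floating
point).

## Similarity and group statistics

Pairwise tract similarity thresholds both subjects' normalised path
distributions at 0.5%, correlates them over the **union** of the surviving
supports, and averages Pearson r across tracts. Union rather than
intersection support preserves sensitivity to non-overlap (two disjoint
tracts anticorrelate rather than being undefined); this choice is recorded
in output metadata. Tracts with fewer than three surviving voxels, or with
no valid streamlines in one subject, are excluded with a warning; a pair
with no usable tract at all is dropped from cohort analyses with a warning.

Group comparisons use the two-sided Mann–Whitney U test: exact enumeration
of all group reassignments (midranks handle ties) when both groups have at
most eight members, the normal approximation with tie and continuity
correction otherwise; Bonferroni adjustment multiplies by the number of
comparisons and caps at 1.

Tracer-style termination maps count termination sites per nucleus voxel and
divide by the group total (so each group's map sums to one before
smoothing), then smooth with a separable cubic B-spline kernel
([1, 4, 1]/6 per axis), clipping negative ringing at zero. Topographic
orderings project mass-weighted centroids onto a supplied axis.

## The phantoms

The phantom layout is specified in fractional grid coordinates so one
topology renders at any resolution. Two default "species" are shipped:
48×56×40 voxels at 1.0 mm and 40×44×32 at 0.5 mm — large enough for
medial/lateral bundle separation and distinct putamen sectors, small enough
that a full two-species blueprint analysis runs in seconds. Bundles are
tubes (radius 1.9 mm / 0.85 mm) around cubic-spline centrelines; in-tube
voxels get the local tangent as a population mean with volume fraction
0.22–0.55 falling off quadratically from the axis. Where tubes overlap, the
three largest-fraction populations are kept (excess simply dropped, no
re-normalisation) and fractions are scaled to sum to at most 0.95.
Orientation samples rotate the mean by an angle drawn uniformly in
[0, 10°] about a uniform random perpendicular axis — bounded, simple, and
sufficient to make tracking genuinely probabilistic.

The layout encodes the organisation the analyses probe: the four StB parts
terminate in putamen sectors ordered parietal → sensorimotor → frontal →
temporal along a dorsolateral→ventromedial axis (sectors are the Voronoi
cells of the tube terminals within the putamen; the generator asserts the
centroid ordering); StBf runs medial to EmCf; MB arcs above the caudate,
dipping through the head between its seed and target so its valid-streamline
path distribution genuinely intersects the caudate; the AC passes through
the amygdala (its revision enhances amygdala connectivity); the FX arcs
posteriorly over the caudate tail to a medial target; the ATR rises anterior
to the caudate head from the thalamus; the four cortico-cortical reference
bundles give frontal test zones distinct fingerprints (dmPFC: CING+ATR;
vmPFC: CING+AMF; OFCr: UF+StBf; FOp: EmCf) and clip the putamen and
hippocampus edges so the cortico-cortical tract subset is not fully
degenerate in the subcortex.

Twin cohorts perturb a base field with smooth random rotation-vector and
fraction-gain fields (coarse Gaussian noise, trilinearly upsampled; rotation
scale 9°, fraction jitter 12%). Pair members receive
`w·N_pair + √(1−w²)·N_subject`, with the shared weight w encoding the
relationship: 0.9 for monozygotic twins, 0.45 for dizygotic twins and
non-twin siblings (identical by construction, so their comparison is a true
null), 0 for unrelated pairs. These effect sizes are free parameters chosen
once so that the expected ordering MZ > DZ ≈ SIB > UNREL is detectable at 20
pairs per group with two tracts per subject; no published effect sizes exist
to match. Cohort analyses use a small dedicated two-bundle phantom
(20×22×16) with thick end-slab targets, because subject-level field
perturbations displace trajectories by a couple of voxels and ribbon-thin
targets would confound perturbation strength with target misses.

**What the phantoms do not emulate:** raw diffusion signals, scanner noise,
crossing-fibre model estimation error, registration misalignment, gyral
folding (the "cortex" is a box shell; the gyral bias that motivates the
intermediary-matrix construction for cortical rows is not itself present),
partial-volume fraction profiles of real tissue, or anatomically accurate
mask geometry. Passing tests therefore demonstrate that the *algorithms*
implement their definitions and recover structure a clean, known substrate
encodes — not that the protocols delineate tracts correctly in real brains.

## Scale of the shipped analyses

The test and acceptance suites run the full pipeline at reduced sampling:
40 seeds per voxel for protocol tracking, 10 tracking seeds for homologue
recovery and variant comparisons, 20 seeds for topography/positioning, and
20-pair groups for twin cohorts. These sizes give comfortably separated
statistics on the phantoms (divergence contrasts of tens of bits; twin
p-values around 10⁻⁵) while keeping a complete run in minutes on one CPU.

## Known limitations

* Nearest-voxel field lookup quantises trajectories at sub-voxel scale;
  tracking across grids of very different resolution requires choosing the
  step relative to the voxel size (half a voxel here).
* The amygdalofugal protocol's validity is one-directional (seed → genu
  plane), so its path distribution does not reach the amygdala on the clean
  phantom; the AC carries the amygdala's blueprint signal instead, and the
  AMF is not assigned a terminal nucleus in variant-specificity analyses.
* Exact Mann–Whitney enumeration grows combinatorially; the ≤ 8 cutoff keeps
  it under 13 000 assignments.
* Blueprint rows are voxel-wise one-hot-dominated on a clean phantom, which
  makes divergence contrasts larger than anything expected of real data;
  contrast magnitudes should be read as qualitative orderings only.
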
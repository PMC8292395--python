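# Methods

## Background and scope

Epithelial cells on a cyclically stretched elastic substrate reorient
perpendicular ("transverse") to the stretch axis. Time-lapse analysis of
this process localizes the driving events to the *relaxation phase* of each
cycle: immediately on release of stretch the cell retracts around its whole
perimeter, and during the remainder of the relaxation it extends — at a
persistent rate in the transverse quadrants and at a rate that decays with
accumulated stretching in the axial quadrants. Reorientation is the
cumulative result of these per-cycle events, not of a continuous rotation.

`cyclostretch` implements both sides of such an experiment in software:

* **synthetic data** — a generator for single-cell binary mask time courses
  under a programmable stretch protocol, plus rendered fluorescence images
  of the square fiducial grid printed on the gel;
* **analysis** — fiducial-grid strain recovery, per-frame morphometrics
  (moment-ellipse orientation index, bounding-rectangle lengths, spreading
  area), difference-imaging quadrant analysis, and an orchestration
  pipeline with population statistics.

Masks are the analysis atoms: segmentation of real micrographs is out of
scope (outlines were traced manually in the original workflow), as are
traction-force microscopy and statistical hypothesis testing.

## The per-cycle cell model

One cycle consists of a stretch window and a relaxation window. The model
treats the cell as passive while the substrate is stretched (difference
images during stretching show only baseline activity), so `during_stretch`
frames are purely the affine image of the current mask. The active events
are:

1. **Release retraction.** An area fraction
   `r(n) = r0 · exp(−(n−1)/r_decay)` of the current spreading area is
   removed at cycle `n` as a uniform perimeter peel (foreground pixels
   sorted by their Euclidean distance to the background, shallowest
   removed first). Retraction is quadrant-independent by construction.
2. **Relaxation protrusion.** Area is added during the relaxation window
   at rate `p_T` (constant over cycles, split between the two transverse
   quadrants) and `p_A(t) = p_A0 · exp(−t/p_A_tau)` with `t` the cumulative
   stretching time (split between the axial quadrants). Protrusion is a
   directional boundary dilation: background pixels nearest the current
   edge are annexed first, restricted to a cone of half-angle
   `protrusion_cone_deg` (default 20°) about the quadrant axis. The cone —
   strictly inside the ±45° quadrant sector — keeps the growing lobes
   spindle-like; without it, growth fans out to the diagonals and inflates
   the *axial* bounding length of a transversely elongating cell.

The exponential forms of `r(n)` and `p_A(t)` are the minimal smooth
formalization of a response that is strong at the first cycle and decays
rapidly with further cycling; no published rate equations or magnitudes
exist for these quantities, so the defaults below are calibrated to
reproduce the qualitative response structure, not fitted values.

Boundary roughness (`noise_sigma`, µm) perturbs the distance ranking used
by both operators, which roughens where pixels are taken or deposited
without changing the target areas. Every realized pixel count is logged, so
the ground-truth table satisfies exact mass bookkeeping:
`Δarea = protrusion − retraction` per cycle.

Degenerate cases: a retraction that would empty the mask raises
`DynamicsError`; stray single-pixel islands created by noisy selection are
dropped by a largest-component filter and charged back to the logged areas;
masks are validated to stay single 4-connected components away from the
frame border.

## Compressed schedule and presets

A real 90-minute run at 0.5 Hz is 2 700 cycles. The pipeline instead
samples the checkpoints {0, 5, 15, 30, 45, 60, 90} min and simulates each
interval as **one effective cycle** (release + relaxation); preset rates
are therefore *per second of elapsed interval time*, and the retraction law
is indexed by effective cycle. This keeps a 6-cell condition under ~3 s on
one CPU while preserving the structure of the response; the per-cycle
engine (`simulate_timecourse`) remains available for uncompressed runs at
arbitrary protocols.

Default geometry: cell radius 25 µm with relative boundary irregularity
0.15, 0.5 µm/pixel, 512×512 frames.

Preset parameter sets (chosen once; orderings are the content, magnitudes
are model choices):

| condition | r0 | r_decay | p_T (s⁻¹) | p_A0 (s⁻¹) | p_A_tau (min) |
|---|---|---|---|---|---|
| control | 0.10 | 1.3 | 1.2e−4 | 2e−5 | 5 |
| blebbistatin | 0.005 | 1.3 | 1e−5 | 4e−5 | 30 |
| nocodazole | 0.14 | 1.3 | 1.7e−4 | 2e−5 | 3 |
| nocodazole + blebbistatin | 0.003 | 1.3 | 5e−6 | 5e−5 | 45 |

Control reproduces: monotone approach of the population orientation index
toward transverse alignment; axial shortening concentrated in the first
half of the run; persistent transverse elongation; spreading area dipping
at the first checkpoint and recovering later. Blebbistatin (myosin II
inhibition) suppresses retraction and transverse protrusion, leaving slow
sustained axial extension — the population index ends on the axial side of
control. Nocodazole (microtubule depolymerization) enhances retraction and
transverse protrusion, ending at least as transverse as control. The
combined preset amplifies the blebbistatin pattern.

Because the orientation index depends only on the fitted-ellipse *angle*,
individual simulated cells saturate near ±1 once their deterministic
elongation exceeds the random initial irregularity; population means
therefore approach the extremes faster than real populations, whose
cell-to-cell variability is far richer. This, the exaggerated late-run
transverse growth (the constant `p_T` acts over every simulated second),
and the perfectly elastic affine substrate are the main idealizations to
keep in mind when reading passing tests: they validate the analysis chain
and the response structure, not biological magnitudes.

## Micropattern generator and strain analysis

The fiducial grid is a 6×6 array of 50 µm squares at 100 µm pitch
(default). Each square is filled with a 1 µm bead lattice (inset 0.4 µm,
chosen so the detected square side equals the printed 50 µm at the default
raster); bead positions are mapped by the affine substrate strain about the
pattern center, perturbed by Gaussian localization noise
(`bead_noise_sigma`), and rendered as σ = 0.4 µm Gaussian spots. The canvas
is sized for strains up to 25%.

`detect_grid` thresholds with Otsu's method, labels components, rejects
border-touching components and components deviating >50% from the median
area, and reports per-square centroids and axis-aligned extents. Rows and
columns are recovered by 1-D gap clustering of the centroid coordinates
(split at gaps larger than one square side — safe up to the 20% strain the
device supports).

Strain is **pitch-based**: `eps = Δpitch/pitch_ref` per axis, from
center-to-center spacing. Centroid spacing is insensitive to the threshold
level, whereas the apparent side length shifts with it; side lengths are
still reported for cross-checks. Residual strain is the same computation on
a before/after-relaxation pair and is quoted as a magnitude percentage.
The default substrate anisotropy (transverse/axial ratio 0.15, Poisson-like
contraction with configurable sign) reproduces a measured transverse/axial
strain ratio ≤ 16% and an axial/transverse ratio ≥ 6, and two independent
noise draws of a relaxed grid measure a residual strain orders of magnitude
below the 0.72% elasticity bound.

## Morphometrics conventions

* **Ellipse fit**: the moment-equivalent ellipse of the filled mask (same
  area-normalized second central moments); full axes `4√λ` of the moment
  eigenvalues. For eccentricity < 0.01 the angle is undefined and reported
  as 0 by tie-break.
* **θ and cos 2θ**: θ is measured from the stretch axis, wrapped into
  (−90°, 90°]. Two published conventions exist — index +1 for a cell
  parallel to stretching (definition used here by default) and the
  sign-flipped version measured from the transverse direction (used in
  some time-course plots). Both are exposed via the `reference` argument of
  `orientation_index`; all internal tables use the stretch-axis reference,
  so transverse alignment is negative.
* **Rectangle lengths**: the stretch-axis-aligned bounding rectangle, since
  the lengths are read "along the axial and transverse directions"; not the
  minimum-area rotated rectangle.
* **Quadrant partition**: ±45° diagonals through the foreground centroid of
  the *earlier* frame of each pair; diagonal ties and the centroid pixel go
  to the axial sectors (on an ideal centered disc this biases the axial
  sectors by a few percent of a quadrant — real centroids are generic and
  tie-free).
* **Normalization** of quadrant changes: mean spreading area of the two
  frames of the pair by default (`pair_mean_area`); `initial_area` is
  selectable, reflecting the two phrasings of the published normalization.

Because the compressed schedule uses intervals of different lengths, the
extension-phase quadrant values scale with the interval; the invariant
"transverse extension is constant while axial extension decays" holds for
the extension *rates* (value per second of relaxation window). In the
uncompressed per-cycle mode, extension is conventionally measured over a
10 s window with cycling halted; with the constant-rate transverse law the
actual 1 s relaxation phase accrues exactly 10% of such a measurement
(`relaxation_fraction_check`).

## Determinism and numerics

One root seed drives everything: per-cell streams are spawned with
`numpy.random.SeedSequence`, and every selection noise draw comes from the
per-cell stream. Identical configurations produce bitwise-identical frame
stacks and CSV tables (hash-checked in the tests). Affine resampling is
bilinear with re-binarization at 0.5 for masks, making
`apply_substrate_strain` invertible to within ~1 pixel (round-trip Jaccard
> 0.98 at 15% strain). Area targets are rounded to whole pixels, so
rate-law checks carry a rasterization tolerance (5–10%) while conservation
identities (difference-map quadrant sums) are exact in pixels.

## Problem sizes

Default test and acceptance runs use 6 cells × 7 checkpoints at 512×512,
6×6 fiducial grids at ~1500×1500, and ≤64×64 masks for the exhaustive
brute-force property checks. The full test suite runs in well under a
minute; the acceptance script in a few seconds.
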
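# Methods

This note documents the measurement definitions, processing conventions,
statistical procedures, and the synthetic-data model implemented by
`apicaltrack`, together with the design choices made where several
reasonable conventions exist.

## Measurement model

A segmented frame is an integer label image in which 0 marks the 1-pixel
boundary skeleton (and background) and k ≥ 1 marks cell k. Two apical
domains are derived per cell:

* **medial domain** — the cell region eroded by one pixel with the 3×3
  (8-connected) structuring element. The 3×3 element was chosen because a
  "one pixel constriction" is ambiguous between 4- and 8-connectivity; the
  8-connected erosion matches the visual convention of the common tracking
  tools and is stated here as the contract. Cells too thin to survive
  erosion are flagged degenerate and their medial quantities reported
  missing, never zero.
* **junctional domain** — every skeleton pixel 8-adjacent to the cell
  region, including vertex pixels. Domain intensity is the arithmetic mean
  of the channel over the domain (total fluorescence / area), and the
  apical pixel area is the medial pixel count.

Pairwise junction pixel sets (skeleton pixels 8-adjacent to both cells)
exclude vertex pixels — skeleton pixels touching ≥ 3 cells — so that no
pixel is attributed to two different junctions. The per-cell junctional
domain keeps vertices, because a cell's junctional belt is a closed ring.

Junction z-offsets are looked up in an optional z-stack: each junction
endpoint's depth is the argmax along z at that pixel, with ties resolved to
the smallest z (deterministic); `delta_z_micron` is the absolute depth
difference times the z-step. When a junction has more than two vertex
pixels, the most distant pair is taken as its endpoints.

## Preprocessing

Pipeline order is fixed and logged: **mask → filter → smooth → standardize**
for fluorescence; geometry is never masked, so cells stay tracked through
imaging anomalies (e.g. a frame range with a transient fluorescence drop is
masked for intensities only).

* **Track filters.** Cell tracks shorter than 30 frames and junction tracks
  shorter than 15 frames are discarded; the boundary lengths themselves (30
  and 15) are kept. Removal counts are logged per stage.
* **Smoothing.** Centered 7-frame moving average. At track ends the window
  is truncated to the available ±3 neighbors rather than trimming three
  frames per end, so the smoothed series spans the whole track. Masked
  frames contribute nothing to any window and remain missing afterwards.
* **Standardization.** Per-track mean-centering and division by the track's
  own standard deviation, computed over usable (unmasked) frames only, with
  the sample (n−1) denominator — stated here and held fixed; delta
  statistics are scale-consistent under either denominator choice. Tracks
  with fewer than two usable frames or zero spread are flagged degenerate
  and emitted all-missing (never a division by zero).
* **Units.** Lengths scale by the per-embryo `microns_per_pixel` s, areas by
  s². Corrected junction length is the Euclidean hypotenuse
  √(ℓ² + Δz²) — the unique choice that restores the 3D chord length from
  its 2D projection.

## Orientation conventions

Junction orientation is the angle between the junction chord and the
embryonic ML axis, folded into [0°, 90°] (0 = ML-aligned, 90 = AP-aligned);
it is invariant to endpoint order and, when the per-embryo axis angle is
rotated together with the coordinates, to image rotation. Junctions with
mean orientation < 45° are classified AP, ≥ 45° ML; exactly 45° resolves to
ML because the source convention defines only strict inequalities and the
boundary has measure zero in continuous data.

## Genotype calling and mosaic handling

Genotype is a lineage property, so each cell track receives one call from
its track-mean medial membrane-BFP score: crispant iff score ≥ threshold.
Threshold precedence: per-embryo manual override (authoritative, since real
studies threshold each embryo by eye) → automatic between-class-variance
(Otsu) split of the log₁₀-score histogram at 256 bins. The automatic split
is accepted only if it looks genuinely bimodal: both classes must hold ≥ 2%
of cells and the Ashman-style separation |μ₁−μ₀|/√((σ₀²+σ₁²)/2) of the
*linear*-intensity classes must exceed 3.5 (an Otsu split of a single
Gaussian yields ≈ 2.7; two modes 5 s.d. apart yield ≫ 5). Otherwise the
embryo falls back to all-control with a warning, and the run manifest
records which path was used. Manual per-track overrides are applied last.

Neighbor genotype counts partition each cell's per-frame neighbor set;
a cell is **interface-flagged** if it ever had an opposite-genotype
neighbor, and junction status follows its two flanking cells
(control/control, crispant/crispant, otherwise "at mosaic interface").
Interface cells and interface junctions are excluded from every statistical
comparison by default (flag-only exclusion: records stay in the tables).

## T1 detection

A stable neighbor exchange is recorded when the adjacency of a cell pair
(A, B) that had been stably present ends in an absence lasting ≥ `k_stable`
frames, and within ±`pair_window` frames a pair (C, D) of common neighbors
of A and B gains adjacency that also persists ≥ `k_stable` frames. Defaults
`k_stable = 5` (≈ 5 min) and `pair_window = 3` (tolerating the transient
4-fold vertex) are documented, configurable defaults — the stability
criterion used by the original tracking tools is unpublished, so
sensitivity to `k_stable` should be reported rather than assumed. Requiring
the preceding run (presence before a loss, absence before a gain) to be
stable as well suppresses flicker echoes: a 2-frame contact flicker
produces no event. Each event increments the stable-exchange count of all
four cells, so per-cell counts sum to 4× the event count.

## Statistics

* **Two-sample KS.** D is computed by a scan over the pooled sorted values
  with right-continuous ECDFs (exact under ties); p comes from the
  asymptotic KS distribution at effective size n_a·n_b/(n_a+n_b).
* **Peacock 2D KS.** D maximizes the empirical quadrant-fraction difference
  over the four quadrant orientations anchored at candidate origins.
  `full_grid` mode (default) scans the full pooled-x × pooled-y grid;
  `sample_origins` restricts to the pooled data points and is never larger.
  Quadrants use closed lower half-planes (x ≤ x₀, y ≤ y₀); cumulative
  counts give all four orientations by inclusion–exclusion. Because the
  finite-sample null of D is awkward, p-values default to label permutation
  of the pooled sample with p = (#{D* ≥ D} + 1)/(n_perm + 1), n_perm = 999,
  explicit seed. Both the variant and the p-value mode are recorded with
  every result.
* **Pearson.** r and the t-distributed p (n−2 d.o.f.) plus the
  least-squares line, via the standard scipy routines.

No multiple-testing correction is applied anywhere, matching common
practice for these figure-by-figure comparisons.

## Synthetic data model

The generator stands in for deposited tracking data; it aims to reproduce
the *statistical structure* of such datasets, not any real embryo's
numbers.

* **Geometry.** A jittered hexagonal lattice is tessellated by Voronoi into
  n shared-vertex polygonal cells. Per frame, each cell's target area
  follows its regime ramp and vertices relax toward the targets by gradient
  steps on the squared area residual plus an edge-length spring
  (regularization toward rest lengths scaled with the local target-area
  ratio). This is deliberately *not* a force-balanced vertex model: the
  artifact needs kinematically consistent tracked geometry (areas, lengths,
  orientations co-varying), not tissue mechanics.
* **Regimes.** Anterior-like controls constrict gradually (default −50%
  area across the movie); anterior-like crispants are dilation-biased (70%
  dilate by +35%, the rest constrict weakly). Posterior-like sheets are a
  mixture: 60% constrict late and rapidly (onset at 75% of the movie),
  the remainder drift/dilate (+15%). Amplitudes are fractional area
  changes — target areas must live in area units for the relaxation to be
  well-posed; the per-track s.d.-scale deltas emerge downstream.
* **Intensities.** Channel intensity = baseline + c·(−z_A(t)) + AR(1)
  noise, where z_A is the cell's realized standardized area and the
  coefficient c is calibrated so that the configured target correlation is
  realized *on the smoothed series the analysis sees*: a centered w-frame
  mean retains fraction (w + 2Σ(w−k)ρᵏ)/w² of AR(1) noise variance while
  leaving the slow area signal essentially intact, so
  c = |r|·σ_smoothed/√(1−r²). Defaults: anterior-control couplings −0.7
  (medial actin), −0.5/−0.6/−0.4 (junctional actin, medial/junctional
  N-cadherin); near-zero N-cadherin coupling in posterior-like and
  anterior-crispant regimes. These mirror the qualitative contrasts of the
  biology but are configuration, never asserted as truth. AR(1) ρ = 0.8 by
  default so 7-frame smoothing is exercised meaningfully.
* **Tracer.** Membrane-BFP is constant per lineage, drawn from
  N(100, 50) for controls and N(1000, 50) for crispants (floored at 1),
  plus small per-frame noise; the mosaic is a half-plane of the initial
  centroid x-coordinate, so a genuine interface exists.
* **Scripted T1s.** At configured frames the most central eligible interior
  edge is collapsed and re-expanded orthogonally (A, B lose adjacency;
  their common neighbors C, D gain it); ground truth records the four cells
  and the frame.
* **Rendering.** Polygons are rasterized to a label image; pixels
  4-adjacent to a different cell become the 0-valued skeleton. Channels are
  painted with the tabulated per-domain means (cell interiors take the
  medial value; each skeleton pixel the mean of its adjacent cells'
  junctional values), and the realized per-cell painted means are recorded
  by direct pixel enumeration for closure tests.

**What the generator does not emulate:** segmentation error and track
breakage, cell division/extrusion, pulsatile (sub-minute) contractility,
spatial intensity gradients within a domain, bleaching, and mechanical
force balance. Passing recovery tests therefore demonstrates that the
pipeline measures what it claims on clean tracked data of the right
statistical shape — not that it is robust to segmentation artifacts.

## Numerical choices and degenerate inputs

Standardization tolerance in validation is 1e-9 on the track mean and s.d.
Quadrant fractions place zero deltas in the non-negative quadrant (ties are
measure-zero in continuous data). Peacock's degenerate fast path (all
points identical in both samples) returns D = 0. Missing values are
serialized as empty CSV cells and parsed as missing (literal "NA" is also
accepted), never as zero, so masked fluorescence cannot bias means; floats
are written at full round-trip precision, making write → read → write a
byte-level fixed point.

## Problem sizes

Default test and acceptance runs use 300 cells × 60 frames for cohort
recovery (one embryo-scale movie), 200 random instances (n ≤ 40) for
statistic-oracle agreement, 500 null simulations at n = 50 per sample with
999 permutations for calibration, and 40-cell movies for T1 scripting.
These sizes give stable estimates (binomial s.e. of a 5% rate at 500 sims
is ≈ 1%) while keeping a full run in minutes on one core.

## Known limitations

The Peacock permutation p is exchangeable-null exact but costly for very
large samples; use `sample_origins` mode or subsample there. Automatic
genotype thresholds are a stand-in for per-embryo manual thresholds and
must be reviewed via the manifest. The T1 detector assumes contiguous
adjacency series from a tracker without identity switches; it does not
resolve rosettes (> 4 cells) and treats them as overlapping pairwise
events.
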
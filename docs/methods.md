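# Methods

## Scope and measurement model

`calwave` quantifies evoked intercellular calcium waves in acute-slice
time-lapse recordings and the 3-D morphology of the astrocytes that carry
them, and compares two experimental groups (a control group and a treated
group, labelled CTL and VPA throughout) with the normality-gated statistics
typical of slice physiology.  Every stage can be exercised against
simulated data in which the "true" answer is planted, so correctness is
established by recovery rather than by visual inspection.

### Wave quantification

A movie is a T x H x W stack acquired at a fixed frame interval (default
1 s over 200 frames) with electrical stimulation delivered after a
pre-stimulus window (default 15 frames).  The pixelwise mean of the
pre-stimulus frames is the basal fluorescence F_b, and every trace is
normalised as dF/F = (F − F_b)/F_b.  By construction the pre-stimulus
dF/F of any ROI averages to exactly zero.

An ROI is *recruited* when its dF/F stays at or above
`threshold_k x SD(pre-stimulus dF/F)` for at least `min_frames`
consecutive frames at some t >= the stimulus frame; the activation frame
is the first frame of the first such run.  Defaults: `threshold_k = 2.5`,
`min_frames = 3`.  Three frames of persistence (rather than two) is used
because with ~70 ROIs x ~185 post-stimulus frames a 2.5 SD threshold held
for only two frames produces roughly one spurious run every other movie,
and a single false early activation on the farthest cell corrupts t1 and
can make the speed undefined; the third frame cuts the false-run rate by
two orders of magnitude and introduces no timing bias, because the
activation frame is the run's first frame.  When the pre-stimulus SD is
exactly zero (noiseless input) an absolute floor `dff_floor = 0.2` is
used.

Geometry: each ROI's distance from the stimulation site is the 2-D
Euclidean centroid distance in µm, binned into half-open concentric rings
[50k, 50(k+1)) µm — a cell at exactly 50 µm belongs to ring 1.  Per slice
the package reports recruited cells per ring, the maximum length (largest
recruited-cell distance), the wave speed
`max_length / (t1 − t0)` with t0 the earliest post-stimulus activation
time and t1 the activation time of the cell at maximum length (earliest
among ties, so the denominator is never shrunk), the mean peak amplitude
(peak raw dF in a.u.; peak dF/F is also recorded), and the trapezoidal
area under the post-stimulus dF/F curve.

A caveat worth knowing: speed as defined is a ratio estimator that
overestimates the underlying propagation speed by the factor
d_max/(d_max − d_0) when the nearest recruited cell sits at distance
d_0 > 0 from the electrode, because the travel time to the first cell is
not observed.  With dense recruitment near the site (the default
simulation condition) the bias is a few percent; with sparse inner
recruitment it can reach ~15%.  The estimator is kept as defined because
it is the field's definition; recovery tests quantify the error instead
of hiding it.

ROI detection operates on the maximum post-stimulus dF/F projection,
smoothed at half the expected cell radius; local maxima exceeding the
background median by `detect_noise_k = 5` robust SDs (1.4826 x MAD)
become centroids with disk masks, overlaps resolved by nearest-centroid
assignment so ROIs are always disjoint.  Detection is deterministic.  A
CSV of centroids can be injected instead, bypassing detection entirely —
the recovery tests use this to separate detection error from
classification error.

### Co-labeling

Astrocytes are identified on a static second channel (systemic red-dye
staining).  The channel is thresholded with Otsu's method — invariant to
positive rescaling, empty with a warning on a constant image — and an ROI
is co-labeled when at least `min_overlap = 0.5` of its pixels fall in the
foreground.  Per slice the package reports co-labeled fractions of the
reference and recruited populations and per-ring recruited-and-co-labeled
counts, which partition the recruited counts exactly.

### Morphometrics

Cells in a confocal z-stack are segmented as 26-connected components
above an intensity threshold (the pipeline defaults to half the intensity
range, which recovers the pre-blur surface of a blurred binary object;
plain Otsu is available).  Volume is voxel count x voxel volume, with
per-axis scaling for anisotropic voxels.  Each component is thinned to a
medial-axis skeleton and converted to a voxel graph; branchpoints are
connected clusters of degree >= 3 voxels (adjacent junction voxels count
once), branches are the paths between terminals, and terminal spurs
shorter than `prune_length` (default 2 voxels) are removed iteratively.

Branch length is measured by chord sampling: the Euclidean distances
between every 3rd voxel along the path are summed (with the raw step sum
used for very short paths).  The conventional 1/sqrt(2)/sqrt(3) step sum
overestimates oblique straight branches by 6–8% (digital zig-zag), enough
to push recovered group means visibly off their planted values; chord
sampling recovers planted branch lengths to ~2% while still following
genuine curvature at the ~2-voxel scale.  The per-cell "branch length" is
the mean over branches by default; the total is also reported.

Soma density is counted in fixed 50 x 200 µm visual fields with half-open
bounds (a centroid on the max edge is excluded), matching the counting
convention used for the density comparisons.

### Statistics

Each metric is summarised per group as mean ± SEM (SD with n−1
denominator over sqrt(n); SEM is NA for n = 1).  Normality of each group
is tested with Shapiro–Wilk (n >= 3 required); if both groups have
p > alpha (default 0.05) the groups are compared with a two-sided t test
— Welch by default, since equal variances are rarely defensible; the
pooled Student form is available by flag — otherwise with a two-sided
Mann–Whitney U (exact when both n <= 20 and tie-free, tie-corrected
normal approximation otherwise).  Which test ran is a pure function of
the two Shapiro p-values and alpha, and is recorded alongside all
intermediate p-values.  Significance is strict (p < alpha); p = alpha is
flagged not significant.  Effect sizes are integer percent changes of the
treated group versus control, rounded half away from zero.  No
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists).  Western-blot densitometry divides each target band's
optical density by its loading-control band and rescales so the control
group mean ratio is 1.

The unrounded percent change satisfies
pc(c, v) = −pc(v, c) · v/c, equivalently
(1 + pc(c, v)/100)(1 + pc(v, c)/100) = 1; the rounded form does not.

## Synthetic data

The movie simulator is the package's ground-truth oracle, not a rendering
toy; its defaults are the study conditions the analysis assumes.

- Protocol: 200 frames at 1 Hz, stimulus after frame 15; 160 x 160 px at
  2.5 µm/px (a 400 µm field) with the stimulation site at the centre;
  120 cells of 5 µm radius placed uniformly with minimum centroid
  separation 2 x radius (rejection sampling), so ROIs stay resolvable.
- Recruitment: per-ring probabilities (defaults 0.9, 0.8, 0.6, 0.4, 0.2
  by 50 µm annulus; the last entry extends outward).  A recruited cell at
  distance d activates exactly at stimulus onset + d/v (default
  v = 27.3 µm/s), so planted activation times are consistent with the
  planted speed before frame quantisation.
- Transient: f(t) = A(1 − e^(−t/τ_rise)) e^(−t/τ_decay), normalised to
  unit peak so the planted amplitude is exactly the peak; τ_rise = 2 s and
  τ_decay = 10 s are plausible for a slow green calcium dye sampled at
  1 Hz and slow enough that a 1 Hz protocol resolves the rise.  Peak
  amplitude decays as A·e^(−d/λ) with λ = 150 µm, reproducing transients
  that shrink with distance from the stimulation site.
- Noise: additive Gaussian per pixel per frame (default SD 3 a.u. on a
  baseline of 100 a.u.).  Photobleaching, motion, optics/PSF and shot
  noise are deliberately not modeled; passing recovery tests therefore
  demonstrates correctness of the measurement chain, not robustness to
  those real-data artifacts.
- Co-label channel: a static image with bright disks at co-labeled cells
  (each cell co-labeled independently with `colabel_prob`).
- Stimulus electrical parameters (20 pulses, 200 µA, 10 Hz) are carried
  as metadata only.
- Determinism: a single integer seed fixes every output byte; experiments
  derive per-slice seeds by hashing (seed, group index, slice index)
  through NumPy's SeedSequence, so slices are independent and
  reproducible in any order.

Morphology phantoms are capsule-voxelised tube trees (voxel centres
within the tube radius of any generating segment) plus spheres: cylinder
(0 branchpoints), Y tree (1 branchpoint, 3 branches), H tree
(2 branchpoints, 5 branches), and random trees whose topology is grown by
spawning branch pairs at tips, so branch and branchpoint counts are known
by construction.  Tube radii below ~2 voxels are avoided for the
deterministic phantoms: 3-D thinning of a quasi-planar 2-voxel slab can
retract entire arms before they become endpoint-protected curves,
destroying the planted topology (observed on the H phantom at
radius 1.5 µm / 1 µm voxels).

Group phantom sets ("CTL-like": 5 branches of mean 29.5 µm, mean volume
1188 µm³; "VPA-like": 6 branches of mean 39.3 µm, mean volume 1690 µm³)
calibrate the tube radius in two passes: the analytic
r = sqrt(V/(pi·L_total)) start is rescaled once so the mean realized voxel
volume of the actual generated trees hits the target, absorbing the
orientation- and offset-dependent discretisation of the tube
cross-section (up to ±20% at ~2-voxel radii) and junction overlap.

## Problem sizes

Recovery statistics are computed at sizes chosen to give stable Monte
Carlo estimates while keeping the default test run quick: 50 movies for
speed/ring recovery, 100 seeds for co-label CI coverage, 100 replicate
null experiments (10 slices per group each, on 64 x 64 px movies with
ground-truth ROI injection), and 14 cells per group for morphology
recovery.  The per-seed substreams make any of these reproducible in
isolation.

## Known limitations

- Touching cells merge under connected-component segmentation; no
  watershed splitting is attempted.
- Channel alignment is assumed exact; there is no registration.
- No motion/bleach correction, spike deconvolution, Sholl or
  territory analysis.
- The null-calibration property (null experiments non-significant in
  >= 95% of seeds) sits exactly on the type-I error rate of the gated
  test: with a test of size alpha = 0.05 the expected pass rate of the
  95% bound is itself ~50–60% in any finite replicate set, and only the
  slight conservatism of the tie-corrected Mann–Whitney branch provides
  margin.  Measured sizes over 300 replicates are 5.3% (recruited count)
  and 3.7% (max length), i.e. the workflow is correctly calibrated.
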
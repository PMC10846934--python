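# Methods

`expalm` implements the quantitative analysis stages of a combined
expansion-microscopy + PALM experiment in fission yeast: single-molecule
localization tables are drift-corrected, their average localization
precision is estimated (NeNA), super-resolution images are reconstructed,
and the expansion is characterized by macroscale size ratios
(expansion factor), fluorescent-signal retention, and a microscale
isotropy statistic.  Because such studies typically do not release raw
image data, the package ships a first-class synthetic generator whose
parameter-recovery behaviour is the package's verification surface.

## Conventions

Coordinates are continuous nanometre positions in a Cartesian frame with
the origin at the top-left corner of camera pixel (0, 0); the centre of
raster pixel (r, c) at pixel size p is ((c+0.5)p, (r+0.5)p).  Frames are
0-based and all ranges half-open.  Everything is 2-D: the emulated
experiments image a single focal plane, and all implemented statistics
(widths, nearest-neighbour distances, drift) are planar.

## Synthetic data (`expalm.synth`)

A cell is a 2-D spherocylinder (default width 2.4 µm, length 8 µm —
a typical interphase fission-yeast cell — with an optional 2.36 µm
nuclear disk excluded from the cytosolic distribution).  Molecules are
uniform over the interior and blink in frame-contiguous bursts: bursts
per molecule are geometric, burst length is geometric with mean
`on_time_frames`, and burst placement is uniform over all positions that
overlap the movie, so emitter occupancy is stationary from frame 0.
(Placing burst *starts* uniformly inside the movie instead produces a
density ramp over the first ~on-time frames; with long-lived emitters
the sparse early frames then dominate the error of any integrating drift
estimator, an artefact of the generator rather than of the estimators.)
The observed position is the molecule's true position plus the frame's
drift (shared by all molecules, as for physical stage motion) plus i.i.d.
Gaussian noise of sd `sigma_loc` per axis.  Defaults emulate the study
conditions: `sigma_loc` 14 nm for non-expanded and 26.5 nm for expanded
samples, movies of 3000 frames.  Blinking statistics for mEos2 are not
published; the defaults (about 3 localizations per molecule in bursts of
1–2 frames) are placeholders constrained only by the generator's own
invariants (containment, emission counts, determinism), and individual
analyses choose the blinking regime that represents their marker (see
below).

Expansion is a uniform scaling about the cell centre.  Optional
distortion adds a smooth displacement field: per axis, the sum of K = 4
random sinusoidal modes with wavelengths drawn from [L, 2L], recentred
and rescaled so the displacement magnitude has zero mean and a requested
RMS over the expanded points.  The wavelength floor L is the
*unexpanded* cell length: the field emulates gel inhomogeneity that is
structured at the specimen scale, which after ~5x expansion produces the
local strain (tens of percent) that microscale-isotropy screening is
meant to catch.  A field with wavelengths at the *expanded* cell scale
produces almost pure affine strain inside one cell and is nearly
indistinguishable from isotropic rescaling by any density-matched
statistic.

Spot stacks render integrated-amplitude 2-D Gaussians plus flat
background with optional Poisson shot noise; sources placed on a circle
(`ring_positions`) emulate the labelled nuclear envelope seen in one
focal plane for the nuclear-diameter assay.

## Tracking (`expalm.tracking`)

Greedy frame-ordered nearest-neighbour linking: per frame, candidate
links (active track -> unclaimed localization within `max_dist`) are
assigned in order of increasing distance, ties broken by lower
localization index.  A track tolerates up to `max_gap` consecutive dark
frames (default 5, the usual "allowed blinking interval"), i.e. a link
may span a frame difference of `max_gap + 1`.  "Steps" count
inter-detection links, so the standard "drop trajectories of three steps
and less" filter is `min_steps=4`.

One practical caveat the tests quantify: `max_dist` acts as a symmetric
truncation about the *previous* position, so when it is only a few times
the localization noise (the conventional 3 sigma), the retained
displacements are biased toward zero and a frame-to-frame drift integral
inherits a percent-level systematic shrinkage that accumulates over the
movie.  Drift estimation therefore uses a generous radius (~8 sigma at
the sparse marker densities involved), where the bias is negligible.

## Drift correction (`expalm.drift`)

All three estimators return the apparent sample motion relative to frame
0; correction subtracts it, so apply-then-correct is an exact identity.

* **Cross-correlation**: temporal sub-stacks rendered as 2-D histograms
  (`render_px`, default 10 nm) on a common grid are registered to the
  first non-empty sub-stack by FFT cross-correlation with a 3x3-centroid
  sub-pixel peak (local minimum subtracted in the window).  Offsets are
  anchored at sub-stack central frames and interpolated linearly, with
  *linear* extrapolation at the movie edges before re-anchoring frame 0
  to zero.  Constant extrapolation would leave the drift accrued between
  frame 0 and the first anchor as a permanent offset of the whole
  trajectory; with linear drift of ~1 nm/frame and 300-frame sub-stacks
  that constant alone (~150 nm) would dwarf every other error source.
* **Frame-to-frame**: the mean displacement of all track links spanning
  each consecutive frame pair, integrated over time, then smoothed by a
  centred moving average (default 11 frames) and re-anchored.  Pairs
  without links contribute zero shift and support 0.  The estimator's
  error telescopes within each track's lifetime, so its accuracy is set
  by track turnover: with n concurrent tracks of typical length M the
  integrated error grows like sigma * sqrt(T/(nM)).  It is therefore the
  method of choice when dedicated marker cells contribute dense,
  long-lived (photostable) emitters, and degrades for fast-blinking
  markers — which is also why the recovery simulations use marker
  emitters with on-times much longer than the movie.
* **Fiducials**: each marker is followed from its seed position (nearest
  localization within `radius` of its last known position); markers seen
  in less than half the frames are dropped.  The trajectory is the mean
  over fiducials of (position − frame-0 position); anchoring at frame 0
  doubles the per-frame error variance relative to the naive
  sigma^2/n_fiducials averaging bound, which the tests account for.

Sub-stack registration assumes the same underlying structure is sampled
in every sub-stack.  With PALM markers whose lifetime is comparable to a
sub-stack this is subtly violated: molecules shared between the first
and a later sub-stack can only *disappear* during the later one, which
under drift skews the correlation peak against the drift direction.
The recovery conditions use photostable markers, where the effect
vanishes; for fast-blinking data the frame-to-frame estimator or
shorter sub-stacks are preferable.

`assess_reliability` returns the longest movie prefix whose
trailing-window (default 50 frames) mean support stays above a floor,
for discarding the low-density tail of bleached movies.

## NeNA precision (`expalm.nena`)

For every localization in frame t the distance to its nearest neighbour
in frame t+1 is collected; re-detections of one molecule dominate the
small-distance part and follow p(d) = d/(2 sigma^2) exp(-d^2/(4 sigma^2))
(Rayleigh with scale sigma*sqrt(2), mode at sigma*sqrt(2)), where sigma
is the average experimental localization precision.  The histogram
(100 bins over [0, `fit_range_max`], default 150 nm, 300 nm for the
broader expanded-sample distances) is least-squares fitted with the
kernel plus a Gaussian nearby-molecule term and a linear uniform
background, all amplitudes bounded non-negative; the initial sigma is
the histogram mode divided by sqrt(2).  On clean data known to contain
only the kernel, the correction terms should be disabled
(`include_neighbor=False, include_uniform=False`): a free correction
Gaussian sitting near the kernel mode can otherwise absorb several
percent of its mass and bias sigma low.  The recovery tests exercise
both regimes at the study's two precisions (13.9 and 26.5 nm).

## Rendering (`expalm.render`)

Count histograms at a default 10 nm reconstruction pixel over the
bounding box padded by one pixel, with half-open grid-aligned bins
(boundary values fall into the higher-index bin; shifting all
localizations by one pixel shifts the image exactly one pixel).
Gaussian blur (sigma = the dataset's NeNA value, by convention) uses
reflective borders so counts are conserved.  8/16-bit export is
display-only normalization and never feeds quantification.

## Quantification (`expalm.quantify`)

* **Cytosol width**: principal axes from the second moments of the raw
  (unmerged) localizations; width = 1st–99th percentile span of the
  minor-axis projection.  A percentile span is used instead of min/max
  because raw SMLM data contain stray localizations; against a uniform
  spherocylinder the 1–99 reading under-reads the geometric width by
  ~2.5% (the tests pin this against numerical integration of the
  marginal), a bias that cancels exactly in expanded/non-expanded
  ratios.
* **Nuclear diameter**: median background subtraction, centroid
  refinement on the positive signal, radial profile in 1-px annuli,
  diameter = twice the outer radius where the profile falls to half its
  peak (linear interpolation).  On diffraction-limited images of a thin
  ring this reading is broadened by 2*sqrt(2 ln 2)*sigma_PSF (~330 nm at
  sigma_PSF = 142 nm); passing `psf_sigma_nm` subtracts that analytic
  broadening.  As with the width, the uncorrected bias largely cancels
  in the expansion-factor ratio only when both sizes are measured far
  above the PSF scale, so the correction matters mainly for
  non-expanded nuclei.
* **Expansion factor**: ratio of expanded to non-expanded mean size with
  first-order error propagation.
* **Spot intensity / retention**: integrated 14 x 22 px ROI minus a
  nearby background ROI, averaged over the first three frames;
  retention is the per-step percentage of a reference step with
  propagated standard errors.

## Isotropy statistic (`expalm.isotropy`)

Cell area is the convex hull of the localizations (the hull's inward
bias at finite n cancels between expanded and density-matched reference
cells).  For each expanded cell, every reference cell is rescaled about
its centroid so its point density (points per hull area) matches; since
uniform scaling multiplies all NN distances by the factor and divides
density by its square, the matched mean NN distance is computed in
closed form (`nn * sqrt(rho/rho_target)`) — exactly equivalent to
scale-then-measure, which a test verifies.  The z-score of the expanded
cell's mean NN distance against the matched reference mean and sample sd
is the per-cell statistic; a two-sided one-sample t-test of the z-scores
against 0 summarizes the population (a two-sample variant is provided).

Distortion lowers the expected mean NN distance at matched global
density (E[sqrt(rho_local)] <= sqrt(E[rho_local]) by Jensen's
inequality), so anisotropy pushes z negative and |z| up.  Two
calibration caveats are deliberate outcomes of the design rather than
defects: (1) all expanded cells share one reference sample, so z-scores
are positively correlated — the one-sample t-test is anti-conservative
under the null and its p-values are not uniform; the per-cell z-scores,
not the pooled p, are the robust readout.  (2) For the same reason the
null |z| > 1.96 fraction sits near 0.06–0.08 rather than 0.05 (t-tails
with 29 df plus shared-reference correlation), and single-batch summary
statistics (mean z over 100 cells) fluctuate with sd ~ sqrt(1/100 +
1/30) ≈ 0.21; the acceptance battery therefore reports these calibration
quantities averaged over 10 independent replicates at the stated batch
sizes.

## Problem sizes and numerical choices

The recovery batteries run at the study's movie scale (3000 frames,
several hundred thousand localizations per field, 30 reference + 100
expanded cells of ~600 points) and complete in well under a minute each
on one CPU.  Tolerances asserted by the tests are derived from
independent oracles (closed forms, numerical integration, ground-truth
simulation) rather than from the estimators themselves.  Degenerate
inputs (empty tables, collinear hulls, zero-signal images, missing
columns) raise typed errors with actionable messages; all randomness
flows through explicit integer seeds and fixed seeds give bit-identical
outputs.

## Known limitations

2-D only; no fluorophore photophysics beyond geometric blinking; no
EM-gain/camera noise model; greedy (not globally optimal) tracking; no
redundant cross-correlation or 3-D drift; NeNA assumes a single pooled
precision rather than per-localization photon-based estimates.  Passing
recovery tests show the estimators are correct under the generator's
assumptions (uniform cytosolic emitters, Gaussian noise, shared drift);
they cannot certify behaviour under structured samples, depth-dependent
aberrations or heterogeneous labelling that real data may exhibit.
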
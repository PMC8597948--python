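# Methods

This note documents the models, numerical choices, and synthetic study
conditions behind `probeloc`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model

All volumes are regular 3D grids with per-axis micron spacing, canonical
axis order (ML, DV, AP), and an origin at the center of voxel (0,0,0).
Voxel ownership is half-open toward increasing index
(`[center − s/2, center + s/2)` per axis), which makes region lookups at
boundary points deterministic; points outside the grid resolve to the
reserved outside label 0. Downsampling is block-mean (not strided), with
trailing partial blocks averaged over the voxels present, so the global
mean is preserved exactly for factor-divisible shapes.

## Thin-plate-spline warping

Landmark transforms are 3D polyharmonic splines with kernel U(r) = r (the
3D biharmonic choice; the kernel is a recorded field so r³ can be swapped
in) and an affine polynomial part, solved from the standard symmetric block
system with side conditions Σwᵢ = 0 and Σwᵢcᵢᵀ = 0. Regularization is 0 by
default: every landmark is a deliberate manual correspondence and is
interpolated exactly (asserted at < 1e−6 μm); a ridge parameter is exposed
for noisy landmark sets. Moving points closer than 1e−6 μm are rejected as
duplicates; coplanar configurations are rejected because the affine part is
underdetermined. Inversion is by swap-fitting the landmark pairs, exact at
the landmarks and approximate elsewhere — documented as such, with the
forward/inverse round-trip error shrinking with landmark density. Volume
warping is pull-back resampling with trilinear interpolation and 0 fill.

## Track and electrodes

The probe track is the piecewise-linear interpolation of the annotated dye
centerline, resampled at 1 μm (each segment split into equal pieces so
vertices and total length are preserved exactly; the resampling density is
below any meaningful precision). Arc length is 0 at the brain-entry end.
Queries beyond the tip extend the terminal segment linearly and are
flagged rather than rejected, because dim dye tips under-estimate the true
tip and anchoring legitimately pushes sites past the annotated end.

Anchoring maps shank depth to arc length piecewise-linearly through the
anchor points, extrapolating beyond the anchored range with the nearest
segment's slope; the map is orientation-agnostic (segments must share one
sign; scaling factors are reported as magnitudes), with a single-anchor
fallback that applies an externally supplied scaling factor (in practice
the mean factor from sibling penetrations in the same brain). Both sites of
a Neuropixels row share one depth; the 16–32 μm lateral in-row offset is
sub-voxel at every atlas resolution used and is ignored. The tip offset
(physical tip to first row) defaults to 0 and is configurable.

## Electrophysiology

Preprocessing: per-channel temporal-median subtraction, then per-sample
cross-channel-median subtraction (common average referencing), then band
split — LFP low-pass 300 Hz resampled to 2.5 kHz, AP band-pass 300–5000 Hz
at the native 30 kHz. Filters are zero-phase forward-backward order-3
Butterworth: only the corner frequencies are physically meaningful, and
zero-phase filtering preserves event timing. Multiunit events are negative
threshold crossings at −50 μV with a 1 ms per-channel dead time (the dead
time is this package's choice; it prevents one spike producing several
events); amplitudes are handled in μV after gain conversion, so thresholds
are acquisition-gain-independent. LFP power is the mean squared signal
over the full 0–300 Hz band by default, with an optional sub-band.

The brain-surface detector takes the LFP-power depth profile, estimates
out-of-brain and in-brain plateau levels from the profile's two ends
(plateau fraction configurable; the workflow uses 10% because only the
shallow ~0.5 mm of a 3.84 mm bank is out of the brain), and reports the
first bin from the out-of-brain end exceeding the plateau midpoint, with
confidence = plateau separation / pooled spread (< 2 is an error). Other
landmark signatures (white-matter quiet stretches, rate transitions) are
computed as depth profiles but matched manually, which is how these
landmarks are identified in practice.

Evoked activity is counted in a configurable post-stimulus window (0–5 ms
captures direct axonal responses, 5–20 ms synaptic ones; the end-to-end
study uses 0–20 ms to cover both targets in one profile) and
baseline-subtracted using an equal-duration pre-stimulus window, which
keeps the Gaussian fit's offset term small. Depth bins are centered on the
channel grid — edges placed exactly on channel depths would shift every
bin center by half a bin.

## Groundtruth fits and statistics

Profiles are normalized to [0,1] so fluorescence and evoked counts share an
amplitude scale, then fitted with K Gaussians + offset by bounded
nonlinear least squares. K is an analyst's choice (the number of distinct
projection targets along the probe). Initialization is multi-start: the K
largest local maxima with a minimum mutual separation (so two starts never
land inside one noisy peak top), a spread variant, and an evenly spaced
fallback. Peaks are matched greedily by nearest mean, each peak used once;
unmatched peaks are reported but never enter the accuracy statistic. The
per-penetration error is the mean |Δpeak| over its matched pairs (an
explicit assumption), and the study summary is mean ± sample SD (n−1)
across penetrations. The paired comparison between anchoring spaces is a
standard two-tailed paired t test.

## Synthetic phantom

The phantom emulates the groundtruth experiment end to end on a 200×300×200
grid at 20 μm (ML 4 mm × DV 6 mm × AP 4 mm) — a deliberate miniature that
fits in memory and runs in seconds per brain.

**Geometry and deformation.** The in vivo ("subject") brain is a stack of
horizontal layers (cortical L1, cortex, a fiber tract, hippocampus,
thalamus, midbrain) below a surface plane at DV 600 μm. The atlas space is
an enlarged image of it. Along the insertion axis the local linear
enlargement is anchored at the brain surface and declines with depth,
scale(z) = 1.5 − 0.11·z[mm], giving a mean enlargement of ≈1.32 over a
3.3 mm insertion — calibrated so that a dye-tip placed in the enlarged
space overshoots a 3.3 mm manipulator reading by ≈1 mm, the regime real
atlas-space placements show. The depth *gradient* of the enlargement is
essential, not decorative: a uniform enlargement is absorbed exactly by
linear inter-anchor scaling, so only nonuniform enlargement produces the
error that anchoring in an in-vivo-shaped space avoids. On top of this
fixed profile a seeded smooth low-order polynomial field (quadratic/cubic
terms, 130 μm amplitude) adds brain-specific distortion; amplitudes are
capped so the map stays invertible, and the DV profile's inverse is closed
form.

**Spaces and landmarks.** Manual subject→atlas landmarks are sampled on a
jittered grid through the true deformation with 50 μm Gaussian jitter
(250 landmarks — the typical manual count). A separate in-skull template
space shares the subject's geometry (that is its purpose), and its atlas
correspondence is a second landmark set with only 15 μm jitter: template-
to-template alignment is done once between clean averaged images and is
far less noisy than any per-subject warp. This separation matters: an
early design derived the undistorted space by inverting the subject's own
noisy warp, which doubles warp noise in that space's arc-length metric and
buries the enlargement penalty.

**Penetrations, recordings, blobs.** Tracks enter at gridded surface
positions with up to 6° tilt, a 30 μm bow, and 3.1–3.4 mm insertion depth
(so the tip bank always spans the surface). Each penetration carries a
192-channel, 30 kHz recording: Gaussian noise (12 μV in brain, 3 μV in
saline above the surface), a per-channel-phase 6 Hz LFP (150 μV, in-brain
only), region-dependent Poisson multiunit spiking with region-typical
amplitudes, and evoked responses: two fluorescent blobs placed exactly on
the track (a tight fiber-tract target responding at 2 ms and a broader
thalamic target at 6 ms), each producing per-stimulus events with Gaussian
depth weighting (peak probability 0.85, 0.3 ms latency jitter) over 150
stimuli at 25 Hz. Dye is rendered as a Gaussian tube (σ 30 μm) with a
brighter, smeared tip; the emulated annotator places centerline points
every 200 μm with 20 μm jitter and errs on the tip depth by the 100 μm
smear scale. Ephys anchor depths for the fiber-tract and
hippocampus/thalamus boundaries carry 30 μm jitter, emulating manual
landmark matching; the cortical L1 transition is deliberately *not* an
anchor (it is a cross-validation signature). Everything is deterministic
in (spec, seed); recordings are regenerated on demand from stored child
seeds rather than held in memory.

**Presets.** `exact` switches off every stochastic source (no jitters, no
noise, deterministic evoked counts, uniform enlargement with no gradient
or polynomial field) and measures the pipeline's numerical floor;
`realistic` is the default condition described above; `hard` doubles the
jitters and noise. Accuracy studies pool 17 penetrations from a cohort of
4 brains (each with its own deformation realization and landmark set), the
way a real study pools animals — with a single brain, that brain's warp
error at the anchor boundaries biases every penetration identically and
can mask or mimic the between-space contrast.

**What passing tests do and do not show.** The phantom's anatomy is planar
layers, its noise Gaussian/Poisson, its evoked responses perfectly matched
to fluorescence, and its annotation errors unbiased. Passing therefore
demonstrates the pipeline's correctness and its error budget under stated
noise — not performance on real tissue, where projection spread, dimpling
(~0.1 mm, not modeled beyond the tip-smear term), non-planar anatomy, and
operator idiosyncrasies add error the phantom does not contain.

## Problem sizes

The default test suite exercises miniature phantoms (60×150×60 grids, 2
penetrations, 40–60 stimuli); the acceptance run uses the full presets
(exact: 4 penetrations, 300 stimuli; realistic: 17 penetrations across 4
brains, 150 stimuli each). These sizes were chosen so a study completes in
minutes on one CPU while keeping ≥15 penetrations, the scale at which the
cohort statistics are meaningful.

## Known limitations

* TPS fitting is dense (O(n³) in landmarks); fine for the ≤1000-landmark
  regime it is designed for.
* The approximate (swap-fitted) inverse is exact only at landmarks; the
  workflow minimizes inverse applications by mapping arc lengths through
  track correspondences instead of re-warping 3D points where possible.
* Anchor discovery is automated only for the brain surface; all other
  landmarks are inputs.
* NRRD support covers 3D raw/gzip attached-header files only.
* The single-shank, row-symmetric probe model does not cover multi-shank
  geometries.
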
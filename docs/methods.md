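# Methods

`raftrack` quantifies how a membrane receptor's punctate fluorescent
domains change when a ligand clusters and immobilises them: the treated
condition is expected to show fewer, larger, brighter domains that move
more slowly and less linearly than in the untreated condition.  The
package implements the full measurement chain on calibrated time-lapse
stacks and ships a ground-truthed simulator so every stage is testable
without external data.

## Synthetic movies

The generator emulates 2-minute movies at a 2 s lapse (60 frames) of
diffraction-limited receptor domains on a 128×128 px field at
0.16 µm/px (a typical 100× confocal scale; the pixel size is
configurable and all physical thresholds downstream are stated in
physical units, so this default is not load-bearing).

**Untreated (brownian) condition.**  Each of 40 spots performs free 2-D
Brownian motion with D = 0.01 µm²/s: per-axis steps are
Normal(0, √(2·D·Δt)) in µm, reflected at the field borders.  At the
default calibration this gives a mean 2-D step of ≈1.57 px/frame
(≈7.5 µm/min), comfortably below the 42 µm/min linking cap.

**Treated (clustered) condition.**  A `cluster_fraction` (default 0.8)
share of spots is attracted at 0.5 µm/frame to the nearest of 8 cluster
centers; once within the capture radius (0.5 µm) a spot locks a small
(σ = 0.5 px) co-localisation offset and rides rigidly on its center.
Centers are not frozen: each wobbles with per-axis Gaussian steps of sd
0.16 µm, reflected inside the capture radius around its anchor.  This
capture-and-confine design is deliberate.  A fully frozen cluster would
be removed by the pipeline's own stationary-area exclusion (mean step
≥ 1 px/frame), leaving the treated linearity sample populated only by
the untouched free diffusers and erasing the phenotype the pipeline is
supposed to detect.  Confined wobble keeps captured domains just above
the stationary threshold (≈1.25 px/frame ≈ 6 µm/min) while bounding
their net displacement by the confinement radius, which is precisely
the "slower and less linear" signature of ligand-arrested clusters.
Clustered simulations run a 40-frame unrecorded burn-in so recording
starts at capture steady state, emulating imaging long after treatment;
without it the first frames of both conditions would be
indistinguishable.

**Rendering.**  Spots are isotropic Gaussians (σ = 1.3 px) with peak
amplitude 80 over a background of 100, truncated at ±5σ (truncated mass
< 0.5%).  Poisson shot noise is applied to the clean image, then
Gaussian read noise (σ = 3), then clipping to 16 bit.  The peak
signal-to-background-noise ratio is 80/√(100+3²) ≈ 7.7 ≈ 8.  The noise
and SNR values are asserted defaults, not derived from any particular
instrument.  Ground truth carries the continuous tracks, the
spot-to-center assignments, and per-frame label images of the regions
where the noiseless spot signal reaches ≥50% of the nominal peak.

What the simulator does *not* reproduce: photobleaching, blinking,
3-D optics, camera gain structure, cell shapes, and any kinetic realism
in the clustering mechanism (capture-and-confine is the simplest model
producing the observed endpoint phenotype).  Passing tests therefore
demonstrate that the measurement chain recovers known motion and
morphometric differences under idealised imaging, not that it is robust
to every artefact of real microscopy.

## Segmentation

Background is removed by grey morphological opening with a disk
(default radius 50 px — the de-facto rolling-ball standard of
interactive tools); for radii ≥ 12 px the disk is applied via a
footprint-sequence decomposition, an octagonal approximation that is
orders of magnitude faster with deviations ~1e-3 on unit-scale images.
A large-radius unsharp mask (radius 25 px, amount 0.9 — radius ≫ PSF so
puncta are enhanced against diffuse membrane signal) precedes
thresholding.  The threshold is a manual intensity value by design —
the intended semi-automated workflow — with an Otsu fallback for
unattended runs, flagged in output metadata.  For the default synthetic
movies the manual threshold is 70 units on the enhanced scale, chosen
once by inspecting rendered frames: the opening-based background leaves
a noise floor near 33 units while true spots reach 150–200.  Domains
are 8-connected components of at least 4 px (sub-PSF specks are noise),
measured — area, mean intensity, centroid — on the background-subtracted
image, *not* the contrast-enhanced one.  Domains are counted per cell
by the cell label under each centroid; synthetic movies, which have no
cell outlines, use a fixed 2×2 tiling of the field as pseudo-cells.

## Spot detection

The à-trous B3-spline wavelet transform (kernel (1/16)[1,4,6,4,1],
holes doubling per level) decomposes each frame into detail planes that
reconstruct the input exactly.  Detection thresholds the level-2 plane
at k·σ̂ with k = 3 and σ̂ = MAD/0.6745 estimated per frame (robust to
the spots themselves and to slow illumination drift).  Supra-threshold
8-connected components smaller than 8 px are discarded: isolated noise
exceedances of a 3σ threshold span 1–5 px after the level-2 smoothing,
whereas a real spot's component covers well over 10 px, so the cut sits
mid-gap.  Each surviving component becomes one spot with the
intensity-weighted centroid on the thresholded detail plane (background-
free by construction) as its sub-pixel position and the component's
summed detail mass as its intensity.  Localisation accuracy at the
default SNR is ≈0.2–0.3 px RMSE.

## Linking and tracks

Spots in consecutive frames are linked by an exact assignment problem:
link cost is the squared displacement in px², admissible only when the
implied speed is at most 42 µm/min (8.75 px/frame at the default
calibration), with birth/death alternatives at 1.05 × cap² — marginally
above the worst admissible link, so a single admissible link always
beats a death plus a birth.  Because gap closing is disabled (tracks
must be gap-free), the movie-wide optimisation decomposes into
independent per-frame-pair problems, so solving each pair exactly
(Jonker–Volgenant on the augmented matrix) reproduces the movie-wide
optimum; this equivalence is the module's central claim and is tested
against brute-force enumeration of all admissible partial matchings.
Equal-cost ties are broken toward the lexicographically smallest link
set by a rank-ordered perturbation of 1e-9/(n·m), far below any
meaningful cost difference.  Chains of links become tracks; unlinked
spots become singleton tracks; a spot that disappears and reappears
yields two tracks.  Dynamics analysis keeps tracks of at least 5 frames
("over four frames", read as point count ≥ 5 rather than link count ≥ 5;
the threshold is exposed as `min_track_frames`).

## Mobility metrics

Per track: mean step (px/frame), mean frame-to-frame speed (µm/min) —
"average speed per punctum" is the mean instantaneous speed, the only
quantity the frame sampling supports — net head-to-tail displacement,
total path length, and rho = net displacement / path length ∈ [0, 1]
(1 = straight monotone motion, →0 = confined or random motion; NaN for
zero-path tracks, which the stationary filter removes first).  The
stationary-area exclusion keeps tracks with mean step ≥ 1.0 px/frame
(boundary inclusive) and applies to the rho analysis by default; a
`stationary_filter_scope="both"` flag extends it to speeds, since the
original analysis description is ambiguous on that point.  Condition
summaries report median, quartiles and 10th/90th percentiles with
linear interpolation between closest ranks (recorded in metadata
because box-plot conventions differ).

## Statistics

Condition comparisons use a permutation test for the difference of
means, which assumes only exchangeability.  Defaults: 10 000 random
label permutations, two-sided, with the add-one correction
p = (#{|T_perm| ≥ |T_obs|}+1)/(n+1), guaranteeing a valid p ∈ (0, 1];
when the number of distinct assignments is ≤ 20 000 the test switches
to exhaustive enumeration and p is exact.  The permutation unit is
whatever observational unit is supplied (domains, per-cell counts, or
tracks); no nesting correction is attempted.  The cholesterol-efflux
utility computes media counts / (media + cells counts) × 100.

## Problem sizes and numerical choices

The two-condition experiment defaults to one 60-frame 128×128 movie per
condition; the phenotype-recovery test uses ten such paired simulations
with Fig-morphometrics measured on the first five frames of each movie —
sizes chosen so the whole suite exercises every stage end to end at
desk scale.  Degenerate inputs are handled explicitly: empty masks give
empty domain lists, all-noise frames may return zero spots, empty frame
sides give zero links, zero-path tracks are excluded before rho.
Reconstruction of the wavelet transform is exact to 1e-6 relative;
assignment optimality is exact up to the 1e-9-scale tie-break
perturbation.

## Known limitations

Manual thresholds do not transfer across imaging conditions; Otsu can
over-segment sparse-foreground frames.  The detector reports one spot
per merged cluster, so tightly co-localised receptors are counted as a
single domain (which is also what the morphometric endpoints intend).
No gap closing means a single missed detection splits a track, biasing
lifetimes downward equally in both conditions.  The permutation test
treats tracks as independent even though tracks from one cell are
correlated.
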
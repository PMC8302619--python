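# Methods

`punctakit` re-implements, as a tested pipeline, the image-analysis
computations used to establish that immobile, actin-tethered IP₃R puncta are
the sites of Ca²⁺ puffs: spot segmentation of TIRF puncta, object-based
colocalization with randomization nulls, single-particle mobility
classification, FRAP mobile fractions, Ca²⁺-puff detection and site mapping,
and fluorescence-to-[Ca²⁺] calibration.  Real micrographs for these analyses
are not publicly deposited, so every stage is validated against synthetic
microscopy data with known ground truth.

## Conventions

Images are `(T, Y, X)` arrays in arbitrary fluorescence units (FU);
coordinates are 0-based with `x` the column and `y` the row index; a pixel's
centre sits at its integer index, and physical position (nm) is
`index × pixel_size_nm`.  Background correction subtracts, per frame, the
mean intensity of a user-supplied region outside the cell and clamps
negative values to zero (downstream segmentation assumes non-negative
intensities).  Whether background should be per-frame or per-movie is an
open choice; per-frame was picked because it also absorbs slow lamp drift.

## Spot segmentation (`spots`)

Puncta are segmented by seeded radial growth:

1. **Seeds.** All local intensity maxima of a frame (strictly greater than
   their 8-neighbours; plateau maxima reduced to the lexicographically
   smallest pixel) at or above a per-image seed threshold.  The default
   threshold is robust: median + 5 × (1.4826·MAD); it can be overridden per
   image, mirroring how tracking tools require per-image detection
   thresholds.  By default the working frame is Gaussian-smoothed (σ = 1 px)
   before seed detection and growth; at a peak signal-to-background-noise
   ratio of 5 this lifts the effective detection SNR to ~10 and keeps both
   recall and precision above 0.95.
2. **Border intensity.** For each seed, mean intensities are computed in
   concentric 1-px rings out to 10 px; the border threshold is the ring mean
   at the first radius where the radial profile flattens (relative drop
   between successive rings < 0.05).  The flattening point is the local
   background shoulder of the spot; the numeric rule (0.05, 10 px) is our
   operationalization and is configurable.
3. **Growth.** Breadth-first growth from the seed in order of decreasing
   intensity; a pixel is accepted iff it is above the border threshold, no
   brighter than the accepted 4-neighbour through which it is reached
   (monotone descent), and 4-adjacent to the region.  Seeds are processed in
   decreasing intensity; contested pixels stay with the first spot that
   claimed them.  Growth uses 4-connectivity, maxima detection
   8-connectivity (strict regions, permissive peaks).
4. **Localization.** The punctum centroid is refined by a 2-D Gaussian
   least-squares fit (amplitude, centre, width, offset) in a 9×9 window of
   the raw frame, falling back to the border-subtracted intensity-weighted
   region centroid when the fit fails or wanders.  The plain region centroid
   reaches ~0.4 px RMS at SNR 5 because read noise and ragged
   monotone-descent regions dominate; the Gaussian fit reaches ~0.26 px,
   near the Thompson localization bound (~0.23 px) for these conditions, and
   is the standard sub-pixel localizer in particle-tracking practice.
   `localizer="region"` restores the bare region centroid.

Punctum integrated intensity is the sum of (intensity − border) over the
pixel set — the flux above the local background shoulder — so the
puncta-to-whole-cell fluorescence fraction used as a threshold-consistency
check books photons rather than background.

## Object-based colocalization (`coloc`)

Colocalization between two segmented channels is the fraction of channel-A
puncta whose centre-to-centre nearest-neighbour distance to channel B is
strictly below a criterion: 160 nm by default (one camera pixel), 130 nm for
65-nm-pixel super-resolution data; the criterion is tied to the imaging
modality preset and can be overridden.  Distances are computed in nm from
sub-pixel centroids with a KD-tree (verified against an O(n²) oracle).

Significance comes from randomizing the **segmented B objects**: each
iteration (100 by default) relocates every B pixel set rigidly to a uniform
random in-mask position, without overlap and fully inside the mask (bounded
retries), and recomputes the distances against the fixed A centroids.  The
p-value is the add-one permutation estimator
`(1 + #{null fraction ≥ observed}) / (n_iterations + 1)` — never exactly
zero.  The null also yields the mean cumulative distance curve with a
pointwise 2.5–97.5 percentile band.  A fast point-mode (centroids only) is
used for analytic checks: for complete spatial randomness the expected
criterion fraction is `1 − exp(−λπr²)`, and the point-mode null reproduces
it within Monte-Carlo error.

Actin-style filament channels are handled mask-based: Gaussian filter
(σ = 0.5 px) then threshold (Otsu by default, absolute override), and the
Manders split coefficient `M = Σ I over (reference ∧ analysis) / Σ I over
analysis` reports the fraction of a channel's fluorescence on the filament
mask.  Distance-based colocalization can be partitioned by named regions
(e.g. on/off filaments, or the peripheral annulus — mask pixels within 15 px
(2.4 µm at 160 nm pixels) of the cell boundary by Euclidean distance
transform — versus the central core); B candidates are restricted to the A
punctum's region.

## Single-particle mobility (`tracking`)

Per-frame detections are linked frame-to-frame by minimum-cost bipartite
matching with a hard speed gate (1.5 µm/s — above the maximal velocity of
genuine puncta), then track segments are joined across gaps of up to 2
missed frames when the implied speed stays within the gate.  The matching
objective is explicit: match as many gated pairs as possible, minimizing the
total matched distance (augmented assignment matrix with a per-unmatched
cost equal to the gate distance).  The gap limit of 2 frames is our default;
the gate and the 45-frame minimum below are the published operating
parameters.

For each trajectory of at least 45 frames the time-averaged MSD is computed
over all in-trajectory frame pairs per lag (lags with fewer than two pairs
dropped), and γ² = 4Dt^α is fitted by least squares on log t vs log MSD over
the first 10 lags (the noisy long-lag tail is excluded; range configurable).
Mobility classes come directly from α: immobile α < 0.1 (the published
operative criterion), sub-diffusive 0.1 ≤ α < 0.8, diffusive 0.8 ≤ α < 1.2,
directed α ≥ 1.2.  Band edges are configurable; the published workflow used
a machine-learning trajectory classifier and then applied the α < 0.1 rule
within its sub-diffusive class — here the α bands replace the classifier
because the α rule is the operative criterion.  Perfectly stationary
trajectories (all-zero MSD) are assigned α = 0, D = 0 rather than a fit
failure.  A two-colour temporal overlay (frames 30 s apart in green and
magenta; immobile structures white) is provided for visual confirmation.

With a hard speed gate, a Brownian particle occasionally exceeds the gate in
one step (probability `exp(−g²/(4DΔt))` per step) and its track fragments;
fragments ≥ 45 frames are still classified.  This is a property of gated
linking itself, not of this implementation.

## FRAP (`frap`)

Bleach-ROI traces are normalized to the mean of the pre-bleach frames
(≥ 3 required).  The mobile fraction is
`Mf = (F_plateau − F_post) / (F_pre − F_post)`, with the plateau from a
single-exponential recovery fit `F(t) = F_post + (F_plateau − F_post)(1 −
e^(−t/τ))` and, when the fit fails, the mean of the final 20% of post-bleach
frames.  The published analysis delegates to an ImageJ plugin without
stating a formula; this is the conventional definition that plugin
implements.  No correction for acquisition photobleaching or whole-cell
bleach depletion is applied (none was described); Mf is clamped to [0, 1]
and is invariant to rescaling the raw trace.

## Ca²⁺ puffs and calibration (`puffs`)

ΔF/F₀ is computed per pixel against the temporal mean of a fixed
pre-stimulus baseline window (50 frames = 2.5 s at 20 frames/s by default;
not a running percentile); pixels with non-positive baseline are masked and
reported.  A ΔF/F_max variant divides by the Ca²⁺-saturated indicator
signal instead.

The event detector is a transparent replacement for the published FLIKA
detection whose role here — counting events and sites, amplitudes,
centroids — it serves with matched monotone behaviour: spatial Gaussian
smoothing (σ = 1 px), threshold ΔF/F₀ > 0.3, 26-connected space-time
components, minimum duration 2 frames at 20 frames/s.  Three design choices
harden it: components under 10 space-time voxels are rejected (isolated
noise crossings; genuine puffs cover hundreds of voxels), an event starting
within 3 frames of a previous event's end and within 500 nm is merged as a
threshold-flicker echo of the same release, and event timing is measured on
the frames that reach the detection threshold.  An optional hysteresis
low-threshold exists but is off by default: chaining at a low threshold can
spatially merge simultaneous events at sites only ~1.3 µm apart.  Event
counts are monotone non-increasing in both the amplitude and the duration
threshold — the sensitivity control used to confirm detection robustness.

Events are grouped into release sites by single-linkage clustering with a
500 nm cutoff (inclusive at the boundary), motivated by the sub-punctum
wander of successive puff centroids at a site; distances from event
centroids to immobile puncta reuse the colocalization distance engine.
Sites closer than about two spatial widths of an event cannot be separated
when their events overlap in time; the detector's accuracy contract
therefore applies to sites ≥ 2 µm apart.

Population fluorescence is calibrated with the single-site isotherm
`[Ca²⁺] = K_D (F − F_min)/(F_max − F)` (Fluo-8: K_D = 389 nM); F at the
dynamic-range midpoint returns exactly K_D, saturated or sub-F_min inputs
are errors, and the inverse mapping round-trips to machine precision.

## Synthetic data (`synth`)

The generators emulate the statistical structure each analysis assumes, with
known truth:

* **Puncta fields** — B centroids uniform in the mask with a hard minimum
  spacing of 4σ_PSF (keeps spots individually segmentable; congested fields
  can be produced by lowering the factor but are outside the accuracy
  contract); ⌊coloc_fraction·n_A⌋ A centroids uniform in 80-nm discs around
  distinct B centroids (criterion-proof by construction); remaining A
  uniform but excluded from a 160-nm zone around every B so the generated
  colocalized fraction is *exact* — under pure CSR placement chance
  proximity would add ≈ `1 − exp(−λπr²)` ≈ 0.06 at the default densities
  and the construction fraction would not be the measurable truth.  Spots
  are rendered as point-sampled isotropic Gaussians (σ = 110 nm at 100 nm
  pixels, the diffraction-limited width for green emission at high NA);
  an isolated spot integrates to amplitude·2πσ² within 1%.
* **Noise** — Poisson shot noise on signal + baseline plus Gaussian read
  noise, then baseline re-subtraction and clamping (a background-corrected
  sCMOS/EMCCD approximation).  "SNR 5" throughout means peak amplitude =
  5 × the background noise s.d. `sqrt(baseline + read²)`.
* **Filaments** — cubic splines through random in-mask waypoints (ordered
  along their principal axis), sampled uniformly in arc length and rendered
  with a Gaussian cross-section; the truth mask is the FWHM footprint of the
  centre-line.
* **Motion** — immobile (fixed position), Brownian (per-axis step variance
  2DΔt), directed (constant velocity) and, behind a flag, confined
  (reflecting circular boundary) particles; isotropic Gaussian localization
  noise is added to every class.  Defaults D = 0.01 µm²/s, v = 0.5 µm/s,
  20 nm localization noise, Δt = 0.1 s, ≥ 45 frames.
* **FRAP** — `F(t) = F_post + Mf (F_pre − F_post)(1 − e^(−t/τ))` with
  pre-bleach frames and Gaussian noise (default 2% of F_pre, τ = 10 s).
* **Puffs** — events multiply a uniform baseline locally by `1 + ΔF/F₀(t)`
  with a Gaussian spatial profile (σ = 600 nm), linear rise (2 frames) and
  exponential decay (τ = 8 frames); event centroids jitter ~100 nm around
  their site; starts are stratified in time per site so successive events at
  one site remain individually countable.

What the generators do **not** emulate: photobleaching, 3-D PSFs and
defocus, camera gain and fixed-pattern noise, spatially varying background,
receptor clustering substructure, puff kinetics beyond rise/decay, and
spatially correlated motion.  Passing tests therefore demonstrate that the
algorithms recover the statistical structure they target at realistic SNR —
not that they are robust to every artefact of real microscopy.

## Numerical choices and degenerate inputs

Strict `<` at the colocalization criterion; inclusive merge at the site
cutoff; plateau maxima tie-break by lexicographic pixel order; contested
segmentation pixels by seed-intensity order; p-values add-one; empty frames,
empty event lists and too-short trajectories return empty results rather
than errors; constant FRAP traces (no bleach depth), saturated calibration
inputs, empty masks and zero whole-cell fluorescence raise `ValueError`.
All stochastic code takes a seed or `numpy.random.Generator`; identical
seeds reproduce reports byte for byte.

## Problem sizes used in the test and acceptance runs

Twenty 20×20 µm cells with 300+300 puncta at SNR 5 for colocalization
recovery; 100 null iterations and 50 CSR runs for calibration; 100 random
point sets (n ≤ 2000) and 1000 random frame pairs (≤ 6 particles) for the
oracle checks; 200-trajectory ensembles of 300 frames for classification;
100 FRAP curves per mobile fraction; three 400-frame 128×128 puff movies
(20 events each).  These sizes give binomial/Monte-Carlo error comfortably
below the accuracy bands being checked while keeping a full run in well
under a minute per stage on one CPU.

## Known limitations

* The radial-profile flattening rule and its defaults are one reasonable
  operationalization of a verbally specified border criterion.
* Object randomization treats B puncta as independent rigid objects; any
  exclusion structure between real puncta beyond non-overlap is not
  preserved.
* The α-band classifier ignores trajectory-level uncertainty in α; near-band
  trajectories can flip class with noise (the acceptance ensembles quantify
  the practical error rates).
* FRAP fitting assumes a single-exponential recovery; reaction-dominant or
  two-component recoveries will bias τ (though Mf is less sensitive).
* Puff amplitudes are smoothed ΔF/F₀ maxima; they are comparable in rank to
  FLIKA's internally normalized amplitudes but not numerically mapped to
  them.
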
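# Methods

This note documents the models, parameter choices and numerical decisions
behind `csfflow`, and what its synthetic validation does and does not show
about real data.

## Scene model (synthetic generator)

The generator emulates cross-sectional time-lapse imaging of fluid-filled
brain compartments seeded with sparse bright tracers.  A scene (`FlowSpec`)
is a set of disjoint polygonal compartments, each carrying one steady flow
model:

- **vortex** — solid-body rotation (tangential speed ωr) inside 80% of the
  vortex radius, tapering as cos² to zero at the rim.  The angular rate ω is
  calibrated on a dense deterministic in-region grid (spacing R/80) so that
  the *median speed over uniformly distributed points* equals the requested
  target to well within 1%; the median is the calibration point because it
  is the pipeline's reported statistic.  Handedness convention: the image
  is row-major with y increasing downward, and "clockwise" means a point
  directly right of the centre moves with negative y (v = ω·(dy, −dx)).
- **uniform** — constant drift at the target speed.
- **static** — zero flow (negative controls).

A movie-level zero-mean pulsatile term A·sin(2πft) can ride on every
compartment's field along a configurable axis.  Its default amplitude is
**zero**: in the system this generator emulates, pulsatile CSF flow is
absent during the covered embryonic stages, so the study conditions are
non-pulsatile; the term exists to test that time-averaged velocimetry
cancels zero-mean components (left-Riemann Euler integration of a sine over
whole periods cancels exactly on a uniform grid, which the tests exploit).

Particles are seeded uniformly per compartment at `particle_density`
(default 14 per 1000 px², chosen so the mean nearest-neighbour spacing,
≈4 px, stays comfortably above the 2-px resolvability limit of the default
2 µm blob σ at 2 µm pixels).  Each frame they advance by forward Euler with
sub-stepping capped at 0.1 px displacement per substep — stricter than
needed for positional accuracy because tangential Euler steps inflate orbit
radii linearly in step size; at 0.1 px the radius drift over a 240-frame
movie is 1–2%, negligible against the 10% recovery tolerance.  Particles
die per frame with probability 1 − `survival_prob` (or on leaving their
compartment) and are replaced at uniform-random in-compartment positions,
keeping the density exactly stationary and providing a steady supply of
fresh, independently seeded tracks.  Rendering: isotropic Gaussian blobs
(σ = 2 µm ≈ the lateral resolution of the emulated instrument) with ±20%
per-particle amplitude jitter, constant background offset and i.i.d.
Gaussian noise.  Blob SNR (peak amplitude / noise sd) defaults to 10.
Identical spec + seed gives bit-identical movies and ground truth.

What the generator does **not** emulate: correlated OCT speckle, shadowing
and attenuation artefacts, particle polydispersity, out-of-plane motion and
focus drift, wall-attached debris.  Passing recovery tests therefore show
the chain is correct and well-calibrated for sparse-blob advection imaging;
they do not certify performance on heavily speckled or dense scenes.

## Detection

Scale-matched LoG filtering, σ = blob_radius/√2, sign-flipped and
scale-normalized (×σ²) so bright blobs give positive responses comparable
across scales.  The image mean is removed before filtering because the
truncated discrete LoG kernel does not annihilate constants exactly.
Local 3×3 maxima above the quality threshold (default: 5× the MAD-robust sd
of the response, a data-driven noise floor) are refined by per-axis
quadratic interpolation (clamped to ±0.5 px) and non-maximum-suppressed at
one blob radius, higher quality first, lexicographic (row, col) order
breaking exact ties.  Maxima within one blob radius of the border are
discarded (no valid 3×3 fit).  At the default density ~9% of particle
pairs fall inside the suppression radius and merge; this is a resolvability
property of the scene, not a detector defect, and downstream stages are
robust to it.

## Linking

Frame-to-frame linking solves the square augmented assignment problem
(costs = squared displacement, links pruned at `max_link_distance`,
diagonal "no-link" alternatives priced at 1.05× the largest allowed cost,
zero lower-right completion block), which minimizes
Σ(link costs) + alt·(#unlinked) exactly; `scipy.optimize.linear_sum_assignment`
provides the solver and its canonical lowest-row-first ordering fixes ties.
A second assignment pass joins track ends to later track starts
(gap ≤ `max_gap_frames`, distance ≤ `max_gap_distance`) and chains are
merged; single-detection orphans are dropped.  The default linking radius
is twice the per-frame displacement of the fastest expected flow — at
33 µm/s and 30 fps that is ≈2.2 µm, to which experiment configs add one
pixel of localization-noise allowance.

## Windowed WLS velocimetry

Windows hold `window_frames` points (default: half a second of frames, 15
at 30 fps; a full-second window is a config choice).  A trailing remainder
of ≥3 points forms its own shorter window, smaller remainders merge into
the previous one; tracks shorter than 3 points contribute nothing.  Weights
default to detection quality normalized per window to (0, 1] (uniform
fallback when degenerate); the closed-form normal equations give the
velocity, the weighted centroid gives the position, and the fit confidence
1/(1 + RMS/pixel) feeds the GP noise model.  Window-level vectors (not
per-track medians) are passed downstream: each window is an
independent-enough, locally linear summary, and the dense-field stage is
the place where spatial aggregation happens.  For rotating flow the linear
fit underestimates arc speed by ~θ²/24 over a window of turning angle θ —
<1% at the speeds and window lengths used here.

## GP dense field

Velocity components are fitted independently (two scalar GPs; no
divergence-free coupling) with an isotropic squared-exponential kernel and
homoscedastic noise scaled per observation as σ_n²/wᵢ.  Targets are
centred on their weighted mean, which makes constant fields exact.
Hyperparameters (ℓ, σ_f², σ_n²) maximize the log marginal likelihood over
log-parameters with analytic gradients, L-BFGS-B, and 3 extra seeded random
restarts; bounds keep ℓ within [10⁻³, 10]× the data span.  Exact GP cost is
cubic, so the optimization runs on a seeded subsample of ≤400 vectors and
the final predictor conditions on ≤2000 (seeded subsample); both caps are
package defaults, recorded in the output metadata.  The reported
uncertainty is the posterior sd of the latent field (it tends to the prior
sd far from data and is minimal at observations).  The pipeline fits one
GP per labelled compartment rather than one across the whole ventricle
union: compartments are separated by walls, and a stationary kernel would
otherwise smooth across unconnected regions.

## Statistics

Median speed = median of vector norms in the selection; dense-field pixels
by default (every masked pixel contributes one vector, matching how an
operator reads the speed map), sparse stage-2 vectors by option (then n
reflects data rather than grid resolution).  Areas are label pixel counts ×
pixel area.  Wilcoxon matched-pairs: zeros dropped, midranks, exact
conditional distribution of W⁺ for n ≤ 25 via subset-sum convolution over
doubled ranks (ties stay exact), normal approximation beyond; two-sided
p = 2·min(tails) capped at 1.  Mann–Whitney: exact when both groups ≤10
and tie-free, otherwise tie-corrected normal approximation without
continuity correction (identical samples then give p = 1 exactly).
Significance threshold α = 0.01 throughout.

## Visualization

Polarity projections estimate the static background as the per-pixel
temporal median over the *whole* movie (so short selected ranges still
foreground correctly), threshold the residual at 5× its MAD-sd, tint each
frame's foreground by its time-indexed colormap colour (default viridis)
and max-project; the background renders grayscale underneath.  Kymographs
sample bilinearly at unit-pixel arc-length steps along a polyline with
optional transverse averaging.  Beat frequency is the argmax of the
position-averaged one-sided power spectrum excluding DC, declared 0 when
the peak is below 3× the spectral median (the "no beat" criterion used for
paralyzed-cilia fixtures).

## Recovery experiments and problem sizes

The acceptance experiments configure the five stage-46 compartments as
vortices at the published medians (3.5/6.2/6.6/11.8/33.2 µm/s), 2 µm
pixels, 30 fps, 240 frames, SNR 10 and per-frame survival set so ≥150
distinct tracks arise per compartment (~35 standing particles each).  These
sizes keep a full five-compartment run under a minute on one CPU while
leaving estimator error well inside the ±10% tolerance; pilot runs across
seeds put single-compartment relative errors at 2–5%.  The paired
"ablation" experiments use 8 simulated animals, each a small
single-compartment movie (60 frames, ~15 particles) with its own speed
drawn from 5–12 µm/s, analysed twice with fresh particle seeds and
summarized by sparse-vector medians; with n = 8 the smallest attainable
two-sided exact p is 2⁻⁷ ≈ 0.0078, so flow-loss detection at α = 0.01
requires (and gets) a consistent sign across all animals.

## Known limitations

- Exact GP only; very dense vector sets are subsampled rather than
  approximated with inducing points.
- No motion-model (Kalman) tracking; crossing particles at displacements
  comparable to their separation can swap identities.
- The static/dynamic split in the polarity projection assumes a stationary
  background.
- 2D only; out-of-plane flow components are invisible by construction.
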
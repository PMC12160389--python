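# Methods

This note documents the models, parameter choices, and numerical decisions
behind `spontdyn`, and what its synthetic-data validation does and does not
establish about real recordings.

## Signal model and preprocessing

Raw fluorescence is modelled per pixel as
`F_pt = B_t · (1 + c_pt) + ε_pt`, where `B_t` is a multiplicative baseline
(constant or slowly drifting), `ε` is additive camera noise, and the
calcium signal follows the single-pole indicator recursion
`c_t = y_t + γ·c_{t−1}` with `y_t` the new activity and γ the per-frame
decay (0.89 per 20 ms for GCaMP8m).

* **Baseline** `F0_pt`: running rank-order filter, 36th percentile over a
  28.5 s window centred on `t`. Nearest-rank (ceil) indexing is used; at
  trace edges the window is truncated rather than padded, so edge baselines
  are order statistics of observed data only. The window length in frames
  is `round(28.5 s / Δt)` forced odd. `window_s=None` computes a
  whole-trace percentile — exact for drift-free recordings and O(T) rather
  than O(T·w); the validation runs use it because their synthetic sessions
  are generated without drift.
* **ΔF/F**: `r = (F − F0)/F0`; a non-positive baseline inside the ROI is an
  error naming the offending pixel.
* **Deconvolution** (prior-frame subtraction): `y_t = r_t − γ·r_{t−1}`,
  with `y_0 := r_0` (equivalent to assuming zero ΔF/F before the
  recording). This is the exact left-inverse of the indicator recursion:
  at zero noise the round trip reproduces planted activity to better than
  1e−9 (verified in float64).
* Motion correction is a pluggable pre-stage (identity by default);
  synthetic movies are motion-free.

## Event segmentation

A pixel is active when its deconvolved trace exceeds its own mean by 4 SD
(moments over the whole recording; zero-variance pixels are never active).
Per-frame masks are cleaned by binary opening with the 3×3 all-ones
element, then removal of 8-connected components smaller than 0.028 mm²
(13 pixels at the 0.0022 mm² pixel area); the explicit area rule is applied
because opening alone does not bound component area. Events are maximal
runs of frames with ≥ 1 active pixel, bounded by fully inactive frames;
runs touching the recording boundary are kept but flagged (their durations
are truncated, so they are excluded from wave fitting). Only events whose
union-across-frames active area reaches 1 mm² (455 pixels) are analysed.

## Correlation patterns and surrogates

Frames are band-passed with a difference of Gaussians (SDs 23 and 194 µm)
implemented as normalised convolution over the ROI, so out-of-ROI pixels
contribute nothing. Seed-point maps are Pearson correlations across the
per-event frames (maximally active frame, or within-event sum).

The surrogate null independently rotates every frame by a uniform multiple
of 10° and reflects it in x/y with probability 0.5 about the ROI centroid,
using nearest-neighbour resampling (interpolation would smooth the frames
and bias surrogate correlations downward); pixels mapped outside the ROI
become missing values and drop out of the correlation pairwise. The
long-range statistic is the median correlation at local maxima
(8-neighbourhood) whose distance from the seed lies in 1.3–1.7 mm, with an
800 µm minimum separation between maxima enforced with a *Euclidean* disk
footprint — a square (Chebyshev) neighbourhood would also suppress diagonal
module neighbours lying farther than the separation, emptying the band.
`p` is the fraction of surrogate medians ≥ the real median. A real map with
no maxima in the band is reported undefined, never `p = 0`; surrogates
without band maxima fall back to the band median so the null distribution
is not truncated. Calibration on isotropic noise gives an approximately
uniform `p` (≈5% of nulls below 0.05).

## Wavelength

The per-event wavelength is twice the radius of the first minimum of the
radially averaged 2-D autocorrelation of the band-passed frame. The
autocorrelation is computed by FFT over the zero-padded, ROI-masked frame
and normalised by the mask-overlap count at each lag (unbiased); the radial
profile is binned at one pixel pitch; the first bin lying below both
neighbours by at least 5e−3 (a prominence guard against numerical ripples)
marks the minimum, whose radius is refined by parabolic interpolation.
Frames whose profile has no qualifying minimum within the ROI radius return
undefined rather than a guess.

## Propagation and wavefront fitting

`PA` is the ever-active area outside nine 3×3 binary dilations of the
onset-frame mask (Chebyshev radius 9 px ≈ 420 µm at 46.9 µm pitch);
`PA = 0` defines static events. Pixel coordinates are pixel centres in mm,
origin at the ROI centroid, x along columns (rightward), y along rows
(downward), with θ measured from +x toward +y.

The planar model `t̂_ON = x·[cos θ, sin θ]/v + t_SHIFT` is fit by MSE over
onset times. For a fixed direction θ, the optimal slope `1/v` and
intercept are the exact linear least-squares solution, so the fit scans θ
on a 10° grid with the profiled closed-form optimum and then refines θ
continuously (bounded scalar minimisation, 1e−3 degree tolerance); only
directions with positive slope are admissible (the opposite direction
appears at θ+180°). This reaches the same argmin as a dense grid over
(v, θ, t_SHIFT) — asserted against an exhaustive scan in the tests — with
better resolution. Events with identical onsets everywhere are flagged
degenerate (simultaneous activation). Fitted speeds are clipped to
1–300 mm/s, and fits above the detectability ceiling
(FOV diameter / frame interval; 150 mm/s at 3 mm and 20 ms) are excluded
from the linear-fraction statistic.

Significance: the event's frame order is permuted (100 draws, permutations
not forced to be derangements), onset times recomputed, and the model
refit; fit quality is −MSE, so the real fit is significant when its MSE
lies below the 5th percentile of permuted MSEs. Events shorter than five
frames are excluded (too few distinguishable permutations), not failed.
Axial statistics double the angles folded mod 180° and apply the Rayleigh
test (via `pingouin`); given a significant axis, a two-sided binomial test
compares the counts travelling either way along it (±90° bins).

## Motif clustering

Exactly-five-frame (100 ms) dynamic events are band-passed, PCA-denoised
with 20 components *per frame position* (the basis per position matches the
permutation structure of the null), concatenated, and correlated pairwise.
The null permutes frame identity independently at each position across
events (preserving the shared rise-and-fall envelope), recomputes all
pairwise correlations, and pools the off-diagonals over 1,000 permutations;
the threshold is the pooled 99th percentile (a single global threshold).
Repeats per event count above-threshold partners; greedy clustering
repeatedly takes the remaining event with the most partners (ties to the
lowest index) together with those partners, stopping when a cluster would
have fewer than 10 events. `Fr` is the span of cluster initiation times
over the session duration; `Fb` the fraction of 10-minute bins containing a
cluster event. Silhouette scores (scikit-learn) compare the greedy
clustering with hierarchical and k-means alternatives at matched cluster
count; the frame-shuffle control deranges each member's frames (rejection
sampling, seeded), correlates the permuted vector with each cluster's mean
vector, and reports the fraction retaining their original cluster.

## Template groups and decoding

All frames of events ≤ 200 ms are each fit with a sum of elliptical 2-D
Gaussians — one component per local activity peak (minimum peak separation
4 px, capped at 10), initialised from local moments and refined by bounded
least squares with an analytic Jacobian; optimiser failure falls back to
the moment template, flagged. Seeding per peak rather than per connected
component keeps one Gaussian per module even when adjacent modules merge
into one component.

The membership threshold of a template is its worst Pearson correlation
with copies of itself translated on the integer grid within the one-SD
*ellipse* of its sharpest component (smallest geometric-mean SD; zero shift
included, so the threshold never exceeds 1). Two readings were considered
for "one SD" on multi-component templates: the widest component lets a
modular template shift by most of a module period, driving the threshold
toward zero and producing a single catch-all group; the sharpest component
keeps the threshold discriminative (~0.8 on synthetic sessions) and
recovers planted motif identity exactly, so it is the package's choice.

Grouping greedily selects the template with the most above-threshold
matched events among those not yet grouped; an event contributes only its
best-correlated frame. The decoder takes, per time offset, the session
frame at (template-frame time + offset) for every member — from the
continuous deconvolved movie, whether or not inside an event — projects
onto the first 8 principal components fit at that offset only (no leakage
across offsets), size-matches groups by subsampling (100 draws), and scores
an RBF-kernel SVM (C = 1, scale gamma) by stratified 5-fold
cross-validation. An offset is significant when ≥ 95% of subsamples beat
the 95th percentile of their own 100 label-shuffle accuracies. Offsets at
which any group runs out of frames are flagged invalid, not failed.

## Synthetic sessions: what they emulate

The generator's defaults are the reference study conditions: 46.9 µm
pixels (0.0022 mm² area), 20 ms frames, a 3 mm circular field of view,
0.69 mm modular wavelength, γ = 0.89, 6.9% static events, 32 mm/s planar
waves.

* **Modular patterns** are white noise filtered by a Gaussian spectral ring
  (relative bandwidth 0.15). The ring wavenumber is derived by root-finding
  the first minimum of the analytic (Hankel-transform) autocorrelation of
  the ring power spectrum, so the radially averaged autocorrelation of a
  generated pattern has its first minimum at `wavelength/2` *by
  construction* — the generator's `wavelength` is exactly the quantity the
  estimator measures. (Note that for a plane wave `cos(2πx/λ)` the radial
  average is Bessel-like and the estimator returns ≈1.22 λ; the modular
  definition above is the meaningful one for this analysis.)
* **Static events**: 2 frames, a morphologically robust footprint of
  550–750 px (~1.2–1.65 mm², matching observed static-event areas)
  pre-stabilised under opening and the minimum-component rule so that
  planted area equals detectable area; full amplitude at onset, decaying —
  every active pixel is active from the first frame.
* **Wave events**: a modular footprint (35% of the ROI) activating in the
  planar-onset order at 32 mm/s in a uniformly random direction, onsets
  quantised to the frame grid (optional Gaussian jitter), each pixel
  staying active for 2 frames; duration ≈ 5–7 frames, consistent with
  ~100 ms dynamic events.
* **Motif events**: five frames; an activation window of radius 1 mm
  travelling 0.2 mm/frame across the field gates modular fields that evolve
  with lag-one correlation 0.95, so events initiate with a localised module
  set and progress into new territory (hence classify as dynamic, and
  summed-event correlation maps resemble single-frame maps). Active values
  are concavely graded (square root) and normalised to unit mean so motif
  events are as bright as the other kinds; instances add 10% multiplicative
  noise. The library (6 motifs by default) is a deterministic function of
  the session seed.
* **Forward model**: indicator recursion, multiplicative baseline
  (1,000 counts) with optional sinusoidal drift, additive Gaussian camera
  noise (SD 2 counts — the camera noise level is a free parameter, not a
  claim). Event amplitude is 0.5 ΔF/F with a triangular envelope
  (floor 0.6). Quiet gaps are uniform 0.2–2 s (arbitrary, configurable).
  All randomness flows from one seed through `numpy.random.SeedSequence`;
  identical configurations are bitwise reproducible.

**What passing tests show — and do not.** Parameter recovery on these
sessions demonstrates that the implementation computes each statistic
correctly and that the chain of thresholds is self-consistent at realistic
signal-to-noise. It does not establish robustness to features the
generator omits: brain motion, haemodynamic or optical artefacts,
non-exponential indicator kinetics, overlapping/merged events, amplitude
heterogeneity across events, or non-planar wave shapes beyond the motif
construction.

## Problem sizes of the validation runs

The reproduction script (`scripts/acceptance.py`) uses 50 modular frames
(64×64) for the wavelength estimate, one 1,000-event session (~66×66 ×
~60,000 frames) for the static-event percentage, and 100 planar-wave
events for the speed recovery; the test suite runs the motif, template and
null-calibration analyses at tens of events and 100–200 permutations.
These sizes put every recovered quantity well inside its tolerance while
keeping a full run to a few minutes on one CPU; all counts are ordinary
function arguments, so larger studies are one parameter away.

## Known limitations

* The five-or-more-frames rule leaves wave significance untested for the
  brief static-like events; they are reported excluded, not insignificant.
* The greedy cluster/group algorithms are order-dependent by design
  (strongest first); ties resolve to the lowest event index for
  determinism.
* `peak_local_max` plateau handling means strictly flat correlation maps
  (a degenerate input) can report spurious maxima; real and synthetic maps
  are never flat.
* The decoder at paper-scale settings (±2,000 ms × 100 subsamples × 100
  shuffles) is computationally heavy; the defaults implement it faithfully
  and smaller settings are exposed as arguments.
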
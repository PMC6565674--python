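# Methods

This note documents the models, parameter choices and numerical decisions
behind `zfscreen`, and what the synthetic-data validation does and does not
establish about real recordings.

## Synthetic calcium recordings

**What is emulated.** Atlas-registered volumetric GCaMP recordings of a
larval zebrafish brain at 20 Hz: eleven labeled anatomical regions (Ce,
HBl, HBr, OBl, OBr, OTl, OTr, Pa, SPa, Ha, Th) tiled as connected Voronoi
cells of an ellipsoidal brain mask; neurons as small in-plane voxel
clusters; a light-stimulus protocol (pre-stimulus rest, then stimuli of
two 500-ms pulses 1 s apart delivered every 2 min); wild-type vs mutant
conditions; per-compound connectivity perturbations.

**Correlation planting.** Each neuron fires at total rate R (default
0.1 Hz). For an area pair (i, j) with target correlation ρ in a state, a
shared Poisson event stream of rate ρ·R is injected into all neurons of
both areas; each neuron adds private events at rate (1 − Σρ over its
pairs)·R. Binned counts of a cross-pair neuron pair then have correlation
exactly ρ (shared variance over total), which is analytically invertible
and preserved by the common calcium kernel (linear filtering of jointly
white streams leaves per-time correlation unchanged in expectation). A
request with Σρ > 1 for some area is unreachable and raises with the
attainable bound. Two caveats follow from the construction: within-area
correlation equals Σρ of that area's pairs (not independently
controllable), and empirical correlations over finite windows fluctuate
with the *number of shared events*, not just the frame count — resting
windows of a few minutes are needed before estimates settle.

**Rendering.** Spikes are convolved with a single-exponential calcium
kernel (1-frame rise, τ_decay = 1.5 s; indicator kinetics configurable),
scaled by a gain over a baseline fluorescence of 30 (arbitrary units), and
drawn into 2×2-voxel in-plane footprints. Gaussian noise (sd 2) is added
inside the brain mask only, as shot noise of the fluorescent tissue; the
outside is dark with a small constant camera offset. (Adding symmetric
noise to a near-zero background and clipping at zero would manufacture
heavy-tailed relative-fluorescence artifacts that no real dark background
shows.) The mutant condition multiplies all firing rates by a
stimulus-locked surge (×5, 5-s exponential decay) after each stimulus,
producing the photosensitive hyper-synchronous bursts of the model; the
spontaneous-burst rate in unstimulated recordings is a free parameter
(default 0) rather than an asserted value.

**Scale.** Default synthetic geometry is desk-scale: a few z-planes of
24×24–64×64 voxels and 3–20 neurons per region, at the real 20-Hz
volumetric rate. The validation suite uses 4×24×24 voxels, 3
neurons/region, a 240-s resting period and 1–3 stimuli; these sizes were
chosen once as the package's canonical validation conditions.

## Voxel processing

- *Time-varying filter*: a voxel is kept iff its trace's sample SD
  strictly exceeds the slice mean minus one slice SD, computed over the
  pre-stimulus window. The strict inequality makes the degenerate
  all-identical slice keep everything rather than discard everything.
- *Supervoxel merging*: k-means on features = unit-normalized standardized
  traces (squared Euclidean distance then equals 2(1−r)) reduced by PCA to
  ≤ 20 components, plus in-plane coordinates scaled to [0, 1]×0.5.
  Clustering runs per 12×12 slice neighborhood so the cluster budget
  scales with local voxel count — a whole-slice k-means spends its
  clusters splitting the large uncorrelated background cloud and leaves
  correlated neighboring neurons merged, which inflates inter-area
  correlations. k is selected per neighborhood by cross-validated
  reconstruction error over held-out timepoints, predicting each voxel's
  held-out trace by the mean of the *other* members of its cluster
  (singletons predict the voxel's time-mean), with the smallest k within
  0.5% of the minimum chosen so noise plateaus do not trigger spurious
  splits. Final k-means uses 10 restarts (4 during CV), seeded. Clusters
  are split into 8-connected in-plane components; adjacent fragments whose
  traces correlate above 0.9 are re-merged (they arise when a unit
  straddles a neighborhood border).
- *ΔF/F*: centred 20-s sliding-mean baseline with shrinking edge windows
  (alignment was an open choice; centred is symmetric and phase-free).
- *Active detection*: a supervoxel is active iff its resting ΔF/F maximum
  exceeds median + c·1.4826·MAD of the same resting trace, c = 4.5. The
  rule is scale-free, so its false-positive rate on plain Gaussian noise
  is governed by extreme-value statistics: the expected maximum of T
  independent noise samples is ≈ √(2 ln T)·σ ≈ 3.8σ at T ≈ 10³, hence a
  threshold at 3σ would flag most stationary-noise supervoxels. c = 4.5
  keeps the noise false-active rate below ~1% at typical resting lengths
  while transients an order of magnitude above the noise floor are always
  caught.

All windows are half-open `[start, end)` seconds; indices are 0-based
(t, z, y, x).

## Connectivity fingerprints

Per larva and (pair, state): Pearson r between every active supervoxel of
area A and every one of area B on ΔF/F restricted to the state's
concatenated windows (ΔF/F chosen for scale invariance); the metric is the
mean of |r|. A state contributing fewer than 100 frames is rejected
(missing). Early windows across stimuli are concatenated before
correlation — the fingerprint has exactly three state slots. Group
fingerprints average per-larva metrics, skipping missing entries; metrics
missing everywhere stay missing and are mean-imputed (logged) before
clustering. Significance of wild-type resting correlations is assessed
against circular-shift surrogates of the same larvae's traces (unpaired
two-tailed t-test across larvae, Jarque–Bera normality warning); the
surrogate null is a documented design choice, as the comparison sample for
that t-test was genuinely open. Divergence maps report the signed
difference of group means per pair with an unpaired t-test; pairs at
p ≥ 0.05 are reported as "no change".

## Clustering and polytherapy selection

Normalization is column-wise (x − mean)/sd (sample sd), constant columns
→ 0. Clustering: Ward linkage on Euclidean distances; the flat cut
maximizes the *relative* gap between successive merge heights (scale-free;
near-zero heights floored at 10⁻³ of the tallest merge so duplicate rows
do not force a maximal cut). The reference cluster is the one holding the
untreated wild-type rows (majority with a warning if split). Selection
repeats: recluster remaining compound rows with the fixed reference (and
optional context) rows; take the non-reference cluster with the nearest
centroid; select its compound row closest to the reference centroid;
eliminate the cluster. Cluster-to-reference distance is
centroid-to-centroid ("closest cluster" had no stated definition); ties
break lexicographically, making the result deterministic and row-order
invariant. BCD/WCD are centroid distance and mean within-group distance.

## Stationarity QA (ARR-κ)

κ is the sample variance (denominator T−1) of the 30-s sliding-window
correlation series, step 1 s. The surrogate null fits an AR(2) to *each
area trace*, draws jointly Gaussian innovations with the fitted residual
correlation, simulates stationary surrogate trace pairs, and pushes them
through the same sliding-window correlation; the verdict is *stationary*
iff the observed κ lies in the central 1−α band of the surrogate κ
distribution (α = 0.05). Fitting the AR(2) to the SWC series itself (the
procedure's verbal recipe) conditions the null on the observed κ and
leaves the test with neither size nor power; it is retained only as a
fallback when raw traces are unavailable and the trace-based form is the
shipped test, reported as "ARR-kappa" (the Priestley–Subba Rao test is
out of scope). Measured operating characteristics on desk-scale inputs:
false-dynamic rate 0.05 on stationary AR(2) pairs, power 1.0 against
sinusoidally modulated coupling. Innovations are Gaussian with matched
variance (residual bootstrap was the alternative); non-stationary AR fits
are shrunk toward white noise with a warning. The optional block-bootstrap
mode (5-min blocks assembled from shuffled 30-s windows) is off by
default.

Subgroup stability: each area's active supervoxels are split uniformly at
random into halves 50 times; the difference of the two half-pairings'
mean-|r| is recorded and a one-sample t-test against zero mean is
reported. Because random halves are exchangeable the differences are
sign-symmetric — heterogeneous subpopulations inflate their *dispersion*,
not their mean, and the returned differences should be inspected alongside
the p-value.

## Behavior

The tracker skeletonizes each silhouette, prunes spur branches, walks the
two-endpoint path, extends both ends to the silhouette boundary minus the
local medial radius (the skeleton of a disk-swept body stops short of the
tips; a blunt end needs a tight stop, a tapered tail ~1 px of slack),
smooths the path with a spline for sub-pixel vertices, and places 5 points
at arc-length quantiles {0, ¼, ½, ¾, 1}. The head is the endpoint with the
larger mean silhouette half-width over the first quarter of the path, ties
resolved by previous-frame continuity. Features: forward/lateral velocity
of the anterior midpoint decomposed along the body centreline (the two
anterior points); HV% counts frames above FV_mean + FV_STD and is defined
as 0 when FV_STD = 0; tail angles are the three posterior segment angles
relative to the centreline, absolute values summed (TB), with the summed
per-vertex frame-to-frame change as dTB. An optional moving-average window
(default off; 0.4–0.6 s in the validation scenarios) smooths velocities
and angles before the statistics — total-variation-like features (dTB,
HV%) are otherwise biased upward by pixel-quantization jitter. Divergence
of a feature is the absolute fractional deviation of the treated group
mean from the untreated baseline mean (unit-free before the RMS); a zero
baseline falls back to absolute difference with a log message. The
side-effect score is the RMS of the six divergences; its SD comes from
per-larva combined scores.

The validation motion program (velocity 25 px/s modulated ±50% at 0.25 Hz,
yaw 50 ± 80°/s, tail beat 12° at 1 Hz, body length 60 px at 25 fps) was
chosen so all six features have nonzero programmed values; tracked means
over 10 seeds agree with truth-track values within 5% per feature.

## LFP seizure detection and efficacy

EMD uses standard sifting: cubic-spline envelopes through maxima/minima
with the first and last two extrema mirrored beyond the signal ends
(anchoring envelopes at raw endpoint values drags them toward the signal
and leaks boundary artifacts into later IMFs), mean-envelope subtraction,
and a normalized-energy stopping criterion (tolerance 0.2, ≤ 30 sifts,
≤ 6 IMFs); extraction stops on a monotone residual. IMFs plus residual
reconstruct the input to float precision by construction. Features per
2-s segment (50% overlap) and per IMF (4 used, zero-padded): variance,
skewness, excess kurtosis. The first IMF of broadband noise is
intrinsically sub-Gaussian (excess kurtosis ≈ −0.6; sifting regularizes it
toward quasi-sinusoidal oscillation) — a property worth knowing when
interpreting the features; deeper IMFs are near-Gaussian. The classifier
is a linear discriminant on standardized features with balanced class
priors (seizure segments are a small training minority; empirical priors
miss low-amplitude event edges) and log-compressed variance features
(burst/background variance ratios span orders of magnitude). Recordings
are robust-scaled (1.4826·MAD) before feature extraction, making event
counts invariant to amplitude rescaling. Consecutive positive segments
merge into events; at least 2 consecutive positives are required, which
suppresses isolated false-positive segments over long recordings. Seizure
frequencies are normalized to a 45-min interval; the efficacy score is
1 − post/baseline — the unique linear map through the two anchors
(unchanged = 0, seizure-free = 1.00) — with negative values flagged as
worsening and zero-baseline larvae excluded by raising.

Measured on synthetic labeled recordings at the default SNR (burst peak
8× background SD): segment-level sensitivity ≈ 0.92 and specificity
≈ 0.99; all planted events in 45-min recordings are recovered with zero
false events.

## Dose–response screen

Conditions are monotherapies and pairwise combinations over the semi-log
dose grid {10%, 30%, 100%} of the screening concentration (m compounds ×
k doses → m·k + C(m,2)·k² rows; 15 for two compounds). Efficacy enters the
polytherapy-vs-monotherapy comparison at the per-larva level (unpaired
two-tailed t-tests vs each same-dose monotherapy); p-values are reported
raw, with Holm correction available but off by default.

## End-to-end screen

`pipeline.run_screen` drives a YAML-configured screen: planted wild-type
and mutant connectivity maps, per-compound restore fractions, recordings
per condition, fingerprint assembly, clustering + selection, stationarity
QA, and LFP/behavior scoring of the selected hits. One global seed fans
out to per-stage substreams; outputs are stamped with the config hash and
seed and byte-identical across repeated runs. Unknown config keys are
rejected against a versioned schema.

## What passing tests do and do not show

The synthetic generator plants exact second-order structure with bursty
Poisson spiking, but it does not model optics (light-sheet PSF,
scattering), registration error, motion or bleaching, overlapping neurons,
inhomogeneous firing statistics, or real seizure electrography. Passing
validation therefore establishes that the *algorithms* recover planted
structure under controlled conditions — correlation recovery within ±0.1,
pooled planted-vs-measured Pearson ≥ 0.95, exact selection agreement with
a brute-force oracle, detector sensitivity/specificity ≥ 0.9 — not that
the same accuracy holds on real recordings, where the unmodeled effects
dominate the error budget.

## Known limitations

- Supervoxel counts depend on the neighborhood tiling; units straddling
  borders rely on the correlation re-merge pass.
- Planted correlations are exchangeable within an area; within-area
  heterogeneity must be constructed manually (as the subgroup-stability
  tests do).
- The SWC-fit fallback of the ARR test is diagnostic only (no power).
- The behavioral tracker assumes one larva per region of interest and a
  tapered body; multi-animal scenes and identity tracking are out of
  scope.
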
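# Methods

`shrewhier` analyses multi-area extracellular recordings made while a
head-fixed animal views a standard battery of visual stimuli: locally sparse
noise, static gratings, naturalistic textures with spectrally matched noise
controls, and a large bank of object and face images. Because such recordings
are rarely shareable, the package pairs every analysis with a forward
simulator whose hidden parameters mirror every fitted quantity; all tests run
against that synthetic world.

## The synthetic world

**Geometry and timing.** The monitor subtends ±54° azimuth × ±38° elevation;
positions are degrees of visual angle with the screen centre at (0, 0).
Images are shown at 3 Hz (167 ms stimulus, 167 ms grey); sparse-noise frames
last 100 ms.

**Stimuli.** Sparse noise places one 5° dot per cell of a 4 × 3 scheduling
grid on every frame, all dots of one polarity (all white or all black per
frame, balanced and shuffled), with candidate dot centres on a finer 32 × 18
lattice (576 positions) so that histograms accumulate over a fixed location
set. Gratings form a 6 orientation × 5 spatial-frequency (0.1–1.6 cpd,
log-spaced) × 4 phase factorial — 120 conditions, five repeats. Textures come
as 15 families × 5 samples built from a shared family recipe (oriented
band-pass channels plus a coarse-envelope-gated fine channel, which creates
the cross-scale phase alignment that phase scrambling destroys); each texture
has a Fourier-phase-scrambled partner with an identical amplitude spectrum.
The object bank holds 1,392 procedural shaded silhouettes and 201 faces drawn
from a stereotyped part-based recipe (oval head, symmetric eyes, nose,
mouth), so faces cluster in feature space by appearance, never by label
injection.

**Features.** The default extractor is a fixed complex-Gabor energy stack
(4 orientations × 2 scales) followed, per "layer", by average pooling over a
window that doubles with depth and a seeded random **linear** readout to
4,096 dimensions; rectification lives entirely in the energy magnitude. Two
properties matter: features are a pure function of the image (no per-bank
normalisation), so auxiliary image banks live in the same space as the
stimulus bank; and the linear readout keeps the principal-component scores
close to elliptical, which the axis-model estimator implicitly assumes. A
PCA summary (default 50 components, deterministic SVD with sign fixing)
accompanies every layer. A trained DNN can be substituted through the same
interface; nothing in the package requires network weights.

**Neurons.** Each ground-truth unit carries a baseline rate (1–8 Hz),
response latency, circular Gaussian receptive field (centre, σ, ON/OFF/both
polarity, gain), Von Mises × log-Gaussian grating tuning, a unit-norm
preferred axis in the 50-component feature space with a ramp nonlinearity
(`rectified`, i.e. max(0, z), by default; `linear` available), texture
modulation with its own onset time, and a per-block waveform-amplitude
profile. Spiking is inhomogeneous Poisson: evoked terms switch on at the
unit's latency and last for the stimulus duration; negative rates are clipped
at zero and counted. Per-area defaults form a posterior-to-anterior ladder
(σ: 4° → 16°; latency: 40 → 90 ms), with texture modulation onsets of 45 ms
in the V2-like area and 90 ms in the V1-like area.

**What the generator does not emulate.** No eye movements, adaptation,
correlated (non-Poisson) variability, bursting, drift other than the block
amplitude profile, or photorealistic image content. A green recovery test
therefore establishes that the estimators are correct under the model
assumptions they state, not that they are robust to every failure mode of
real recordings.

## Analyses and numerical choices

**Responsiveness.** A unit is responsive to a class when its mean evoked
count in [0, 100] ms exceeds a Poisson expectation trained on the [−50, 0] ms
baselines of that class's trials by ≥ 5 SD; a unit is visually responsive if
it passes for any class. Because the expectation λ̂ is estimated from the
same N trials, the null SD of the difference is √(λ̂(1+s)/N) with s the
response/baseline duration ratio; the package defaults to this calibrated
form (null z ~ N(0,1); measured null rate 0/1000 at 5 SD). The naive
√(λ̂/N) convention is available (`include_baseline_variance=False`) but its
null z is over-dispersed by √3 at s = 2, which pushed the measured null rate
to 0.8%. Zero baselines are floored at half a spike across all windows.

**Block stability.** For the ten-block object set, the per-block waveform
amplitude is proxied by the mean spike amplitude (sorted outputs rarely ship
full waveforms); the threshold is 0.6 × the third-largest block amplitude and
blocks whose suprathreshold count falls below mean − 2 SD are dropped. With
fewer than three blocks the filter is skipped with a warning.

**Half-peak latency.** PSTH of trial-summed counts in 5-ms bins (no
smoothing), gratings and texture/noise trials pooled. The peak must exceed
the 99.75th percentile of the Poisson count implied by baseline firing; note
this is a per-bin criterion applied to the max over ~40 post-onset bins, so
its unit-level null rate is 1 − 0.9975⁴⁰ ≈ 9.5%, and the calibration tests
assert that construction-implied rate. Latency is the left edge of the first
bin at or above (r_baseline + r_peak)/2.

**Receptive fields.** Each frame's spikes credit all 12 dot locations; the
decorrelated placement cancels off-field credits in the average — almost.
The cancellation is exact only within the RF's own scheduling cell, so
locations in other cells inherit a small constant elevation and fitted σ is
compressed by roughly 20% for σ ≈ 5° (more for fields wider than a cell).
Centres are unaffected (< 1° error in recovery runs), the area *ordering* of
sizes is preserved exactly, and fits on location-wise Poisson data recover σ
within the stated 25%. The fit is a circular 2-D Gaussian plus constant
(σ ∈ [1°, 40°], centre within monitor + 10°, multi-start from the top-3
histogram peaks); quality Q = (O − E)/√E over the locations within 10° of
the fitted centre, with E from the fitted baseline; Q > 5 declares a field.
RF size defaults to the FWHM diameter 2√(2 ln 2)·σ (convention configurable).

**Tuning and texture.** Orientation: R(θ) = B + A·exp(κ(cos 2(θ−θ₀) − 1))
with 0–180° as the full period, trials pooled over SF and phase; a fit is
"included" when A ≥ 0.5 × the unit's mean grating rate. Spatial frequency:
Gaussian in log f; monotone profiles are clamped to the tested range and
flagged. Categorical variance explained is 100·(V_total − V_residual)/V_total
with population (divide-by-n) variances; at area scope both terms are summed
across cells before the ratio. Texture-vs-noise divergence uses a paired
two-tailed t-test across cells per 10-ms bin with per-bin α = 0.01 and no
multiplicity correction (so the family-wise null rate over k bins is
1 − 0.99ᵏ, which the calibration tests use); an optional consecutive-bins
requirement is exposed.

**Axis model.** The preferred axis is the normalised OLS coefficient vector
of per-image mean responses on the 50 PC scores (unwhitened) — the direction
whose 1-D projection maximises explained variance. Ten-fold cross-validation
over images: fold axes sign-aligned to fold 1 (ties toward a positive first
coordinate), averaged, renormalised; every image's projection comes from the
fold that excluded it; ev_cv is the squared correlation of held-out
projections with responses. With the default rectified ramp and the clustered
(hence non-elliptical) feature distribution, the OLS direction differs from
the generating axis by construction — a model-mismatch bias, not an estimator
defect — so recovery tests use linear ramp cells, for which noiseless
recovery is exact; at split-half explainable ≈ 0.5 and 1,593 images the
median cosine to ground truth exceeds 0.9. Explainable variance is the
Spearman–Brown-corrected split-half correlation 2ρ/(1+ρ) over odd/even
repeat halves (deterministic; seeded random split available), clamped to
[0, 1] with the raw value retained; it estimates the signal fraction of the
repeat-averaged response. Tuning curves rescale projections so the
nearest-rank 1st/99th percentiles map to ∓1 (98% of stimuli inside by
construction), with 16 equal bins and empty bins reported as missing.

**Decoding and reconstruction.** PC decoding regresses each feature
component on repeatedly subsampled 100-cell populations with 10-fold CV,
reporting held-out R² (negative values raw). Reconstruction maps decoded
scores back through the orthonormal basis (the Moore–Penrose pseudoinverse of
an orthonormal projection is its transpose), retrieves the nearest auxiliary
image by Euclidean distance in full feature space (ties to the lowest id),
and scores |v_recon − v_original| / |v_best − v_original| with v_best the
auxiliary image nearest the *original* (the alternative reading — nearest the
reconstruction — is a config flag). The auxiliary bank must be disjoint from
the presented images; a zero denominator raises.

**Selectivity and identity.** Face selectivity is a Welch t between
per-image mean responses to faces vs everything else plus
FSI = (μ_f − μ_o)/(μ_f + μ_o); t > 5 marks face cells and t ≥ 15 highly
selective ones. Identity decoding is hand-rolled Gaussian naive Bayes
(per-class per-neuron mean and variance, absolute variance floor 1e-6, flat
priors), trained on all-but-one repeat and tested on the held-out repeat,
resampling neuron subsets and splits; sklearn's GaussianNB serves as an
independent cross-check in tests, never as the implementation. The view
invariance index is the mean Pearson correlation between frontal and
non-frontal population vectors, averaged over views then identities. The
low-level control computes 13 versioned image indices (luminance, RMS and
Michelson contrast, foreground area/perimeter/compactness/aspect/centroid,
spectral centroid and bandwidth, orientation anisotropy, edge density),
their per-cell regression variance, an RF-weighted luminance/contrast
variant, and identity variance within seven spectral-centroid quantile
groups.

## Orchestration

`RunConfig` (YAML-loadable) fixes the world and all thresholds; every stage
derives its generator from the run seed by hashing the stage name, so equal
configs give byte-identical outputs. The demo configuration (5 areas × 24
units, 1,200 noise frames, 300 objects, 512-D features, reduced resampling)
finishes in ~1–2 minutes on one CPU; paper-scale stimulus counts are the
generator defaults and can be restored per field. Known limitations: the
demo's anterior areas have long latencies relative to the fixed 100-ms
response window, so their responsive fractions and decoding scores are
deliberately modest; normalized decoding distances sit above 1 because the
demo auxiliary bank is small and populations are 20 cells, not 100.
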
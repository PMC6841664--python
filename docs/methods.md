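# Methods

This note documents the models, conventions and design choices behind
`affectlink`.  It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A cohort watches short audio-visual clips while EEG and frontal video
are recorded; after each clip the viewer reports valence and arousal
(integers 1-9) and one of twelve emotion tags.  The analysis asks which
stimulus properties co-vary with which physiological responses.  Three
cue spaces are extracted per 15 s analysis window — 30 audio-visual
stimulus cues, 96 + 496 EEG features, 30 facial-geometry features —
and related pairwise by canonical correlation analysis (CCA), with the
canonical projections then correlated against the self-reported labels.
A separate analysis compares convolutional-network representations of
EEG topographic images and fused face images layer by layer.

Real recordings of this kind are restricted-access; the package
therefore ships a synthetic-data generator with a planted latent-affect
structure that serves as ground truth for every stage.

## Windowing

Recordings are cut into 15 s windows advanced by 1 s, giving
`floor((T - 15)/1) + 1` windows for a `T`-second recording (21 for 35 s,
103 for 117 s).  Windows overlap heavily, so window rows are strongly
dependent; see "Statistical honesty" below.

## Synthetic-data generator (`synthdata`)

Each trial draws a latent `z = (z_valence, z_arousal)`, i.i.d. standard
normal.  A `LinkageConfig` maps each modality knob to one latent at a
chosen signal-to-noise ratio: the knob receives `u = z + e`,
`e ~ N(0, 1/snr²)` (snr=None means noise-free; snr ≤ 0 is rejected).
Defaults: texture, lighting and audio follow valence; central-beta and
face geometry follow arousal; snr = 2.

* **Labels.** `clip(round(5 + 2 z + ε), 1, 9)` per axis with optional
  Gaussian label noise ε; the emotion tag is the latent's
  valence/arousal quadrant crossed with an intensity tier on the latent
  radius (r < 0.8 mild, < 1.6 moderate, else strong), giving the
  documented 12-tag vocabulary in `affectlink.types.EMOTION_TAGS`.
* **EEG.** Sum of band-limited Gaussian noise in theta (4-7 Hz, 4 µV),
  alpha (7-13 Hz, 6 µV), beta (13-30 Hz, 3 µV) plus a 1 µV broadband
  floor, synthesized in the frequency domain so band standard
  deviations are calibrated in microvolts.  At C3/Cz/C4 the beta
  amplitude is scaled by `exp(0.35 u)` — the planted arousal linkage.
  Optional artifact bursts (Hann-windowed transients, default 500 µV)
  exercise the cleaner.  The default montage is the common 32-electrode
  10-20 cap with approximate 2-D disk coordinates.
* **Frames.** A smooth base pattern (Gaussian-filtered noise, σ = 3 px)
  plus per-pixel grain with amplitude `0.09 exp(-0.5 u_texture)`: more
  texture latent means finer-grained-free, more homogeneous frames.
  The grain field is frozen within a shot so visual excitement tracks
  shot cuts rather than the texture knob; two anchor pixels pin the
  gray-level quantization range so the GLCM cues respond to grain
  amplitude rather than to range jitter.  Lighting level is
  `0.5 + 0.18 tanh(0.4 u_light)`; hue and saturation are constant per
  shot; scheduled cuts redraw the pattern and shift the hue.
* **Audio.** A three-harmonic stack at `f0 = 220·2^(0.25 u_pitch)` Hz,
  gain `10^(3 u_loud/20)`, a slow 0.2 Hz amplitude drift (nonzero
  loudness range), and optional 4 Hz amplitude modulation marking
  voiced clips.
* **Landmarks.** A canonical 49-point template (see
  `docs/face_features.md`); eye opening `0.030(1 + 0.22 u)` and nose
  scale `1 + 0.12 u` in template units, small per-frame jitter.  A
  rasterizer draws a simple skin-ellipse face for the detection/fusion
  path.

Desk-scale defaults (64×64 frames at 4 fps, 8 kHz mono audio, 32 × 256 Hz
EEG) reflect that frame content here is synthetic texture, not video;
the EEG shape matches the emulated headset exactly.  What the generator
does **not** emulate: volume conduction and electrode covariance
structure, photorealistic faces, real music/speech, and real-world
correlations between cues beyond the planted linkage.  Passing tests
therefore demonstrate that the pipeline recovers structure it is
designed to detect, not that it would find the same structure in real
recordings.

## Audio cues (19)

13 MFCCs (25 ms frames, 10 ms hop, 40 HTK-mel triangular filters, log
floored at 1e-10, orthonormal DCT-II, coefficients 1-13, frame means),
gated block loudness and loudness range (simplified two-stage
K-weighting: 2nd-order Butterworth high-pass at 60 Hz plus a 0.85
pre-emphasis shelf; 400 ms blocks, 100 ms hop; -70 absolute and -10
relative gates; range = 95th - 10th percentile; values are dB relative
to full scale, not absolute LUFS — analyses use relative levels only),
a voice-probability heuristic (per-frame harmonicity in the 85-300 Hz
f0 lag range times one-minus-spectral-flatness, scaled by the clip's
2-8 Hz envelope-modulation fraction; pluggable so a trained VAD can be
substituted), and three pitch features from a chromagram correlated
with Krumhansl-Kessler major/minor profiles (keyclarity = best key
correlation clipped to [0,1]; mode = best-major minus best-minor;
harmonic flux = mean L2 frame-to-frame change of the normalized 55-2000
Hz spectrum).  Silence returns documented sentinels (zero MFCCs, floor
loudness, zero range/voicing/pitch features).  Clip-level aggregation
is the mean over frames throughout.

## Visual cues (11)

GLCM texture uses 8 gray levels quantized over each frame's own range,
offsets {(0,1),(1,0)}, symmetric and normalized; descriptors are
contrast Σp(i-j)², energy Σp², homogeneity Σp/(1+|i-j|), and the
normalized (i,j) covariance (sentinel 0 when degenerate).  Lighting key
is the median LUV lightness (scaled to [0,1]) and the fraction of
pixels below the 0.2 shadow threshold (mirroring the saturation
convention).  Colour energy is mean(V·S) × std(V·S) in HSV — raw energy
times colour contrast.  Saturation proportion counts HSV saturation
> 0.2.  Visual excitement is the fraction of pixels whose CIE-Lab ΔE
(CIE76) exceeds 10 between consecutive frames, with frames wider than
128 px downscaled first.  Shots are declared where the mean per-channel
HSV histogram half-L1 difference exceeds 0.3 with a 0.6 s minimum scene
length; sequences faster than 8 fps are uniformly subsampled before cue
computation.  Cues are computed per 15 s window.

## EEG features (96 + 496)

Band power uses Welch's averaged periodogram (2 s Hann segments, 50%
overlap); the band value is the mean density over band bins, ordered
channel-major (theta, alpha, beta per channel) — 96 values for 32
channels.  The gamma band is deliberately excluded.  Conditional
entropy H(X|Y) = H(X,Y) − H(Y) is estimated from a joint histogram with
16 equal-width bins per channel over the window's own range, reported
in bits; the 496 features are the lower triangle (i > j, row-major) of
the 32×32 pair matrix.  Bits and 16 bins are configurable choices; the
estimator is the plug-in histogram estimator, adequate at 3840 samples
per window for 16 bins.

Cleaning is a simplified artifact-subspace method behind a `Cleaner`
protocol: 0.5 Hz high-pass (forward-backward Butterworth with long
even-symmetric padding — the filter rings for seconds at this cutoff),
a robust calibration covariance (0.5 s windows whose total RMS exceeds
3× the median are excluded), then 50%-overlapping windows whose
principal axes are compared against the calibration variance along the
same axes; directions exceeding k = 5 standard deviations are removed
and the window reconstructed from the retained subspace, with Hann
overlap-add so transients straddling window boundaries are still
caught.  Flat channels pass through with a logged warning.  A full
artifact-subspace-reconstruction implementation (calibration-data
selection, channel-wise RANSAC) can be substituted through the same
interface.

## CCA (`cca`)

Inputs are z-scored per column (constant columns dropped with a logged
warning).  The fit solves the whitened cross-covariance SVD
`(Cxx+rI)^(-1/2) Cxy (Cyy+rI)^(-1/2) = U S Vᵀ`; ridge r = 1e-3 by
default because the 496-dimensional entropy block against a limited
per-subject window count makes covariances singular; r = 0 is reserved
for full-rank oracle checks and raises a clear error on rank-deficient
input.  Feature attribution uses structure correlations ("loadings",
the correlation of each original feature with a canonical variate), not
raw weights; ties in |loading| break by frozen column order.  Fitting
is per subject by default, aggregated across subjects by mean absolute
loading; a pooled fit drives the behaviour correlations.

"Projecting back the joint space" is operationalized as the
first-component canonical variate scores per side plus loading-based
attribution.  Valence/arousal use Pearson correlation of the variate
with the labels, also reporting the cue maximizing
|corr(cue, variate)|·|corr(variate, label)|; emotions use a class-mean
linear model (one-hot with intercept = grand mean, coefficients =
class-mean deviations, frequency-weighted sum zero; classes with < 2
trials excluded), reporting the largest-|coefficient| class; band
contrasts use the paired-sample t-test with a documented sentinel
(t = 0, p = 1) for zero-variance differences.

### Statistical honesty

Overlapping windows inflate the effective sample size, so nominal
p-values from window-level correlations are optimistic.
`block_permutation_pvalue` permutes labels at the clip level (all
windows of a clip move together) and is the honest alternative;
reported nominal p-values should be read as descriptive.

### The planted-linkage experiment

`pipeline.linkage_experiment` reruns the core recovery claim: with the
texture knob moved to the arousal latent (lighting and audio stay on
valence), the 30 AV cues and 96 PSD features from n independent 15 s
windows are fit by CCA, and detection means the top AV |loading| is
`glcm_homogeneity` while the top EEG |loading| is a beta feature at
C3/Cz/C4.  The experiment uses ridge 0.5: the four GLCM cues are
near-collinear responses to the same grain knob, and a small ridge lets
the weight vector concentrate on whichever cue best denoises the shared
factor, boosting that cue's self-loading arbitrarily; a strong ridge
shrinks the weights toward the per-cue correlations (partial-least-
squares-like), making loading attribution stable.  Experiment-scale
settings (32×32 frames, 2 frames per window, 128 Hz EEG, coarser audio
hops) keep the 20-seed sweep tractable; the planted effect sizes are
untouched.

## RSA (`rsa`)

EEG windows become 32×32 RGB images: per band (theta→R, alpha→G,
beta→B), channel powers are interpolated over the unit scalp disk
(linear inside the electrode hull, nearest outside, zero outside the
disk), min-max scaled per image (a uniform band maps to flat 0.5).
Face inputs are wavelet-fused frames replicated to three channels.

The probe network is a width-reduced VGG-style stack — five blocks of
3×3 convolutions (2+2+3+3+3 = 13) with 2×2 max-pooling between blocks,
then two dense layers: 15 probe points, mirroring a 16-layer network
with its classification layer discarded.  It is a seeded, forward-only
NumPy implementation with He-initialized random weights; no training is
performed (no autodiff framework is used), which random-projection
theory and the package's own coupled-versus-decoupled test show is
sufficient for the structural similarity claims made here.  Per layer,
activations (subsampled to ≤ 4096 values with a seeded per-layer-index
mask, so equal-width layers share masks and self-comparison is exact)
yield an RDM of 1 − Pearson correlation across inputs (sentinel
dissimilarity 1 for zero-variance rows); the similarity matrix entry
(i, j) is the Spearman correlation between the upper triangles of the
two networks' RDMs — rank correlation being standard RSA practice.

## Face pipeline notes

Frame fusion uses a 4-level bior4.4 decomposition in periodization mode
(the transform stays square, so the fused coefficient set reconstructs
exactly): mean approximation, per-position max-|detail| selection.  The
default face "detector" finds the largest bright connected component
(matching the synthetic rasterizer) behind a pluggable interface that
accepts any candidate-box provider; candidates under 50×50 px or
touching the image margin are rejected.  Landmark detection itself is
out of scope — any 49-point provider plugs in, and the synthetic path
uses ground-truth landmarks directly.  For synthetic windows the
per-window **mean landmarks** feed the feature table (computing
features on the fused image via a re-run detector is the alternative
path for real video and is intentionally not the default).

## Problem sizes

Unit tests run at seconds-scale sizes.  The acceptance suite uses: the
exhaustive 15-300 s windowing sweep; 50 random CCA oracle fixtures
(p, q ≤ 6, n ≤ 500); 20 seeds × n = 2000 for planted-correlation
recovery; 1e5 samples for entropy calibration; 20 seeds × 1500 windows
at SNR 2 for the end-to-end linkage sweep; 50 inputs for the RSA null.
`scripts/acceptance.py` re-derives the same quantities at a reduced
sweep scale (8 seeds × 600 windows) and runs the full pipeline on a
small synthetic cohort.

## Known limitations

* The cleaner is a simplified subspace method, not full ASR; its
  guarantees are only those its tests establish (pass-through on clean
  synthetic data, ≥ 80% burst-peak attenuation).
* Loudness is relative, not calibrated LUFS; voice probability is a
  heuristic, not a trained VAD.
* The emotion regression is a class-mean model; with few classes
  present it degenerates gracefully but says little.
* Random-weight network activations support structural RSA claims only;
  trained-feature claims are out of scope.
* All recovery claims are conditional on the generator's planted
  linkage; none transfer to real recordings without revalidation.
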
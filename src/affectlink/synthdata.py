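"""Synthetic multimodal trial generator with a planted latent-affect structure.

Each trial draws a two-dimensional standard-normal latent (valence,
arousal) and derives every modality from it through documented knobs:

* frame texture fine-grain and lighting level  (-> GLCM homogeneity /
  contrast and lighting key in :mod:`affectlink.visualcues`),
* audio fundamental frequency and gain        (-> pitch / loudness cues),
* beta-band EEG amplitude at the central electrodes C3/Cz/C4
  (-> band power features in :mod:`affectlink.eegfeat`),
* eye-opening and nose-scale landmark geometry (-> eye-height / nose
  features in :mod:`affectlink.facefeat`),
* behaviour labels ``clip(round(5 + 2 z), 1, 9)`` per axis plus a
  12-way emotion tag chosen by latent quadrant x intensity tier.

The linkage is configurable: :class:`LinkageConfig` says which latent
drives each knob and at what signal-to-noise ratio (the knob sees
``z + e`` with ``e ~ N(0, 1/snr^2)``; ``snr=None`` means noise-free).
Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .montage import CENTRAL_CHANNELS, default_montage
from .types import (
    AudioClip,
    BehaviorLabels,
    EEGEpoch,
    EMOTION_TAGS,
    FrameSequence,
    LandmarkSequence,
    LatentAffect,
    StimulusClip,
    SynthTrial,
)

__all__ = [
    "LinkageConfig",
    "gen_dataset",
    "gen_trial",
    "gen_eeg",
    "gen_frames",
    "gen_audio",
    "gen_landmarks",
    "face_template",
    "render_face",
    "labels_from_latent",
    "emotion_from_latent",
]


# --------------------------------------------------------------------------
# linkage configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageConfig:
    """Which latent drives each modality knob, and how noisily.

    ``snr`` is the ratio of latent std (1) to knob-noise std; ``None``
    disables knob noise entirely.  ``label_noise_sd`` is the std of the
    Gaussian added to the 5 + 2z label rule before rounding.
    """

    snr: float | None = 2.0
    texture_latent: str = "valence"   # frame fine-texture grain
    lighting_latent: str = "valence"  # frame lightness level
    audio_latent: str = "valence"     # pitch + loudness
    beta_latent: str = "arousal"      # central-channel beta amplitude
    face_latent: str = "arousal"      # eye opening + nose scale
    label_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noise-free)")
        for attr in ("texture_latent", "lighting_latent", "audio_latent",
                     "beta_latent", "face_latent"):
            if getattr(self, attr) not in ("valence", "arousal"):
                raise ValueError(f"{attr} must be 'valence' or 'arousal'")

    def noisy_knob(self, latent: LatentAffect, which: str, rng: np.random.Generator) -> float:
        z = latent.z_valence if getattr(self, which) == "valence" else latent.z_arousal
        if self.snr is None:
            return float(z)
        return float(z + rng.standard_normal() / self.snr)


ZERO_NOISE = LinkageConfig(snr=None, label_noise_sd=0.0)


# --------------------------------------------------------------------------
# labels
# --------------------------------------------------------------------------

def emotion_from_latent(latent: LatentAffect) -> str:
    """12-way tag: valence/arousal quadrant (4) x intensity tier (3).

    Tiers split on the latent radius r = hypot(z_v, z_a): mild r < 0.8,
    moderate 0.8 <= r < 1.6, strong r >= 1.6.  The quadrant blocks in
    :data:`affectlink.types.EMOTION_TAGS` are (+v,+a), (-v,+a),
    (-v,-a), (+v,-a); zero counts as positive.
    """
    zv, za = latent.z_valence, latent.z_arousal
    if zv >= 0 and za >= 0:
        quadrant = 0
    elif zv < 0 and za >= 0:
        quadrant = 1
    elif zv < 0 and za < 0:
        quadrant = 2
    else:
        quadrant = 3
    r = math.hypot(zv, za)
    tier = 0 if r < 0.8 else (1 if r < 1.6 else 2)
    return EMOTION_TAGS[quadrant * 3 + tier]


def labels_from_latent(latent: LatentAffect, linkage: LinkageConfig,
                       rng: np.random.Generator) -> BehaviorLabels:
    """Affect labels linearly linked (plus optional noise) to the latent."""
    def scale(z: float) -> int:
        noise = linkage.label_noise_sd * rng.standard_normal() if linkage.label_noise_sd else 0.0
        return int(np.clip(round(5.0 + 2.0 * z + noise), 1, 9))

    return BehaviorLabels(
        valence=scale(latent.z_valence),
        arousal=scale(latent.z_arousal),
        emotion=emotion_from_latent(latent),
    )


# --------------------------------------------------------------------------
# EEG
# --------------------------------------------------------------------------

#: (low Hz, high Hz, baseline amplitude in microvolt std)
_EEG_BANDS = {"theta": (4.0, 7.0, 4.0), "alpha": (7.0, 13.0, 6.0), "beta": (13.0, 30.0, 3.0)}
_BROADBAND_UV = 1.0          # white floor over 0.5-45 Hz
_BETA_GAIN_PER_Z = 0.35      # log-amplitude slope of central beta vs latent


def gen_eeg(latent: LatentAffect, n_channels: int = 32, fs: float = 256.0,
            seconds: float = 15.0, seed: int | np.random.SeedSequence = 0, *,
            beta_knob: float | None = None,
            artifact_bursts: int = 0, burst_amp_uv: float = 500.0,
            burst_s: float = 0.2) -> EEGEpoch:
    """Band-limited oscillatory EEG with a planted arousal->beta linkage.

    Each channel is a sum of theta/alpha/beta band-limited Gaussian noise
    plus a small broadband floor, synthesized in the frequency domain.
    At the central electrodes the beta amplitude is scaled by
    ``exp(0.35 * u)`` where ``u`` defaults to ``z_arousal`` (pass
    ``beta_knob`` to override with a noisy knob value).  Optional
    high-amplitude artifact bursts support cleaner tests.
    """
    if fs < 64:
        raise ValueError("fs must be >= 64 Hz to resolve the beta band")
    n = int(round(seconds * fs))
    if n < 2 * int(fs):
        raise ValueError("recording shorter than one PSD window (2 s)")
    names, xy = default_montage(n_channels)
    rng = np.random.default_rng(seed)

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    nf = len(freqs)
    u = latent.z_arousal if beta_knob is None else beta_knob

    # per-channel, per-bin target std spectrum (microvolts)
    amp = np.zeros((n_channels, nf))
    central = [i for i, nm in enumerate(names) if nm in CENTRAL_CHANNELS]
    for band, (lo, hi, base_uv) in _EEG_BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        m = int(mask.sum())
        if m == 0:
            continue
        ch_amp = np.full(n_channels, base_uv)
        if band == "beta":
            ch_amp[central] *= math.exp(_BETA_GAIN_PER_Z * u)
        # scale so the band's time-domain std equals ch_amp
        amp[:, mask] += np.outer(ch_amp, np.ones(m)) * n / (2.0 * math.sqrt(m))
    bb = (freqs >= 0.5) & (freqs < 45.0)
    amp[:, bb] += _BROADBAND_UV * n / (2.0 * math.sqrt(bb.sum()))

    # irfft carries a 1/n factor; with per-bin std sigma_k = amp the
    # time-domain band std comes out at ch_amp microvolts (see amp scaling above)
    spec = (rng.standard_normal((n_channels, nf))
            + 1j * rng.standard_normal((n_channels, nf))) * amp
    data = np.fft.irfft(spec, n=n, axis=1)

    if artifact_bursts:
        burst_n = max(int(round(burst_s * fs)), 4)
        env = np.hanning(burst_n)
        for _ in range(artifact_bursts):
            ch = int(rng.integers(n_channels))
            t0 = int(rng.integers(0, n - burst_n))
            data[ch, t0:t0 + burst_n] += burst_amp_uv * env * np.sign(rng.standard_normal())

    return EEGEpoch(data=data, fs=fs, channel_names=names, channel_xy=xy)


# --------------------------------------------------------------------------
# frames
# --------------------------------------------------------------------------

def gen_frames(texture_knob: float = 0.0, light_knob: float = 0.0, *,
               n_frames: int = 60, fps: float = 4.0,
               size: tuple[int, int] = (64, 64), n_cuts: int = 0,
               saturation: float = 0.5, hue: float = 0.08,
               seed: int | np.random.SeedSequence = 0) -> FrameSequence:
    """Textured-noise frames with dedicated knobs per visual cue.

    * ``texture_knob`` shrinks the per-pixel fine-noise amplitude
      (``a = 0.09 exp(-0.5 u)``), raising GLCM homogeneity and lowering
      contrast as u grows.
    * ``light_knob`` shifts the global lightness level (lighting key).
    * ``n_cuts`` abrupt pattern-and-hue switches create detectable shots.
    * ``saturation``/``hue`` feed the colour-energy and saturation cues.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    h, w = size
    level = 0.5 + 0.18 * math.tanh(0.4 * light_knob)
    fine_amp = 0.09 * math.exp(-0.5 * texture_knob)

    # segment boundaries for planted shot cuts
    bounds = np.linspace(0, n_frames, n_cuts + 2).round().astype(int)
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    for s in range(n_cuts + 1):
        base = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0, mode="wrap")
        base /= max(base.std(), 1e-12)
        seg_hue = (hue + 0.31 * s) % 1.0
        # fine grain is frozen within a shot (static film grain); a small
        # per-frame flicker stays below the perceptual change threshold so
        # visual excitement tracks cuts, not the texture knob
        grain = rng.standard_normal((h, w))
        for t in range(bounds[s], bounds[s + 1]):
            v = (level + 0.12 * base + fine_amp * grain
                 + 0.01 * rng.standard_normal((h, w)))
            v = np.clip(v, 0.02, 0.98)
            # two anchor pixels pin the gray-level quantization range so the
            # GLCM cues respond to grain amplitude, not to range jitter
            v[0, 0], v[0, 1] = 0.02, 0.98
            hsv = np.stack([np.full_like(v, seg_hue), np.full_like(v, saturation), v], axis=-1)
            frames[t] = np.round(hsv2rgb(hsv) * 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=fps)


# --------------------------------------------------------------------------
# audio
# --------------------------------------------------------------------------

def gen_audio(pitch_knob: float = 0.0, loud_knob: float = 0.0, *,
              seconds: float = 15.0, fs: float = 8000.0, voiced: bool = False,
              seed: int | np.random.SeedSequence = 0) -> AudioClip:
    """Harmonic tone stack with pitch/loudness knobs and optional voicing.

    Fundamental ``f0 = 220 * 2**(0.25 u_pitch)`` with five 1/k harmonics;
    overall gain ``10**(3 u_loud / 20)`` (3 dB per latent unit) times a
    slow 0.2 Hz amplitude drift that gives a nonzero loudness range.
    ``voiced=True`` adds a 4 Hz amplitude modulation, the signature the
    voice-probability cue looks for.
    """
    n = int(round(seconds * fs))
    if n < int(0.05 * fs):
        raise ValueError("clip shorter than one analysis frame")
    rng = np.random.default_rng(seed)
    f0 = 220.0 * 2.0 ** (0.25 * pitch_knob)
    phase = (2.0 * np.pi * f0 / fs) * np.arange(n, dtype=np.float32)
    tone = np.zeros(n, dtype=np.float32)
    for k in range(1, 4):
        tone += np.sin(np.float32(k) * phase + np.float32(rng.uniform(0, 2 * np.pi))) / k
    tone /= np.max(np.abs(tone))
    t = np.arange(n, dtype=np.float32) / np.float32(fs)
    env = 1.0 + 0.3 * np.sin(2 * np.pi * 0.2 * t + np.float32(rng.uniform(0, 2 * np.pi)))
    if voiced:
        env *= 1.0 + 0.5 * np.sin(2 * np.pi * 4.0 * t)
    gain = 0.1 * 10.0 ** (3.0 * loud_knob / 20.0)
    samples = gain * env * tone + 0.003 * rng.standard_normal(n).astype(np.float32)
    return AudioClip(samples=np.clip(samples, -1.0, 1.0, dtype=np.float32, casting="unsafe"), fs=fs)


# --------------------------------------------------------------------------
# landmarks + rasterizer
# --------------------------------------------------------------------------

def face_template(eye_open: float = 0.030, nose_scale: float = 1.0,
                  lip_open: float = 0.012, mouth_width: float = 0.36) -> np.ndarray:
    """Canonical 49-point face in the unit square (y grows downward).

    Layout (0-based): 0-4 left eyebrow, 5-9 right eyebrow, 10-13 nose
    bridge (top->tip), 14-18 nose base (left->right, 16 = tip centre),
    19-24 left eye, 25-30 right eye (outer corner, 2 top, inner corner,
    2 bottom), 31-42 outer lip (left corner, 5 top, right corner,
    5 bottom right->left), 43-48 inner lip.
    """
    pts = np.zeros((49, 2))
    xs = np.linspace(0.14, 0.40, 5)
    pts[0:5] = np.column_stack([xs, 0.28 - 0.02 * np.sin(np.linspace(0, np.pi, 5))])
    pts[5:10, 0] = 1.0 - pts[0:5, 0][::-1]  # mirror across the midline
    pts[5:10, 1] = pts[0:5, 1][::-1]
    # nose bridge and base, scaled about the bridge top
    bridge = np.column_stack([np.full(4, 0.5), np.linspace(0.36, 0.54, 4)])
    base = np.array([[0.40, 0.60], [0.45, 0.615], [0.50, 0.62], [0.55, 0.615], [0.60, 0.60]])
    nose = np.vstack([bridge, base])
    anchor = np.array([0.5, 0.36])
    pts[10:19] = anchor + (nose - anchor) * nose_scale
    e = eye_open / 2.0
    pts[19:25] = [[0.23, 0.40], [0.27, 0.40 - e], [0.33, 0.40 - e],
                  [0.37, 0.40], [0.33, 0.40 + e], [0.27, 0.40 + e]]
    pts[25:31] = [[0.77, 0.40], [0.73, 0.40 - e], [0.67, 0.40 - e],
                  [0.63, 0.40], [0.67, 0.40 + e], [0.73, 0.40 + e]]
    wm = mouth_width / 2.0
    cx, cy = 0.5, 0.76
    top_x = np.linspace(cx - 0.6 * wm, cx + 0.6 * wm, 5)
    pts[31] = [cx - wm, cy]
    pts[32:37] = np.column_stack([top_x, cy - np.array([0.025, 0.035, 0.040, 0.035, 0.025])])
    pts[37] = [cx + wm, cy]
    pts[38:43] = np.column_stack([top_x[::-1], cy + np.array([0.045, 0.052, 0.055, 0.052, 0.045])[::-1]])
    pts[43] = [cx - 0.75 * wm, cy]
    pts[44:46] = [[cx - 0.3 * wm, cy - lip_open], [cx + 0.3 * wm, cy - lip_open]]
    pts[46] = [cx + 0.75 * wm, cy]
    pts[47:49] = [[cx + 0.3 * wm, cy + lip_open], [cx - 0.3 * wm, cy + lip_open]]
    return pts


def gen_landmarks(face_knob: float = 0.0, *, n_frames: int = 60,
                  image_size: tuple[int, int] = (256, 256),
                  jitter: float = 0.001,
                  seed: int | np.random.SeedSequence = 0) -> LandmarkSequence:
    """49-point trajectories with eye-opening and nose scale driven by the knob.

    ``eye_open = 0.030 (1 + 0.22 u)`` (floored at a sliver) and
    ``nose_scale = 1 + 0.12 u`` in template units; per-frame Gaussian
    jitter emulates head micro-motion.  The face box spans the middle
    half of the image.
    """
    rng = np.random.default_rng(seed)
    ih, iw = image_size
    box = (iw * 0.25, ih * 0.25, iw * 0.5, ih * 0.5)
    eye_open = max(0.030 * (1.0 + 0.22 * face_knob), 0.004)
    nose_scale = float(np.clip(1.0 + 0.12 * face_knob, 0.5, 1.6))
    unit = face_template(eye_open=eye_open, nose_scale=nose_scale)
    x0, y0, w, h = box
    base = unit * [w, h] + [x0, y0]
    traj = base[None] + jitter * min(w, h) * rng.standard_normal((n_frames, 49, 2))
    return LandmarkSequence(points=traj, face_box=box)


def render_face(landmarks: np.ndarray, face_box: tuple[float, float, float, float],
                image_size: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Rasterize a simple grayscale face for the detection/fusion path.

    Skin ellipse (bright) on a dark background, with eyebrows, eyes,
    nose and lips filled darker; synthetic stand-in for a camera frame.
    """
    ih, iw = image_size
    img = np.full((ih, iw), 40, dtype=np.uint8)
    x0, y0, w, h = face_box
    rr, cc = draw_ellipse(y0 + h / 2, x0 + w / 2, h * 0.62, w * 0.55, shape=img.shape)
    img[rr, cc] = 180
    for idx in (slice(0, 5), slice(5, 10), slice(19, 25), slice(25, 31),
                slice(31, 43), slice(10, 19)):
        poly = landmarks[idx]
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        img[rr, cc] = 80
    return img


# --------------------------------------------------------------------------
# trials
# --------------------------------------------------------------------------

def gen_trial(subject: int, clip: int, clip_seconds: float, linkage: LinkageConfig,
              seed: int, *, eeg_fs: float = 256.0, n_channels: int = 32,
              fps: float = 4.0, frame_size: tuple[int, int] = (64, 64),
              audio_fs: float = 8000.0, n_cuts: int | None = None,
              artifact_bursts: int = 0) -> SynthTrial:
    """One multimodal trial; all modalities share the trial latent."""
    ss = np.random.SeedSequence([seed, subject, clip])
    keys = ss.spawn(7)
    rng = np.random.default_rng(keys[0])
    latent = LatentAffect(*rng.standard_normal(2))

    knobs = {name: linkage.noisy_knob(latent, f"{name}_latent", rng)
             for name in ("texture", "lighting", "audio", "beta", "face")}
    if n_cuts is None:
        n_cuts = int(clip_seconds // 12)
    n_frames = max(int(round(clip_seconds * fps)), 2)

    frames = gen_frames(knobs["texture"], knobs["lighting"], n_frames=n_frames,
                        fps=fps, size=frame_size, n_cuts=n_cuts, seed=keys[1])
    audio = gen_audio(knobs["audio"], knobs["audio"], seconds=clip_seconds,
                      fs=audio_fs, voiced=bool(clip % 3 == 0), seed=keys[2])
    eeg = gen_eeg(latent, n_channels=n_channels, fs=eeg_fs, seconds=clip_seconds,
                  seed=keys[3], beta_knob=knobs["beta"],
                  artifact_bursts=artifact_bursts)
    lms = gen_landmarks(knobs["face"], n_frames=n_frames, seed=keys[4])
    labels = labels_from_latent(latent, linkage, np.random.default_rng(keys[5]))
    return SynthTrial(subject=subject, clip=clip,
                      stimulus=StimulusClip(audio=audio, frames=frames),
                      eeg=eeg, landmarks=lms, labels=labels, latent=latent,
                      seed=seed, knobs=knobs)


def gen_dataset(n_subjects: int, n_clips: int, clip_seconds: float,
                linkage: LinkageConfig | None = None, seed: int = 0,
                **trial_kwargs) -> list[SynthTrial]:
    """``n_subjects x n_clips`` multimodal trials with planted linkage.

    Emulates a cohort watching short stimulus clips; counts are
    configurable.  ``clip_seconds`` must cover at least one 15 s
    analysis window.
    """
    if n_subjects <= 0 or n_clips <= 0:
        raise ValueError("counts must be positive")
    if clip_seconds < 15:
        raise ValueError("clip_seconds must be >= 15 (one analysis window)")
    linkage = linkage if linkage is not None else LinkageConfig()
    return [gen_trial(s, c, clip_seconds, linkage, seed, **trial_kwargs)
            for s in range(n_subjects) for c in range(n_clips)]
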
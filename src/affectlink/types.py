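"""Shared container types for the multimodal affect pipeline.

All containers are thin dataclasses around NumPy arrays.  Conventions:

* EEG is stored channels x samples in microvolts.
* Frame sequences are ``(n_frames, height, width, 3)`` uint8 RGB.
* Audio is a mono float array (stereo inputs are downmixed by averaging
  at load time).
* Landmarks follow the 49-point layout documented in
  ``docs/face_features.md`` (eyebrows 2x5, nose 9, eyes 2x6, outer lip
  12, inner lip 6), pixel coordinates with y increasing downwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 12-category emotion vocabulary: 4 valence/arousal quadrants x 3
#: intensity tiers (mild, moderate, strong).  See docs/methods.md.
EMOTION_TAGS: tuple[str, ...] = (
    "amusement", "joy", "excitement",        # valence+, arousal+
    "anxiety", "fear", "anger",              # valence-, arousal+
    "boredom", "sadness", "disgust",         # valence-, arousal-
    "calmness", "contentment", "tenderness", # valence+, arousal-
)


@dataclass
class AudioClip:
    """Mono waveform with its sampling rate (Hz)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 2:  # stereo: downmix by averaging
            self.samples = self.samples.mean(axis=1)
        if self.samples.ndim != 1:
            raise ValueError("audio samples must be 1-D (mono) or 2-D (stereo)")
        if self.fs < 8000:
            raise ValueError(f"audio sampling rate must be >= 8000 Hz, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class FrameSequence:
    """Ordered RGB frames of uniform size plus the frame rate."""

    frames: np.ndarray  # (n, h, w, 3) uint8
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n, h, w, 3)")
        if len(self.frames) < 2:
            raise ValueError("a frame sequence needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class StimulusClip:
    """Paired audio waveform and frame sequence for one stimulus window."""

    audio: AudioClip
    frames: FrameSequence


@dataclass
class EEGEpoch:
    """Multichannel EEG segment.

    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Unique channel labels (10-20 montage names by default).
    channel_xy
        ``(n_channels, 2)`` 2-D scalp coordinates (unit head disk,
        nose towards +y), used for topographic interpolation.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_xy: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_xy = np.asarray(self.channel_xy, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        n = self.data.shape[0]
        if len(self.channel_names) != n or self.channel_xy.shape != (n, 2):
            raise ValueError("channel metadata does not match data shape")
        if len(set(self.channel_names)) != n:
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.channel_xy)):
            raise ValueError("channel coordinates must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class LandmarkSet:
    """49 facial landmarks plus the detected face box ``(x, y, W, H)``."""

    points: np.ndarray  # (49, 2) pixel coordinates
    face_box: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.shape != (49, 2):
            raise ValueError("expected exactly 49 (x, y) landmark points")
        _, _, w, h = self.face_box
        if w < 50 or h < 50:
            raise ValueError("face box below the 50x50 pixel minimum")


@dataclass
class LandmarkSequence:
    """Per-frame 49-point landmark trajectories for one window."""

    points: np.ndarray  # (n_frames, 49, 2)
    face_box: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 3 or self.points.shape[1:] != (49, 2):
            raise ValueError("expected shape (n_frames, 49, 2)")

    def mean_landmarks(self) -> LandmarkSet:
        """Per-window mean landmark positions (the synthetic-path default)."""
        return LandmarkSet(self.points.mean(axis=0), self.face_box)


@dataclass
class BehaviorLabels:
    """Self-reported affect: valence/arousal on 1..9, one of 12 emotion tags."""

    valence: int
    arousal: int
    emotion: str

    def __post_init__(self) -> None:
        if not (1 <= self.valence <= 9 and 1 <= self.arousal <= 9):
            raise ValueError("valence/arousal must lie in 1..9")
        if self.emotion not in EMOTION_TAGS:
            raise ValueError(f"unknown emotion tag {self.emotion!r}")


@dataclass
class LatentAffect:
    """Standard-normal latent affect coordinates driving a synthetic trial."""

    z_valence: float
    z_arousal: float


@dataclass
class SynthTrial:
    """One synthetic trial: all modalities generated from the same latent."""

    subject: int
    clip: int
    stimulus: StimulusClip
    eeg: EEGEpoch
    landmarks: LandmarkSequence
    labels: BehaviorLabels
    latent: LatentAffect
    seed: int
    knobs: dict = field(default_factory=dict)
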
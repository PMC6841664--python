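"""Eleven visual cues from a stimulus frame sequence.

The cue set mirrors what film-affect studies extract from a clip:
motion (visual excitement), editing pace (shot count / average shot
duration), lighting key (median lightness + shadow proportion in LUV),
colour energy, four GLCM texture descriptors, and the proportion of
saturated pixels.  All cues are averaged over the frames of the window
being analysed.

Conventions (configurable via keyword arguments):

* GLCM: 8 gray levels quantized over each frame's own range, offsets
  {(0,1), (1,0)}, symmetric, normalized to a joint probability.
  Descriptors use contrast = sum p (i-j)^2, energy = sum p^2,
  homogeneity = sum p / (1 + |i-j|), correlation = normalized (i,j)
  covariance (sentinel 0 for a zero-variance matrix).
* Lightness and shadow: LUV L channel scaled to [0,1]; shadow threshold
  0.2 by default.
* Visual excitement: fraction of pixels whose CIE-Lab delta-E exceeds 10
  between consecutive frames (frames wider than 128 px are downscaled
  first).
* Shots: normalized per-channel HSV histogram difference with threshold
  0.3 and a 0.6 s minimum scene length.
* Frame sampling: sequences faster than 8 fps are uniformly subsampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv, rgb2lab, rgb2luv
from skimage.transform import resize

from .types import FrameSequence

__all__ = [
    "VisualCues",
    "VISUAL_CUE_NAMES",
    "glcm_features",
    "lighting_key",
    "color_energy",
    "saturation_proportion",
    "visual_excitement",
    "detect_shots",
    "extract_visual_cues",
]

log = logging.getLogger(__name__)

VISUAL_CUE_NAMES: tuple[str, ...] = (
    "visual_excitement", "n_shots", "avg_shot_duration",
    "lighting_key_median", "shadow_proportion", "color_energy",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
    "saturation_proportion",
)


@dataclass(frozen=True)
class VisualCues:
    visual_excitement: float
    n_shots: int
    avg_shot_duration: float
    lighting_key_median: float
    shadow_proportion: float
    color_energy: float
    glcm_contrast: float
    glcm_correlation: float
    glcm_energy: float
    glcm_homogeneity: float
    saturation_proportion: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in VISUAL_CUE_NAMES], dtype=float)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _to_float(frames: np.ndarray) -> np.ndarray:
    return frames.astype(np.float64) / 255.0


def _quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of a grayscale frame over its own range."""
    lo, hi = float(gray.min()), float(gray.max())
    if hi <= lo:
        return np.zeros(gray.shape, dtype=np.intp)
    q = ((gray - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def cooccurrence_matrix(q: np.ndarray, levels: int,
                        offsets: tuple[tuple[int, int], ...]) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix."""
    counts = np.zeros(levels * levels, dtype=np.int64)
    h, w = q.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        counts += np.bincount((a * levels + b).ravel(), minlength=levels * levels)
    p = counts.reshape(levels, levels).astype(np.float64)
    p = p + p.T  # symmetric: count each pair in both directions
    total = p.sum()
    return p / total if total > 0 else p


def _glcm_descriptors(p: np.ndarray) -> tuple[float, float, float, float]:
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        log.warning("GLCM correlation undefined for zero-variance matrix; returning 0")
        correlation = 0.0
    else:
        cov = float((p * (i - mu_i) * (j - mu_j)).sum())
        correlation = cov / np.sqrt(var_i * var_j)
    return contrast, correlation, energy, homogeneity


# --------------------------------------------------------------------------
# cue operations
# --------------------------------------------------------------------------

def glcm_features(frames: FrameSequence, levels: int = 8,
                  offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0)),
                  ) -> tuple[float, float, float, float]:
    """Frame-averaged (contrast, correlation, energy, homogeneity)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    vals = np.empty((frames.n_frames, 4))
    for t, frame in enumerate(_to_float(frames.frames)):
        gray = frame.mean(axis=-1)
        p = cooccurrence_matrix(_quantize(gray, levels), levels, offsets)
        vals[t] = _glcm_descriptors(p)
    c, r, e, h = vals.mean(axis=0)
    return float(c), float(r), float(e), float(h)


def lighting_key(frames: FrameSequence, shadow_threshold: float = 0.2,
                 ) -> tuple[float, float]:
    """Frame-averaged (median lightness in [0,1], shadow-pixel proportion)."""
    medians, shadows = [], []
    for frame in _to_float(frames.frames):
        lightness = rgb2luv(frame)[..., 0] / 100.0
        medians.append(np.median(lightness))
        shadows.append(np.mean(lightness < shadow_threshold))
    return float(np.mean(medians)), float(np.mean(shadows))


def _color_energy_hsv(hsv: np.ndarray) -> float:
    vals = []
    for frame in hsv:
        p = frame[..., 2] * frame[..., 1]
        vals.append(p.mean() * p.std())
    return float(np.mean(vals))


def color_energy(frames: FrameSequence) -> float:
    """mean(brightness*saturation) x std(brightness*saturation), frame-averaged.

    The first factor is the raw colour energy (bright saturated area),
    the second the colour contrast; a gray or uniformly coloured frame
    scores 0.
    """
    return _color_energy_hsv(np.stack([rgb2hsv(f) for f in _to_float(frames.frames)]))


def saturation_proportion(frames: FrameSequence, threshold: float = 0.2) -> float:
    """Mean fraction of pixels with HSV saturation above ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    hsv = np.stack([rgb2hsv(f) for f in _to_float(frames.frames)])
    return float(np.mean(hsv[..., 1] > threshold))


def visual_excitement(frames: FrameSequence, jnd: float = 10.0,
                      max_width: int = 128) -> float:
    """Mean fraction of perceptually changed pixels between frame pairs.

    A pixel counts as changed when its CIE-Lab difference (delta-E 76)
    exceeds ``jnd``; 10 units is far above the just-noticeable ~2.3.
    """
    if frames.n_frames < 2:
        raise ValueError("need at least 2 frames")
    imgs = _to_float(frames.frames)
    if imgs.shape[2] > max_width:
        scale = max_width / imgs.shape[2]
        shape = (int(imgs.shape[1] * scale), max_width)
        imgs = np.stack([resize(f, shape + (3,), anti_aliasing=True) for f in imgs])
    labs = np.stack([rgb2lab(f) for f in imgs])
    de = np.sqrt(((labs[1:] - labs[:-1]) ** 2).sum(axis=-1))
    return float((de > jnd).mean(axis=(1, 2)).mean())


def _hsv_histograms(hsv: np.ndarray, bins: int) -> np.ndarray:
    out = np.empty((3, bins))
    for c in range(3):
        h, _ = np.histogram(hsv[..., c], bins=bins, range=(0.0, 1.0))
        out[c] = h / h.sum()
    return out


def _detect_shots_hsv(hsv: np.ndarray, fps: float, duration: float,
                      threshold: float, min_scene_s: float, bins: int,
                      ) -> tuple[int, float]:
    hists = np.stack([_hsv_histograms(f, bins) for f in hsv])
    scores = 0.5 * np.abs(hists[1:] - hists[:-1]).sum(axis=-1).mean(axis=-1)
    min_gap = min_scene_s * fps
    cuts: list[int] = []
    last_cut = -np.inf
    for t, s in enumerate(scores, start=1):
        if s > threshold and t - last_cut >= min_gap:
            cuts.append(t)
            last_cut = t
    n_shots = len(cuts) + 1
    return n_shots, duration / n_shots


def detect_shots(frames: FrameSequence, threshold: float = 0.3,
                 min_scene_s: float = 0.6, bins: int = 16) -> tuple[int, float]:
    """(number of shots, average shot duration in seconds).

    The content-change score for each frame transition is the mean over
    HSV channels of half the L1 histogram difference (in [0,1]); a cut
    is declared when the score exceeds ``threshold`` and the previous
    cut is at least ``min_scene_s`` ago.
    """
    hsv = np.stack([rgb2hsv(f) for f in _to_float(frames.frames)])
    return _detect_shots_hsv(hsv, frames.fps, frames.duration,
                             threshold, min_scene_s, bins)


def _subsample(frames: FrameSequence, max_fps: float = 8.0) -> FrameSequence:
    if frames.fps <= max_fps:
        return frames
    step = int(np.ceil(frames.fps / max_fps))
    sub = frames.frames[::step]
    if len(sub) < 2:
        sub = frames.frames[: 2]
        step = 1
    return FrameSequence(frames=sub, fps=frames.fps / step)


def extract_visual_cues(frames: FrameSequence, *, glcm_levels: int = 8,
                        shadow_threshold: float = 0.2,
                        saturation_threshold: float = 0.2,
                        shot_threshold: float = 0.3,
                        max_fps: float = 8.0) -> VisualCues:
    """All eleven visual cues for one frame sequence."""
    sub = _subsample(frames, max_fps=max_fps)
    contrast, correlation, energy, homogeneity = glcm_features(sub, levels=glcm_levels)
    key_median, shadow = lighting_key(sub, shadow_threshold=shadow_threshold)
    hsv = np.stack([rgb2hsv(f) for f in _to_float(sub.frames)])  # shared conversion
    n_shots, avg_shot = _detect_shots_hsv(hsv, sub.fps, sub.duration,
                                          shot_threshold, 0.6, 16)
    return VisualCues(
        visual_excitement=visual_excitement(sub),
        n_shots=n_shots,
        avg_shot_duration=avg_shot,
        lighting_key_median=key_median,
        shadow_proportion=shadow,
        color_energy=_color_energy_hsv(hsv),
        glcm_contrast=contrast,
        glcm_correlation=correlation,
        glcm_energy=energy,
        glcm_homogeneity=homogeneity,
        saturation_proportion=float(np.mean(hsv[..., 1] > saturation_threshold)),
    )
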
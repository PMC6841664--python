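"""Face-frame fusion and the 30 normalized landmark-geometry features.

The 49-point landmark layout is defined in
:func:`affectlink.synthdata.face_template` and documented in
``docs/face_features.md`` together with the canonical 30-feature table
(one row per feature: name, landmark indices, formula, normalizer).
That table is this package's frozen definition of the feature space:
it covers every measure affective-expression analysis relies on (eye heights and
widths, eyebrow-to-eye and eyebrow-to-lip distances, lip width and
height, inner-mouth area, nose area, width and height) plus documented
hand-picked geometry rows, for exactly 30.

Normalization: horizontal distances / W, vertical distances / H,
Euclidean distances / sqrt(W*H), polygon areas (shoelace) / (W*H) —
so the cues are invariant to face scale and position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .types import LandmarkSet

__all__ = [
    "FaceCues",
    "FACE_FEATURE_TABLE",
    "FACE_CUE_NAMES",
    "fuse_frames",
    "compute_face_cues",
    "detect_face",
    "shoelace_area",
]

log = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# the canonical 30-feature table
# --------------------------------------------------------------------------
# kinds: dx = |mean_x(A) - mean_x(B)| / W        (horizontal distance)
#        dy = |mean_y(A) - mean_y(B)| / H        (vertical distance)
#        dist = ||centroid(A) - centroid(B)|| / sqrt(W*H)
#        area = shoelace polygon area of A / (W*H)
FACE_FEATURE_TABLE: tuple[tuple[str, str, tuple, tuple], ...] = (
    ("left_eye_height",       "dy",   (20, 21), (23, 24)),
    ("right_eye_height",      "dy",   (26, 27), (29, 30)),
    ("left_eye_width",        "dx",   (19,), (22,)),
    ("right_eye_width",       "dx",   (25,), (28,)),
    ("left_eye_area",         "area", (19, 20, 21, 22, 23, 24), ()),
    ("right_eye_area",        "area", (25, 26, 27, 28, 29, 30), ()),
    ("left_brow_eye_dist",    "dy",   (0, 1, 2, 3, 4), (19, 20, 21, 22, 23, 24)),
    ("right_brow_eye_dist",   "dy",   (5, 6, 7, 8, 9), (25, 26, 27, 28, 29, 30)),
    ("left_brow_lip_dist",    "dist", (0, 1, 2, 3, 4), tuple(range(31, 43))),
    ("right_brow_lip_dist",   "dist", (5, 6, 7, 8, 9), tuple(range(31, 43))),
    ("brow_separation",       "dx",   (4,), (5,)),
    ("left_brow_length",      "dist", (0,), (4,)),
    ("right_brow_length",     "dist", (5,), (9,)),
    ("lip_width",             "dx",   (31,), (37,)),
    ("lip_height",            "dy",   (34,), (40,)),
    ("outer_mouth_area",      "area", tuple(range(31, 43)), ()),
    ("inner_mouth_area",      "area", tuple(range(43, 49)), ()),
    ("nose_width",            "dx",   (14,), (18,)),
    ("nose_height",           "dy",   (10,), (16,)),
    ("nose_area",             "area", (10, 14, 15, 16, 17, 18), ()),
    ("eye_separation_inner",  "dx",   (22,), (28,)),
    ("eye_separation_outer",  "dx",   (19,), (25,)),
    ("nose_lip_dist",         "dy",   (16,), (34,)),
    ("left_eye_lip_dist",     "dist", (22,), (31,)),
    ("right_eye_lip_dist",    "dist", (28,), (37,)),
    ("lip_corner_tilt",       "dy",   (31,), (37,)),
    ("brow_nose_dist",        "dy",   tuple(range(0, 10)), (16,)),
    ("inner_lip_height",      "dy",   (44, 45), (47, 48)),
    ("eye_mouth_dist",        "dy",   tuple(range(19, 31)), tuple(range(31, 43))),
    ("nose_eye_dist",         "dist", (16,), (22, 28)),
)

FACE_CUE_NAMES: tuple[str, ...] = tuple(row[0] for row in FACE_FEATURE_TABLE)
assert len(FACE_FEATURE_TABLE) == 30


@dataclass(frozen=True)
class FaceCues:
    values: np.ndarray  # 30 values ordered as FACE_CUE_NAMES

    def __getitem__(self, name: str) -> float:
        return float(self.values[FACE_CUE_NAMES.index(name)])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def shoelace_area(points: np.ndarray) -> float:
    """Unsigned polygon area of an ordered (n, 2) vertex ring."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def compute_face_cues(lm: LandmarkSet) -> FaceCues:
    """Evaluate the canonical 30-feature table on one landmark set."""
    _, _, w, h = lm.face_box
    if w <= 0 or h <= 0:
        raise ValueError("degenerate face box")
    pts = lm.points
    vals = np.empty(len(FACE_FEATURE_TABLE))
    for k, (_, kind, a_idx, b_idx) in enumerate(FACE_FEATURE_TABLE):
        a = pts[list(a_idx)].mean(axis=0)
        if kind == "area":
            vals[k] = shoelace_area(pts[list(a_idx)]) / (w * h)
            continue
        b = pts[list(b_idx)].mean(axis=0)
        if kind == "dx":
            vals[k] = abs(a[0] - b[0]) / w
        elif kind == "dy":
            vals[k] = abs(a[1] - b[1]) / h
        elif kind == "dist":
            vals[k] = float(np.hypot(*(a - b))) / np.sqrt(w * h)
        else:  # pragma: no cover - table is frozen
            raise ValueError(f"unknown feature kind {kind}")
    return FaceCues(values=vals)


# --------------------------------------------------------------------------
# wavelet fusion
# --------------------------------------------------------------------------

def fuse_frames(face_images: list[np.ndarray], wavelet: str = "bior4.4",
                level: int = 4) -> np.ndarray:
    """Fuse grayscale face frames into one representative image.

    Multilevel 2-D wavelet decomposition of each frame; the fused
    approximation is the per-position mean, each detail coefficient is
    taken from the frame with the maximum absolute value at that
    position; the inverse transform returns the fused image.
    """
    if len(face_images) == 0:
        raise ValueError("need at least one image")
    imgs = [np.asarray(im, dtype=np.float64) for im in face_images]
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("all face images must share one size")
    level = max(min(level, pywt.dwtn_max_level(shape, wavelet)), 1)
    # periodization keeps the transform square (bijective), so the fused
    # coefficient set corresponds exactly to the reconstructed image
    decs = [pywt.wavedec2(im, wavelet, level=level, mode="periodization")
            for im in imgs]

    fused = [np.mean([d[0] for d in decs], axis=0)]
    for lev in range(1, level + 1):
        bands = []
        for b in range(3):
            stack = np.stack([d[lev][b] for d in decs])
            pick = np.abs(stack).argmax(axis=0)
            bands.append(np.take_along_axis(stack, pick[None], axis=0)[0])
        fused.append(tuple(bands))
    out = pywt.waverec2(fused, wavelet, mode="periodization")
    return out[: shape[0], : shape[1]]


def read_landmarks_csv(path) -> "np.ndarray":
    """Load landmark trajectories from CSV with columns frame, x, y
    (49 rows per frame, point order as documented); returns
    ``(n_frames, 49, 2)``."""
    import pandas as pd

    df = pd.read_csv(path)
    frames = sorted(df["frame"].unique())
    out = np.empty((len(frames), 49, 2))
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != 49:
            raise ValueError(f"frame {f} has {len(sub)} landmark rows, expected 49")
        out[k] = sub[["x", "y"]].to_numpy()
    return out


# --------------------------------------------------------------------------
# face detection
# --------------------------------------------------------------------------

def detect_face(frame: np.ndarray, min_size: int = 50, margin: float = 0.02,
                detector=None) -> tuple[int, int, int, int] | None:
    """Face box ``(x, y, W, H)`` or ``None``.

    ``detector`` may be any callable ``frame -> iterable of (x, y, W, H)``
    candidate boxes (e.g. a Haar-cascade wrapper); the default finds the
    largest bright connected component, which matches the synthetic
    rasterizer's skin-on-dark rendering.  Candidates smaller than
    ``min_size`` square or touching the ``margin`` border fraction are
    rejected; the synthetic pipeline normally bypasses detection because
    landmarks are known.
    """
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame.mean(axis=-1)
    h, w = frame.shape

    if detector is not None:
        candidates = list(detector(frame))
    else:
        if frame.max() == frame.min():
            log.info("blank frame: no face")
            return None
        mask = frame > threshold_otsu(frame)
        labels = cc_label(mask)
        regions = regionprops(labels)
        candidates = []
        for r in sorted(regions, key=lambda r: r.area, reverse=True):
            minr, minc, maxr, maxc = r.bbox
            candidates.append((minc, minr, maxc - minc, maxr - minr))

    mr, mc = margin * h, margin * w
    for (x, y, bw, bh) in candidates:
        if bw < min_size or bh < min_size:
            continue
        if x < mc or y < mr or x + bw > w - mc or y + bh > h - mr:
            continue
        return int(x), int(y), int(bw), int(bh)
    log.info("no face candidate passed the size/margin filters")
    return None
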
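"""EEG cleaning, windowing, and the 96 + 496 EEG features.

Feature contract (frozen; loading interpretation downstream depends on
it):

* ``band_psd`` returns 3 values per channel in channel-major order
  (theta, alpha, beta per channel) -> 96 values for a 32-channel
  montage.  Bands: theta 4-7 Hz, alpha 7-13 Hz, beta 13-30 Hz (the
  gamma band is deliberately excluded).  Estimator: Welch averaged
  periodogram, 2 s Hann segments, 50% overlap; the band value is the
  mean spectral density over band bins.
* ``conditional_entropy_matrix`` returns the lower triangle (i > j,
  row-major) of the pairwise H(channel_i | channel_j) matrix ->
  C(32,2) = 496 values.  Estimator: 16 equal-width bins per channel
  over the window's own range, joint-histogram plug-in entropy, in bits.

Cleaning is a simplified artifact-subspace method behind the
``Cleaner`` protocol: high-pass at 0.5 Hz, principal axes from a
robust calibration covariance, and per-window removal of components
whose amplitude exceeds ``cutoff_k`` times the calibration scale.  A
full artifact-subspace-reconstruction implementation can be substituted
through the same interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Protocol

import numpy as np
from scipy import signal

from .types import EEGEpoch

__all__ = [
    "BANDS",
    "EEGCues",
    "Cleaner",
    "CleanerConfig",
    "SubspaceCleaner",
    "window_epochs",
    "clean_eeg",
    "band_psd",
    "psd_feature_names",
    "conditional_entropy_pair",
    "conditional_entropy_matrix",
    "entropy_feature_names",
    "extract_eeg_cues",
]

log = logging.getLogger(__name__)

#: band name -> (low Hz inclusive, high Hz exclusive)
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (7.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class EEGCues:
    """psd: channel-major band powers; cond_entropy: lower-triangle pairs."""

    psd: np.ndarray
    cond_entropy: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.psd, self.cond_entropy])


# --------------------------------------------------------------------------
# windowing
# --------------------------------------------------------------------------

def window_epochs(recording: EEGEpoch, win_s: float = 15.0, hop_s: float = 1.0,
                  ) -> list[EEGEpoch]:
    """Sliding windows: floor((T - win)/hop) + 1 segments of ``win_s``."""
    if recording.duration < win_s:
        raise ValueError("recording shorter than one window")
    win_n = int(round(win_s * recording.fs))
    hop_n = int(round(hop_s * recording.fs))
    count = (recording.n_samples - win_n) // hop_n + 1
    return [replace(recording, data=recording.data[:, k * hop_n:k * hop_n + win_n])
            for k in range(count)]


# --------------------------------------------------------------------------
# cleaning
# --------------------------------------------------------------------------

class Cleaner(Protocol):
    def __call__(self, recording: EEGEpoch) -> EEGEpoch: ...


@dataclass(frozen=True)
class CleanerConfig:
    highpass_hz: float = 0.5
    window_s: float = 0.5
    cutoff_k: float = 5.0
    calib_rms_factor: float = 3.0  # windows above this x median RMS are left out of calibration


class SubspaceCleaner:
    """Simplified artifact-subspace cleaner (see module docstring)."""

    def __init__(self, config: CleanerConfig | None = None) -> None:
        self.config = config or CleanerConfig()

    def __call__(self, recording: EEGEpoch) -> EEGEpoch:
        cfg = self.config
        if recording.duration < 10.0:
            raise ValueError("need >= 10 s of data for calibration statistics")
        x = recording.data
        flat = x.std(axis=1) < 1e-12
        if flat.any():
            names = [recording.channel_names[i] for i in np.where(flat)[0]]
            log.warning("flat channels passed through uncleaned: %s", names)

        if cfg.highpass_hz > 0:
            sos = signal.butter(4, cfg.highpass_hz, btype="highpass",
                                fs=recording.fs, output="sos")
            # long even-symmetric padding: the filter rings for seconds at
            # a 0.5 Hz cutoff and the default padding leaves edge transients
            padlen = min(x.shape[1] - 1, int(8.0 * recording.fs))
            y = signal.sosfiltfilt(sos, x, axis=1, padlen=padlen, padtype="even")
        else:
            y = x.copy()
        y[flat] = x[flat]

        win_n = max(int(round(cfg.window_s * recording.fs)), 8)
        n_win = y.shape[1] // win_n
        if n_win < 4:
            raise ValueError("recording too short for subspace calibration")
        wins = y[:, :n_win * win_n].reshape(y.shape[0], n_win, win_n)

        # robust calibration covariance: drop windows with outlying total RMS
        rms = np.sqrt((wins ** 2).mean(axis=(0, 2)))
        keep = rms <= cfg.calib_rms_factor * np.median(rms)
        calib = wins[:, keep, :].reshape(y.shape[0], -1)
        calib_cov = calib @ calib.T / calib.shape[1]

        # 50%-overlapping windows with Hann overlap-add reconstruction, so a
        # transient straddling a window boundary is central in the shifted
        # window and still caught
        k2 = cfg.cutoff_k ** 2
        hop = win_n // 2
        taper = np.hanning(win_n) + 1e-6
        acc = np.zeros_like(y)
        wsum = np.zeros(y.shape[1])
        for start in range(0, y.shape[1] - win_n + 1, hop):
            seg = y[:, start:start + win_n]
            win_cov = seg @ seg.T / win_n
            evals, vecs = np.linalg.eigh(win_cov)
            # calibration variance along each of this window's principal axes
            ref = np.maximum(np.einsum("ij,ij->j", vecs, calib_cov @ vecs), 1e-12)
            bad = evals > k2 * ref
            if bad.any():
                retain = vecs[:, ~bad]
                seg = retain @ (retain.T @ seg)
            acc[:, start:start + win_n] += seg * taper
            wsum[start:start + win_n] += taper
        tail = wsum == 0  # any trailing samples no window covered
        acc[:, tail] = y[:, tail]
        wsum[tail] = 1.0
        out = acc / wsum
        return replace(recording, data=out)


def clean_eeg(recording: EEGEpoch, config: CleanerConfig | None = None,
              cleaner: Cleaner | None = None) -> EEGEpoch:
    """Clean a recording with the default subspace cleaner (or a substitute)."""
    if cleaner is None:
        cleaner = SubspaceCleaner(config)
    return cleaner(recording)


# --------------------------------------------------------------------------
# band PSD
# --------------------------------------------------------------------------

def band_psd(window: EEGEpoch, bands: dict[str, tuple[float, float]] = BANDS,
             segment_s: float = 2.0) -> np.ndarray:
    """Mean Welch spectral density per (channel, band), channel-major."""
    hi_edge = max(hi for _, hi in bands.values())
    if window.fs / 2.0 < hi_edge:
        raise ValueError(f"fs too low to cover the {hi_edge} Hz band edge")
    nperseg = min(int(round(segment_s * window.fs)), window.n_samples)
    freqs, pxx = signal.welch(window.data, fs=window.fs, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    out = np.empty(window.n_channels * len(bands))
    for b, (lo, hi) in enumerate(bands.values()):
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            raise ValueError(f"no PSD bins inside band {lo}-{hi} Hz")
        out[b::len(bands)] = pxx[:, sel].mean(axis=1)
    return out


def psd_feature_names(channel_names: list[str],
                      bands: dict[str, tuple[float, float]] = BANDS) -> list[str]:
    return [f"psd_{ch}_{band}" for ch in channel_names for band in bands]


# --------------------------------------------------------------------------
# conditional entropy
# --------------------------------------------------------------------------

def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning over the series' own range (constant -> bin 0)."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros(len(x), dtype=np.intp)
    idx = ((x - lo) / (hi - lo) * bins).astype(np.intp)
    return np.minimum(idx, bins - 1)


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def conditional_entropy_pair(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    """H(X|Y) = H(X,Y) - H(Y) in bits, from an equal-width joint histogram."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    bx = _discretize(x, bins)
    by = _discretize(y, bins)
    joint = np.bincount(bx * bins + by, minlength=bins * bins)
    h_joint = _entropy_bits(joint)
    h_y = _entropy_bits(np.bincount(by, minlength=bins))
    return max(h_joint - h_y, 0.0)


def conditional_entropy_matrix(window: EEGEpoch, bins: int = 16) -> np.ndarray:
    """Lower-triangle H(ch_i | ch_j), i > j, row-major; C(n,2) values."""
    n = window.n_channels
    binned = np.stack([_discretize(window.data[c], bins) for c in range(n)])
    marginals = [np.bincount(binned[c], minlength=bins) for c in range(n)]
    h_marg = np.array([_entropy_bits(m) for m in marginals])
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(1, n):
        for j in range(i):
            joint = np.bincount(binned[i] * bins + binned[j], minlength=bins * bins)
            out[k] = max(_entropy_bits(joint) - h_marg[j], 0.0)
            k += 1
    return out


def entropy_feature_names(channel_names: list[str]) -> list[str]:
    return [f"ce_{channel_names[i]}|{channel_names[j]}"
            for i in range(1, len(channel_names)) for j in range(i)]


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def extract_eeg_cues(window: EEGEpoch, bins: int = 16,
                     include_entropy: bool = True) -> EEGCues:
    """PSD (+ optional conditional-entropy) features for one window."""
    psd = band_psd(window)
    ce = conditional_entropy_matrix(window, bins=bins) if include_entropy \
        else np.empty(0)
    return EEGCues(psd=psd, cond_entropy=ce)


def read_eeg_csv(csv_path, sidecar_path=None) -> EEGEpoch:
    """Load an EEG recording from CSV (channels as columns, one row per
    sample) plus a JSON sidecar carrying ``fs``, ``channel_names`` and
    ``channel_xy``; the sidecar defaults to ``<csv stem>.json``."""
    import json
    from pathlib import Path

    import pandas as pd

    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    df = pd.read_csv(csv_path)
    names = meta["channel_names"]
    return EEGEpoch(data=df[names].to_numpy().T, fs=float(meta["fs"]),
                    channel_names=list(names),
                    channel_xy=np.asarray(meta["channel_xy"], dtype=float))
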
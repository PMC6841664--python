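"""Nineteen audio cues from a stimulus waveform.

The cue vector is: 13 Mel-frequency cepstral coefficients (frame means,
coefficients 1-13 with the 0th energy coefficient excluded), gated mean
loudness plus loudness range (broadcast-style block measurement, LU-like
relative units), voice probability, and three pitch features
(keyclarity, mode, harmonic flux from a chromagram correlated against
Krumhansl-style key profiles).

Everything is built directly on scipy/NumPy:

* MFCC: 25 ms frames, 10 ms hop, Hann window, 40 triangular mel filters
  (HTK mel scale), log energies floored at 1e-10, orthonormal DCT-II.
* Loudness: simplified two-stage K-style weighting (2nd-order Butterworth
  high-pass at 60 Hz followed by a first-order pre-emphasis shelf),
  400 ms blocks with 100 ms hop, -70 absolute and -10 relative gating;
  range = 95th - 10th percentile of gated block loudness.  Levels are
  relative (dB re full scale), not absolute LUFS.
* Voice probability: a documented heuristic combining per-frame
  harmonicity (normalized autocorrelation peak in the 85-300 Hz f0
  range), spectral flatness, and clip-level 2-8 Hz amplitude-modulation
  energy; monotone in each component, in [0,1].  Pluggable: pass any
  callable ``clip -> float`` to :func:`extract_audio_cues` to substitute
  a trained voice-activity model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.fft import dct, next_fast_len, rfft

from .types import AudioClip

__all__ = [
    "AudioCues",
    "AUDIO_CUE_NAMES",
    "mfcc",
    "loudness",
    "voice_probability",
    "pitch_features",
    "extract_audio_cues",
]

log = logging.getLogger(__name__)

AUDIO_CUE_NAMES: tuple[str, ...] = tuple(
    [f"mfcc_{i}" for i in range(1, 14)]
    + ["loudness", "loudness_range", "voice_probability",
       "pitch_keyclarity", "pitch_mode", "pitch_harmonic_flux"]
)

_LOG_FLOOR = 1e-10
_SILENCE_RMS = 1e-6
_LOUDNESS_FLOOR_DB = -70.0

# Krumhansl-Kessler tonal hierarchy profiles (C major / C minor).
_KK_MAJOR = np.array([6.35, 2.23, 3.48, 2.33, 4.38, 4.09,
                      2.52, 5.19, 2.39, 3.66, 2.29, 2.88])
_KK_MINOR = np.array([6.33, 2.68, 3.52, 5.38, 2.60, 3.53,
                      2.54, 4.75, 3.98, 2.69, 3.34, 3.17])


def _rotations_z(profile: np.ndarray) -> np.ndarray:
    """All 12 key rotations of a profile, z-scored (for fast correlation)."""
    rots = np.stack([np.roll(profile, k) for k in range(12)])
    return (rots - rots.mean(axis=1, keepdims=True)) / rots.std(axis=1, keepdims=True)


_KK_MAJOR_Z = _rotations_z(_KK_MAJOR)
_KK_MINOR_Z = _rotations_z(_KK_MINOR)


@dataclass(frozen=True)
class AudioCues:
    mfcc: np.ndarray  # 13 coefficients
    loudness: float
    loudness_range: float
    voice_probability: float
    pitch_keyclarity: float
    pitch_mode: float
    pitch_harmonic_flux: float

    def as_array(self) -> np.ndarray:
        return np.concatenate([
            np.asarray(self.mfcc, dtype=float),
            [self.loudness, self.loudness_range, self.voice_probability,
             self.pitch_keyclarity, self.pitch_mode, self.pitch_harmonic_flux],
        ])


# --------------------------------------------------------------------------
# framing helpers
# --------------------------------------------------------------------------

def _frame(x: np.ndarray, frame_n: int, hop_n: int) -> np.ndarray:
    """(n_frames, frame_n) strided view of x; trailing partial frame dropped."""
    if len(x) < frame_n:
        raise ValueError("clip shorter than one analysis frame")
    return np.lib.stride_tricks.sliding_window_view(x, frame_n)[::hop_n]


@lru_cache(maxsize=8)
def _mel_filterbank_cached(n_mels: int, n_fft: int, fs: float) -> np.ndarray:
    return mel_filterbank(n_mels, n_fft, fs)


def mel_filterbank(n_mels: int, n_fft: int, fs: float) -> np.ndarray:
    """Triangular mel filters (HTK scale), shape (n_mels, n_fft//2 + 1)."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2.0), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.linspace(0.0, fs / 2.0, n_fft // 2 + 1)
    fb = np.zeros((n_mels, len(bin_freqs)))
    for m in range(n_mels):
        left, center, right = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - left) / max(center - left, 1e-12)
        down = (right - bin_freqs) / max(right - center, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


# --------------------------------------------------------------------------
# MFCC
# --------------------------------------------------------------------------

def mfcc(clip: AudioClip, n_coeffs: int = 13, frame_ms: float = 25.0,
         hop_ms: float = 10.0, n_mels: int = 40) -> np.ndarray:
    """Clip-level MFCCs 1..n_coeffs (frame means; 0th coefficient excluded)."""
    frame_n = int(round(frame_ms * 1e-3 * clip.fs))
    hop_n = max(int(round(hop_ms * 1e-3 * clip.fs)), 1)
    frames = _frame(clip.samples, frame_n, hop_n) * np.hanning(frame_n)
    power = np.abs(rfft(frames, axis=1)) ** 2
    fb = _mel_filterbank_cached(n_mels, frame_n, float(clip.fs))
    logmel = np.log(np.maximum(power @ fb.T, _LOG_FLOOR))
    coeffs = dct(logmel, type=2, norm="ortho", axis=1)[:, 1:n_coeffs + 1]
    return coeffs.mean(axis=0)


# --------------------------------------------------------------------------
# loudness
# --------------------------------------------------------------------------

def _k_weight(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(2, 60.0, btype="highpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, x)
    return np.concatenate([[y[0]], y[1:] - 0.85 * y[:-1]])  # pre-emphasis shelf


def loudness(clip: AudioClip, block_s: float = 0.4, hop_s: float = 0.1,
             ) -> tuple[float, float]:
    """(gated mean block loudness, loudness range) in dB-like relative units."""
    if clip.duration < 3.0 * 0.999:
        raise ValueError("clip must be >= 3 s for a meaningful loudness range")
    y = _k_weight(clip.samples, clip.fs)
    # block mean power via a cumulative sum (cheaper than explicit framing)
    block_n = int(round(block_s * clip.fs))
    hop_n = int(round(hop_s * clip.fs))
    csum = np.concatenate([[0.0], np.cumsum(y.astype(np.float64) ** 2)])
    starts = np.arange(0, len(y) - block_n + 1, hop_n)
    power = (csum[starts + block_n] - csum[starts]) / block_n
    level = 10.0 * np.log10(np.maximum(power, 10.0 ** (_LOUDNESS_FLOOR_DB / 10.0)))
    gated = level[level > _LOUDNESS_FLOOR_DB]
    if len(gated) == 0:  # all-silent clip
        return _LOUDNESS_FLOOR_DB, 0.0
    ungated_mean = 10.0 * np.log10(np.mean(10.0 ** (gated / 10.0)))
    gated = gated[gated > ungated_mean - 10.0]
    mean_loud = 10.0 * np.log10(np.mean(10.0 ** (gated / 10.0)))
    lo, hi = np.percentile(gated, [10.0, 95.0])
    return float(mean_loud), float(hi - lo)


# --------------------------------------------------------------------------
# voice probability
# --------------------------------------------------------------------------

def voice_probability(clip: AudioClip, frame_ms: float = 50.0,
                      hop_ms: float = 25.0, f0_range: tuple[float, float] = (85.0, 300.0),
                      ) -> float:
    """Heuristic speech-likeness score in [0, 1].

    Per frame: harmonicity h = peak normalized autocorrelation within the
    f0 lag range, spectral flatness s (geometric/arithmetic spectrum
    ratio).  Frame voicing v = h * (1 - s).  Clip score =
    mean(v) * (0.3 + 0.7 m) where m is the fraction of envelope
    modulation energy in the speech-syllable 2-8 Hz band.
    """
    frame_n = int(round(frame_ms * 1e-3 * clip.fs))
    hop_n = max(int(round(hop_ms * 1e-3 * clip.fs)), 1)
    frames = _frame(clip.samples, frame_n, hop_n)
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt((frames ** 2).mean(axis=1))
    active = rms > _SILENCE_RMS
    if not active.any():
        return 0.0

    # autocorrelation via FFT; padding by the largest lag of interest makes
    # the circular estimate exact (linear) over the f0 lag range
    lag_lo = max(int(clip.fs / f0_range[1]), 1)
    lag_hi = min(int(clip.fs / f0_range[0]) + 1, frame_n - 1)
    nfft = next_fast_len(frame_n + lag_hi + 1)
    spec = np.abs(rfft(frames, n=nfft, axis=1)) ** 2
    acf = np.fft.irfft(spec, n=nfft, axis=1)[:, :frame_n]
    harm = np.zeros(len(frames))
    denom = np.maximum(acf[:, 0], 1e-20)
    if lag_hi > lag_lo:
        harm = np.clip(acf[:, lag_lo:lag_hi].max(axis=1) / denom, 0.0, 1.0)

    power = spec[:, 1:nfft // 2]
    power = np.maximum(power, _LOG_FLOOR)
    flatness = np.exp(np.mean(np.log(power), axis=1)) / power.mean(axis=1)
    v = harm * (1.0 - np.clip(flatness, 0.0, 1.0))
    v[~active] = 0.0

    # 2-8 Hz amplitude-modulation fraction of the envelope spectrum
    env = rms - rms.mean()
    fs_env = clip.fs / hop_n
    if len(env) >= 8 and env.std() > 0:
        espec = np.abs(rfft(env)) ** 2
        efreq = np.fft.rfftfreq(len(env), 1.0 / fs_env)
        total = espec[1:].sum()
        mod = espec[(efreq >= 2.0) & (efreq <= 8.0)].sum() / total if total > 0 else 0.0
    else:
        mod = 0.0
    return float(np.clip(v.mean() * (0.3 + 0.7 * mod), 0.0, 1.0))


# --------------------------------------------------------------------------
# pitch features
# --------------------------------------------------------------------------

def _chromagram(clip: AudioClip, frame_ms: float, hop_ms: float,
                fmin: float = 55.0, fmax: float = 2000.0,
                ) -> tuple[np.ndarray, np.ndarray]:
    """(per-frame chroma (n,12), per-frame normalized harmonic spectra)."""
    frame_n = int(round(frame_ms * 1e-3 * clip.fs))
    hop_n = max(int(round(hop_ms * 1e-3 * clip.fs)), 1)
    frames = _frame(clip.samples, frame_n, hop_n) * np.hanning(frame_n)
    power = np.abs(rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frame_n, 1.0 / clip.fs)
    band = (freqs >= fmin) & (freqs <= fmax)
    pitch_class = (np.round(12.0 * np.log2(freqs[band] / 440.0)) + 69).astype(int) % 12
    chroma = np.zeros((len(frames), 12))
    for pc in range(12):
        sel = pitch_class == pc
        if sel.any():
            chroma[:, pc] = power[:, band][:, sel].sum(axis=1)
    harm = power[:, band]
    norms = np.linalg.norm(harm, axis=1, keepdims=True)
    harm = np.divide(harm, np.maximum(norms, 1e-20))
    return chroma, harm


def pitch_features(clip: AudioClip, frame_ms: float = 100.0, hop_ms: float = 50.0,
                   ) -> tuple[float, float, float]:
    """(keyclarity, mode, harmonic_flux).

    keyclarity = max Pearson correlation of the clip-mean chroma against
    the 24 rotated major/minor key profiles, clipped to [0,1]; mode =
    best-major minus best-minor correlation in [-1,1]; harmonic_flux =
    mean frame-to-frame L2 change of the normalized harmonic spectrum.
    Digital silence returns the (0, 0, 0) sentinel.
    """
    if np.sqrt(np.mean(clip.samples ** 2)) < _SILENCE_RMS:
        return 0.0, 0.0, 0.0
    chroma, harm = _chromagram(clip, frame_ms, hop_ms)
    mean_chroma = chroma.mean(axis=0)
    if mean_chroma.std() == 0:
        return 0.0, 0.0, 0.0

    cz = (mean_chroma - mean_chroma.mean()) / mean_chroma.std()
    best_major = float((_KK_MAJOR_Z @ cz).max() / 12.0)
    best_minor = float((_KK_MINOR_Z @ cz).max() / 12.0)
    keyclarity = float(np.clip(max(best_major, best_minor), 0.0, 1.0))
    mode = float(np.clip(best_major - best_minor, -1.0, 1.0))
    flux = float(np.linalg.norm(np.diff(harm, axis=0), axis=1).mean()) if len(harm) > 1 else 0.0
    return keyclarity, mode, flux


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def extract_audio_cues(clip: AudioClip, *, mfcc_hop_ms: float = 10.0,
                       vad_hop_ms: float = 25.0, pitch_hop_ms: float = 50.0,
                       vad=None) -> AudioCues:
    """All nineteen audio cues for one clip.

    Hop sizes are configurable (coarser hops trade temporal resolution
    for speed in large sweeps); ``vad`` may be any callable
    ``AudioClip -> float`` replacing the built-in voice-probability
    heuristic.
    """
    coeffs = mfcc(clip, hop_ms=mfcc_hop_ms)
    loud, loud_range = loudness(clip)
    vp = float(vad(clip)) if vad is not None else \
        voice_probability(clip, hop_ms=vad_hop_ms)
    key, mode, flux = pitch_features(clip, hop_ms=pitch_hop_ms)
    return AudioCues(mfcc=coeffs, loudness=loud, loudness_range=loud_range,
                     voice_probability=vp, pitch_keyclarity=key,
                     pitch_mode=mode, pitch_harmonic_flux=flux)
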
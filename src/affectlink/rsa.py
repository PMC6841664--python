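"""Representational similarity between EEG-image and face-image networks.

Pipeline: each 15 s EEG window is rendered as a 3-channel topographic
image (R/G/B = theta/alpha/beta band power interpolated over the scalp
disk); each face window is its fused grayscale frame replicated to
3 channels.  Both image sets are passed through a scaled-down VGG-style
convolutional stack (13 conv layers in 5 blocks + 2 dense layers = 15
probe points, mirroring a 16-layer network with its classification
layer discarded).  For every probe layer a representational
dissimilarity matrix (RDM, 1 - Pearson correlation between flattened
activations) is computed over the input set, and the layer x layer
similarity matrix holds the Spearman rank correlation between the
upper triangles of the two networks' RDMs.

The network is a seeded, forward-only NumPy implementation with He
initialization; at this scale RSA's structural claims (RDM symmetry,
self-similarity, coupled > decoupled inputs) do not require trained
weights.  Activations are subsampled to at most 4096 values per layer
with a seeded mask for cost control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import griddata

from .eegfeat import BANDS, band_psd
from .types import EEGEpoch

__all__ = [
    "TopoImage",
    "NetworkConfig",
    "VGGStyleNet",
    "build_network",
    "eeg_to_topo_image",
    "layer_rdm",
    "similarity_matrix",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# EEG -> topographic image
# --------------------------------------------------------------------------

@dataclass
class TopoImage:
    """RGB band-power scalp map plus the electrode -> pixel mapping."""

    image: np.ndarray                      # (side, side, 3) in [0, 1]
    channel_pixels: dict[str, tuple[int, int]]


def eeg_to_topo_image(window: EEGEpoch, side: int = 32) -> TopoImage:
    """Interpolate per-band channel powers onto the unit scalp disk.

    Linear interpolation inside the electrode hull, nearest-neighbour
    outside it, zero outside the scalp disk; each band is min-max
    scaled to [0, 1] per image (a constant band maps to 0.5 inside the
    disk).  Bands are stacked as RGB in theta/alpha/beta order.
    """
    if window.n_channels < 4:
        raise ValueError("need at least 4 electrodes for interpolation")
    powers = band_psd(window).reshape(window.n_channels, len(BANDS))
    xy = window.channel_xy
    grid = np.linspace(-1.0, 1.0, side)
    gx, gy = np.meshgrid(grid, grid)
    inside = gx ** 2 + gy ** 2 <= 1.0

    img = np.zeros((side, side, len(BANDS)))
    for b in range(len(BANDS)):
        vals = powers[:, b]
        lin = griddata(xy, vals, (gx, gy), method="linear")
        near = griddata(xy, vals, (gx, gy), method="nearest")
        band_img = np.where(np.isnan(lin), near, lin)
        lo, hi = band_img[inside].min(), band_img[inside].max()
        if hi - lo > 1e-9 * max(abs(hi), 1e-30):
            band_img = (band_img - lo) / (hi - lo)
        else:  # uniform band power: flat mid-gray inside the disk
            band_img = np.full_like(band_img, 0.5)
        band_img[~inside] = 0.0
        img[:, :, b] = band_img

    # pixel coordinates of each electrode (row, col); all inside the disk
    px = {name: (int(round((y + 1) / 2 * (side - 1))),
                 int(round((x + 1) / 2 * (side - 1))))
          for name, (x, y) in zip(window.channel_names, xy)}
    return TopoImage(image=img, channel_pixels=px)


# --------------------------------------------------------------------------
# scaled-down VGG-style network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Conv blocks as (filters, repeats) plus two dense widths.

    The default mirrors the 16-layer topology (2+2+3+3+3 convolutions,
    two dense layers) at reduced width for a 32 x 32 input.
    """

    blocks: tuple[tuple[int, int], ...] = ((8, 2), (16, 2), (32, 3), (32, 3), (32, 3))
    dense: tuple[int, int] = (64, 64)
    input_side: int = 32
    in_channels: int = 3
    seed: int = 0


class VGGStyleNet:
    """Forward-only convolutional stack with named probe layers."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        side = config.input_side
        rng = np.random.default_rng(config.seed)
        self.conv_weights: list[tuple[np.ndarray, np.ndarray, str]] = []
        self.probe_names: list[str] = []
        c_in = config.in_channels
        for bi, (filters, repeats) in enumerate(config.blocks, start=1):
            for ri in range(1, repeats + 1):
                w = rng.standard_normal((3, 3, c_in, filters)) * np.sqrt(2.0 / (9 * c_in))
                b = np.zeros(filters)
                name = f"conv{bi}_{ri}"
                self.conv_weights.append((w, b, name))
                self.probe_names.append(name)
                c_in = filters
            side //= 2
            if side < 1:
                raise ValueError("config collapses the spatial grid before the last block")
        flat = side * side * c_in
        self.dense_weights: list[tuple[np.ndarray, np.ndarray, str]] = []
        for di, width in enumerate(config.dense, start=1):
            w = rng.standard_normal((flat, width)) * np.sqrt(2.0 / flat)
            name = f"fc{di}"
            self.dense_weights.append((w, np.zeros(width), name))
            self.probe_names.append(name)
            flat = width

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        n, h, wd, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.zeros((n, h, wd, w.shape[-1]))
        for di in range(3):
            for dj in range(3):
                out += xp[:, di:di + h, dj:dj + wd, :] @ w[di, dj]
        return np.maximum(out + b, 0.0)

    @staticmethod
    def _pool(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        return x[:, : h // 2 * 2, : w // 2 * 2, :].reshape(
            n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))

    def forward(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """Probe activations for a batch of (n, side, side, channels) images."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.config.input_side:
            raise ValueError("batch must be (n, side, side, channels)")
        acts: dict[str, np.ndarray] = {}
        ci = 0
        for filters, repeats in self.config.blocks:
            for _ in range(repeats):
                w, b, name = self.conv_weights[ci]
                x = self._conv(x, w, b)
                acts[name] = x
                ci += 1
            x = self._pool(x)
        x = x.reshape(x.shape[0], -1)
        for w, b, name in self.dense_weights:
            x = np.maximum(x @ w + b, 0.0)
            acts[name] = x
        return acts


def build_network(config: NetworkConfig | None = None) -> VGGStyleNet:
    """Seeded VGG-style network; the default exposes 15 probe layers."""
    return VGGStyleNet(config or NetworkConfig())


# --------------------------------------------------------------------------
# RDMs and the similarity matrix
# --------------------------------------------------------------------------

def layer_rdm(activations: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation dissimilarity matrix over inputs.

    Rows with zero activation variance get the documented sentinel
    dissimilarity 1 off-diagonal.  The result is symmetric with an
    exactly zero diagonal.
    """
    a = np.asarray(activations, dtype=float).reshape(len(activations), -1)
    if len(a) < 3:
        raise ValueError("need at least 3 inputs for an RDM")
    sd = a.std(axis=1)
    dead = sd == 0
    safe = np.where(dead[:, None], np.nan, a)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(safe)
    rdm = 1.0 - np.clip(corr, -1.0, 1.0)
    rdm[dead, :] = 1.0
    rdm[:, dead] = 1.0
    rdm = 0.5 * (rdm + rdm.T)
    np.fill_diagonal(rdm, 0.0)
    return rdm


def _subsample(act: np.ndarray, max_values: int, rng: np.random.Generator) -> np.ndarray:
    flat = act.reshape(len(act), -1)
    if flat.shape[1] <= max_values:
        return flat
    idx = rng.choice(flat.shape[1], size=max_values, replace=False)
    return flat[:, idx]


def similarity_matrix(acts_a: dict[str, np.ndarray], acts_b: dict[str, np.ndarray],
                      max_values: int = 4096, seed: int = 0) -> np.ndarray:
    """Layer x layer Spearman correlation between the two networks' RDMs.

    ``acts_a`` and ``acts_b`` are probe-name -> activation dictionaries
    for the *same* ordered input-trial list shown to each network.
    Entry (i, j) compares the upper triangle of layer i's RDM (network
    A) with layer j's (network B); a degenerate constant RDM yields the
    0 sentinel.
    """
    n_a = {len(v) for v in acts_a.values()} | {len(v) for v in acts_b.values()}
    if len(n_a) != 1:
        raise ValueError("mismatched trial lists between networks")
    # one seeded mask per layer *index*: layers of equal width get the same
    # mask in both networks, so a self-comparison has an exactly-1 diagonal
    rdms_a = [layer_rdm(_subsample(v, max_values, np.random.default_rng([seed, i])))
              for i, v in enumerate(acts_a.values())]
    rdms_b = [layer_rdm(_subsample(v, max_values, np.random.default_rng([seed, i])))
              for i, v in enumerate(acts_b.values())]
    iu = np.triu_indices(next(iter(n_a)), k=1)
    out = np.zeros((len(rdms_a), len(rdms_b)))
    for i, ra in enumerate(rdms_a):
        va = ra[iu]
        for j, rb in enumerate(rdms_b):
            vb = rb[iu]
            if va.std() == 0 or vb.std() == 0:
                out[i, j] = 0.0
                continue
            rho = stats.spearmanr(va, vb).statistic
            out[i, j] = 0.0 if np.isnan(rho) else float(rho)
    return out
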
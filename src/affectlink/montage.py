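"""Default 32-channel scalp montage.

Channel order follows the common 32-electrode 10-20 cap layout used by
consumer research headsets (Biosemi-32 ordering).  Coordinates are
approximate 2-D positions on the unit head disk obtained by azimuthal
projection of the standard 10-20 sphere (nose towards +y, left ear at
-x).  They are used only for topographic interpolation and for naming
the central electrodes (C3, Cz, C4); millimetre accuracy is not needed.
"""

from __future__ import annotations

import numpy as np

# name -> (x, y) on the unit head disk
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "AF3": (-0.35, 0.78), "F7": (-0.78, 0.57),
    "F3": (-0.43, 0.58), "FC1": (-0.25, 0.28), "FC5": (-0.68, 0.31),
    "T7": (-0.95, 0.0), "C3": (-0.50, 0.0), "CP1": (-0.25, -0.28),
    "CP5": (-0.68, -0.31), "P7": (-0.78, -0.57), "P3": (-0.43, -0.58),
    "Pz": (0.0, -0.55), "PO3": (-0.35, -0.78), "O1": (-0.29, -0.90),
    "Oz": (0.0, -0.92), "O2": (0.29, -0.90), "PO4": (0.35, -0.78),
    "P4": (0.43, -0.58), "P8": (0.78, -0.57), "CP6": (0.68, -0.31),
    "CP2": (0.25, -0.28), "C4": (0.50, 0.0), "T8": (0.95, 0.0),
    "FC6": (0.68, 0.31), "FC2": (0.25, 0.28), "F4": (0.43, 0.58),
    "F8": (0.78, 0.57), "AF4": (0.35, 0.78), "Fp2": (0.31, 0.95),
    "Fz": (0.0, 0.55), "Cz": (0.0, 0.0),
}

CHANNEL_NAMES: tuple[str, ...] = tuple(_POSITIONS)

#: Electrodes over the central strip; planted arousal effects in the
#: synthetic generator target these.
CENTRAL_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4")


def channel_xy(names: tuple[str, ...] | list[str] = CHANNEL_NAMES) -> np.ndarray:
    """2-D scalp coordinates for the requested channel names, in order."""
    return np.array([_POSITIONS[n] for n in names], dtype=np.float64)


def default_montage(n_channels: int = 32) -> tuple[list[str], np.ndarray]:
    """Names and coordinates for the first ``n_channels`` default electrodes.

    For ``n_channels`` beyond 32, synthetic extras are placed on an inner
    ring (the generator allows oversized montages for stress tests).
    """
    if n_channels <= 32:
        names = list(CHANNEL_NAMES[:n_channels])
        return names, channel_xy(names)
    names = list(CHANNEL_NAMES)
    extra = n_channels - 32
    angles = 2 * np.pi * np.arange(extra) / max(extra, 1)
    xy = np.vstack([channel_xy(names),
                    0.35 * np.column_stack([np.cos(angles), np.sin(angles)])])
    names += [f"X{i+1}" for i in range(extra)]
    return names, xy
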
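import numpy as np
import pytest

from affectlink.types import AudioClip, FrameSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frames(arrays, fps=4.0):
    """Stack 2-D or 3-D frame arrays (values in 0..255) into a FrameSequence."""
    frames = []
    for a in arrays:
        a = np.asarray(a, dtype=np.uint8)
        if a.ndim == 2:
            a = a[..., None].repeat(3, axis=-1)
        frames.append(a)
    return FrameSequence(frames=np.stack(frames), fps=fps)


def constant_frames(value, n=3, size=(8, 8), fps=4.0):
    return make_frames([np.full(size, value)] * n, fps=fps)


def sine_clip(freq=440.0, seconds=5.0, fs=8000.0, amp=0.1):
    t = np.arange(int(seconds * fs)) / fs
    return AudioClip(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)
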
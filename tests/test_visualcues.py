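"""Visual cue operations against hand-derived and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectlink.types import FrameSequence
from affectlink.visualcues import (VISUAL_CUE_NAMES, color_energy,
                                   cooccurrence_matrix, detect_shots,
                                   extract_visual_cues, glcm_features,
                                   lighting_key, saturation_proportion,
                                   visual_excitement)

from conftest import constant_frames, make_frames


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def brute_force_glcm_descriptors(gray_levels, levels, offsets):
    """Enumerate every pixel pair in Python; the independent texture oracle."""
    h, w = gray_levels.shape
    counts = {}
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    for pair in ((gray_levels[r, c], gray_levels[r2, c2]),
                                 (gray_levels[r2, c2], gray_levels[r, c])):
                        counts[pair] = counts.get(pair, 0) + 1
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    contrast = sum(q * (i - j) ** 2 for (i, j), q in p.items())
    energy = sum(q ** 2 for q in p.values())
    homogeneity = sum(q / (1 + abs(i - j)) for (i, j), q in p.items())
    mu_i = sum(q * i for (i, _), q in p.items())
    mu_j = sum(q * j for (_, j), q in p.items())
    var_i = sum(q * (i - mu_i) ** 2 for (i, _), q in p.items())
    var_j = sum(q * (j - mu_j) ** 2 for (_, j), q in p.items())
    if var_i <= 0 or var_j <= 0:
        corr = 0.0
    else:
        cov = sum(q * (i - mu_i) * (j - mu_j) for (i, j), q in p.items())
        corr = cov / np.sqrt(var_i * var_j)
    return contrast, corr, energy, homogeneity


class TestGLCM:
    def test_constant_frame_degenerate_matrix(self):
        c, r, e, h = glcm_features(constant_frames(128))
        assert (c, e, h) == (0.0, 1.0, 1.0)
        assert r == 0.0  # zero-variance sentinel

    def test_two_level_checkerboard_hand_case(self):
        # every horizontal pair differs by exactly one level:
        # contrast = 1, homogeneity = 1/(1+1) = 0.5
        board = (np.indices((4, 4)).sum(axis=0) % 2) * 255
        fr = make_frames([board, board])
        c, r, e, h = glcm_features(fr, levels=2, offsets=((0, 1),))
        assert c == pytest.approx(1.0, abs=1e-12)
        assert h == pytest.approx(0.5, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(2, 4), st.integers(0, 10_000))
    def test_matches_pair_enumeration_oracle(self, levels, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, levels, size=(rng.integers(2, 9), rng.integers(2, 9)))
        offsets = ((0, 1), (1, 0))
        p = cooccurrence_matrix(q, levels, offsets)
        i = np.arange(levels)[:, None]
        j = np.arange(levels)[None, :]
        ours = ((p * (i - j) ** 2).sum(), (p ** 2).sum(),
                (p / (1 + abs(i - j))).sum())
        c, r, e, h = brute_force_glcm_descriptors(q, levels, offsets)
        assert ours[0] == pytest.approx(c, abs=1e-12)
        assert ours[1] == pytest.approx(e, abs=1e-12)
        assert ours[2] == pytest.approx(h, abs=1e-12)

    def test_noise_lowers_homogeneity_and_raises_contrast(self, rng):
        flat = constant_frames(128, n=2, size=(32, 32))
        noisy_arr = 128 + rng.integers(-60, 60, size=(2, 32, 32))
        noisy = make_frames(list(noisy_arr))
        c0, _, _, h0 = glcm_features(flat)
        c1, _, _, h1 = glcm_features(noisy)
        assert c1 > c0 and h1 < h0


# --------------------------------------------------------------------------
# lighting, colour, saturation, excitement
# --------------------------------------------------------------------------

class TestLightingKey:
    def test_black_and_white_extremes(self):
        m0, s0 = lighting_key(constant_frames(0))
        m1, s1 = lighting_key(constant_frames(255))
        assert (m0, s0) == (0.0, 1.0)
        assert m1 == pytest.approx(1.0, abs=1e-6) and s1 == 0.0

    def test_half_black_half_white_shadow_fraction(self):
        half = np.zeros((8, 8))
        half[:, 4:] = 255
        _, shadow = lighting_key(make_frames([half, half]))
        assert shadow == pytest.approx(0.5)


class TestColorAndSaturation:
    def test_gray_and_uniform_saturated_frames_score_zero(self):
        assert color_energy(constant_frames(100)) == 0.0
        red = np.zeros((8, 8, 3), dtype=np.uint8)
        red[..., 0] = 200
        assert color_energy(make_frames([red, red])) == pytest.approx(0.0, abs=1e-12)

    def test_two_tone_frame_matches_pixel_level_formula(self):
        frame = np.zeros((8, 8, 3), dtype=np.uint8)
        frame[:, :4, 0] = 200                      # saturated red half
        frame[:, 4:] = 60                          # gray half
        from skimage.color import rgb2hsv
        hsv = rgb2hsv(frame.astype(float) / 255)
        p = hsv[..., 2] * hsv[..., 1]
        expected = p.mean() * p.std()
        assert color_energy(make_frames([frame, frame])) == pytest.approx(expected, rel=1e-12)

    def test_saturation_proportion_extremes_and_quarter(self):
        assert saturation_proportion(constant_frames(77)) == 0.0
        red = np.zeros((8, 8, 3), dtype=np.uint8)
        red[..., 0] = 255
        assert saturation_proportion(make_frames([red, red])) == 1.0
        # exactly 25% of pixels at saturation 0.5, rest gray
        mixed = np.full((8, 8, 3), 200, dtype=np.uint8)
        mixed[:2, :, 1:] = 100                     # saturation (200-100)/200 = 0.5
        assert saturation_proportion(make_frames([mixed, mixed])) == pytest.approx(0.25)


class TestVisualExcitement:
    def test_static_clip_scores_zero(self):
        assert visual_excitement(constant_frames(90, n=4)) == 0.0

    def test_alternating_black_white_scores_one(self):
        b = np.zeros((8, 8))
        w = np.full((8, 8), 255)
        assert visual_excitement(make_frames([b, w, b, w])) == 1.0

    def test_half_flip_scores_half(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        b[:4] = 255                                # half the pixels flip maximally
        assert visual_excitement(make_frames([a, b, a])) == pytest.approx(0.5)


class TestShots:
    def test_static_clip_is_one_shot(self):
        fr = constant_frames(120, n=8, fps=2.0)
        n, avg = detect_shots(fr)
        assert n == 1 and avg == pytest.approx(4.0)

    def test_single_content_switch_gives_two_shots(self):
        dark = np.full((16, 16), 30)
        bright = np.full((16, 16), 220)
        fr = make_frames([dark] * 4 + [bright] * 4, fps=2.0)
        n, _ = detect_shots(fr)
        assert n == 2

    def test_two_planted_cuts_give_ten_second_average(self):
        frames = []
        for value in (40, 140, 240):               # three 10 s segments
            frames += [np.full((16, 16), value)] * 10
        n, avg = detect_shots(make_frames(frames, fps=1.0))
        assert n == 3
        assert avg == pytest.approx(10.0)


# --------------------------------------------------------------------------
# aggregation & invariants
# --------------------------------------------------------------------------

class TestExtractVisualCues:
    def test_static_gray_clip_vector(self):
        cues = extract_visual_cues(constant_frames(128, n=4, fps=2.0))
        assert cues.visual_excitement == 0.0
        assert cues.n_shots == 1
        assert cues.saturation_proportion == 0.0
        assert len(cues.as_array()) == 11

    def test_deterministic_on_repeated_call(self, rng):
        fr = make_frames(list(rng.integers(0, 255, size=(3, 12, 12, 3))), fps=2.0)
        np.testing.assert_array_equal(extract_visual_cues(fr).as_array(),
                                      extract_visual_cues(fr).as_array())

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounded_cues_respect_ranges_on_random_clips(self, seed):
        rng = np.random.default_rng(seed)
        fr = make_frames(list(rng.integers(0, 256, size=(3, 8, 8, 3))), fps=4.0)
        c = extract_visual_cues(fr)
        assert 0.0 <= c.visual_excitement <= 1.0
        assert 0.0 <= c.lighting_key_median <= 1.0
        assert 0.0 <= c.shadow_proportion <= 1.0
        assert 0.0 <= c.saturation_proportion <= 1.0
        assert c.color_energy >= 0.0
        assert c.glcm_contrast >= 0.0
        assert -1.0 <= c.glcm_correlation <= 1.0
        assert 0.0 < c.glcm_energy <= 1.0
        assert 0.0 < c.glcm_homogeneity <= 1.0
        assert c.n_shots >= 1 and c.avg_shot_duration > 0
        assert np.all(np.isfinite(c.as_array()))
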
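"""EEG windowing, cleaning, band power, and conditional entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from affectlink.eegfeat import (BANDS, band_psd, clean_eeg,
                                conditional_entropy_matrix,
                                conditional_entropy_pair, entropy_feature_names,
                                psd_feature_names, window_epochs)
from affectlink.montage import default_montage
from affectlink.synthdata import gen_eeg
from affectlink.types import EEGEpoch, LatentAffect


def _epoch(data, fs=256.0):
    data = np.atleast_2d(data)
    names, xy = default_montage(data.shape[0])
    return EEGEpoch(data=data, fs=fs, channel_names=names, channel_xy=xy)


# --------------------------------------------------------------------------
# windowing
# --------------------------------------------------------------------------

class TestWindowing:
    @pytest.mark.parametrize("seconds,expected", [(35, 21), (15, 1), (117, 103)])
    def test_fifteen_second_window_one_second_hop_counts(self, seconds, expected):
        rec = _epoch(np.zeros((2, seconds * 256)))
        wins = window_epochs(rec)
        assert len(wins) == expected
        assert all(w.n_samples == 15 * 256 for w in wins)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(15, 300))
    def test_count_formula_for_integer_durations(self, seconds):
        rec = _epoch(np.zeros((1, seconds * 128)), fs=128.0)
        assert len(window_epochs(rec)) == (seconds - 15) // 1 + 1

    def test_window_starts_advance_by_the_hop(self):
        rec = _epoch(np.arange(20 * 128, dtype=float)[None, :], fs=128.0)
        wins = window_epochs(rec, win_s=15, hop_s=1)
        assert wins[1].data[0, 0] == 128.0
        assert wins[5].data[0, 0] == 5 * 128.0

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            window_epochs(_epoch(np.zeros((1, 10 * 256))))


# --------------------------------------------------------------------------
# cleaning
# --------------------------------------------------------------------------

class TestCleaner:
    def test_clean_signal_passes_through(self):
        e = gen_eeg(LatentAffect(0, 0), seconds=35, seed=7)
        c = clean_eeg(e)
        assert c.data.shape == e.data.shape
        for i in range(e.n_channels):
            assert np.corrcoef(e.data[i], c.data[i])[0, 1] > 0.99

    def test_large_burst_is_attenuated(self):
        e = gen_eeg(LatentAffect(0, 0), seconds=35, seed=3,
                    artifact_bursts=3, burst_amp_uv=500)
        c = clean_eeg(e)
        assert np.abs(c.data).max() <= 0.2 * np.abs(e.data).max()

    def test_flat_channel_passed_through_with_warning(self, caplog):
        e = gen_eeg(LatentAffect(0, 0), seconds=15, seed=2)
        e.data[5] = 0.0
        with caplog.at_level("WARNING"):
            c = clean_eeg(e)
        assert "flat" in caplog.text
        np.testing.assert_array_equal(c.data[5], 0.0)

    def test_too_short_recording_rejected(self):
        e = gen_eeg(LatentAffect(0, 0), seconds=8, seed=2)
        with pytest.raises(ValueError, match="10 s"):
            clean_eeg(e)


# --------------------------------------------------------------------------
# band PSD
# --------------------------------------------------------------------------

class TestBandPSD:
    def test_pure_alpha_tone_concentrates_in_alpha(self):
        t = np.arange(15 * 256) / 256.0
        data = np.zeros((4, len(t)))
        data[1] = 50 * np.sin(2 * np.pi * 10 * t)
        vals = band_psd(_epoch(data)).reshape(4, 3)
        theta, alpha, beta = vals[1]
        assert alpha > 100 * (theta + beta)

    def test_output_is_channel_major_96_vector(self):
        e = gen_eeg(LatentAffect(0, 0), seconds=15, seed=0)
        psd = band_psd(e)
        assert psd.shape == (96,)
        assert np.all(psd >= 0)
        names = psd_feature_names(e.channel_names)
        assert names[0] == "psd_Fp1_theta" and names[2] == "psd_Fp1_beta"
        assert len(names) == 96

    def test_quadratic_amplitude_scaling(self):
        e = gen_eeg(LatentAffect(0, 0), seconds=15, seed=4)
        doubled = _epoch(2 * e.data)
        np.testing.assert_allclose(band_psd(doubled), 4 * band_psd(e), rtol=1e-2)

    def test_insufficient_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            band_psd(_epoch(np.zeros((2, 500)), fs=40.0))

    def test_full_band_power_matches_time_domain_variance(self, rng):
        # Parseval sanity for the density scaling convention
        data = rng.standard_normal((3, 30 * 128))
        e = _epoch(data, fs=128.0)
        dens = band_psd(e, bands={"full": (0.0, 64.0)})
        total = dens * 64.0  # mean density x bandwidth
        np.testing.assert_allclose(total, data.var(axis=1), rtol=0.05)


# --------------------------------------------------------------------------
# conditional entropy
# --------------------------------------------------------------------------

def oracle_conditional_entropy(x, y, bins):
    """Dictionary-counting joint-histogram oracle, all Python."""
    def binned(v):
        lo, hi = min(v), max(v)
        if hi <= lo:
            return [0] * len(v)
        return [min(int((s - lo) / (hi - lo) * bins), bins - 1) for s in v]
    bx, by = binned(list(x)), binned(list(y))
    n = len(bx)
    joint, marg = {}, {}
    for a, b in zip(bx, by):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        marg[b] = marg.get(b, 0) + 1
    h_joint = -sum(c / n * np.log2(c / n) for c in joint.values())
    h_y = -sum(c / n * np.log2(c / n) for c in marg.values())
    return max(h_joint - h_y, 0.0)


class TestConditionalEntropy:
    def test_self_conditioning_is_exactly_zero(self, rng):
        x = rng.standard_normal(2000)
        assert conditional_entropy_pair(x, x) == 0.0

    def test_independent_uniforms_give_log2_bins(self, rng):
        x = rng.uniform(size=100_000)
        y = rng.uniform(size=100_000)
        assert conditional_entropy_pair(x, y, bins=16) == pytest.approx(4.0, abs=0.05)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(2, 4), st.integers(0, 10_000))
    def test_matches_dictionary_oracle(self, bins, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 1000))
        x = rng.standard_normal(n)
        y = x * rng.uniform(-1, 1) + rng.standard_normal(n)
        assert conditional_entropy_pair(x, y, bins=bins) == pytest.approx(
            oracle_conditional_entropy(x, y, bins), abs=1e-12)

    def test_conditioning_never_increases_entropy(self, rng):
        for _ in range(20):
            x = rng.standard_normal(3000)
            y = 0.5 * x + rng.standard_normal(3000)
            h_x = oracle_conditional_entropy(x, np.zeros(3000), bins=16)  # H(X)
            assert conditional_entropy_pair(x, y) <= h_x + 1e-12

    def test_matrix_is_lower_triangle_of_496_nonnegative_values(self):
        e = gen_eeg(LatentAffect(0, 0), seconds=15, seed=9)
        ce = conditional_entropy_matrix(e)
        assert ce.shape == (496,)
        assert np.all(ce >= 0)
        names = entropy_feature_names(e.channel_names)
        assert len(names) == 496
        assert names[0] == "ce_AF3|Fp1"

    def test_duplicated_channel_pair_entry_is_zero(self):
        data = np.random.default_rng(0).standard_normal((3, 4000))
        data[1] = data[0]
        ce = conditional_entropy_matrix(_epoch(data))
        assert ce[0] == 0.0  # H(ch1 | ch0) with ch1 == ch0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            conditional_entropy_pair(np.zeros(10), np.zeros(11))


# --------------------------------------------------------------------------
# planted linkage
# --------------------------------------------------------------------------

def test_high_arousal_trials_have_higher_central_beta():
    """One-sided comparison at alpha = 0.01, 50 trials per group."""
    def cz_beta(z, seed):
        e = gen_eeg(LatentAffect(0, z), fs=128.0, seconds=15, seed=seed)
        return band_psd(e).reshape(e.n_channels, 3)[e.channel_index("Cz"), 2]

    hi = [cz_beta(+1.0, s) for s in range(50)]
    lo = [cz_beta(-1.0, s) for s in range(1000, 1050)]
    t, p = stats.ttest_ind(hi, lo, alternative="greater")
    assert p < 0.01


def test_csv_sidecar_round_trip(tmp_path):
    import json
    import pandas as pd
    from affectlink.eegfeat import read_eeg_csv

    e = gen_eeg(LatentAffect(0, 0), n_channels=4, fs=128.0, seconds=15, seed=1)
    pd.DataFrame(e.data.T, columns=e.channel_names).to_csv(
        tmp_path / "rec.csv", index=False)
    (tmp_path / "rec.json").write_text(json.dumps(
        {"fs": e.fs, "channel_names": e.channel_names,
         "channel_xy": e.channel_xy.tolist()}))
    loaded = read_eeg_csv(tmp_path / "rec.csv")
    np.testing.assert_allclose(loaded.data, e.data)
    assert loaded.fs == e.fs and loaded.channel_names == e.channel_names
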
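import math

import numpy as np
import pytest
import pywt
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from oracles import peen_bruteforce, sampen_bruteforce
from sevodoa.features import (
    FEATURE_NAMES,
    HybridFeatureExtractor,
    PeEnParams,
    SampEnParams,
    WaveletEntropyParams,
    alpha_ratio,
    assemble_features,
    band_spectra,
    permutation_entropy,
    sample_entropy,
    wavelet_entropy,
)
from sevodoa.preprocess import window
from sevodoa.records import EEGRecord


def _tone(freq, amp=1.0, n=500, fs=100.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestSampleEntropy:
    def test_constant_window_is_zero(self):
        assert sample_entropy(np.full(500, 2.5)) == 0.0

    def test_periodic_window_matches_bruteforce(self):
        x = np.tile([1.0, 2.0, 3.0], 10)  # period 3, N=30
        p = SampEnParams(m=2, r=0.2, N=30)
        assert sample_entropy(x, p) == pytest.approx(sampen_bruteforce(x, 2, 0.2), abs=1e-9)

    def test_noise_more_irregular_than_periodic(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(500)
        periodic = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 100)
        assert sample_entropy(noise) > sample_entropy(periodic)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(100), SampEnParams(N=500))

    def test_no_long_matches_returns_finite_ceiling(self):
        # widely separated values: every pair matches at m but a huge jump
        # prevents any m+1 match only for pathological, hand-built series
        x = np.array([0.0, 0.0, 1e6, 0.0, 0.0, -1e6, 0.1, 0.1, 2e6, 0.1])
        p = SampEnParams(m=2, r=1e-7, N=10)
        with pytest.warns(UserWarning, match="ceiling"):
            v = sample_entropy(x, p)
        assert np.isfinite(v) and v > 0

    @given(
        data=st.lists(st.integers(-50, 50), min_size=20, max_size=40),
        a=st.sampled_from([0.5, 2.0, 4.0]),
        b=st.integers(-10, 10),
    )
    def test_affine_invariance(self, data, a, b):
        x = np.asarray(data, dtype=float)
        if x.std() == 0:
            return
        p = SampEnParams(m=2, r=0.2, N=x.size)
        assert sample_entropy(a * x + b, p) == pytest.approx(sample_entropy(x, p), abs=1e-12)


class TestPermutationEntropy:
    def test_monotone_window_is_zero(self):
        assert permutation_entropy(np.arange(500.0)) == 0.0

    def test_alternating_saturates_m2(self):
        x = np.tile([0.0, 1.0], 250)
        # 499 embeddings split 250/249 between the two patterns
        assert permutation_entropy(x, PeEnParams(m=2, N=500)) == pytest.approx(1.0, abs=1e-4)

    def test_hand_enumerated_example(self):
        x = np.array([4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0])
        p = PeEnParams(m=3, tau=1, N=7)
        expected = peen_bruteforce(x, 3, 1)
        assert expected == pytest.approx(0.588762155916294, abs=1e-12)
        assert permutation_entropy(x, p) == pytest.approx(expected, abs=1e-12)

    def test_too_short_window(self):
        with pytest.raises(ValueError):
            permutation_entropy(np.ones(3), PeEnParams(m=4, tau=2, N=10))

    @given(
        data=st.lists(st.integers(-50, 50), min_size=10, max_size=40),
        a=st.sampled_from([0.5, 2.0, 3.0]),
        b=st.integers(-10, 10),
    )
    def test_scale_invariance(self, data, a, b):
        x = np.asarray(data, dtype=float)
        p = PeEnParams(m=3, tau=1, N=x.size)
        assert permutation_entropy(a * x + b, p) == pytest.approx(
            permutation_entropy(x, p), abs=1e-12
        )


class TestWaveletEntropy:
    def test_zero_window(self):
        assert wavelet_entropy(np.zeros(512)) == 0.0

    def test_energy_in_one_scale_gives_near_zero(self):
        rng = np.random.default_rng(0)
        coeffs = pywt.wavedec(rng.standard_normal(512), "db4", level=5)
        kept = [np.zeros_like(c) for c in coeffs]
        kept[3] = coeffs[3]
        y = pywt.waverec(kept, "db4")[:512]
        assert wavelet_entropy(y) < 0.1

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        p = WaveletEntropyParams()
        coeffs = pywt.wavedec(x, p.wavelet, level=p.levels)
        energies = np.array([np.sum(c**2) for c in coeffs])
        probs = energies / energies.sum()
        expected = -np.sum(probs * np.log(probs))
        assert wavelet_entropy(x, p) == pytest.approx(expected, abs=1e-12)
        assert 0 <= wavelet_entropy(x, p) <= np.log(p.levels + 1)


class TestBandSpectra:
    def test_tone_lands_in_its_bin(self):
        s = band_spectra(_tone(35.2))
        assert s.shape == (42,)
        in_band = s[:40]
        assert in_band[int((35.2 - 30.0) / 0.5)] > 0.9 * in_band.sum()
        assert s[41] < 1e-6 * s[40]  # 47-50 Hz average ~ 0

    def test_zero_window(self):
        np.testing.assert_array_equal(band_spectra(np.zeros(500)), np.zeros(42))

    def test_average_bins_are_means_of_halfhz_bins(self):
        rng = np.random.default_rng(2)
        s = band_spectra(rng.standard_normal(500))
        assert s[40] == pytest.approx(s[: 2 * 17].mean(), rel=1e-12)
        assert s[41] == pytest.approx(s[2 * 17 : 40].mean(), rel=1e-12)
        assert np.all(s >= 0)


class TestAlphaRatio:
    def test_equal_band_energy_is_zero(self):
        w = _tone(36.0) + _tone(10.0)
        assert alpha_ratio(w) == pytest.approx(0.0, abs=0.05)

    def test_low_band_dominates_negative(self):
        rng = np.random.default_rng(3)
        w = _tone(10.0, amp=10.0) + 0.01 * rng.standard_normal(500)
        assert alpha_ratio(w) < 0

    def test_hundredfold_energy_ratio(self):
        w = _tone(36.0, amp=10.0) + _tone(10.0, amp=1.0)  # E ratio = 100
        assert alpha_ratio(w) == pytest.approx(2.0, abs=0.1)

    def test_zero_denominator_sentinel(self):
        with pytest.warns(UserWarning, match="alpha-ratio"):
            assert math.isnan(alpha_ratio(np.zeros(500)))


class TestAssembly:
    def test_single_window_shape_and_order(self):
        rng = np.random.default_rng(4)
        rec = EEGRecord(samples=rng.standard_normal(500), fs=100.0)
        fm = assemble_features(window(rec, 500, 500))
        assert fm.values.shape == (1, 46)
        assert tuple(fm.names) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 46

    def test_rows_depend_only_on_their_window(self):
        rng = np.random.default_rng(5)
        rec = EEGRecord(samples=rng.standard_normal(1500), fs=100.0)
        fm = assemble_features(window(rec, 500, 500))
        solo = assemble_features(window(EEGRecord(rec.samples[500:1000], 100.0), 500, 500))
        np.testing.assert_allclose(fm.values[1], solo.values[0], atol=1e-12)

    def test_transformer_matches_assemble(self):
        rng = np.random.default_rng(6)
        W = rng.standard_normal((3, 500))
        ext = HybridFeatureExtractor().fit(W)
        out = ext.transform(W)
        assert out.shape == (3, 46)
        assert list(ext.get_feature_names_out()) == list(FEATURE_NAMES)
        rec = EEGRecord(samples=W.reshape(-1), fs=100.0)
        fm = assemble_features(window(rec, 500, 500))
        np.testing.assert_allclose(out, fm.values, atol=1e-12)


def test_depth_monotonicity_on_synthetic_session(session600):
    """Entropies and 30-47 Hz power fall as effect-site concentration rises."""
    _, feats, labels = session600
    for name in ("sampen", "peen", "power_mean_30_47Hz"):
        rho = spearmanr(labels, feats.column(name)).statistic
        assert rho < -0.3, f"{name}: rho={rho}"
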
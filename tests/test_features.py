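"""Welch PSD grid, analytic feature values, brute-force entropy oracles and
gain-invariance properties."""
import numpy as np
import pytest

from earsim import features as F
from earsim.features import (
    FEATURE_NAMES,
    FeatureParams,
    extract_epoch_features,
    freq_features,
    time_features,
    welch_psd,
)

FS = 256.0


def tone(freq, fs=FS, seconds=30.0, phase=0.1):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


class TestWelch:
    def test_grid_spacing_and_segments(self):
        psd = welch_psd(tone(10.0), FS)
        assert psd.df == pytest.approx(0.2)
        assert psd.n_segments == 11

    def test_peak_at_tone_frequency(self):
        psd = welch_psd(tone(10.0), FS)
        assert psd.freqs[np.argmax(psd.psd)] == pytest.approx(10.0, abs=psd.df)

    def test_parseval_mean_mode(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(FS * 30))
        psd = welch_psd(x, FS, average="mean")
        power = psd.psd.sum() * psd.df
        assert power == pytest.approx(x.var(), rel=0.05)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="70"):
            welch_psd(np.zeros(1000), 60.0)


class TestTimeFeatures:
    def test_constant_epoch_degenerates(self):
        out = time_features(np.ones(1000))
        assert out["std"] == 0.0
        assert out["zero_crossings"] == 0.0
        assert out["max_first_derivative"] == 0.0
        assert np.isnan(out["sample_entropy"])

    def test_hjorth_activity_is_variance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        out = time_features(x)
        assert out["hjorth_activity"] == pytest.approx(x.var())

    def test_zero_crossings_of_sinusoid(self):
        # 2 Hz over 30 s -> 2 * f * T = 120 sign changes
        assert time_features(tone(2.0))["zero_crossings"] == 120

    def test_sample_entropy_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(250)
        r = 0.2 * x.std()
        emb = lambda m: np.lib.stride_tricks.sliding_window_view(x, m)

        def pairs(e):
            d = np.max(np.abs(e[:, None, :] - e[None, :, :]), axis=2)
            return (np.sum(d <= r) - len(e)) // 2

        expected = -np.log(pairs(emb(3)) / pairs(emb(2)[: len(x) - 2]))
        assert F.sample_entropy(x, 2, r) == pytest.approx(expected, abs=1e-10)

    def test_approximate_entropy_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(250)
        r = 0.2 * x.std()

        def phi(m):
            e = np.lib.stride_tricks.sliding_window_view(x, m)
            d = np.max(np.abs(e[:, None, :] - e[None, :, :]), axis=2)
            return np.mean(np.log((d <= r).sum(axis=1) / len(e)))

        assert F.approximate_entropy(x, 2, r) == pytest.approx(
            phi(2) - phi(3), abs=1e-10
        )

    def test_permutation_entropy_monotone_sequence_is_zero(self):
        assert F.permutation_entropy(np.arange(100.0)) == pytest.approx(0.0)

    def test_permutation_entropy_white_noise_near_one(self):
        rng = np.random.default_rng(4)
        assert F.permutation_entropy(rng.standard_normal(20000)) > 0.99

    def test_lempel_ziv_matches_reference_parser(self):
        def lz_reference(x):
            b = bytes((np.asarray(x, float) > np.median(x)).astype(np.uint8))
            n, i, c = len(b), 0, 0
            while i < n:
                l = 1
                while i + l <= n and b.find(b[i : i + l], 0, i + l - 1) != -1:
                    l += 1
                c += 1
                i += l
            return c * np.log2(n) / n

        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.standard_normal(rng.integers(20, 300))
            assert F.lempel_ziv_complexity(x) == pytest.approx(lz_reference(x))

    def test_dfa_white_noise_near_half(self):
        rng = np.random.default_rng(6)
        vals = [F.dfa_exponent(rng.standard_normal(4096)) for _ in range(5)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.08)

    def test_katz_fd_straight_line_is_one(self):
        assert F.katz_fd(np.linspace(0.0, 1.0, 500)) == pytest.approx(1.0)

    def test_higuchi_white_noise_near_two(self):
        rng = np.random.default_rng(7)
        assert F.higuchi_fd(rng.standard_normal(5000)) == pytest.approx(2.0, abs=0.15)


class TestFreqFeatures:
    def test_pure_delta_tone_concentrates_power(self):
        out = freq_features(welch_psd(tone(2.0), FS))
        assert out["relpow_delta"] > 0.99
        assert out["relpow_beta"] < 0.01

    def test_flat_density_entropy_and_flatness_one(self):
        psd = welch_psd(tone(10.0), FS)
        flat = F.PSDEstimate(
            psd.freqs, np.ones_like(psd.psd), 5.0, 0.5, "median", "hamming", 11
        )
        out = freq_features(flat)
        assert out["spectral_flatness"] == pytest.approx(1.0)
        assert out["spectral_entropy"] == pytest.approx(1.0)
        assert out["spectral_crest"] == pytest.approx(1.0)

    def test_symmetric_density_centroid(self):
        psd = welch_psd(tone(10.0), FS)
        f = psd.freqs
        dens = np.exp(-0.5 * ((f - 10.0) / 1.5) ** 2)
        sym = F.PSDEstimate(f, dens, 5.0, 0.5, "median", "hamming", 11)
        out = freq_features(sym)
        assert out["spectral_centroid"] == pytest.approx(10.0, abs=0.05)
        assert abs(out["spectral_skewness"]) < 0.05

    def test_relative_powers_sum_to_one(self):
        rng = np.random.default_rng(8)
        out = freq_features(welch_psd(rng.standard_normal(int(FS * 30)), FS))
        total = sum(out[f"relpow_{b}"] for b in ("delta", "theta", "alpha", "sigma", "beta", "gamma"))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_delta_beta_ratio_monotone_in_power_shift(self):
        """Shifting power from delta to beta strictly lowers delta/beta."""
        rng = np.random.default_rng(9)
        ratios = []
        for w_delta in (0.8, 0.5, 0.2):
            from earsim.synth import SimConfig, generate_recording_pair

            bw = {
                s: {"delta": w_delta, "theta": 0.0, "alpha": 0.0, "sigma": 0.0,
                    "beta": 1.0 - w_delta, "gamma": 0.0}
                for s in ("W", "NREM", "REM")
            }
            cfg = SimConfig(n_epochs=1, seed=10, stage_sequence=("W",),
                            band_weights=bw, pink_level=0.0)
            psg, _, _ = generate_recording_pair(cfg)
            out = freq_features(welch_psd(psg.channels["C3"], FS))
            ratios.append(out["delta_beta_ratio"])
        assert ratios[0] > ratios[1] > ratios[2]


class TestEpochVector:
    def test_feature_count_and_order_stable(self):
        rng = np.random.default_rng(11)
        a = extract_epoch_features(rng.standard_normal(int(FS * 30)), FS)
        b = extract_epoch_features(tone(5.0), FS)
        assert list(a) == list(b) == list(FEATURE_NAMES)
        assert len(a) == 45

    def test_gain_invariance_after_max_normalization(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(int(FS * 30))
        a = extract_epoch_features(x, FS)
        b = extract_epoch_features(10.0 * x, FS)
        for name in FEATURE_NAMES:
            va, vb = a[name], b[name]
            if np.isnan(va) and np.isnan(vb):
                continue
            assert va == pytest.approx(vb, rel=1e-9), name
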
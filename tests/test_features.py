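import numpy as np
import pytest
from scipy.stats import ranksums

from vmdseiz import (
    BandSet,
    HiguchiParams,
    ParameterError,
    SyntheticSpec,
    VMDParams,
    band_differential_entropy,
    differential_entropy,
    extract_features,
    higuchi_fd,
    make_dataset,
    make_fd_series,
)

NYQUIST_FRACTION = {  # band width / Nyquist at fs 256, the analytic variance
    "delta": 3.0 / 128.0,
    "theta": 4.0 / 128.0,
    "alpha": 5.0 / 128.0,
    "beta": 17.0 / 128.0,
    "gamma": 20.0 / 128.0,
}


class TestDifferentialEntropy:
    def test_zero_point(self):
        """A band whose estimated variance is 1/(2 pi e) has DE exactly 0."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)  # one 1-s window at fs 256
        de0 = band_differential_entropy(x, 256.0)["alpha"]
        sigma2 = np.exp(2 * de0) / (2 * np.pi * np.e)  # invert the formula
        x_scaled = x * np.sqrt(1.0 / (2 * np.pi * np.e) / sigma2)
        assert band_differential_entropy(x_scaled, 256.0)["alpha"] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_doubling_amplitude_adds_ln2(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(512)
        base = band_differential_entropy(x, 256.0)
        doubled = band_differential_entropy(2.0 * x, 256.0)
        for name in base:
            assert doubled[name] - base[name] == pytest.approx(np.log(2), abs=1e-6)
        assert differential_entropy(2.0 * x, 256.0) - differential_entropy(
            x, 256.0
        ) == pytest.approx(np.log(2), abs=1e-6)

    def test_white_noise_closed_form(self):
        """Per-band DE of unit-variance white noise matches the analytic
        value 0.5*ln(2 pi e * bandwidth/Nyquist)."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(256 * 60)  # 60 windows tighten the estimate
        per_band = band_differential_entropy(x, 256.0)
        for name, frac in NYQUIST_FRACTION.items():
            expected = 0.5 * np.log(2 * np.pi * np.e * frac)
            assert per_band[name] == pytest.approx(expected, abs=0.1)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(512)
        assert differential_entropy(x + 7.5, 256.0) == pytest.approx(
            differential_entropy(x, 256.0), abs=1e-9
        )

    def test_constant_signal_rejected(self):
        with pytest.raises(ParameterError):
            differential_entropy(np.ones(512), 256.0)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            differential_entropy(np.ones(100), 256.0)

    def test_band_validation(self):
        with pytest.raises(ParameterError):
            BandSet([("a", 1.0, 8.0), ("b", 4.0, 13.0)])  # overlap
        with pytest.raises(ParameterError):
            BandSet([("a", 5.0, 2.0)])


class TestHiguchiFd:
    def test_straight_line(self):
        series, _ = make_fd_series("line", 1024, seed=0)
        assert higuchi_fd(series, HiguchiParams(k_max=8)) == pytest.approx(
            1.0, abs=0.02
        )

    def test_white_noise(self):
        fds = [
            higuchi_fd(make_fd_series("white_noise", 512, seed=s)[0])
            for s in range(20)
        ]
        assert np.mean(fds) == pytest.approx(2.0, abs=0.1)

    @pytest.mark.parametrize("hurst", [0.2, 0.5, 0.8])
    def test_fbm_dimension(self, hurst):
        fds = [
            higuchi_fd(make_fd_series("fbm", 512, hurst=hurst, seed=s)[0])
            for s in range(20)
        ]
        assert np.mean(fds) == pytest.approx(2.0 - hurst, abs=0.1)

    def test_monotone_in_hurst(self):
        means = []
        for hurst in (0.2, 0.5, 0.8):
            fds = [
                higuchi_fd(make_fd_series("fbm", 512, hurst=hurst, seed=s)[0])
                for s in range(20)
            ]
            means.append(np.mean(fds))
        assert means[0] > means[1] > means[2]

    def test_constant_rejected(self):
        with pytest.raises(ParameterError):
            higuchi_fd(np.ones(512))

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            higuchi_fd(np.ones(16), HiguchiParams(k_max=8))

    def test_clamp_warns_out_of_range(self):
        # heavily oversampled noise pushes the raw estimate above 2
        rng = np.random.default_rng(4)
        x = rng.standard_normal(512)
        fd = higuchi_fd(np.cumsum(x) + 5 * x, HiguchiParams(k_max=64))
        assert 1.0 <= fd <= 2.0

    def test_fit_range_subset(self):
        series, _ = make_fd_series("white_noise", 512, seed=5)
        fd_all = higuchi_fd(series, HiguchiParams(k_max=8))
        fd_sub = higuchi_fd(series, HiguchiParams(k_max=8, fit_range=(2, 4, 8)))
        assert abs(fd_all - fd_sub) < 0.3  # same series, compatible estimates


class TestExtractFeatures:
    def test_full_montage_column_count(self):
        spec = SyntheticSpec(
            n_channels=23, informative_channels=(0,), n_epochs_per_class=1, seed=8
        )
        epochs, _ = make_dataset(spec)
        fm = extract_features(epochs, spec.fs)
        assert fm.values.shape == (2, 276)  # 23 channels x 6 modes x 2
        assert len(fm.channel_groups) == 23

    def test_single_channel_single_epoch(self):
        spec = SyntheticSpec(
            n_channels=1, informative_channels=(), n_epochs_per_class=1, seed=8
        )
        epochs, _ = make_dataset(spec)
        fm = extract_features(epochs[:1], spec.fs)
        assert fm.values.shape == (1, 12)

    def test_column_order_contract(self):
        spec = SyntheticSpec(n_channels=2, informative_channels=(), n_epochs_per_class=1, seed=8)
        epochs, _ = make_dataset(spec)
        fm = extract_features(epochs[:1], spec.fs, vmd_params=VMDParams(K=2))
        assert fm.feature_index == [
            (0, 0, "DE"), (0, 0, "HFD"), (0, 1, "DE"), (0, 1, "HFD"),
            (1, 0, "DE"), (1, 0, "HFD"), (1, 1, "DE"), (1, 1, "HFD"),
        ]
        assert fm.channel_groups == {0: [0, 1, 2, 3], 1: [4, 5, 6, 7]}

    def test_determinism(self):
        spec = SyntheticSpec(n_channels=2, informative_channels=(0,), n_epochs_per_class=1, seed=9)
        epochs, _ = make_dataset(spec)
        a = extract_features(epochs, spec.fs)
        b = extract_features(epochs, spec.fs)
        np.testing.assert_array_equal(a.values, b.values)

    def test_planted_contrast(self, small_features):
        """Ictal epochs: lower DE, higher HFD, on informative channels only."""
        fm, truth = small_features
        lab = fm.labels
        for ch in fm.channel_groups:
            de_cols = [j for j in fm.channel_groups[ch] if fm.feature_index[j][2] == "DE"]
            hfd_cols = [j for j in fm.channel_groups[ch] if fm.feature_index[j][2] == "HFD"]
            d_de = fm.values[lab == 1][:, de_cols].mean() - fm.values[lab == 0][:, de_cols].mean()
            d_hfd = fm.values[lab == 1][:, hfd_cols].mean() - fm.values[lab == 0][:, hfd_cols].mean()
            if ch in truth:
                assert d_de < 0
                assert d_hfd > 0
                p = ranksums(
                    fm.values[lab == 1][:, hfd_cols].mean(axis=1),
                    fm.values[lab == 0][:, hfd_cols].mean(axis=1),
                ).pvalue
                assert p < 0.01
            else:
                assert abs(d_de) < 0.2
                assert abs(d_hfd) < 0.05

    def test_de_source_raw_switch(self):
        spec = SyntheticSpec(n_channels=1, informative_channels=(), n_epochs_per_class=1, seed=10)
        epochs, _ = make_dataset(spec)
        fm = extract_features(epochs[:1], spec.fs, de_source="raw")
        de_vals = [
            fm.values[0, j]
            for j, (_, _, name) in enumerate(fm.feature_index)
            if name == "DE"
        ]
        # raw-channel DE repeats across all modes of the channel
        assert np.ptp(de_vals) == 0.0

    def test_mismatched_channel_counts_rejected(self):
        s1 = SyntheticSpec(n_channels=1, informative_channels=(), n_epochs_per_class=1, seed=1)
        s2 = SyntheticSpec(n_channels=2, informative_channels=(), n_epochs_per_class=1, seed=1)
        e1, _ = make_dataset(s1)
        e2, _ = make_dataset(s2)
        with pytest.raises(ParameterError):
            extract_features([e1[0], e2[0]], 256.0)

    def test_csv_round_trip(self, tmp_path, small_features):
        fm, _ = small_features
        path = tmp_path / "f.csv"
        fm.to_csv(path)
        from vmdseiz import FeatureMatrix

        back = FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert back.feature_index == fm.feature_index
        assert back.channel_groups == fm.channel_groups
        np.testing.assert_array_equal(back.labels, fm.labels)
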
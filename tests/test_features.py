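import numpy as np
import pytest

from wavedisc.features import (
    FeatureID,
    UndefinedCorrelationError,
    ZeroVarianceError,
    build_catalog,
    extract_features,
    wavelet_correlation,
    wavelet_variance,
    zscore_normalize,
)
from wavedisc.modwt import get_filter, level_filter_width, modwt


class TestZScore:
    def test_standardizes_to_mean_zero_unit_sd(self):
        z = zscore_normalize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-np.sqrt(1.5), 0, np.sqrt(1.5)])
        assert abs(z.mean()) < 1e-10
        assert abs(z.std() - 1.0) < 1e-10

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.standard_normal(100)
        z = zscore_normalize(x)
        np.testing.assert_allclose(zscore_normalize(z), z, atol=1e-10)

    def test_constant_series_raises_with_context(self):
        with pytest.raises(ZeroVarianceError, match="Cz"):
            zscore_normalize(np.array([5.0, 5.0, 5.0]), label="trial 0, channel Cz")


class TestWaveletVariance:
    def test_zero_series_has_zero_variance_at_every_level(self):
        d = modwt(np.zeros(64), get_filter("haar"), 3)
        for j in (1, 2, 3):
            assert wavelet_variance(d, j) == 0.0

    def test_averaging_window_excludes_boundary(self, rng):
        """At N=100, d4, level 2: L_j=10 so exactly M_j=91 coefficients count."""
        f = get_filter("d4")
        assert level_filter_width(2, f.L) == 10
        x = rng.standard_normal(100)
        d = modwt(x, f, 2)
        seg = d.wavelet_coeffs[1][9:]
        assert seg.size == 91
        assert wavelet_variance(d, 2) == pytest.approx(np.mean(seg**2))

    def test_white_noise_haar_level1_near_half(self, rng):
        """Haar level-1 coefficients are (x_t - x_{t-1})/2, variance 2*sigma^2/4."""
        x = rng.standard_normal(10000)
        d = modwt(x, get_filter("haar"), 1)
        assert wavelet_variance(d, 1) == pytest.approx(0.5, abs=0.03)

    def test_insufficient_length_for_level(self):
        d = modwt(np.random.default_rng(1).standard_normal(8), get_filter("haar"), 3)
        with pytest.raises(ValueError, match="too short"):
            wavelet_variance(d, 3)  # L_3 = 8 -> M_3 = 1


class TestWaveletCorrelation:
    def test_self_correlation_is_one(self, rng):
        d = modwt(rng.standard_normal(128), get_filter("d4"), 3)
        for j in (1, 2, 3):
            assert wavelet_correlation(d, d, j) == pytest.approx(1.0)

    def test_negated_series_gives_minus_one(self, rng):
        x = rng.standard_normal(128)
        f = get_filter("d4")
        dx, dy = modwt(x, f, 2), modwt(-x, f, 2)
        for j in (1, 2):
            assert wavelet_correlation(dx, dy, j) == pytest.approx(-1.0)

    def test_independent_noise_correlations_near_zero(self, rng):
        """|rho_j| stays within ~4 standard errors of 0 for independent inputs."""
        f = get_filter("d4")
        N = 2000
        dx = modwt(rng.standard_normal(N), f, 4)
        dy = modwt(rng.standard_normal(N), f, 4)
        for j in range(1, 5):
            M_j = N - level_filter_width(j, f.L) + 1
            assert abs(wavelet_correlation(dx, dy, j)) < 4 / np.sqrt(M_j)

    def test_mismatched_decompositions_rejected(self, rng):
        dx = modwt(rng.standard_normal(64), get_filter("d4"), 2)
        dy = modwt(rng.standard_normal(64), get_filter("haar"), 2)
        with pytest.raises(ValueError, match="same filter"):
            wavelet_correlation(dx, dy, 1)

    def test_constant_segment_is_undefined(self):
        # Haar level-1 details of a ramp are constant off the boundary
        d = modwt(np.arange(32.0), get_filter("haar"), 1)
        with pytest.raises(UndefinedCorrelationError):
            wavelet_correlation(d, d, 1)


class TestCatalog:
    @pytest.mark.parametrize(
        "P,J,ftypes,expected",
        [
            (63, 11, ("variance", "correlation"), 22176),
            (2, 1, ("variance", "correlation"), 3),
            (3, 2, ("correlation",), 6),
            (5, 4, ("variance",), 20),
        ],
    )
    def test_count_law(self, P, J, ftypes, expected):
        """|catalog| = J*P variances + J*P(P-1)/2 correlations."""
        assert len(build_catalog(P, J, ftypes)) == expected

    def test_deterministic_order_and_pair_normalization(self):
        cat = build_catalog(["A", "B", "C"], 2)
        names = [fid.name for fid in cat]
        assert names[:6] == [
            "var_j1_A", "var_j2_A", "var_j1_B", "var_j2_B", "var_j1_C", "var_j2_C",
        ]
        assert names[6:9] == ["cor_j1_A_B", "cor_j1_A_C", "cor_j1_B_C"]
        for fid in cat:
            if fid.ftype == "correlation":
                assert fid.chan_a < fid.chan_b

    def test_empty_ftypes_rejected(self):
        with pytest.raises(ValueError):
            build_catalog(3, 2, ())


class TestExtractFeatures:
    def test_length_matches_catalog_and_bounds_hold(self, rng):
        trial = rng.standard_normal((4, 128))
        names = ["c1", "c2", "c3", "c4"]
        fv = extract_features(trial, names, wavelet="d4", J=3)
        cat = build_catalog(names, 3)
        assert fv.values.size == len(cat)
        for fid, v in zip(cat, fv.values):
            if fid.ftype == "variance":
                assert v >= 0
            else:
                assert -1.0 <= v <= 1.0

    def test_identical_channels_correlate_perfectly(self, rng):
        row = rng.standard_normal(128)
        fv = extract_features(
            np.vstack([row, row]), ["a", "b"], wavelet="haar", J=3,
            ftypes=("correlation",),
        )
        np.testing.assert_allclose(fv.values, 1.0)

    def test_gain_invariance(self, rng):
        """Multiplying a channel by a positive constant changes no feature."""
        trial = rng.standard_normal((3, 256))
        scaled = trial * np.array([[1.0], [250.0], [1e-3]])
        names = ["x", "y", "z"]
        a = extract_features(trial, names, wavelet="d6", J=3)
        b = extract_features(scaled, names, wavelet="d6", J=3)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_coupled_pair_peaks_at_matching_level(self, coupled_dataset):
        """The injected 16-30 Hz coupling shows up at its octave level, not remote ones."""
        cfg, trials, labels, truth = coupled_dataset
        level = truth["coupled_pairs"][0]["levels"][0]
        pair = truth["coupled_pairs"][0]["channels"]
        names = cfg.channel_names
        # average over class-0 trials (the coupled class)
        J = 6
        cat = build_catalog(names, J, ("correlation",))
        idx_at = next(
            i for i, fid in enumerate(cat)
            if fid.level == level and set(fid.channels) == set(pair)
        )
        idx_remote = next(
            i for i, fid in enumerate(cat)
            if fid.level == 1 and set(fid.channels) == set(pair)
        )
        vals_at, vals_remote = [], []
        for trial, lab in zip(trials, labels):
            if lab != "foot":  # class 0
                continue
            fv = extract_features(trial, names, wavelet="d4", J=J,
                                  ftypes=("correlation",))
            vals_at.append(fv.values[idx_at])
            vals_remote.append(fv.values[idx_remote])
        assert np.mean(vals_at) > np.mean(vals_remote) + 0.3

    def test_constant_channel_error_names_trial_and_channel(self):
        trial = np.vstack([np.ones(64), np.arange(64.0)])
        with pytest.raises(ZeroVarianceError, match="bad_ch"):
            extract_features(trial, ["bad_ch", "ok"], trial_id="t7")
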
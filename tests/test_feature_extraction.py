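"""FCM, SDA, Hilbert, FFT, DCT extractors and feature statistics."""

import numpy as np
import pytest
from scipy.fft import dct as scipy_dct, idct as scipy_idct
from scipy.special import logsumexp

import ovaclass as ov
from ovaclass.errors import ConfigurationError, DataError
from ovaclass.feature_extraction import (
    default_n_features,
    sda_block_scores,
    sda_fit,
)


class TestFCM:
    def test_two_well_separated_clusters(self):
        """Items {0,0,0,10,10,10} split into centers {0,10} with crisp
        memberships and a non-increasing objective."""
        model = ov.fcm_fit(np.array([0.0, 0, 0, 10, 10, 10]), 2, seed=1)
        np.testing.assert_allclose(np.sort(model.centers.ravel()), [0.0, 10.0], atol=1e-3)
        own = model.memberships.max(axis=1)
        assert np.all(own > 0.99)
        assert np.all(np.diff(model.objective_path) <= 1e-9)

    def test_single_cluster_closed_form(self):
        items = np.array([1.0, 2.0, 3.0, 10.0])
        model = ov.fcm_fit(items, 1, seed=0)
        assert model.centers.ravel()[0] == pytest.approx(items.mean())
        np.testing.assert_allclose(model.memberships, 1.0)

    def test_equidistant_item_has_half_memberships(self):
        model = ov.fcm_fit(np.array([-10.0, -10, 10, 10, 0]), 2, seed=2)
        np.testing.assert_allclose(model.memberships[4], [0.5, 0.5], atol=1e-5)

    def test_more_clusters_than_items_rejected(self):
        with pytest.raises(ConfigurationError):
            ov.fcm_fit(np.array([1.0, 2.0]), 3)

    def test_features_recover_group_means(self):
        """Two perfectly correlated gene groups, C=2: each feature equals the
        within-group mean expression of each sample."""
        rng = np.random.default_rng(4)
        a, b = rng.uniform(1, 2, size=6), rng.uniform(8, 9, size=6)
        values = np.vstack([np.tile(a, (5, 1)), np.tile(b, (5, 1))])
        f = ov.fcm_features(values, n_clusters=2, seed=0)
        got = np.sort(f.values, axis=1)
        want = np.sort(np.stack([a, b], axis=1), axis=1)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_c_equals_n_genes_reproduces_genes(self):
        values = np.array([[0.0] * 4, [5.0] * 4, [10.0] * 4, [20.0] * 4, [40.0] * 4])
        values = values + np.arange(4) * 0.1
        f = ov.fcm_features(values, n_clusters=5, seed=0)
        np.testing.assert_allclose(
            np.sort(f.values, axis=1), np.sort(values.T, axis=1), atol=1e-3
        )

    def test_study_scale_dimension_contract(self):
        assert default_n_features(16000, "FCM") == 660
        assert default_n_features(16000, "DCT") == 3300


class TestSDA:
    def _toy(self):
        rng = np.random.default_rng(8)
        # 8 genes x 6 samples; classes far apart
        normal = rng.normal(0.0, 0.3, size=(8, 3))
        cancer = rng.normal(6.0, 0.3, size=(8, 3))
        values = np.hstack([normal, cancer])
        labels = np.array([0, 0, 0, 1, 1, 1])
        return values, labels

    def test_block_scores_match_bruteforce(self):
        """Package block scores equal a naive double-loop evaluation of the
        log-sum-exp kernel sums (including gene standardization)."""
        values, labels = self._toy()
        model = sda_fit(values, labels, n_features=4, lambda_=0.7)
        scores = sda_block_scores(values, model)

        mean = values.mean(axis=1)
        sd = values.std(axis=1)
        z = ((values - mean[:, None]) / sd[:, None]).T  # samples x genes
        blocks = np.array_split(np.arange(8), 4)
        for s in range(6):
            for b, block in enumerate(blocks):
                for cls in (0, 1):
                    terms = []
                    for i in range(6):
                        if labels[i] != cls or i == s:
                            continue
                        d2 = float(np.sum((z[s, block] - z[i, block]) ** 2))
                        terms.append(-0.7 * d2)
                    assert scores[s, b, cls] == pytest.approx(logsumexp(terms), rel=1e-9)

    def test_own_class_score_exceeds_cross_class(self):
        values, labels = self._toy()
        model = sda_fit(values, labels, n_features=4)
        scores = sda_block_scores(values, model)
        for s in range(6):
            own, other = labels[s], 1 - labels[s]
            assert np.all(scores[s, :, own] > scores[s, :, other])

    def test_self_exclusion_lowers_own_score(self):
        """A training sample scored with itself present (exp(0)=1 term)
        strictly exceeds the self-excluded score."""
        values, labels = self._toy()
        model = sda_fit(values, labels, n_features=4)
        excluded = sda_block_scores(values, model)  # self-excluding
        included = sda_block_scores(values, model, sample_columns=[-1] * 6)
        for s in range(6):
            own = labels[s]
            assert np.all(included[s, :, own] > excluded[s, :, own])
            np.testing.assert_allclose(
                included[s, :, 1 - own], excluded[s, :, 1 - own]
            )

    def test_softmax_features_bounded_and_oriented(self):
        values, labels = self._toy()
        model = sda_fit(values, labels, n_features=4)
        f = ov.sda_features(values, model)
        assert np.all((f.values >= 0) & (f.values <= 1))
        assert np.all(f.values[labels == 1] > 0.5)
        assert np.all(f.values[labels == 0] < 0.5)

    def test_invalid_lambda_and_empty_class(self):
        values, labels = self._toy()
        with pytest.raises(ConfigurationError, match="lambda"):
            sda_fit(values, labels, lambda_=0.0)
        with pytest.raises(DataError, match="class"):
            sda_fit(values, np.ones(6, dtype=int), n_features=2)


class TestTransforms:
    def test_hilbert_envelope_of_cosine_is_one(self):
        n = 512
        values = np.cos(2 * np.pi * 16 * np.arange(n) / n)[:, None]
        f = ov.hilbert_features(values, n_features=n)
        interior = f.values[0, n // 16 : -n // 16]
        np.testing.assert_allclose(interior, 1.0, atol=1e-2)

    def test_hilbert_constant_envelope_is_abs(self):
        values = np.full((128, 1), -3.5)
        f = ov.hilbert_features(values, n_features=32)
        np.testing.assert_allclose(f.values, 3.5, atol=1e-9)

    def test_hilbert_envelope_scales_linearly(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((200, 3))
        base = ov.hilbert_features(x, n_features=50).values
        scaled = ov.hilbert_features(2.5 * x, n_features=50).values
        np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-9)

    def test_dct_constant_is_dc_only(self):
        values = np.full((64, 2), 2.0)
        f = ov.dct_features(values, n_features=64)
        assert f.values[0, 0] == pytest.approx(2.0 * np.sqrt(64))
        np.testing.assert_allclose(f.values[:, 1:], 0.0, atol=1e-12)

    def test_dct_orthonormal_inverse_and_parseval(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((96, 4))
        f = ov.dct_features(x, n_features=96)
        np.testing.assert_allclose(
            scipy_idct(f.values.T, type=2, norm="ortho", axis=0), x, atol=1e-9
        )
        np.testing.assert_allclose(
            np.sum(f.values**2, axis=1), np.sum(x**2, axis=0), rtol=1e-9
        )

    def test_fft_constant_all_energy_at_dc(self):
        n = 64
        values = np.full((n, 1), 3.0)
        f = ov.fft_features(values, n_features=n // 2 + 1)
        assert f.values[0, 0] == pytest.approx(n * 3.0)
        np.testing.assert_allclose(f.values[0, 1:], 0.0, atol=1e-9)

    def test_fft_magnitudes_shift_invariant(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(128)
        a = ov.fft_features(x[:, None], n_features=30).values
        b = ov.fft_features(np.roll(x, 17)[:, None], n_features=30).values
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)

    def test_fft_matches_bruteforce_dft(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(64)
        f = ov.fft_features(x[:, None], n_features=33).values[0]
        k = np.arange(64)
        brute = np.array(
            [abs(np.sum(x * np.exp(-2j * np.pi * kk * k / 64))) for kk in range(33)]
        )
        np.testing.assert_allclose(f, brute, rtol=1e-9, atol=1e-9)

    def test_transform_dimension_contract(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal((100, 5))
        for fn, nf in [(ov.hilbert_features, 21), (ov.dct_features, 21),
                       (ov.fft_features, 21)]:
            assert fn(x, n_features=nf).values.shape == (5, 21)


class TestFeatureStatistics:
    def test_gaussian_moments(self):
        rng = np.random.default_rng(23)
        values = rng.standard_normal((200, 500))
        labels = np.array([0] * 100 + [1] * 100)
        s = ov.feature_statistics(values, labels)
        for cls in (s.normal, s.cancer):
            assert cls.kurtosis == pytest.approx(3.0, abs=0.1)
            assert cls.skewness == pytest.approx(0.0, abs=0.1)
            assert cls.variance == pytest.approx(cls.std_dev**2, rel=1e-12)

    def test_identical_class_means_pearson_one(self):
        rng = np.random.default_rng(24)
        row = rng.uniform(size=30)
        values = np.tile(row, (8, 1))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        s = ov.feature_statistics(values, labels)
        assert s.normal.pearson == pytest.approx(1.0)

    def test_constant_series_entropy_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert ov.sample_entropy(np.full(50, 2.0)) == 0.0

    def test_entropy_positive_for_noise(self):
        rng = np.random.default_rng(25)
        assert ov.sample_entropy(rng.standard_normal(200)) > 0.5
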
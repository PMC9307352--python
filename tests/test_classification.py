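"""Target encoding, DFA exponent, and the six classifiers."""

import numpy as np
import pytest

import ovaclass as ov
from ovaclass.classification import (
    ALGORITHMS,
    TargetEncoding,
    bayesian_linear_regression,
    decode_scores,
)
from ovaclass.errors import ConfigurationError


class TestTargetEncoding:
    def test_encode_examples(self):
        np.testing.assert_allclose(
            ov.encode_targets(np.array([1, 0, 1])), [0.9, 0.1, 0.9]
        )
        np.testing.assert_allclose(ov.encode_targets(np.zeros(4, dtype=int)), 0.1)

    def test_decode_round_trip(self):
        labels = np.array([0, 1, 1, 0, 1])
        assert np.array_equal(decode_scores(ov.encode_targets(labels)), labels)

    def test_non_binary_rejected(self):
        with pytest.raises(ConfigurationError, match="binary"):
            ov.encode_targets(np.array([0, 1, 2]))

    def test_gap_invariant_enforced(self):
        with pytest.raises(ConfigurationError, match="gap"):
            TargetEncoding(t_cancer=0.6, t_normal=0.4)


class TestDFAAlpha:
    def test_white_noise_exponent(self):
        rng = np.random.default_rng(0)
        alpha = ov.dfa_alpha(rng.standard_normal(4096))
        assert alpha == pytest.approx(0.5, abs=0.1)

    def test_integrated_noise_exponent(self):
        rng = np.random.default_rng(0)
        alpha = ov.dfa_alpha(np.cumsum(rng.standard_normal(4096)))
        assert alpha == pytest.approx(1.5, abs=0.15)

    def test_linear_ramp_detrended_exactly(self):
        """Order-1 detrending annihilates a pure linear profile: every box's
        RMS fluctuation drops below 1e-8."""
        from ovaclass.classification import dfa_fluctuations

        _, fluct = dfa_fluctuations(
            np.linspace(0.0, 50.0, 256), integrate=False
        )
        assert np.all(fluct < 1e-8)

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert ov.dfa_alpha(np.zeros(256)) == 0.0

    def test_too_few_box_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            ov.dfa_alpha(np.random.default_rng(1).standard_normal(256), box_sizes=[4, 8])


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestClassifiers:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_training_accuracy(self, algorithm, separable_1d):
        X, y = separable_1d
        model = ov.fit(algorithm, X, y, seed=0)
        scores, pred = model.predict(X)
        assert np.array_equal(pred, y)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_score_label_consistency(self, algorithm):
        rng = np.random.default_rng(40)
        X = rng.standard_normal((30, 20))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1] += 0.5
        model = ov.fit(algorithm, X, y, seed=1)
        scores, pred = model.predict(rng.standard_normal((10, 20)))
        assert np.array_equal(pred, (scores > 0.5).astype(int))

    def test_knn_k1_returns_identical_training_label(self, separable_1d):
        X, y = separable_1d
        model = ov.fit("KNN", X, y, k=1)
        _, pred = model.predict(X[[2, 7]])
        assert pred.tolist() == [y[2], y[7]]

    def test_knn_even_k_rejected(self):
        with pytest.raises(ConfigurationError, match="odd"):
            ov.fit("KNN", np.zeros((4, 2)), np.array([0, 0, 1, 1]), k=2)

    def test_bldc_recovers_noise_free_weights(self):
        """On noise-free linear targets the evidence iteration drives the
        noise precision up and the posterior mean to the exact weights, the
        same solution as ridge regression with vanishing prior."""
        rng = np.random.default_rng(41)
        X = rng.standard_normal((20, 2))
        w = np.array([1.7, -0.6])
        t = X @ w
        weights, alpha, beta = bayesian_linear_regression(X, t)
        np.testing.assert_allclose(weights, w, rtol=1e-3)
        # oracle: ordinary least squares (ridge with prior precision -> 0)
        ols = np.linalg.lstsq(X, t, rcond=None)[0]
        np.testing.assert_allclose(weights, ols, rtol=1e-3)

    def test_lr_matches_normal_equations(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((15, 3))
        y = np.array([0] * 7 + [1] * 8)
        model = ov.fit("LR", X, y)
        phi = np.hstack([np.ones((15, 1)), X])
        t = ov.encode_targets(y)
        oracle = np.linalg.pinv(phi) @ t
        np.testing.assert_allclose(model.coef_, oracle, rtol=1e-9)

    @pytest.mark.parametrize("algorithm", ["KNN", "LR", "BLDC"])
    def test_training_order_invariance(self, algorithm):
        rng = np.random.default_rng(43)
        X = rng.standard_normal((24, 6))
        y = np.array([0] * 12 + [1] * 12)
        X[y == 1] += 1.0
        probe = rng.standard_normal((8, 6))
        base = ov.fit(algorithm, X, y, seed=5).predict(probe)[0]
        perm = rng.permutation(24)
        permuted = ov.fit(algorithm, X[perm], y[perm], seed=5).predict(probe)[0]
        np.testing.assert_allclose(base, permuted, atol=1e-9)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_serialization_round_trip(self, algorithm, tmp_path):
        rng = np.random.default_rng(44)
        X = rng.standard_normal((20, 18))
        y = np.array([0] * 10 + [1] * 10)
        X[y == 1] += 1.5
        model = ov.fit(algorithm, X, y, seed=2)
        path = tmp_path / f"{algorithm}.json"
        ov.save_model(model, path)
        restored = ov.load_model(path)
        probe = rng.standard_normal((6, 18))
        np.testing.assert_allclose(
            model.predict(probe)[0], restored.predict(probe)[0], atol=1e-12
        )

    def test_gmm_multi_component_still_separates(self):
        rng = np.random.default_rng(45)
        X0 = np.vstack([rng.normal(-4, 0.5, (10, 2)), rng.normal(-8, 0.5, (10, 2))])
        X1 = np.vstack([rng.normal(4, 0.5, (10, 2)), rng.normal(8, 0.5, (10, 2))])
        X = np.vstack([X0, X1])
        y = np.array([0] * 20 + [1] * 20)
        model = ov.fit("GMM", X, y, seed=3, n_components=2)
        _, pred = model.predict(X)
        assert np.mean(pred == y) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(46)
        X = rng.standard_normal((30, 5))
        y = np.array([0] * 15 + [1] * 15)
        probe = rng.standard_normal((5, 5))
        for algorithm in ALGORITHMS:
            a = ov.fit(algorithm, X, y, seed=7).predict(probe)[0]
            b = ov.fit(algorithm, X, y, seed=7).predict(probe)[0]
            np.testing.assert_array_equal(a, b)
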
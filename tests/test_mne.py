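"""MNE encoding model: prediction, gradient, fitting, shuffle null,
feature extraction."""

import numpy as np
import pytest
from scipy.special import expit

from astrorf.mne import (
    MaximumNoiseEntropyModel,
    nll_and_gradient,
    pack_params,
    predict,
    unpack_params,
)
from astrorf.spectro import PcaReduction
from astrorf.stimulus import GroundTruthModel

from conftest import make_white_X


class Params:
    def __init__(self, a, h, J):
        self.a, self.h, self.J = a, np.asarray(h, float), np.asarray(J, float)


def _identity_pca(K):
    return PcaReduction(mean=np.zeros(K), basis=np.eye(K),
                        explained_variance_fraction=1.0)


class TestPredict:
    def test_zero_parameters_give_half(self):
        m = Params(0.0, np.zeros(3), np.zeros((3, 3)))
        assert np.allclose(predict(m, np.random.default_rng(0)
                                   .standard_normal((10, 3))), 0.5)

    def test_bias_log9_gives_point_one(self):
        m = Params(np.log(9.0), np.zeros(2), np.zeros((2, 2)))
        assert predict(m, np.zeros((1, 2)))[0] == pytest.approx(0.1)

    def test_scalar_quadratic_case(self):
        """K=1, a=0, h=1, J=1 at x=1: p = 1/(1+e^2)."""
        m = Params(0.0, [1.0], [[1.0]])
        assert predict(m, np.array([[1.0]]))[0] == pytest.approx(
            1.0 / (1.0 + np.e**2), abs=1e-10)

    def test_nonfinite_input_rejected(self):
        m = Params(0.0, np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            predict(m, np.array([[np.nan, 0.0]]))


class TestGradient:
    @pytest.mark.parametrize("ridge", [0.0, 1e-3])
    def test_matches_central_finite_differences(self, ridge):
        """Analytic gradient agrees with finite differences to 1e-6
        relative on small random instances (K=4, N=50)."""
        rng = np.random.default_rng(12)
        K, N = 4, 50
        X = rng.standard_normal((N, K))
        y = rng.random(N)
        theta = rng.standard_normal(1 + K + K * (K + 1) // 2) * 0.4
        _, g = nll_and_gradient(theta, X, y, ridge)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (nll_and_gradient(tp, X, y, ridge)[0]
                  - nll_and_gradient(tm, X, y, ridge)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_zero_point_stationary_in_a_h_for_balanced_data(self):
        """At theta=0 with y=0.5 and zero-mean X the a and h gradient
        components vanish by symmetry."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 3))
        X -= X.mean(axis=0)
        y = np.full(400, 0.5)
        _, g = nll_and_gradient(np.zeros(1 + 3 + 6), X, y)
        assert abs(g[0]) < 1e-12
        assert np.max(np.abs(g[1:4])) < 1e-12

    def test_pack_unpack_roundtrip(self):
        rng = np.random.default_rng(0)
        a, h = 0.7, rng.standard_normal(5)
        M = rng.standard_normal((5, 5))
        J = M + M.T
        a2, h2, J2 = unpack_params(pack_params(a, h, J), 5)
        assert a2 == a and np.allclose(h2, h) and np.allclose(J2, J)


class TestFit:
    def test_constant_rate_recovers_intercept_only(self):
        """Data from a constant-rate p0 generator: fitted a is near
        log(1/p0 - 1) and h, J are near zero."""
        rng = np.random.default_rng(3)
        N, K, p0 = 3000, 6, 0.2
        X = make_white_X(N, K, seed=1)
        y = rng.binomial(20, p0, size=N) / 20
        m = MaximumNoiseEntropyModel(X, y)
        res = m.fit()
        assert res.a == pytest.approx(np.log(1 / p0 - 1), abs=0.15)
        assert np.linalg.norm(res.h) < 0.1
        assert np.linalg.norm(res.J) < 0.2

    def test_quadratic_feature_recovery(self):
        """A single suppressive quadratic feature is recovered as the
        leading eigenvector of fitted J."""
        rng = np.random.default_rng(7)
        N, K = 8000, 12
        X = make_white_X(N, K, seed=2)
        v = np.linalg.qr(rng.standard_normal((K, 1)))[0][:, 0]
        truth = GroundTruthModel(a=np.log(1 / 0.15 - 1), h=np.zeros(K),
                                 J=2.0 * np.outer(v, v))
        y = rng.binomial(20, predict(truth, X)) / 20
        tm = np.zeros(N, bool)
        tm[: int(0.7 * N)] = True
        folds = np.array_split(np.arange(int(0.7 * N)), 3)
        res = MaximumNoiseEntropyModel(X, y, train_mask=tm, test_mask=~tm,
                                       folds=folds).fit()
        _, V = res.quadratic_eigensystem()
        assert abs(V[:, -1] @ v) > 0.95

    def test_prediction_invariant_under_basis_rotation(self):
        """Rotating the stimulus basis and rotating (h, J) consistently
        leaves predictions unchanged."""
        rng = np.random.default_rng(11)
        K = 5
        X = rng.standard_normal((40, K))
        M = rng.standard_normal((K, K))
        J = M + M.T
        h = rng.standard_normal(K)
        m1 = Params(0.3, h, J)
        R = np.linalg.qr(rng.standard_normal((K, K)))[0]
        m2 = Params(0.3, R.T @ h, R.T @ J @ R)
        assert np.allclose(predict(m1, X), predict(m2, X @ R), atol=1e-10)

    def test_divergence_check_and_shapes(self):
        with pytest.raises(ValueError):
            MaximumNoiseEntropyModel(np.zeros((10, 3)), np.full(10, 1.5))


class TestEvaluate:
    def _fitted(self, seed=0, N=600, K=4):
        rng = np.random.default_rng(seed)
        X = make_white_X(N, K, seed=seed + 1)
        y = rng.binomial(20, 0.2, size=N) / 20
        tm = np.zeros(N, bool)
        tm[: int(0.7 * N)] = True
        folds = np.array_split(np.arange(int(0.7 * N)), 3)
        m = MaximumNoiseEntropyModel(X, y, train_mask=tm, test_mask=~tm,
                                     folds=folds)
        return m.fit(maxiter=150)

    def test_p_value_counting_conventions(self):
        res = self._fitted()
        ev = res.evaluate(n_shuffles=20, seed=4)
        r = int(np.sum(ev.null_similarities >= ev.cosine_similarity))
        assert ev.p_value == r / 20
        assert ev.p_value_plus_one == (r + 1) / 21
        assert ev.significant == (ev.p_value < 0.05)

    def test_evaluation_deterministic_under_seed(self):
        res = self._fitted()
        e1 = res.evaluate(n_shuffles=5, seed=9)
        e2 = res.evaluate(n_shuffles=5, seed=9)
        assert np.array_equal(e1.null_similarities, e2.null_similarities)

    def test_cosine_extremes(self):
        from astrorf.mne import _cosine
        v = np.array([1.0, 2.0, 3.0])
        assert _cosine(2 * v, v) == pytest.approx(1.0)
        assert _cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        with pytest.raises(FloatingPointError):
            _cosine(np.zeros(3), v)


class TestExtractFeatures:
    def test_diagonal_J_yields_classified_candidates(self):
        """J = diag(2, -1, 0): eigenvalue 2 is inhibitory, -1 excitatory."""
        K = 3
        X = make_white_X(100, K, seed=0)
        m = MaximumNoiseEntropyModel(X, np.full(100, 0.5))
        res = m.fit(maxiter=0)  # keep parameters at init
        res.J = np.diag([2.0, -1.0, 0.0])
        res.h = np.zeros(K)
        feats = res.extract_features(_identity_pca(K))
        by_eig = {round(f.eigenvalue, 6): f for f in feats
                  if f.kind == "quadratic"}
        assert by_eig[2.0].sign_class == "inhibitory"
        assert by_eig[-1.0].sign_class == "excitatory"

    def test_single_feature_truth_yields_one_significant(self):
        """Fit to a pure quadratic-suppressive truth: exactly the true
        feature exceeds the shuffle eigenvalue null."""
        rng = np.random.default_rng(21)
        N, K = 5000, 8
        X = make_white_X(N, K, seed=5)
        v = np.linalg.qr(rng.standard_normal((K, 1)))[0][:, 0]
        truth = GroundTruthModel(a=np.log(1 / 0.15 - 1), h=np.zeros(K),
                                 J=2.5 * np.outer(v, v))
        y = rng.binomial(20, predict(truth, X)) / 20
        tm = np.zeros(N, bool)
        tm[: 3500] = True
        folds = np.array_split(np.arange(3500), 3)
        res = MaximumNoiseEntropyModel(X, y, train_mask=tm, test_mask=~tm,
                                       folds=folds).fit(maxiter=200)
        res.evaluate(n_shuffles=25, seed=2)
        feats = res.extract_features(_identity_pca(K))
        sig = [f for f in feats if f.significant and f.kind == "quadratic"]
        # count concentrates at 1 (the familywise null admits a ~5%
        # false-positive rate per unit)
        assert 1 <= len(sig) <= 2
        best = max(sig, key=lambda f: abs(f.eigenvalue))
        assert best.sign_class == "inhibitory"
        assert abs(best.reduced_vector @ v) > 0.9

    def test_asymmetric_J_rejected(self):
        X = make_white_X(50, 3, seed=0)
        m = MaximumNoiseEntropyModel(X, np.full(50, 0.5))
        res = m.fit(maxiter=0)
        from astrorf.mne import MNEResults
        with pytest.raises(ValueError, match="symmetric"):
            MNEResults(m, 0.0, np.zeros(3),
                       np.array([[0, 1.0, 0], [0, 0, 0], [0, 0, 0.0]]),
                       res.fold_scores, res.fit_meta)


class TestSummary:
    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(0)
        X = make_white_X(200, 3, seed=0)
        y = rng.binomial(20, 0.3, 200) / 20
        res = MaximumNoiseEntropyModel(X, y).fit(maxiter=50)
        text = res.summary()
        assert "Maximum Noise Entropy" in text
        assert "bias a" in text and "eigenvalues of J" in text
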
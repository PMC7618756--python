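"""Synthetic stimulus, ground-truth models, rasters, population structure."""

import numpy as np
import pytest
from scipy import signal

from astrorf.mne import predict
from astrorf.spectro import PcaReduction
from astrorf.stimulus import (
    GroundTruthModel,
    SyntheticStimulusSpec,
    gabor_feature_map,
    generate_population,
    generate_usv_stimulus,
    make_ground_truth,
    simulate_event_raster,
)

from conftest import make_white_X


class TestGenerateUsvStimulus:
    def test_duration_arithmetic(self):
        spec = SyntheticStimulusSpec(n_segments=15)
        assert spec.total_duration == 170.0  # 20 + 15 * (8 + 2)
        short = SyntheticStimulusSpec(n_segments=1, lead_silence=0.0, seed=0)
        wave = generate_usv_stimulus(short)
        assert len(wave) == int(10.0 * short.sample_rate)

    def test_silence_pads_are_exact_zeros(self):
        spec = SyntheticStimulusSpec(n_segments=1, lead_silence=0.0, seed=2)
        wave = generate_usv_stimulus(spec)
        fs = int(spec.sample_rate)
        assert np.all(wave[:fs] == 0.0)
        assert np.all(wave[-fs:] == 0.0)
        assert np.any(wave[fs:-fs] != 0.0)

    def test_seeded_determinism(self):
        spec = SyntheticStimulusSpec(n_segments=1, seed=5)
        assert np.array_equal(generate_usv_stimulus(spec),
                              generate_usv_stimulus(spec))

    def test_band_exceeding_nyquist_rejected(self):
        spec = SyntheticStimulusSpec(band=(45_000.0, 140_000.0))
        with pytest.raises(ValueError, match="band"):
            generate_usv_stimulus(spec)

    def test_spectral_power_confined_to_band(self, small_waveform):
        """>= 99% of vocalization-segment power lies within 45-110 kHz."""
        wave, spec = small_waveform
        fs = spec.sample_rate
        start = int((spec.lead_silence + spec.pad_silence) * fs)
        seg = wave[start : start + int(spec.segment_duration * fs)]
        f, psd = signal.welch(seg, fs=fs, nperseg=4096)
        in_band = (f >= spec.band[0]) & (f <= spec.band[1])
        assert psd[in_band].sum() / psd.sum() >= 0.99


class TestMakeGroundTruth:
    def test_zero_maps_give_constant_model(self, white_basis):
        p0 = 0.3
        gt = make_ground_truth(white_basis, [], [], a=np.log(1 / p0 - 1))
        X = make_white_X(50, white_basis.n_components, seed=0)
        assert np.allclose(predict(gt, X), p0)
        assert gt.base_rate == pytest.approx(p0)

    def test_positive_eigenvalue_suppresses_probability(self, white_basis):
        rng = np.random.default_rng(0)
        m = gabor_feature_map(rng)
        gt = make_ground_truth(white_basis, [m], [2.0], a=0.0)
        v = white_basis.basis.T @ m.ravel()
        v /= np.linalg.norm(v)
        X = np.outer(np.linspace(0, 3, 10), v)  # growing energy along map
        p = predict(gt, X)
        assert np.all(np.diff(p) < 0)

    def test_eigendecomposition_recovers_two_orthogonal_maps(self, white_basis):
        """J built from two orthogonalized maps with eigenvalues (2, -1)
        decomposes back to those maps and values."""
        rng = np.random.default_rng(1)
        maps = [gabor_feature_map(rng) for _ in range(2)]
        gt = make_ground_truth(white_basis, maps, [2.0, -1.0], a=0.0)
        w, V = np.linalg.eigh(gt.J)
        assert w[-1] == pytest.approx(2.0, abs=1e-10)
        assert w[0] == pytest.approx(-1.0, abs=1e-10)
        assert np.sum(np.abs(w) > 1e-10) == 2
        # eigenvectors match the Gram-Schmidt frame of the projected maps
        P = np.stack([white_basis.basis.T @ m.ravel() for m in maps], axis=1)
        Q, _ = np.linalg.qr(P)
        assert abs(V[:, -1] @ Q[:, 0]) == pytest.approx(1.0, abs=1e-8)

    def test_nonfinite_eigenvalues_rejected(self, white_basis):
        with pytest.raises(ValueError, match="finite"):
            make_ground_truth(white_basis, [np.ones((28, 28))], [np.inf], 0.0)


class TestSimulateEventRaster:
    def test_trial_average_within_binomial_bound(self):
        """Constant p=0.5 model, 10000 trials: every bin mean within
        [0.48, 0.52] (well inside the 99% binomial band)."""
        K = 4
        gt = GroundTruthModel(a=0.0, h=np.zeros(K), J=np.zeros((K, K)))
        X = make_white_X(100, K, seed=1)
        r = simulate_event_raster(gt, X, n_trials=10_000, seed=0)
        means = r.trial_average()
        assert np.all((means > 0.48) & (means < 0.52))

    def test_per_bin_rate_matches_model_probability(self, white_basis):
        """Trial averages track heterogeneous per-bin probabilities within
        a pooled binomial confidence band (>= 100 bins, 10000 trials)."""
        rng = np.random.default_rng(2)
        K = white_basis.n_components
        m = gabor_feature_map(rng)
        gt = make_ground_truth(white_basis, [m], [1.0], a=np.log(1 / 0.2 - 1))
        X = make_white_X(150, K, seed=3)
        p = predict(gt, X)
        r = simulate_event_raster(gt, X, n_trials=10_000, seed=1)
        se = np.sqrt(p * (1 - p) / 10_000)
        z = (r.trial_average() - p) / se
        assert np.mean(np.abs(z) < 2.576) > 0.95  # ~99% coverage expected

    def test_extreme_bias_gives_all_zeros(self):
        gt = GroundTruthModel(a=1e3, h=np.zeros(2), J=np.zeros((2, 2)))
        r = simulate_event_raster(gt, make_white_X(50, 2, seed=0),
                                  n_trials=20, seed=0)
        assert r.binary.sum() == 0

    def test_seeded_determinism_and_embedding(self):
        gt = GroundTruthModel(a=1.0, h=np.zeros(3), J=np.zeros((3, 3)))
        X = make_white_X(30, 3, seed=4)
        t_idx = np.arange(27, 57)
        r1 = simulate_event_raster(gt, X, 5, seed=9, time_index=t_idx,
                                   n_bins=57)
        r2 = simulate_event_raster(gt, X, 5, seed=9, time_index=t_idx,
                                   n_bins=57)
        assert np.array_equal(r1.binary, r2.binary)
        assert r1.binary.shape == (5, 57)
        assert r1.binary[:, :27].sum() == 0  # no events before first patch


class TestGeneratePopulation:
    def _angles(self, A, B):
        from astrorf.subspace import orthonormal_basis, principal_angles
        return principal_angles(orthonormal_basis(A),
                                orthonormal_basis(B)).angles_deg

    def test_full_overlap_gives_zero_angles(self, white_basis):
        X = make_white_X(400, white_basis.n_components, seed=5)
        ds = generate_population(white_basis, X, dim_a=3, dim_b=3,
                                 shared_dim=3, seed=0)
        assert np.max(self._angles(ds.true_maps_a, ds.true_maps_b)) < 1e-6

    def test_zero_overlap_gives_ninety_degrees(self, white_basis):
        X = make_white_X(400, white_basis.n_components, seed=5)
        ds = generate_population(white_basis, X, dim_a=3, dim_b=3,
                                 shared_dim=0, seed=0)
        assert np.min(self._angles(ds.true_maps_a, ds.true_maps_b)) > 90 - 1e-6

    def test_partial_overlap_splits_angles(self, white_basis):
        """shared_dim=1 of 3: smallest angle 0, the other two 90 deg."""
        X = make_white_X(400, white_basis.n_components, seed=5)
        ds = generate_population(white_basis, X, dim_a=3, dim_b=3,
                                 shared_dim=1, seed=0)
        ang = self._angles(ds.true_maps_a, ds.true_maps_b)
        assert ang[0] < 1e-6
        assert np.all(ang[1:] > 90 - 1e-6)

    def test_rasters_match_requested_shape_and_rate(self, white_basis):
        X = make_white_X(600, white_basis.n_components, seed=6)
        ds = generate_population(white_basis, X, n_units_a=2, n_units_b=2,
                                 n_trials=20, base_rate=0.15, seed=1)
        assert len(ds.rasters) == 4
        assert ds.population_labels == ["popA", "popA", "popB", "popB"]
        for r in ds.rasters:
            assert r.binary.shape == (20, 600)
            assert r.trial_average().mean() <= 0.3  # sparse by design

    def test_invalid_dims_rejected(self, white_basis):
        X = make_white_X(100, white_basis.n_components, seed=0)
        with pytest.raises(ValueError, match="shared_dim"):
            generate_population(white_basis, X, dim_a=2, dim_b=2, shared_dim=3)
        with pytest.raises(ValueError, match="exceed"):
            generate_population(white_basis, X, dim_a=20, dim_b=20,
                                shared_dim=0)
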
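"""Shared fixtures: a small synthetic audio pipeline and white-stimulus
ensembles for estimator-property tests."""

import numpy as np
import pytest

from astrorf import (
    PcaReduction,
    SyntheticStimulusSpec,
    compute_spectrogram,
    extract_patches,
    fit_pca,
    generate_usv_stimulus,
    restrict_and_bin,
)


@pytest.fixture(scope="session")
def small_waveform():
    """Two vocalization segments after a short lead silence (22 s total)."""
    spec = SyntheticStimulusSpec(n_segments=2, lead_silence=2.0, seed=1)
    return generate_usv_stimulus(spec), spec


@pytest.fixture(scope="session")
def binned_spectrogram(small_waveform):
    wave, spec = small_waveform
    sg = compute_spectrogram(wave, spec.sample_rate)
    return restrict_and_bin(sg)


@pytest.fixture(scope="session")
def patch_pca(binned_spectrogram):
    """(patches, pca, X) for the small audio stimulus, K=32."""
    patches = extract_patches(binned_spectrogram)
    pca = fit_pca(patches, n_components=32)
    return patches, pca, pca.project(patches.patches)


@pytest.fixture(scope="session")
def white_basis():
    """A synthetic orthonormal 784 x 24 stimulus basis (white ensemble)."""
    rng = np.random.default_rng(42)
    Q, _ = np.linalg.qr(rng.standard_normal((784, 24)))
    return PcaReduction(mean=np.zeros(784), basis=Q,
                        explained_variance_fraction=1.0)


def make_white_X(n_rows: int, n_dims: int, seed: int) -> np.ndarray:
    """Unit-variance Gaussian reduced stimulus ensemble."""
    return np.random.default_rng(seed).standard_normal((n_rows, n_dims))
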
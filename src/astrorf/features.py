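"""Feature comparison: modulation power spectra, low-dimensional
embeddings, event-property clustering, and pairwise unit correlations.

A receptive-field feature is a compact spectrotemporal map; its modulation
power spectrum (squared magnitude of the 2-D DFT, zero-frequency centered)
summarizes the temporal (cycles/s) and spectral (cycles/kHz) modulations
it is tuned to, invariantly to the feature's position in time.  Spectra
are embedded with UMAP for population-level comparison; calcium-event
property vectors (duration, area, rise time, fall time, circularity) are
standardized, embedded and density-clustered with HDBSCAN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModulationSpectrum",
    "EventPropertyVector",
    "modulation_power_spectrum",
    "embed_features",
    "cluster_event_properties",
    "pairwise_unit_correlations",
]

EVENT_PROPERTIES = ("duration", "area", "rise_time", "fall_time", "circularity")


@dataclass
class ModulationSpectrum:
    """2-D modulation power of a spectrotemporal feature map.

    ``power[i, j]`` is the squared DFT magnitude at temporal modulation
    ``temporal_freqs[i]`` (cycles/s) and spectral modulation
    ``spectral_freqs[j]`` (cycles/kHz), zero-frequency centered.  For a
    real-valued map the spectrum is symmetric under 180-degree rotation.
    """

    power: np.ndarray
    temporal_freqs: np.ndarray
    spectral_freqs: np.ndarray


@dataclass
class EventPropertyVector:
    """Morphological/kinetic properties of one calcium event."""

    duration: float  # s
    area: float  # um^2
    rise_time: float  # s
    fall_time: float  # s
    circularity: float  # dimensionless, in (0, 1]

    def as_array(self) -> np.ndarray:
        return np.array([self.duration, self.area, self.rise_time,
                         self.fall_time, self.circularity], float)


def modulation_power_spectrum(
    feature_map: np.ndarray,
    bin_duration: float = 8.192e-3,
    freq_bin_width_hz: float = (110_000.0 - 45_000.0) / 28,
    pad_factor: int = 1,
) -> ModulationSpectrum:
    """Squared magnitude of the 2-D DFT of a feature map, centered.

    No windowing is applied (features are already compact); ``pad_factor``
    > 1 zero-pads for finer modulation sampling.  With the unnormalized
    DFT, Parseval gives ``power.sum() == n_t * n_f * (map**2).sum()`` at
    pad_factor 1.  Axes are cycles/s (rows of the map are time bins of
    ``bin_duration``) and cycles/kHz.
    """
    M = np.asarray(feature_map, float)
    if not np.isfinite(M).all():
        raise ValueError("feature map contains non-finite values")
    nt, nf = M.shape
    F = np.fft.fft2(M, s=(nt * pad_factor, nf * pad_factor))
    power = np.fft.fftshift(np.abs(F) ** 2)
    tfreqs = np.fft.fftshift(np.fft.fftfreq(nt * pad_factor, d=bin_duration))
    ffreqs = np.fft.fftshift(
        np.fft.fftfreq(nf * pad_factor, d=freq_bin_width_hz / 1000.0)
    )
    return ModulationSpectrum(power=power, temporal_freqs=tfreqs,
                              spectral_freqs=ffreqs)


def embed_features(
    spectra: list[ModulationSpectrum] | np.ndarray,
    labels: list[str] | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, list[str] | None]:
    """Embed flattened modulation spectra to 2-D with UMAP.

    The embedding is plumbing around the UMAP library, seeded for
    reproducibility; ``n_neighbors`` is auto-reduced with a warning when
    there are fewer points than neighbors.  Returns (coordinates, labels).
    """
    if isinstance(spectra, np.ndarray):
        X = np.asarray(spectra, float)
    else:
        X = np.stack([s.power.ravel() for s in spectra])
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spectra to embed")
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors={n_neighbors} >= n_points={n}; "
                      f"reducing to {n - 1}")
        n_neighbors = n - 1
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(X)
    return np.asarray(coords), labels


def cluster_event_properties(
    vectors: list[EventPropertyVector] | np.ndarray,
    min_cluster_size: int = 25,
    n_neighbors: int = 15,
    seed: int = 0,
    embed: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize event-property vectors, embed, and density-cluster.

    Properties are z-scored, embedded to 2-D with UMAP (optional) and
    clustered with HDBSCAN; label -1 marks noise points.  Returns
    (labels, 2-D coordinates).  Library-backed stage; parameters exposed.
    """
    if not isinstance(vectors, np.ndarray):
        X = np.stack([v.as_array() for v in vectors])
    else:
        X = np.asarray(vectors, float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if embed:
        coords, _ = embed_features(Z, n_neighbors=n_neighbors, seed=seed)
    else:
        coords = Z[:, :2]
    from sklearn.cluster import HDBSCAN

    labels = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(coords)
    return labels, coords


def pairwise_unit_correlations(series: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between every pair of units.

    ``series`` is (n_units, n_samples).  Returns the full correlation
    matrix (diagonal 1; NaN for pairs involving a zero-variance unit) and
    the pooled finite off-diagonal values (upper triangle) for
    histogramming.
    """
    S = np.asarray(series, float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("need at least 2 equal-length series")
    sd = S.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(S)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, 1.0)
    iu = np.triu_indices_from(C, k=1)
    pooled = C[iu]
    return C, pooled[np.isfinite(pooled)]
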
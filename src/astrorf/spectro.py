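"""Stimulus preprocessing: spectrogram, spectrotemporal patches, PCA reduction.

The encoding models downstream operate on short windows of the stimulus
spectrogram.  A waveform is converted to a power-spectral-density
spectrogram (STFT with 50% overlap), restricted to the ultrasonic
vocalization band and binned to a small number of linear frequency bins,
cut into sliding time-frequency patches (the stimulus history seen by a
unit at each time bin), and reduced by PCA to a tractable dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Spectrogram",
    "StimulusPatchSet",
    "PcaReduction",
    "compute_spectrogram",
    "restrict_and_bin",
    "extract_patches",
    "fit_pca",
]


@dataclass
class Spectrogram:
    """Time-frequency power representation of a stimulus.

    Attributes
    ----------
    power : ndarray, shape (n_time_bins, n_freq_bins)
        Non-negative power per (time, frequency) cell.
    bin_duration : float
        Temporal width of one time bin in seconds (STFT hop / sample rate).
    freq_centers : ndarray
        Center frequency of each frequency bin, Hz.
    origin_time : float
        Time (s) of the center of the first bin relative to waveform start.
    """

    power: np.ndarray
    bin_duration: float
    freq_centers: np.ndarray
    origin_time: float = 0.0

    @property
    def n_time_bins(self) -> int:
        return self.power.shape[0]

    @property
    def n_freq_bins(self) -> int:
        return self.power.shape[1]

    @property
    def freq_resolution(self) -> float:
        """Spacing of the frequency grid, Hz."""
        f = np.asarray(self.freq_centers, float)
        return float(f[1] - f[0]) if f.size > 1 else float("nan")


@dataclass
class StimulusPatchSet:
    """Flattened sliding spectrotemporal windows of a spectrogram.

    Each row of ``patches`` is the row-major flattening of a
    ``window_time_bins x window_freq_bins`` patch: index ``l * n_freq + f``
    holds the power at lag ``l`` (0 = oldest bin in the window) and
    frequency row ``f``.  ``time_index[i]`` is the spectrogram time bin at
    which the i-th window *ends* (the "current" bin).
    """

    patches: np.ndarray
    window_time_bins: int
    window_freq_bins: int
    time_index: np.ndarray
    bin_duration: float = float("nan")
    freq_centers: np.ndarray | None = None

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_dim(self) -> int:
        return self.window_time_bins * self.window_freq_bins

    def unflatten(self, row: np.ndarray) -> np.ndarray:
        """Reshape a flattened patch back to (time, frequency)."""
        return np.asarray(row).reshape(self.window_time_bins, self.window_freq_bins)


@dataclass
class PcaReduction:
    """Affine map from flattened patches to reduced PCA coordinates.

    ``project(s) = (s - mean) @ basis``; ``back_project(x) = mean + basis @ x``
    (or, for directions rather than points, ``basis @ x`` without the mean).
    """

    mean: np.ndarray
    basis: np.ndarray  # (patch_dim, n_components), orthonormal columns
    explained_variance_fraction: float
    explained_variance: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    @property
    def patch_dim(self) -> int:
        return self.basis.shape[0]

    def project(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, float)
        return (s - self.mean) @ self.basis

    def back_project(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return self.mean + x @ self.basis.T

    def lift_direction(self, x: np.ndarray) -> np.ndarray:
        """Back-project a *direction* (no mean offset), e.g. an RF feature."""
        return np.asarray(x, float) @ self.basis.T


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    nfft: int = 4096,
    overlap_fraction: float = 0.5,
    window: str = "hann",
) -> Spectrogram:
    """Power-spectral-density spectrogram by short-time Fourier transform.

    With the defaults at 250 kHz sampling the hop is ``nfft/2`` samples,
    giving a temporal resolution of 8.1920 ms and a frequency resolution of
    sample_rate / nfft = 61.035 Hz.

    Parameters
    ----------
    waveform : 1-D array
        Single-channel stimulus waveform.
    sample_rate : float
        Sampling rate in Hz.
    nfft : int
        STFT segment length in samples.
    overlap_fraction : float
        Fractional overlap of consecutive segments in [0, 1).

    Returns
    -------
    Spectrogram
        ``power`` has shape (n_segments, nfft//2 + 1) in PSD units.
    """
    waveform = np.asarray(waveform, float).squeeze()
    if waveform.ndim != 1:
        raise ValueError("waveform must be single-channel (1-D)")
    if waveform.size < nfft:
        raise ValueError(
            f"waveform has {waveform.size} samples, shorter than one "
            f"STFT window of {nfft}"
        )
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    noverlap = int(round(nfft * overlap_fraction))
    hop = nfft - noverlap
    freqs, times, sxx = signal.spectrogram(
        waveform,
        fs=sample_rate,
        window=window,
        nperseg=nfft,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return Spectrogram(
        power=sxx.T.copy(),
        bin_duration=hop / sample_rate,
        freq_centers=freqs,
        origin_time=float(times[0]),
    )


def restrict_and_bin(
    spec: Spectrogram,
    f_lo: float = 45_000.0,
    f_hi: float = 110_000.0,
    n_bins: int = 28,
) -> Spectrogram:
    """Restrict the frequency axis to [f_lo, f_hi] and average into
    ``n_bins`` linearly spaced bins.

    Each output bin is the *mean* power of the raw FFT bins whose center
    frequency falls inside the corresponding linear sub-interval, so units
    stay comparable even if band edges leave unequal raw-bin counts.  Total
    in-band power is conserved up to this mean-vs-sum convention.
    """
    f = np.asarray(spec.freq_centers, float)
    if f_lo < f[0] - 1e-9 or f_hi > f[-1] + 1e-9:
        raise ValueError(
            f"band [{f_lo}, {f_hi}] Hz outside spectrogram range "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    edges = np.linspace(f_lo, f_hi, n_bins + 1)
    # right-inclusive last bin so f_hi itself is kept
    idx = np.searchsorted(edges, f, side="right") - 1
    idx[f == f_hi] = n_bins - 1
    out = np.empty((spec.n_time_bins, n_bins))
    centers = np.empty(n_bins)
    for b in range(n_bins):
        members = np.nonzero(idx == b)[0]
        if members.size == 0:
            raise ValueError(
                f"frequency bin {b} ([{edges[b]:.1f}, {edges[b + 1]:.1f}] Hz) "
                "contains no FFT bins; increase nfft or widen bins"
            )
        out[:, b] = spec.power[:, members].mean(axis=1)
        centers[b] = 0.5 * (edges[b] + edges[b + 1])
    return Spectrogram(
        power=out,
        bin_duration=spec.bin_duration,
        freq_centers=centers,
        origin_time=spec.origin_time,
    )


def extract_patches(spec: Spectrogram, window: int = 28) -> StimulusPatchSet:
    """Cut sliding spectrotemporal windows out of a spectrogram.

    One patch is produced per time bin ``t >= window - 1``, covering bins
    ``[t - window + 1, t]`` inclusive — the current bin plus its history.
    The first ``window - 1`` bins yield no patch (dropped, not padded).
    """
    T, F = spec.power.shape
    if T < window:
        raise ValueError(f"spectrogram has {T} time bins, fewer than window={window}")
    windows = np.lib.stride_tricks.sliding_window_view(spec.power, window, axis=0)
    # sliding_window_view gives (T-window+1, F, window); transpose to
    # (N, window, F) so flattening is lag-major.
    patches = np.ascontiguousarray(windows.transpose(0, 2, 1)).reshape(
        T - window + 1, window * F
    )
    return StimulusPatchSet(
        patches=patches,
        window_time_bins=window,
        window_freq_bins=F,
        time_index=np.arange(window - 1, T),
        bin_duration=spec.bin_duration,
        freq_centers=np.asarray(spec.freq_centers),
    )


def fit_pca(patches: StimulusPatchSet, n_components: int = 128) -> PcaReduction:
    """Fit PCA on the patch set and return the reduction map.

    Uses the eigendecomposition of the patch covariance via SVD of the
    centered data matrix.  ``explained_variance_fraction`` is the fraction
    of total patch variance captured by the retained components.
    """
    X = np.asarray(patches.patches, float)
    n, d = X.shape
    if n <= n_components:
        raise ValueError(f"need more patches ({n}) than components ({n_components})")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float(np.sum(Xc**2)) / (n - 1)
    if total_var <= 0.0:
        raise ValueError("degenerate input: patches have zero variance")
    # economy SVD; components are right singular vectors
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    k = min(n_components, vt.shape[0])
    basis = vt[:k].T
    # deterministic sign: largest-magnitude element of each component positive
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    basis = basis * flip
    return PcaReduction(
        mean=mean,
        basis=basis,
        explained_variance_fraction=float(var[:k].sum() / total_var),
        explained_variance=var[:k],
    )
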
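"""Plotting helpers for receptive-field features and model diagnostics."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_feature_map", "plot_modulation_spectrum", "plot_raster"]


def plot_feature_map(feature, bin_duration: float = 8.192e-3,
                     band=(45_000.0, 110_000.0), ax=None):
    """Render a spectrotemporal feature map (time on x, frequency on y).

    ``feature`` is an ``RfFeature`` or a bare 2-D map.  The color scale is
    symmetric about zero so suppressive and facilitating regions are
    directly comparable.
    """
    import matplotlib.pyplot as plt

    M = np.asarray(getattr(feature, "map", feature), float)
    if ax is None:
        _, ax = plt.subplots()
    nt = M.shape[0]
    vmax = np.max(np.abs(M)) or 1.0
    im = ax.imshow(M.T, origin="lower", aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax,
                   extent=[-(nt - 1) * bin_duration * 1e3, 0.0,
                           band[0] / 1e3, band[1] / 1e3])
    ax.set_xlabel("time before bin (ms)")
    ax.set_ylabel("frequency (kHz)")
    kind = getattr(feature, "kind", None)
    if kind:
        eig = getattr(feature, "eigenvalue", None)
        title = f"{kind} feature"
        if eig is not None:
            title += f" ({getattr(feature, 'sign_class', '')}, "
            title += f"eigenvalue {eig:.3g})"
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_modulation_spectrum(ms, ax=None):
    """Render a modulation power spectrum (cycles/s vs cycles/kHz)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(ms.power.T, origin="lower", aspect="auto", cmap="viridis",
                   extent=[ms.temporal_freqs[0], ms.temporal_freqs[-1],
                           ms.spectral_freqs[0], ms.spectral_freqs[-1]])
    ax.set_xlabel("temporal modulation (cycles/s)")
    ax.set_ylabel("spectral modulation (cycles/kHz)")
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_raster(raster, bin_duration: float = 8.192e-3, ax=None):
    """Event raster: one row per trial, ticks at event bins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    trials, bins = np.nonzero(raster.binary)
    ax.scatter(bins * bin_duration, trials, marker="|", s=12, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("trial")
    ax.set_ylim(-0.5, raster.n_trials - 0.5)
    if raster.unit_id:
        ax.set_title(raster.unit_id)
    return ax
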
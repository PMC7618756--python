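"""Synthetic stimuli, ground-truth encoding models, and event rasters.

Real inputs to this pipeline are an ultrasonic-vocalization playback
waveform and per-trial calcium event rasters; neither is publicly
deposited, so this module emulates both.  The synthetic stimulus mimics
the study design — vocalization-like segments of frequency-modulated
sweeps in the 45-110 kHz band, each padded by silence and preceded by a
long silent baseline — and rasters are Bernoulli samples from known
second-order logistic (MNE-form) ground-truth models, so recovery of
model parameters, features and population subspaces can be checked
against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .events import EventRaster
from .spectro import PcaReduction

__all__ = [
    "SyntheticStimulusSpec",
    "GroundTruthModel",
    "SyntheticDataset",
    "generate_usv_stimulus",
    "gabor_feature_map",
    "make_ground_truth",
    "simulate_event_raster",
    "generate_population",
]


@dataclass
class SyntheticStimulusSpec:
    """Layout of a synthetic vocalization playback stimulus.

    Default geometry: segments of 8 s of vocalization with 1 s of silence
    on each side, concatenated after a 20 s leading silence; total
    duration = lead_silence + n_segments * (segment_duration +
    2 * pad_silence).
    """

    n_segments: int = 15
    segment_duration: float = 8.0
    pad_silence: float = 1.0
    lead_silence: float = 20.0
    sample_rate: float = 250_000.0
    band: tuple[float, float] = (45_000.0, 110_000.0)
    seed: int = 0

    @property
    def total_duration(self) -> float:
        return self.lead_silence + self.n_segments * (
            self.segment_duration + 2 * self.pad_silence
        )


@dataclass
class GroundTruthModel:
    """Generative second-order logistic model: P(event|s) =
    1/(1 + exp(a + s.h + s'Js)) in reduced stimulus coordinates."""

    a: float
    h: np.ndarray
    J: np.ndarray
    feature_maps: list[np.ndarray] = field(default_factory=list)
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")

    @property
    def base_rate(self) -> float:
        """Event probability for a zero (mean) stimulus."""
        return float(expit(-self.a))


@dataclass
class SyntheticDataset:
    """A two-population synthetic experiment with known feature subspaces."""

    rasters: list[EventRaster]
    truth: list[GroundTruthModel]
    population_labels: list[str]
    shared_subspace_dim: int
    private_subspace_dims: tuple[int, int]
    true_maps_a: np.ndarray  # (patch_dim, dim_a) orthonormal columns
    true_maps_b: np.ndarray  # (patch_dim, dim_b)
    X: np.ndarray | None = None
    time_index: np.ndarray | None = None


# ---------------------------------------------------------------------------
# stimulus synthesis


def _fm_sweep(rng: np.random.Generator, sample_rate: float,
              band: tuple[float, float]) -> np.ndarray:
    """One frequency-modulated tone sweep confined to the band.

    Duration 30-150 ms, frequency extent up to 30 kHz, linear or
    sinusoidal FM, Hann amplitude envelope.
    """
    f_lo, f_hi = band
    dur = rng.uniform(0.030, 0.150)
    n = max(int(round(dur * sample_rate)), 8)
    extent = rng.uniform(3_000.0, 30_000.0) * rng.choice([-1.0, 1.0])
    f0 = rng.uniform(f_lo, f_hi)
    f1 = np.clip(f0 + extent, f_lo, f_hi)
    t = np.arange(n) / sample_rate
    if rng.random() < 0.5:
        inst_f = f0 + (f1 - f0) * t / dur  # linear chirp
    else:
        inst_f = 0.5 * (f0 + f1) + 0.5 * (f1 - f0) * np.sin(
            2 * np.pi * rng.uniform(2.0, 8.0) * t
        )
    phase = 2 * np.pi * np.cumsum(inst_f) / sample_rate
    envelope = np.hanning(n)
    return envelope * np.sin(phase + rng.uniform(0, 2 * np.pi))


def generate_usv_stimulus(spec: SyntheticStimulusSpec) -> np.ndarray:
    """Synthesize a vocalization-like playback waveform.

    Each segment holds 2-6 FM sweeps per second at random times,
    amplitude-normalized so every segment has the same RMS over its
    non-silent samples; silences are exact zeros.  Fully deterministic
    under ``spec.seed``.
    """
    if spec.n_segments < 1:
        raise ValueError("need at least one segment")
    nyquist = spec.sample_rate / 2.0
    if spec.band[1] > nyquist or spec.band[0] <= 0 or spec.band[0] >= spec.band[1]:
        raise ValueError(
            f"band {spec.band} must satisfy 0 < f_lo < f_hi <= Nyquist "
            f"({nyquist:.0f} Hz)"
        )
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    seg_n = int(round(spec.segment_duration * fs))
    pad_n = int(round(spec.pad_silence * fs))
    lead_n = int(round(spec.lead_silence * fs))
    pieces = [np.zeros(lead_n)]
    target_rms = 0.1
    for _ in range(spec.n_segments):
        seg = np.zeros(seg_n)
        n_seconds = int(np.ceil(spec.segment_duration))
        for sec in range(n_seconds):
            for _ in range(int(rng.integers(2, 7))):
                sweep = _fm_sweep(rng, fs, spec.band)
                start = int(rng.uniform(sec, min(sec + 1, spec.segment_duration))
                            * fs)
                stop = min(start + len(sweep), seg_n)
                seg[start:stop] += sweep[: stop - start]
        active = np.abs(seg) > 0
        if active.any():
            seg *= target_rms / np.sqrt(np.mean(seg[active] ** 2))
        pieces += [np.zeros(pad_n), seg, np.zeros(pad_n)]
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# ground-truth models


def gabor_feature_map(rng: np.random.Generator, n_time: int = 28,
                      n_freq: int = 28) -> np.ndarray:
    """A localized Gabor-like time-frequency blob, unit Frobenius norm.

    Gaussian envelope at a random center times a ripple with random
    temporal/spectral modulation — the qualitative shape of recovered
    spectrotemporal receptive-field features.
    """
    t = np.arange(n_time)[:, None]
    f = np.arange(n_freq)[None, :]
    t0 = rng.uniform(0.2 * n_time, 0.8 * n_time)
    f0 = rng.uniform(0.2 * n_freq, 0.8 * n_freq)
    st = rng.uniform(1.5, 4.0)
    sf = rng.uniform(1.5, 4.0)
    wt = rng.uniform(0.0, 0.25)
    wf = rng.uniform(0.0, 0.25)
    phi = rng.uniform(0, 2 * np.pi)
    g = np.exp(-0.5 * (((t - t0) / st) ** 2 + ((f - f0) / sf) ** 2)) * np.cos(
        2 * np.pi * (wt * t + wf * f) + phi
    )
    return g / np.linalg.norm(g)


def make_ground_truth(
    pca: PcaReduction,
    feature_maps: list[np.ndarray],
    eigenvalues: list[float] | np.ndarray,
    a: float,
    linear_map: np.ndarray | None = None,
) -> GroundTruthModel:
    """Assemble a generative model from spectrotemporal feature templates.

    Each map is projected into the reduced stimulus coordinates, the
    projections are re-orthonormalized (Gram-Schmidt via QR), and
    ``J = sum_i lambda_i v_i v_i'``.  ``h`` is the projection of
    ``linear_map`` (zero when absent).  Positive eigenvalues make the
    corresponding feature suppressive (it increases the exponent),
    negative ones facilitating.
    """
    lam = np.asarray(eigenvalues, float)
    if not np.isfinite(lam).all():
        raise ValueError("eigenvalues must be finite")
    if len(feature_maps) != len(lam):
        raise ValueError("one eigenvalue per feature map required")
    K = pca.n_components
    if feature_maps:
        P = np.stack([pca.basis.T @ np.ravel(m) for m in feature_maps], axis=1)
        Q, _ = np.linalg.qr(P)
        V = Q[:, : P.shape[1]]
        J = (V * lam) @ V.T
    else:
        J = np.zeros((K, K))
    h = (pca.basis.T @ np.ravel(linear_map)
         if linear_map is not None else np.zeros(K))
    return GroundTruthModel(a=float(a), h=h, J=0.5 * (J + J.T),
                            feature_maps=[np.asarray(m) for m in feature_maps],
                            eigenvalues=lam)


def simulate_event_raster(
    model: GroundTruthModel,
    X: np.ndarray,
    n_trials: int,
    seed: int,
    time_index: np.ndarray | None = None,
    n_bins: int | None = None,
    unit_id: str = "",
    population: str = "synthetic",
) -> EventRaster:
    """Bernoulli event raster sampled from a ground-truth model.

    ``X`` holds reduced stimulus patches (one row per patch, same
    coordinates as the model).  Each trial draws independent Bernoulli
    events per bin with p = P(event|s).  When ``time_index``/``n_bins``
    are given the raster is embedded in the full spectrogram timeline
    (bins without a stimulus patch stay 0), matching the layout expected
    by :func:`astrorf.events.align`.
    """
    from .mne import predict  # deferred to avoid an import cycle

    p = predict(model, X)
    rng = np.random.default_rng(seed)
    draws = (rng.random((n_trials, len(p))) < p).astype(np.int8)
    if time_index is not None:
        T = int(n_bins) if n_bins is not None else int(np.max(time_index)) + 1
        full = np.zeros((n_trials, T), dtype=np.int8)
        full[:, np.asarray(time_index, int)] = draws
        draws = full
    return EventRaster(binary=draws, unit_id=unit_id, population=population)


def generate_population(
    pca: PcaReduction,
    X: np.ndarray,
    dim_a: int = 3,
    dim_b: int = 3,
    shared_dim: int = 1,
    n_units_a: int = 3,
    n_units_b: int = 3,
    n_trials: int = 20,
    base_rate: float = 0.15,
    strength: float = 4.0,
    seed: int = 0,
    time_index: np.ndarray | None = None,
    n_bins: int | None = None,
) -> SyntheticDataset:
    """Two synthetic unit populations with controlled subspace overlap.

    Builds ``dim_a + dim_b - shared_dim`` jointly orthonormal feature
    directions (Gabor templates, Gram-Schmidt-orthonormalized in the
    reduced stimulus space): population A spans the first ``dim_a``,
    population B reuses the first ``shared_dim`` of A's plus its own
    private directions, so the true principal angles between the two
    feature subspaces are exactly ``shared_dim`` zeros and the rest 90
    degrees.  Each unit is a single-quadratic-feature model (suppressive,
    eigenvalue scaled by ``strength`` relative to the stimulus energy
    along its direction) cycling through its population's directions;
    rasters are Bernoulli samples of those models on ``X``.
    """
    if shared_dim > min(dim_a, dim_b):
        raise ValueError("shared_dim cannot exceed either population dimension")
    d_total = dim_a + dim_b - shared_dim
    if d_total > pca.n_components:
        raise ValueError(
            f"requested {d_total} directions exceed the {pca.n_components}"
            "-dim reduced stimulus space"
        )
    rng = np.random.default_rng(seed)
    # oversample templates, orthonormalize jointly in reduced coordinates
    raw = np.stack(
        [pca.basis.T @ gabor_feature_map(rng).ravel() for _ in range(2 * d_total)],
        axis=1,
    )
    Q, _ = np.linalg.qr(raw)
    V = Q[:, :d_total]  # orthonormal in reduced coords
    idx_a = np.arange(dim_a)
    idx_b = np.r_[np.arange(shared_dim), dim_a + np.arange(dim_b - shared_dim)]
    a0 = float(np.log(1.0 / base_rate - 1.0))
    rasters, truth, labels = [], [], []
    for pop, idx, n_units in (("popA", idx_a, n_units_a),
                              ("popB", idx_b, n_units_b)):
        for u in range(n_units):
            v = V[:, idx[u % len(idx)]]
            lam = strength / float(np.mean((X @ v) ** 2))
            model = GroundTruthModel(
                a=a0, h=np.zeros(pca.n_components), J=lam * np.outer(v, v),
                feature_maps=[pca.lift_direction(v)], eigenvalues=np.array([lam]),
            )
            raster = simulate_event_raster(
                model, X, n_trials, seed=int(rng.integers(2**31)),
                time_index=time_index, n_bins=n_bins,
                unit_id=f"{pop}-{u}", population=pop,
            )
            rasters.append(raster)
            truth.append(model)
            labels.append(pop)
    lift = pca.basis  # orthonormal, so lifted directions stay orthonormal
    return SyntheticDataset(
        rasters=rasters, truth=truth, population_labels=labels,
        shared_subspace_dim=shared_dim,
        private_subspace_dims=(dim_a - shared_dim, dim_b - shared_dim),
        true_maps_a=lift @ V[:, idx_a], true_maps_b=lift @ V[:, idx_b],
        X=X, time_index=time_index,
    )
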
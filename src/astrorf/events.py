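"""Event rasters and stimulus-response alignment.

Per-trial calcium traces are reduced to binary event-onset rasters (onset =
first bin at which a fluorescence excursion reaches 10% of its peak), then
trial-averaged and paired with the reduced stimulus patch whose window ends
at the same time bin.  The aligned dataset carries the 70/30 train/test
split and the 3-fold cross-validation partition of the training block used
by the encoding-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectro import PcaReduction, StimulusPatchSet

__all__ = [
    "EventRaster",
    "AlignedDataset",
    "detect_onsets",
    "binarize_raster",
    "align",
]


@dataclass
class EventRaster:
    """Binary (n_trials x n_bins) event-onset matrix for one unit."""

    binary: np.ndarray
    unit_id: str = ""
    population: str = "synthetic"

    def __post_init__(self):
        b = np.asarray(self.binary)
        if b.ndim != 2:
            raise ValueError("raster must be 2-D (trials x bins)")
        if not np.isin(b, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.binary = b.astype(np.int8)

    @property
    def n_trials(self) -> int:
        return self.binary.shape[0]

    @property
    def n_bins(self) -> int:
        return self.binary.shape[1]

    def trial_average(self) -> np.ndarray:
        """Per-bin mean event indicator across trials, in [0, 1]."""
        return self.binary.mean(axis=0)


@dataclass
class AlignedDataset:
    """Reduced stimulus patches paired with trial-averaged responses.

    ``X[i]`` is the PCA-reduced patch whose window ends at spectrogram bin
    ``time_index[i]``; ``y[i]`` is the trial-averaged response at that bin.
    ``train_mask``/``test_mask`` are a contiguous 70/30 temporal split of
    the rows; ``folds`` partitions the training rows into contiguous
    cross-validation folds.
    """

    X: np.ndarray
    y: np.ndarray
    time_index: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray
    folds: list[np.ndarray]
    unit_id: str = ""
    population: str = "synthetic"

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def detect_onsets(trace: np.ndarray, threshold_fraction: float = 0.10,
                  baseline: float = 0.0) -> np.ndarray:
    """Find event-onset bins in a continuous per-trial signal.

    The trace is segmented into excursions (contiguous runs strictly above
    ``baseline``); within each excursion the onset is the first bin at
    which the signal reaches ``threshold_fraction`` times the excursion
    peak.  Returns sorted unique bin indices; an all-baseline trace yields
    an empty result.
    """
    trace = np.asarray(trace, float)
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite values")
    above = trace > baseline
    if not above.any():
        return np.empty(0, dtype=int)
    # excursion boundaries
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = np.r_[0 if above[0] else [], edges[~above[edges]] + 1].astype(int)
    ends = np.r_[edges[above[edges]], len(trace) - 1 if above[-1] else []].astype(int)
    onsets = []
    for s, e in zip(starts, ends):
        seg = trace[s : e + 1]
        peak = seg.max()
        if peak <= baseline:
            continue
        onset = s + int(np.argmax(seg >= threshold_fraction * peak))
        onsets.append(onset)
    return np.unique(onsets)


def binarize_raster(onsets_per_trial: list[np.ndarray] | dict[int, np.ndarray],
                    n_bins: int, unit_id: str = "",
                    population: str = "synthetic") -> EventRaster:
    """Build a binary raster from per-trial onset bin lists.

    Duplicate onsets within a trial are idempotent (a single 1); onsets
    outside ``[0, n_bins)`` raise.
    """
    if isinstance(onsets_per_trial, dict):
        n_trials = (max(onsets_per_trial) + 1) if onsets_per_trial else 0
        rows = [np.asarray(onsets_per_trial.get(t, []), dtype=int)
                for t in range(n_trials)]
    else:
        rows = [np.asarray(r, dtype=int) for r in onsets_per_trial]
    binary = np.zeros((len(rows), n_bins), dtype=np.int8)
    for t, r in enumerate(rows):
        if r.size and (r.min() < 0 or r.max() >= n_bins):
            raise ValueError(f"trial {t}: onset bin outside [0, {n_bins})")
        binary[t, r] = 1
    return EventRaster(binary=binary, unit_id=unit_id, population=population)


def _contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """Split range(n) into contiguous folds; remainder goes to the earliest."""
    base, rem = divmod(n, n_folds)
    sizes = [base + (1 if i < rem else 0) for i in range(n_folds)]
    out, start = [], 0
    for sz in sizes:
        out.append(np.arange(start, start + sz))
        start += sz
    return out


def align(
    raster: EventRaster,
    patches: StimulusPatchSet,
    pca: PcaReduction,
    train_fraction: float = 0.70,
    n_folds: int = 3,
    seed: int | None = None,
    shuffle_blocks: bool = False,
) -> AlignedDataset:
    """Pair reduced stimulus patches with trial-averaged responses.

    The raster must have one column per spectrogram time bin; only bins
    with a full stimulus history (those having a patch) enter the dataset.
    The split is a contiguous 70/30 temporal block split — overlapping
    patch windows would leak stimulus history across a random row split —
    with the training block partitioned into ``n_folds`` contiguous folds
    (remainder bins assigned to the earliest folds).  With
    ``shuffle_blocks`` the order of train/test blocks is randomized at the
    block level under ``seed``.
    """
    T_expected = patches.time_index[-1] + 1
    if raster.n_bins != T_expected:
        raise ValueError(
            f"raster has {raster.n_bins} bins but spectrogram has "
            f"{T_expected} time bins"
        )
    y_full = raster.trial_average()
    y = y_full[patches.time_index]
    X = pca.project(patches.patches)
    n = len(y)
    n_train = int(round(train_fraction * n))
    order = np.arange(n)
    if shuffle_blocks:
        rng = np.random.default_rng(seed)
        # swap the two contiguous blocks or keep order, at random
        if rng.random() < 0.5:
            order = np.r_[np.arange(n_train, n), np.arange(n_train)]
    train_idx = order[:n_train]
    test_idx = order[n_train:]
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True
    test_mask = ~train_mask
    folds = [train_idx[f] for f in _contiguous_folds(n_train, n_folds)]
    return AlignedDataset(
        X=X,
        y=np.asarray(y, float),
        time_index=np.asarray(patches.time_index),
        train_mask=train_mask,
        test_mask=test_mask,
        folds=folds,
        unit_id=raster.unit_id,
        population=raster.population,
    )
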
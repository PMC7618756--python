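"""File I/O: WAV waveforms, an HDF5 run container, delimited-text exports.

Container layout (one HDF5 file per run):

    /config_yaml            attrs: yaml text, config hash, seed
    /stimulus/waveform      float32 waveform (optional)
    /spectrogram/{power,freq_centers}  attrs: bin_duration
    /pca/{mean,basis,explained_variance}  attrs: explained_variance_fraction
    /rasters/<unit_id>      int8 (trials x bins), attrs: population
    /models/<unit_id>/{h,J} attrs: a, cosine_similarity, p_value, significant
    /features/<unit_id>/<k> 28x28 maps, attrs: kind, eigenvalue, sign_class
    /angles/<pair>          degrees

Every table is additionally exportable as delimited text for
inspectability and diffing.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .events import EventRaster

__all__ = [
    "write_wav",
    "read_wav",
    "save_raster_text",
    "load_raster_text",
    "save_matrix_text",
    "RunContainer",
]


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a single-channel float32 WAV."""
    wavfile.write(path, int(sample_rate), np.asarray(waveform, np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV; integer PCM is rescaled to [-1, 1] floats."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def save_raster_text(path, raster: EventRaster) -> None:
    """Export a raster as `unit<TAB>trial<TAB>bin` rows (events only)."""
    with open(path, "w") as fh:
        fh.write("unit\ttrial\tbin\n")
        trials, bins = np.nonzero(raster.binary)
        for t, b in zip(trials, bins):
            fh.write(f"{raster.unit_id}\t{t}\t{b}\n")


def load_raster_text(path, n_trials: int, n_bins: int) -> list[EventRaster]:
    """Read one or more rasters from a `unit trial bin` delimited file."""
    per_unit: dict[str, dict[int, list[int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("unit"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            unit, trial, b = line.split()
            per_unit.setdefault(unit, {}).setdefault(int(trial), []).append(int(b))
    out = []
    for unit, trials in sorted(per_unit.items()):
        binary = np.zeros((n_trials, n_bins), dtype=np.int8)
        for t, bins in trials.items():
            binary[t, bins] = 1
        out.append(EventRaster(binary=binary, unit_id=unit))
    return out


def save_matrix_text(path, matrix: np.ndarray, fmt: str = "%.8g") -> None:
    np.savetxt(path, np.asarray(matrix), fmt=fmt, delimiter="\t")


class RunContainer:
    """Thin wrapper over an HDF5 file holding all artifacts of one run."""

    def __init__(self, path, mode: str = "r"):
        self.path = Path(path)
        self._f = h5py.File(self.path, mode)

    def close(self):
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- provenance ---------------------------------------------------------

    def stamp(self, config_yaml: str, seed: int) -> None:
        self._f.attrs["config_yaml"] = config_yaml
        self._f.attrs["config_hash"] = hashlib.sha256(
            config_yaml.encode()
        ).hexdigest()
        self._f.attrs["seed"] = int(seed)

    # -- writers ------------------------------------------------------------

    def save_array(self, key: str, arr: np.ndarray, **attrs) -> None:
        if key in self._f:
            del self._f[key]
        d = self._f.create_dataset(key, data=np.asarray(arr))
        for k, v in attrs.items():
            d.attrs[k] = v

    def save_raster(self, raster: EventRaster) -> None:
        self.save_array(f"rasters/{raster.unit_id}", raster.binary,
                        population=raster.population)

    def save_model(self, unit_id: str, results, evaluation=None) -> None:
        g = f"models/{unit_id}"
        self.save_array(f"{g}/h", results.h)
        self.save_array(f"{g}/J", results.J)
        grp = self._f[g]
        grp.attrs["a"] = results.a
        if evaluation is not None:
            grp.attrs["cosine_similarity"] = evaluation.cosine_similarity
            grp.attrs["p_value"] = evaluation.p_value
            grp.attrs["p_value_plus_one"] = evaluation.p_value_plus_one
            grp.attrs["significant"] = evaluation.significant
        else:
            grp.attrs["significance"] = "unavailable (no shuffles run)"

    def save_features(self, unit_id: str, features) -> None:
        for k, f in enumerate(features):
            self.save_array(
                f"features/{unit_id}/{k}", f.map, kind=f.kind,
                eigenvalue=np.nan if f.eigenvalue is None else f.eigenvalue,
                sign_class=f.sign_class, significant=f.significant,
            )

    # -- readers ------------------------------------------------------------

    def load_array(self, key: str) -> np.ndarray:
        return np.asarray(self._f[key])

    def load_raster(self, unit_id: str) -> EventRaster:
        d = self._f[f"rasters/{unit_id}"]
        return EventRaster(binary=np.asarray(d), unit_id=unit_id,
                           population=d.attrs.get("population", "synthetic"))

    def unit_ids(self, group: str = "rasters") -> list[str]:
        return sorted(self._f[group].keys()) if group in self._f else []
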
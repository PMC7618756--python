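"""Principal angles between receptive-field feature subspaces.

Two populations' significant features (columns of a features-by-maps
matrix in the flattened time-frequency space) span linear subspaces; the
principal angles between those subspaces quantify their overlap dimension
by dimension.  An angle of 0 deg marks a shared direction, 90 deg an
orthogonal one.  Orthonormal bases come from rank-revealing QR; cosines of
the angles are the singular values of Q_a' Q_b, which is equivalent to the
recursive maximization definition (cos th_k = max over unit vectors
orthogonal to the previous maximizers) but numerically standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .spectro import PcaReduction

__all__ = [
    "FeatureSubspace",
    "PrincipalAngleResult",
    "orthonormal_basis",
    "principal_angles",
    "compare_populations",
]


@dataclass
class FeatureSubspace:
    """Orthonormal basis for the span of a set of feature vectors."""

    features: np.ndarray  # (ambient_dim, m) original columns
    basis: np.ndarray  # (ambient_dim, r) orthonormal
    label: str = ""

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    @property
    def ambient_dim(self) -> int:
        return self.basis.shape[0]


@dataclass
class PrincipalAngleResult:
    """Ascending principal angles (degrees) between two subspaces."""

    angles_deg: np.ndarray
    pair: tuple[str, str]

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, float)


def orthonormal_basis(features: np.ndarray, label: str = "",
                      rtol: float = 1e-10) -> FeatureSubspace:
    """Rank-revealing orthonormalization of feature columns via pivoted QR.

    Columns that are numerically dependent on earlier ones (diagonal of R
    below ``rtol`` relative to its largest entry) are dropped; the basis
    rank is the numerical rank of the feature matrix.
    """
    F = np.atleast_2d(np.asarray(features, float))
    if F.ndim != 2:
        raise ValueError("features must be a 2-D matrix (ambient_dim x m)")
    if not np.any(F):
        raise ValueError("all-zero feature matrix has no span")
    Q, R, _ = linalg.qr(F, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    r = int(np.sum(diag > rtol * diag[0]))
    return FeatureSubspace(features=F, basis=Q[:, :r], label=label)


def principal_angles(A: FeatureSubspace, B: FeatureSubspace
                     ) -> PrincipalAngleResult:
    """Principal angles between two subspaces, degrees, ascending.

    Computed as arccos of the singular values of ``Q_a' Q_b`` clipped to
    [0, 1]; returns ``min(rank_a, rank_b)`` angles in [0, 90].
    """
    if A.ambient_dim != B.ambient_dim:
        raise ValueError(
            f"ambient dimensions differ: {A.ambient_dim} vs {B.ambient_dim}"
        )
    if A.rank == 0 or B.rank == 0:
        raise ValueError("empty subspace")
    s = np.linalg.svd(A.basis.T @ B.basis, compute_uv=False)
    cosines = np.clip(s, 0.0, 1.0)
    angles = np.degrees(np.arccos(cosines))
    return PrincipalAngleResult(angles_deg=np.sort(angles),
                                pair=(A.label, B.label))


def compare_populations(
    astro_features: np.ndarray,
    neuro_features: np.ndarray,
    stimulus_basis: PcaReduction | np.ndarray | None = None,
    labels: tuple[str, str] = ("astro", "neuro"),
) -> dict[str, PrincipalAngleResult]:
    """Principal angles between two populations' feature sets and, when a
    stimulus basis is given, between each population and the retained
    stimulus subspace.

    ``stimulus_basis`` may be a fitted :class:`PcaReduction` (its
    back-projected component basis is used as the "full stimulus space")
    or an explicit (ambient_dim x r) matrix.  Feature matrices are
    (ambient_dim x m) with one column per significant feature, pooled per
    population.  A population with no features skips its comparisons with
    a warning.
    """
    subspaces: dict[str, FeatureSubspace] = {}
    for lab, F in zip(labels, (astro_features, neuro_features)):
        F = np.atleast_2d(np.asarray(F, float))
        if F.size == 0 or not np.any(F):
            warnings.warn(f"population {lab!r} has no features; "
                          "its comparisons are skipped")
            continue
        subspaces[lab] = orthonormal_basis(F, label=lab)
    out: dict[str, PrincipalAngleResult] = {}
    la, lb = labels
    if la in subspaces and lb in subspaces:
        out[f"{la}-{lb}"] = principal_angles(subspaces[la], subspaces[lb])
    if stimulus_basis is not None:
        S = (stimulus_basis.basis if isinstance(stimulus_basis, PcaReduction)
             else np.asarray(stimulus_basis, float))
        stim = orthonormal_basis(S, label="stimulus")
        for lab in labels:
            if lab in subspaces:
                out[f"{lab}-stimulus"] = principal_angles(subspaces[lab], stim)
    return out
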
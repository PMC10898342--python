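"""Covariance-based (Gaussian-model) mutual-information estimators.

Under a zero-mean multivariate Gaussian model of the stacked pair fluctuation
vector dR = (dR_i, dR_j), mutual information reduces to a log-determinant
ratio of the 6x6 time-averaged covariance <dR dR^T>:

    I = -1/2 ln[ det<dR dR^T> / (det<dR_i dR_i^T> det<dR_j dR_j^T>) ]

(the linearized MI of Lange & Grubmueller).  Discarding the off-diagonal
(orthogonal-axis) correlations leaves only scalar dot products and yields the
isotropic Gaussian form

    I = -1/2 ln[ 1 - <dR_i . dR_j>^2 / (<dR_i^2> <dR_j^2>) ].

Log-determinants go through symmetric eigendecomposition, never raw
determinant ratios; a block whose smallest eigenvalue falls below 1e-10 of
its largest is flagged degenerate instead of producing +/-inf, so full maps
stay writable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dyncorr.exact_estimators import MIValue
from dyncorr.trajectory_io import FluctuationTrajectory

__all__ = [
    "PairCovariance",
    "ScalarCorrelation",
    "MIMatrix",
    "pair_covariance",
    "scalar_correlation",
    "multivariate_gaussian_mi",
    "isotropic_gaussian_mi",
    "gaussian_mi_map",
]

_SINGULAR_RTOL = 1e-10


@dataclass
class PairCovariance:
    """Time-averaged 6x6 second-moment matrix <dR dR^T> for one residue pair."""

    block: np.ndarray  # (6, 6), Angstrom^2
    n_frames: int
    pair: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=float)
        if self.block.shape != (6, 6):
            raise ValueError("pair covariance block must be 6x6")
        if not np.allclose(self.block, self.block.T, atol=1e-10):
            raise ValueError("pair covariance block must be symmetric")

    @property
    def diag_i(self) -> np.ndarray:
        return self.block[:3, :3]

    @property
    def diag_j(self) -> np.ndarray:
        return self.block[3:, 3:]


@dataclass
class ScalarCorrelation:
    """Scalar dot-product correlations for the isotropic Gaussian form."""

    cross: float  # <dR_i . dR_j>
    auto_i: float  # <dR_i^2>
    auto_j: float  # <dR_j^2>
    pair: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.auto_i <= 0 or self.auto_j <= 0:
            raise ValueError("autocorrelations must be positive")


@dataclass
class MIMatrix:
    """Symmetric per-pair MI map; the diagonal (self-MI) is a NaN sentinel."""

    values: np.ndarray  # (N, N), nats; NaN on diagonal
    estimator_tag: str
    residue_labels: list[str]
    degenerate: np.ndarray | None = None  # (N, N) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape, dtype=bool)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def pair_covariance(fluct: FluctuationTrajectory, i: int, j: int) -> PairCovariance:
    """<dR dR^T> for the stacked 6-vector of residues i and j.

    Normalized by n_frames (not n-1); MI is invariant to this choice since it
    cancels in every determinant ratio.
    """
    if fluct.n_frames < 7:
        raise ValueError(
            f"n_frames={fluct.n_frames} < 7: the 6x6 covariance would be "
            "rank-deficient by construction"
        )
    vecs = fluct.pair_vectors(i, j)
    block = vecs.T @ vecs / fluct.n_frames
    block = 0.5 * (block + block.T)  # enforce exact symmetry
    return PairCovariance(block, fluct.n_frames, (i, j))


def scalar_correlation(fluct: FluctuationTrajectory, i: int, j: int) -> ScalarCorrelation:
    """Time-averaged dot products <dR_i . dR_j>, <dR_i^2>, <dR_j^2>."""
    di = fluct.deltas[:, i, :]
    dj = fluct.deltas[:, j, :]
    cross = float(np.mean(np.sum(di * dj, axis=1)))
    auto_i = float(np.mean(np.sum(di * di, axis=1)))
    auto_j = float(np.mean(np.sum(dj * dj, axis=1)))
    return ScalarCorrelation(cross, auto_i, auto_j, (i, j))


def _logdet_psd(matrix: np.ndarray) -> tuple[float, float]:
    """(log-determinant, smallest eigenvalue) of a symmetric PSD matrix."""
    eigvals = np.linalg.eigvalsh(matrix)
    return float(np.sum(np.log(np.clip(eigvals, np.finfo(float).tiny, None)))), float(eigvals[0])


def multivariate_gaussian_mi(cov: PairCovariance) -> MIValue:
    """Linearized (multivariate Gaussian) MI from a 6x6 pair covariance.

    Non-negative by Fischer's inequality for positive semidefinite matrices.
    A singular joint block with nonsingular 3x3 diagonal blocks means the
    Gaussian MI diverges; the result is flagged degenerate rather than +inf.
    """
    eig_i = np.linalg.eigvalsh(cov.diag_i)
    eig_j = np.linalg.eigvalsh(cov.diag_j)
    for name, eig in (("i", eig_i), ("j", eig_j)):
        if eig[0] < _SINGULAR_RTOL * max(eig[-1], np.finfo(float).tiny):
            return MIValue(
                np.nan, "gauss_multi", cov.pair, degenerate=True,
                note=f"marginal block {name} singular (min eigenvalue {eig[0]:.3e})",
            )
    logdet_joint, min_eig = _logdet_psd(cov.block)
    eig_joint = np.linalg.eigvalsh(cov.block)
    if eig_joint[0] < _SINGULAR_RTOL * eig_joint[-1]:
        return MIValue(
            np.nan, "gauss_multi", cov.pair, degenerate=True,
            note=f"joint block singular (min eigenvalue {min_eig:.3e}); MI diverges",
        )
    logdet_i = float(np.sum(np.log(eig_i)))
    logdet_j = float(np.sum(np.log(eig_j)))
    value = -0.5 * (logdet_joint - logdet_i - logdet_j)
    return MIValue(max(value, 0.0) if value > -1e-10 else value, "gauss_multi", cov.pair)


def isotropic_gaussian_mi(corr: ScalarCorrelation) -> MIValue:
    """Isotropic (zero off-diagonal) Gaussian MI from scalar correlations."""
    ratio = corr.cross**2 / (corr.auto_i * corr.auto_j)
    if ratio >= 1.0:
        return MIValue(
            np.nan, "gauss_iso", corr.pair, degenerate=True,
            note="perfect correlation: MI diverges",
        )
    value = -0.5 * np.log1p(-ratio)
    return MIValue(float(value), "gauss_iso", corr.pair)


def gaussian_mi_map(fluct: FluctuationTrajectory, method: str = "gauss_multi") -> MIMatrix:
    """Full symmetric N x N Gaussian MI map.

    Per-pair degeneracies become flags; the map never aborts.  The diagonal is
    NaN (self-MI is unbounded).
    """
    if method not in ("gauss_multi", "gauss_iso"):
        raise ValueError(f"unknown Gaussian method {method!r}")
    n = fluct.n_residues
    values = np.full((n, n), np.nan)
    degenerate = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if method == "gauss_multi":
                mi = multivariate_gaussian_mi(pair_covariance(fluct, i, j))
            else:
                mi = isotropic_gaussian_mi(scalar_correlation(fluct, i, j))
            values[i, j] = values[j, i] = mi.value
            degenerate[i, j] = degenerate[j, i] = mi.degenerate
    return MIMatrix(values, method, list(fluct.residue_labels), degenerate)
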
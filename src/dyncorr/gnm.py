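"""Gaussian Network Model: Kirchhoff matrix, mode decomposition, and MI maps.

The GNM coarse-grains a protein to its C-alpha trace and connects every pair
of residues within a cutoff distance r_c by identical springs.  The Kirchhoff
(connectivity) matrix

    Gamma_ij = -1           if i != j and R_ij <= r_c
    Gamma_ij =  0           if i != j and R_ij >  r_c
    Gamma_ii = -sum_{k!=i} Gamma_ik

is symmetric positive semidefinite with one zero mode (for a connected
contact graph).  Residue cross-correlations are, up to the common prefactor
3 k_B T / gamma, entries of the pseudoinverse:

    <dR_i . dR_j> = sum_{m} lambda_m^{-1} u_m u_m^T   (nonzero modes m)

restricted to any mode subset; "1-all" (all N-1 nonzero modes, mode 1 being
the slowest) reproduces the Moore-Penrose pseudoinverse, while "2-all",
"3-all", ... progressively drop the slowest, largest-scale motions.  Mutual
information follows by feeding these correlations into the isotropic
Gaussian form; the physical prefactor cancels in the ratio, so MI needs no
temperature or force constant.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from dyncorr.gaussian_estimators import MIMatrix
from dyncorr.trajectory_io import StructureModel, load_structure

__all__ = [
    "KirchhoffSystem",
    "GNMCorrelation",
    "build_kirchhoff",
    "gnm_cross_correlation",
    "gnm_mi",
    "gnm_mi_from_structure",
    "parse_mode_subset",
]

_ZERO_MODE_RTOL = 1e-8


@dataclass
class KirchhoffSystem:
    """Connectivity matrix with its eigendecomposition attached."""

    gamma: np.ndarray  # (N, N)
    cutoff_rc: float  # Angstrom
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # orthonormal columns, same order
    residue_labels: list[str]

    @property
    def n_residues(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_nonzero_modes(self) -> int:
        return self.n_residues - 1


@dataclass
class GNMCorrelation:
    """Mode-restricted cross-correlation matrix, in arbitrary units.

    Entries are <dR_i . dR_j> up to the common 3 k_B T / gamma prefactor,
    which cancels in every MI ratio.
    """

    cross: np.ndarray  # (N, N)
    mode_subset: str
    residue_labels: list[str]


def build_kirchhoff(structure: StructureModel, rc: float) -> KirchhoffSystem:
    """Contact-topology Kirchhoff matrix at cutoff ``rc`` (Angstrom).

    Errors out if the contact graph is disconnected (two or more near-zero
    eigenvalues) — a larger cutoff is then needed.
    """
    if rc <= 0:
        raise ValueError("cutoff rc must be positive")
    coords = structure.ca_coords
    n = coords.shape[0]
    dist = squareform(pdist(coords))
    gamma = -(dist <= rc).astype(float)
    np.fill_diagonal(gamma, 0.0)
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    eigenvalues, eigenvectors = np.linalg.eigh(gamma)
    n_zero = int(np.sum(eigenvalues < _ZERO_MODE_RTOL * max(eigenvalues[-1], 1.0)))
    if n_zero > 1:
        raise ValueError(
            f"contact graph disconnected at rc={rc} A ({n_zero} zero modes); "
            "increase the cutoff"
        )
    return KirchhoffSystem(gamma, rc, eigenvalues, eigenvectors, list(structure.residue_labels))


def parse_mode_subset(mode_subset: str | list[int], n_nonzero: int) -> list[int]:
    """Resolve a mode-subset descriptor to 1-based nonzero-mode indices.

    ``"k-all"`` means modes k through N-1 (mode 1 = slowest nonzero mode);
    an explicit list is validated and sorted.  Mode 0 (the rigid-body zero
    mode) may never be requested.
    """
    if isinstance(mode_subset, str):
        base, _, tail = mode_subset.partition("-")
        if tail != "all":
            raise ValueError(f"unrecognized mode subset {mode_subset!r}; expected 'k-all' or a list")
        k = int(base)
        if k < 1:
            raise ValueError("the zero mode cannot be requested; subsets start at mode 1")
        if k > n_nonzero:
            raise ValueError(f"subset {mode_subset!r} empty: only {n_nonzero} nonzero modes exist")
        return list(range(k, n_nonzero + 1))
    modes = sorted(set(int(m) for m in mode_subset))
    if not modes:
        raise ValueError("mode subset is empty")
    if modes[0] < 1:
        raise ValueError("the zero mode cannot be requested; nonzero modes are 1-based")
    if modes[-1] > n_nonzero:
        raise ValueError(f"mode {modes[-1]} out of range (only {n_nonzero} nonzero modes)")
    return modes


def gnm_cross_correlation(
    system: KirchhoffSystem, mode_subset: str | list[int] = "1-all"
) -> GNMCorrelation:
    """Spectral sum of lambda_m^{-1} u_m u_m^T over the requested nonzero modes.

    With subset "1-all" this is the Moore-Penrose pseudoinverse of Gamma.
    """
    modes = parse_mode_subset(mode_subset, system.n_nonzero_modes)
    # eigenvalues ascending: index 0 is the zero mode; nonzero mode m -> column m
    cols = [m for m in modes]
    u = system.eigenvectors[:, cols]
    inv_lam = 1.0 / system.eigenvalues[cols]
    cross = (u * inv_lam) @ u.T
    cross = 0.5 * (cross + cross.T)
    tag = mode_subset if isinstance(mode_subset, str) else ",".join(str(m) for m in modes)
    return GNMCorrelation(cross, tag, list(system.residue_labels))


def gnm_mi(corr: GNMCorrelation) -> MIMatrix:
    """MI map from GNM correlations via the isotropic Gaussian form.

    I_ij = -1/2 ln[1 - cross_ij^2 / (cross_ii cross_jj)]; the physical
    prefactor cancels.  Pairs with |normalized correlation| >= 1 are flagged
    degenerate; the diagonal is the usual NaN sentinel.
    """
    cross = corr.cross
    diag = np.diag(cross)
    if np.any(diag <= 0):
        raise ValueError("cross-correlation diagonal must be positive for MI")
    n = cross.shape[0]
    ratio = cross**2 / np.outer(diag, diag)
    values = np.full((n, n), np.nan)
    degenerate = np.zeros((n, n), dtype=bool)
    off = ~np.eye(n, dtype=bool)
    ok = off & (ratio < 1.0)
    values[ok] = -0.5 * np.log1p(-ratio[ok])
    degenerate[off & ~ok] = True
    return MIMatrix(values, f"gnm_{corr.mode_subset}", list(corr.residue_labels), degenerate)


def gnm_mi_from_structure(
    source: str | os.PathLike | StructureModel,
    rc: float,
    mode_subset: str | list[int] = "1-all",
) -> MIMatrix:
    """One-call pipeline: structure -> Kirchhoff -> correlations -> MI map."""
    structure = source if isinstance(source, StructureModel) else load_structure(source)
    system = build_kirchhoff(structure, rc)
    return gnm_mi(gnm_cross_correlation(system, mode_subset))
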
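"""Synthetic structures and trajectories with known statistical ground truth.

Every estimator in this package is validated against data whose true
mutual information is known in closed form: i.i.d. frames drawn from a
prescribed 3N x 3N Gaussian covariance (for which Gaussian MI is exact and
the histogram estimators must converge to it), toy structures with analytic
contact topology for the GNM, and a deliberately non-Gaussian multi-well
fixture on which linear (covariance-based) MI vanishes while the full joint
distribution carries ~ln 2 nats — the regime where the exact histogram
estimator and the Gaussian approximations genuinely disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dyncorr.exact_estimators import MIValue
from dyncorr.gaussian_estimators import MIMatrix, PairCovariance, multivariate_gaussian_mi
from dyncorr.gnm import GNMCorrelation, KirchhoffSystem, gnm_cross_correlation
from dyncorr.trajectory_io import FluctuationTrajectory, StructureModel

__all__ = [
    "GroundTruthSpec",
    "make_toy_structure",
    "sample_gaussian_trajectory",
    "analytic_gaussian_mi",
    "analytic_mi_profile",
    "make_nongaussian_trajectory",
    "make_single_rho_spec",
    "make_random_spec",
    "gnm_embedded_spec",
]


@dataclass
class GroundTruthSpec:
    """A target 3N x 3N covariance (Angstrom^2) plus the RNG seed."""

    covariance: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        dim = self.covariance.shape[0]
        if self.covariance.ndim != 2 or self.covariance.shape[1] != dim or dim % 3:
            raise ValueError("covariance must be square with dimension divisible by 3")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def n_residues(self) -> int:
        return self.covariance.shape[0] // 3

    def pair_block(self, i: int, j: int) -> np.ndarray:
        """The 6x6 covariance of the stacked (dR_i, dR_j) vector."""
        sl_i = slice(3 * i, 3 * i + 3)
        sl_j = slice(3 * j, 3 * j + 3)
        block = np.empty((6, 6))
        block[:3, :3] = self.covariance[sl_i, sl_i]
        block[:3, 3:] = self.covariance[sl_i, sl_j]
        block[3:, :3] = self.covariance[sl_j, sl_i]
        block[3:, 3:] = self.covariance[sl_j, sl_j]
        return block


# ---------------------------------------------------------------------------
# structures


def make_toy_structure(kind: str, n_residues: int) -> StructureModel:
    """Deterministic toy C-alpha geometries for GNM tests.

    ``"chain"``: collinear beads at 3.8 A spacing.  ``"helix"``: ideal
    alpha-helix (rise 1.5 A/residue, 100 degree twist, radius 2.3 A).
    ``"two-domain"``: two compact clusters joined by a 3-residue linker,
    giving the classic anti-correlated slowest mode.
    """
    if n_residues < 3:
        raise ValueError("toy structures need at least 3 residues")
    if kind == "chain":
        coords = np.zeros((n_residues, 3))
        coords[:, 0] = 3.8 * np.arange(n_residues)
    elif kind == "helix":
        turns = np.deg2rad(100.0) * np.arange(n_residues)
        coords = np.column_stack(
            [2.3 * np.cos(turns), 2.3 * np.sin(turns), 1.5 * np.arange(n_residues)]
        )
    elif kind == "two-domain":
        half = (n_residues - 3) // 2
        other = n_residues - 3 - half
        rng = np.random.default_rng(12345)  # fixed geometry, not a statistical source
        dom1 = rng.normal(scale=2.5, size=(half, 3))
        dom2 = rng.normal(scale=2.5, size=(other, 3)) + np.array([20.0, 0.0, 0.0])
        linker = np.column_stack(
            [np.linspace(4.0, 16.0, 3), np.zeros(3), np.zeros(3)]
        )
        coords = np.vstack([dom1, linker, dom2])
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")
    labels = [f"A:{i + 1}" for i in range(n_residues)]
    return StructureModel(coords, labels, source_id=f"toy-{kind}")


# ---------------------------------------------------------------------------
# covariance recipes


def make_single_rho_spec(rho: float, seed: int = 0) -> GroundTruthSpec:
    """Two residues, unit variances, one cross-correlation rho on the x-x axis pair."""
    cov = np.eye(6)
    cov[0, 3] = cov[3, 0] = rho
    return GroundTruthSpec(cov, seed)


def make_random_spec(n_residues: int, seed: int, strength: float = 0.9) -> GroundTruthSpec:
    """Random well-conditioned 3N x 3N covariance with nontrivial cross-correlations."""
    rng = np.random.default_rng(seed)
    dim = 3 * n_residues
    a = rng.normal(size=(dim, dim + 8)) * strength
    cov = a @ a.T / (dim + 8) + 0.5 * np.eye(dim)
    return GroundTruthSpec(cov, seed)


def gnm_embedded_spec(
    corr: GNMCorrelation | KirchhoffSystem, seed: int = 0
) -> GroundTruthSpec:
    """Isotropic 3N x 3N embedding of a GNM cross-correlation matrix.

    Each Cartesian axis receives an identical, independent copy of the N x N
    correlation matrix: cov[(i,a),(j,b)] = delta_ab * cross_ij.  Sampling from
    this covariance realizes the GNM statistics as an actual trajectory.
    """
    if isinstance(corr, KirchhoffSystem):
        corr = gnm_cross_correlation(corr, "1-all")
    cross = corr.cross
    cov = np.kron(cross, np.eye(3))
    return GroundTruthSpec(cov, seed)


# ---------------------------------------------------------------------------
# samplers


def sample_gaussian_trajectory(spec: GroundTruthSpec, n_frames: int) -> FluctuationTrajectory:
    """I.i.d. zero-mean Gaussian frames from the spec covariance, mean-removed.

    Uses a symmetric eigenvalue factorization, so positive *semi*definite
    covariances (e.g. GNM embeddings, whose rigid-body mode is absent) are
    sampled exactly on their support.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    eigvals, eigvecs = np.linalg.eigh(spec.covariance)
    tol = -1e-8 * max(eigvals[-1], 1.0)
    if eigvals[0] < tol:
        raise ValueError(f"covariance is not PSD: smallest eigenvalue {eigvals[0]:.3e}")
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((n_frames, spec.covariance.shape[0]))
    samples = z @ root.T
    samples -= samples.mean(axis=0, keepdims=True)
    deltas = samples.reshape(n_frames, spec.n_residues, 3)
    return FluctuationTrajectory(deltas)


def make_nongaussian_trajectory(
    kind: str,
    n_residues: int,
    n_frames: int,
    seed: int,
    well_offset: float = 2.0,
    pair: tuple[int, int] = (0, 1),
) -> FluctuationTrajectory:
    """Trajectory with one designated non-Gaussian residue pair.

    ``"double-well"``: residue j of ``pair`` hops between Gaussian wells at
    +/- ``well_offset`` along x.  Residue i occupies four wells at
    (+/-d, +/-d) in the x-y plane whose sign *product* equals j's well sign,
    so every linear cross-covariance entry vanishes in expectation while the
    joint well occupancy carries ~ln 2 nats — covariance-based MI sees
    nothing, the full joint histogram sees the coupling.  All other residues
    are independent unit Gaussians.  Setting ``well_offset=0`` collapses the
    construction to the purely Gaussian case.
    """
    if kind != "double-well":
        raise ValueError(f"unknown non-Gaussian trajectory kind {kind!r}")
    if n_frames < 100:
        raise ValueError("need at least 100 frames for the multi-well fixture")
    i, j = pair
    rng = np.random.default_rng(seed)
    deltas = rng.standard_normal((n_frames, n_residues, 3))
    s = rng.choice([-1.0, 1.0], size=n_frames)  # hidden well of residue j
    a = rng.choice([-1.0, 1.0], size=n_frames)  # free sign of residue i
    d = well_offset
    deltas[:, j, 0] += s * d
    deltas[:, i, 0] += a * d
    deltas[:, i, 1] += a * s * d  # sign product recovers s; covariances all cancel
    deltas -= deltas.mean(axis=0, keepdims=True)
    return FluctuationTrajectory(deltas)


# ---------------------------------------------------------------------------
# analytic oracles


def analytic_gaussian_mi(
    spec: GroundTruthSpec, i: int, j: int, estimator: str = "gauss_multi"
) -> MIValue:
    """Closed-form MI of the generating Gaussian model for one residue pair.

    ``"gauss_multi"`` evaluates the 6x6 log-determinant ratio on the true
    covariance; ``"gauss_iso"`` evaluates the scalar dot-product form
    (the quantity the GNM reproduces).
    """
    block = spec.pair_block(i, j)
    if estimator == "gauss_multi":
        mi = multivariate_gaussian_mi(PairCovariance(block, n_frames=0, pair=(i, j)))
        mi.estimator_tag = "analytic_gauss_multi"
        return mi
    if estimator == "gauss_iso":
        cross = float(np.trace(block[:3, 3:]))
        auto_i = float(np.trace(block[:3, :3]))
        auto_j = float(np.trace(block[3:, 3:]))
        ratio = cross**2 / (auto_i * auto_j)
        if ratio >= 1.0:
            return MIValue(np.nan, "analytic_gauss_iso", (i, j), degenerate=True,
                           note="perfect correlation")
        return MIValue(float(-0.5 * np.log1p(-ratio)), "analytic_gauss_iso", (i, j))
    raise ValueError(f"unknown analytic estimator {estimator!r}")


def analytic_mi_profile(spec: GroundTruthSpec, anchor: int, estimator: str = "gauss_multi"):
    """Analytic MI profile of one anchor residue (oracle for convergence tests)."""
    from dyncorr.convergence import MIProfile

    others = np.array([r for r in range(spec.n_residues) if r != anchor])
    values = np.array(
        [analytic_gaussian_mi(spec, anchor, int(o), estimator).value for o in others]
    )
    return MIProfile(anchor, others, values, f"analytic_{estimator}", n_frames_effective=0)


def analytic_mi_matrix(spec: GroundTruthSpec, estimator: str = "gauss_multi") -> MIMatrix:
    n = spec.n_residues
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = analytic_gaussian_mi(spec, i, j, estimator).value
    return MIMatrix(values, f"analytic_{estimator}", [str(k + 1) for k in range(n)])
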
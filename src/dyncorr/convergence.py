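"""Trajectory-length convergence protocol for MI profiles.

Short MD trajectories sample conformational space poorly, so single-window MI
estimates are noisy.  The protocol here cuts multiple segments of a given
length from different points of a long trajectory, computes MI independently
within each segment (fluctuations re-centered per segment, as independent
short simulations would be), averages per pair, and compares the resulting MI
profile of an anchor residue to a reference profile by RMSD and Pearson
correlation.  Sweeping the segment length yields a convergence curve: the
length at which RMSD flattens marks the trajectory length needed to reproduce
the reference (longest-trajectory, or analytic) MI profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from dyncorr.exact_estimators import GridSpec, exact_anisotropic_mi, exact_isotropic_mi
from dyncorr.gaussian_estimators import (
    MIMatrix,
    isotropic_gaussian_mi,
    multivariate_gaussian_mi,
    pair_covariance,
    scalar_correlation,
)
from dyncorr.trajectory_io import FluctuationTrajectory

__all__ = [
    "SegmentScheme",
    "MIProfile",
    "ConvergenceCurve",
    "plan_segments",
    "averaged_mi",
    "profile_rmsd",
    "profile_correlation",
    "convergence_curve",
]

ESTIMATOR_TAGS = ("exact_aniso", "exact_iso", "gauss_multi", "gauss_iso")


@dataclass(frozen=True)
class SegmentScheme:
    """Where the analysis segments sit inside the parent trajectory."""

    segment_length: int
    n_segments: int
    offsets: tuple[int, ...]
    overlap_allowed: bool

    def __post_init__(self) -> None:
        if list(self.offsets) != sorted(self.offsets):
            raise ValueError("offsets must be sorted")


@dataclass
class MIProfile:
    """MI of one anchor residue against every other residue, in nats."""

    anchor: int
    others: np.ndarray  # residue indices, length N-1
    values: np.ndarray  # same length; NaN where degenerate
    estimator_tag: str = ""
    n_frames_effective: int = 0

    def __post_init__(self) -> None:
        self.others = np.asarray(self.others, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.others.shape != self.values.shape:
            raise ValueError("others and values must have the same length")
        if self.anchor in self.others:
            raise ValueError("profile must exclude the anchor itself")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class ConvergenceCurve:
    """One row per segment length: (length, RMSD to reference, Pearson r, segments)."""

    rows: list[tuple[int, float, float, int]] = field(default_factory=list)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if not self.rows:
            return tuple(np.array([]) for _ in range(4))  # type: ignore[return-value]
        a = np.array(self.rows, dtype=float)
        return a[:, 0].astype(int), a[:, 1], a[:, 2], a[:, 3].astype(int)


def plan_segments(total_frames: int, segment_length: int, n_segments: int) -> SegmentScheme:
    """Evenly spaced segments; non-overlapping whenever they fit.

    If ``n_segments`` disjoint segments fit, offsets tile from frame 0 with
    stride ``floor(total/n)`` truncated to keep segments disjoint and evenly
    spread; otherwise offsets are spread as ``(total-length)/(n-1)`` with
    overlap recorded.
    """
    if segment_length > total_frames:
        raise ValueError(f"segment_length {segment_length} exceeds trajectory ({total_frames} frames)")
    if n_segments < 1:
        raise ValueError("need at least one segment")
    if n_segments == 1:
        return SegmentScheme(segment_length, 1, (0,), overlap_allowed=False)
    max_disjoint = total_frames // segment_length
    if max_disjoint >= n_segments:
        # even spread of disjoint segments across the whole trajectory
        stride = (total_frames - segment_length) / (n_segments - 1)
        offsets = [int(round(k * stride)) for k in range(n_segments)]
        # rounding could re-introduce overlap; fall back to exact tiling
        if any(b - a < segment_length for a, b in zip(offsets, offsets[1:])):
            offsets = [k * segment_length for k in range(n_segments)]
        return SegmentScheme(segment_length, n_segments, tuple(offsets), overlap_allowed=False)
    stride = (total_frames - segment_length) / (n_segments - 1)
    offsets = tuple(int(round(k * stride)) for k in range(n_segments))
    return SegmentScheme(segment_length, n_segments, offsets, overlap_allowed=True)


def _estimate_pair(fluct: FluctuationTrajectory, i: int, j: int, estimator: str, grid: GridSpec | None):
    if estimator == "exact_aniso":
        return exact_anisotropic_mi(fluct, i, j, grid)
    if estimator == "exact_iso":
        return exact_isotropic_mi(fluct, i, j, grid)
    if estimator == "gauss_multi":
        return multivariate_gaussian_mi(pair_covariance(fluct, i, j))
    if estimator == "gauss_iso":
        return isotropic_gaussian_mi(scalar_correlation(fluct, i, j))
    raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATOR_TAGS}")


def _segment_fluct(fluct: FluctuationTrajectory, offset: int, length: int) -> FluctuationTrajectory:
    block = fluct.deltas[offset : offset + length]
    # each segment sees its own mean structure, as an independent short run would
    return FluctuationTrajectory(block - block.mean(axis=0, keepdims=True), list(fluct.residue_labels))


def averaged_mi(
    fluct: FluctuationTrajectory,
    scheme: SegmentScheme,
    estimator: str,
    anchor: int | str = "all",
    grid: GridSpec | None = None,
) -> MIProfile | MIMatrix:
    """Per-pair arithmetic mean of MI over the scheme's segments.

    Fluctuations are recomputed within each segment.  A pair degenerate in
    some segments is averaged over its valid segments only; a pair with no
    valid segment stays NaN.
    """
    if estimator in ("exact_aniso", "exact_iso") and grid is None:
        raise ValueError("histogram estimators require a GridSpec")
    n = fluct.n_residues
    if anchor == "all":
        pair_list = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        a = int(anchor)
        pair_list = [(a, o) for o in range(n) if o != a]

    sums = np.zeros(len(pair_list))
    counts = np.zeros(len(pair_list), dtype=int)
    for offset in scheme.offsets:
        seg = _segment_fluct(fluct, offset, scheme.segment_length)
        for k, (i, j) in enumerate(pair_list):
            mi = _estimate_pair(seg, i, j, estimator, grid)
            if not mi.degenerate and np.isfinite(mi.value):
                sums[k] += mi.value
                counts[k] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    if anchor == "all":
        values = np.full((n, n), np.nan)
        degenerate = np.zeros((n, n), dtype=bool)
        for k, (i, j) in enumerate(pair_list):
            values[i, j] = values[j, i] = means[k]
            degenerate[i, j] = degenerate[j, i] = counts[k] == 0
        return MIMatrix(values, estimator, list(fluct.residue_labels), degenerate)
    others = np.array([j for _, j in pair_list])
    return MIProfile(
        int(anchor), others, means, estimator,
        n_frames_effective=scheme.segment_length * scheme.n_segments,
    )


def _common_valid(a: MIProfile, b: MIProfile) -> tuple[np.ndarray, np.ndarray]:
    if a.anchor != b.anchor or not np.array_equal(a.others, b.others):
        raise ValueError("profiles must share anchor and residue set")
    mask = a.valid & b.valid
    if not np.any(mask):
        raise ValueError("profiles have no common valid entries")
    return a.values[mask], b.values[mask]


def profile_rmsd(a: MIProfile, b: MIProfile) -> float:
    """Root-mean-square deviation between two MI profiles (flagged entries excluded)."""
    va, vb = _common_valid(a, b)
    return float(np.sqrt(np.mean((va - vb) ** 2)))


def profile_correlation(a: MIProfile, b: MIProfile) -> float:
    """Pearson correlation between two MI profiles; NaN if either is constant."""
    va, vb = _common_valid(a, b)
    if va.size < 3:
        raise ValueError("need at least 3 common valid entries for a correlation")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return float("nan")
    return float(stats.pearsonr(va, vb).statistic)


def convergence_curve(
    fluct: FluctuationTrajectory,
    lengths: Sequence[int],
    estimator: str,
    reference: MIProfile,
    anchor: int,
    grid: GridSpec | None = None,
    max_segments: int = 10,
) -> ConvergenceCurve:
    """RMSD and Pearson r of segment-averaged MI profiles versus a reference.

    One row per segment length, lengths ascending.  Each length uses
    ``min(max_segments, floor(total/length))`` segments (at least one).
    """
    lengths = list(lengths)
    if lengths != sorted(lengths):
        raise ValueError("lengths must be sorted ascending")
    curve = ConvergenceCurve()
    for length in lengths:
        n_seg = max(1, min(max_segments, fluct.n_frames // length))
        scheme = plan_segments(fluct.n_frames, length, n_seg)
        profile = averaged_mi(fluct, scheme, estimator, anchor=anchor, grid=grid)
        assert isinstance(profile, MIProfile)
        rmsd = profile_rmsd(profile, reference)
        r = profile_correlation(profile, reference)
        curve.rows.append((length, rmsd, r, scheme.n_segments))
    return curve
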
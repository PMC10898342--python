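"""Shared fixtures: tiny PDB texts and synthetic trajectories, all generated in-test."""

from __future__ import annotations

import numpy as np
import pytest

from dyncorr.synthetic_data import make_single_rho_spec, sample_gaussian_trajectory


def format_atom(serial, name, res_name, chain, res_id, x, y, z, occupancy=1.0, altloc=" ") -> str:
    return (
        f"ATOM  {serial:>5} {name:^4}{altloc}{res_name:<3} {chain}{res_id:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}           {name.strip()[0]:>2}"
    )


def make_pdb_text(coords: np.ndarray, chain: str = "A", res_name: str = "ALA") -> str:
    """Single-model PDB with one CA per residue at the given coordinates."""
    lines = []
    for idx, (x, y, z) in enumerate(np.asarray(coords), start=1):
        lines.append(format_atom(idx, "CA", res_name, chain, idx, x, y, z))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_multimodel_pdb_text(frames: np.ndarray, chain: str = "A") -> str:
    """Multi-model PDB: one MODEL per frame, one CA per residue."""
    lines = []
    for m, frame in enumerate(np.asarray(frames), start=1):
        lines.append(f"MODEL     {m:>4}")
        for idx, (x, y, z) in enumerate(frame, start=1):
            lines.append(format_atom(idx, "CA", "ALA", chain, idx, x, y, z))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def chain3_pdb(tmp_path):
    """Three collinear residues at 3.8 A spacing (the hand-checkable GNM fixture)."""
    coords = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.6, 0.0, 0.0]])
    path = tmp_path / "chain3.pdb"
    path.write_text(make_pdb_text(coords))
    return path


@pytest.fixture
def rho_half_trajectory():
    """1e4-frame sample of the two-residue, single rho=0.5 Gaussian model."""
    spec = make_single_rho_spec(0.5, seed=42)
    return sample_gaussian_trajectory(spec, 10_000)


@pytest.fixture
def random_fluct():
    """Small generic fluctuation trajectory for oracle comparisons."""
    rng = np.random.default_rng(7)
    deltas = rng.normal(size=(500, 4, 3))
    deltas -= deltas.mean(axis=0, keepdims=True)
    from dyncorr.trajectory_io import FluctuationTrajectory

    return FluctuationTrajectory(deltas)
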
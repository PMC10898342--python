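"""Structure and trajectory input, superposition, and fluctuation extraction.

Residues are coarse-grained to their C-alpha atoms.  A trajectory is a
``frames x residues x 3`` coordinate array in Angstrom; fluctuations are the
mean-removed displacements ``Delta R_i(t) = R_i(t) - <R_i>`` that feed every
mutual-information estimator downstream.

Supported on-disk formats: PDB (single- and multi-model, via biotite), DCD and
XTC (via MDAnalysis, topology from a PDB), and a self-describing plain-text
fallback container (TSV: ``frame  residue  x  y  z`` with ``#key=value``
header lines) plus an equivalent ``.npz`` binary variant.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructureModel",
    "CoordinateTrajectory",
    "FluctuationTrajectory",
    "load_structure",
    "load_trajectory",
    "superpose",
    "compute_fluctuations",
    "read_fluct_tsv",
    "write_fluct_tsv",
    "read_fluct_npz",
    "write_fluct_npz",
]


@dataclass
class StructureModel:
    """One C-alpha per residue, in chain + residue order."""

    ca_coords: np.ndarray  # (N, 3) Angstrom
    residue_labels: list[str]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must have shape (N, 3)")
        if self.ca_coords.shape[0] < 2:
            raise ValueError("need at least 2 residues")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return self.ca_coords.shape[0]


@dataclass
class CoordinateTrajectory:
    """Ordered per-frame C-alpha coordinates (Angstrom)."""

    frames: np.ndarray  # (F, N, 3)
    residue_labels: list[str]
    frame_interval: float | None = None  # ps, optional metadata

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_residues, 3)")
        if self.frames.shape[1] < 2:
            raise ValueError("need at least 2 residues")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]


@dataclass
class FluctuationTrajectory:
    """Mean-removed C-alpha displacement series Delta R(t)."""

    deltas: np.ndarray  # (F, N, 3)
    residue_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.deltas.ndim != 3 or self.deltas.shape[2] != 3:
            raise ValueError("deltas must have shape (n_frames, n_residues, 3)")
        if self.deltas.shape[0] < 2:
            raise ValueError("need at least 2 frames for fluctuations")
        if not self.residue_labels:
            self.residue_labels = [str(i + 1) for i in range(self.deltas.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.deltas.shape[0]

    @property
    def n_residues(self) -> int:
        return self.deltas.shape[1]

    def pair_vectors(self, i: int, j: int) -> np.ndarray:
        """Stacked 6-vectors (dXi dYi dZi dXj dYj dZj) per frame."""
        return np.concatenate([self.deltas[:, i, :], self.deltas[:, j, :]], axis=1)


# ---------------------------------------------------------------------------
# readers


def load_structure(path: str | os.PathLike, chain_filter: str | None = None) -> StructureModel:
    """Read a PDB file and return its C-alpha trace.

    Altlocs are resolved to the highest-occupancy conformer.  A residue with
    no C-alpha record is a hard error naming the residue — silently dropping
    residues would desynchronise MI indices from the author numbering.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(os.fspath(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    if chain_filter is not None:
        atoms = atoms[atoms.chain_id == chain_filter]
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms found in {path!r} (chain_filter={chain_filter!r})")
    amino = atoms[struc.filter_amino_acids(atoms)]
    if amino.array_length() > 0:
        atoms = amino

    labels: list[str] = []
    coords: list[np.ndarray] = []
    missing: list[str] = []
    # first occurrence preserves chain+residue file order
    seen: dict[tuple, int] = {}
    order: list[tuple] = []
    for idx in range(atoms.array_length()):
        key = (atoms.chain_id[idx], atoms.res_id[idx], atoms.ins_code[idx])
        if key not in seen:
            seen[key] = idx
            order.append(key)
    for key in order:
        chain, res_id, ins = key
        mask = (atoms.chain_id == chain) & (atoms.res_id == res_id) & (atoms.ins_code == ins)
        res_atoms = atoms[mask]
        ca = res_atoms[res_atoms.atom_name == "CA"]
        label = f"{chain}:{res_id}{ins}".strip()
        if ca.array_length() == 0:
            missing.append(label)
            continue
        coords.append(ca.coord[0])
        labels.append(label)
    if missing:
        raise ValueError(f"residues lacking a CA atom: {', '.join(missing)}")
    return StructureModel(np.asarray(coords), labels, source_id=os.path.basename(os.fspath(path)))


def load_trajectory(
    coords_path: str | os.PathLike,
    topology_path: str | os.PathLike | None = None,
    format_hint: str | None = None,
) -> CoordinateTrajectory:
    """Read a C-alpha trajectory from PDB/DCD/XTC or the fallback container."""
    path = os.fspath(coords_path)
    fmt = (format_hint or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt in ("tsv", "fluct"):
        return _fluct_to_traj(read_fluct_tsv(path))
    if fmt == "npz":
        return _fluct_to_traj(read_fluct_npz(path))
    if fmt == "pdb":
        return _load_multimodel_pdb(path)
    if fmt in ("dcd", "xtc"):
        if topology_path is None:
            raise ValueError(f"{fmt.upper()} input requires topology_path (a PDB with matching atoms)")
        return _load_md_trajectory(path, os.fspath(topology_path))
    raise ValueError(f"unrecognized trajectory format {fmt!r} for {path!r}")


def _fluct_to_traj(pair: tuple[np.ndarray, list[str]]) -> CoordinateTrajectory:
    coords, labels = pair
    return CoordinateTrajectory(coords, labels)


def _load_multimodel_pdb(path: str) -> CoordinateTrajectory:
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(path)
    stack = pdb_file.get_structure(altloc="occupancy")  # AtomArrayStack over models
    ca_mask = stack.atom_name == "CA"
    if not np.any(ca_mask):
        raise ValueError(f"no CA atoms found in {path!r}")
    ca = stack[:, ca_mask]
    labels = [
        f"{ca.chain_id[k]}:{ca.res_id[k]}" for k in range(ca.array_length())
    ]
    return CoordinateTrajectory(np.asarray(ca.coord, dtype=float), labels)


def _load_md_trajectory(path: str, topology: str) -> CoordinateTrajectory:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        universe = mda.Universe(topology, path)
        ca = universe.select_atoms("name CA")
        if ca.n_atoms == 0:
            raise ValueError(f"topology {topology!r} contains no CA atoms")
        labels = [f"{a.segid or a.chainID or 'A'}:{a.resid}" for a in ca]
        frames = np.array([ca.positions.copy() for _ in universe.trajectory], dtype=float)
    return CoordinateTrajectory(frames, labels)


# ---------------------------------------------------------------------------
# superposition and fluctuations


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of one coordinate set onto another."""
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    p = mobile - mob_center
    q = target - tgt_center
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return p @ rot + tgt_center


def superpose(traj: CoordinateTrajectory, reference: str | int = "mean") -> CoordinateTrajectory:
    """Remove rigid-body motion by superposing every frame onto a reference.

    With ``reference="mean"`` the fit iterates: superpose onto the current mean
    structure, recompute the mean, repeat until the mean moves by < 1e-6 A RMSD
    or 10 iterations.  An integer selects a fixed reference frame.
    """
    if traj.n_residues < 3:
        raise ValueError("superposition needs at least 3 residues for a well-defined fit")
    frames = traj.frames.copy()
    if reference == "mean":
        # start from the current mean so an already-converged trajectory is a
        # fixed point (fitting to frame 0 instead would break idempotence),
        # and iterate to numerical convergence so superposition is idempotent
        ref = frames.mean(axis=0)
        for _ in range(500):
            fitted = np.array([_kabsch(f, ref) for f in frames])
            new_ref = fitted.mean(axis=0)
            shift = np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1)))
            frames = fitted
            ref = new_ref
            if shift < 1e-12:
                break
    else:
        ref = frames[int(reference)]
        frames = np.array([_kabsch(f, ref) for f in frames])
    return CoordinateTrajectory(frames, list(traj.residue_labels), traj.frame_interval)


def compute_fluctuations(traj: CoordinateTrajectory) -> FluctuationTrajectory:
    """Subtract each residue's time-mean position: Delta R_i(t) = R_i(t) - <R_i>."""
    if traj.n_frames < 2:
        raise ValueError("fluctuations undefined for a single frame")
    deltas = traj.frames - traj.frames.mean(axis=0, keepdims=True)
    return FluctuationTrajectory(deltas, list(traj.residue_labels))


# ---------------------------------------------------------------------------
# fallback container

_TSV_FMT = "%.17g"


def write_fluct_tsv(path: str | os.PathLike, coords: np.ndarray, labels: list[str] | None = None) -> None:
    """Write a (frames, residues, 3) array to the plain-text fallback container."""
    coords = np.asarray(coords, dtype=float)
    n_frames, n_residues = coords.shape[:2]
    with open(path, "w") as fh:
        fh.write(f"#n_frames={n_frames}\n#n_residues={n_residues}\n#unit=angstrom\n")
        if labels:
            fh.write("#labels=" + ",".join(labels) + "\n")
        fh.write("frame\tresidue\tx\ty\tz\n")
        for f in range(n_frames):
            for r in range(n_residues):
                x, y, z = coords[f, r]
                fh.write(f"{f}\t{r}\t{_TSV_FMT % x}\t{_TSV_FMT % y}\t{_TSV_FMT % z}\n")


def read_fluct_tsv(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            if line.startswith("frame\t"):
                continue
            f, r, x, y, z = line.split("\t")
            rows.append((int(f), int(r), float(x), float(y), float(z)))
    n_frames = int(meta["n_frames"])
    n_residues = int(meta["n_residues"])
    coords = np.full((n_frames, n_residues, 3), np.nan)
    for f, r, x, y, z in rows:
        coords[f, r] = (x, y, z)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"container {path!r} is missing frame/residue rows")
    labels = meta["labels"].split(",") if "labels" in meta else [str(i + 1) for i in range(n_residues)]
    return coords, labels


def write_fluct_npz(path: str | os.PathLike, coords: np.ndarray, labels: list[str] | None = None) -> None:
    coords = np.asarray(coords, dtype=float)
    labels = labels or [str(i + 1) for i in range(coords.shape[1])]
    np.savez(
        path,
        coords=coords,
        labels=np.asarray(labels),
        n_frames=coords.shape[0],
        n_residues=coords.shape[1],
        unit="angstrom",
    )


def read_fluct_npz(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    with np.load(path, allow_pickle=False) as data:
        coords = np.asarray(data["coords"], dtype=float)
        labels = [str(s) for s in data["labels"]]
    return coords, labels
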
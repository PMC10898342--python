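"""Writers and readers for MI tables, profiles, maps, and convergence curves.

All outputs are locale-independent TSV with fixed column order; MI values are
written at full double precision so a write -> read round trip is lossless.
Degenerate (divergent) entries are written as the token ``inf`` and the
diagonal of dense maps as ``inf`` likewise — self-MI is unbounded.  Each
writer can attach a JSON run manifest recording the command line, package
version, and all parameters, so any table can be traced to the run that
produced it.
"""

from __future__ import annotations

import json
import os
import sys
import time
from dataclasses import dataclass, field

import numpy as np

from dyncorr.convergence import ConvergenceCurve, MIProfile
from dyncorr.gaussian_estimators import MIMatrix

__all__ = [
    "RunManifest",
    "write_mi_table",
    "read_mi_table",
    "write_dense_matrix",
    "write_profile",
    "write_convergence_table",
    "write_manifest",
]

_FMT = "%.17g"
LN2 = float(np.log(2.0))


@dataclass
class RunManifest:
    command: str
    parameters: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from dyncorr import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")


def write_manifest(manifest: RunManifest, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.__dict__, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _fmt_value(v: float, bits: bool) -> str:
    if not np.isfinite(v):
        return "inf" if v > 0 or np.isnan(v) else "-inf"
    return _FMT % (v / LN2 if bits else v)


def write_mi_table(
    values: MIProfile | MIMatrix,
    path: str | os.PathLike,
    n_frames: int = 0,
    params: str = "",
    bits: bool = False,
) -> None:
    """Long-format TSV: one row per residue pair, i < j, ascending.

    Header: ``res_i  res_j  mi_nats  estimator  n_frames  params`` (the value
    column is labelled ``mi_bits`` under ``bits=True``).  Degenerate entries
    are the token ``inf``.
    """
    unit_col = "mi_bits" if bits else "mi_nats"
    with open(path, "w") as fh:
        fh.write(f"res_i\tres_j\t{unit_col}\testimator\tn_frames\tparams\n")
        if isinstance(values, MIProfile):
            tag = values.estimator_tag
            nf = n_frames or values.n_frames_effective
            for o, v in zip(values.others, values.values):
                a, b = sorted((values.anchor, int(o)))
                fh.write(f"{a + 1}\t{b + 1}\t{_fmt_value(v, bits)}\t{tag}\t{nf}\t{params}\n")
        else:
            tag = values.estimator_tag
            n = values.n_residues
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(
                        f"{i + 1}\t{j + 1}\t{_fmt_value(values.values[i, j], bits)}"
                        f"\t{tag}\t{n_frames}\t{params}\n"
                    )


def read_mi_table(path: str | os.PathLike) -> dict[tuple[int, int], float]:
    """Read a long-format MI table back into a {(i, j): value} map (1-based keys)."""
    out: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("res_i\t"):
            raise ValueError(f"{path!r} is not an MI table")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            out[(int(cols[0]), int(cols[1]))] = float(cols[2])
    return out


def write_dense_matrix(matrix: MIMatrix, path: str | os.PathLike, bits: bool = False) -> None:
    """Whitespace matrix with residue-label header row/column; diagonal = inf."""
    n = matrix.n_residues
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(matrix.residue_labels) + "\n")
        for i in range(n):
            cells = []
            for j in range(n):
                if i == j:
                    cells.append("inf")
                else:
                    cells.append(_fmt_value(matrix.values[i, j], bits))
            fh.write(matrix.residue_labels[i] + "\t" + "\t".join(cells) + "\n")


def write_profile(profile: MIProfile, path: str | os.PathLike, bits: bool = False) -> None:
    """Two-column profile TSV: residue (1-based), MI versus the anchor."""
    with open(path, "w") as fh:
        fh.write(f"# anchor={profile.anchor + 1} estimator={profile.estimator_tag}\n")
        fh.write("residue\t" + ("mi_bits" if bits else "mi_nats") + "\n")
        for o, v in zip(profile.others, profile.values):
            fh.write(f"{int(o) + 1}\t{_fmt_value(v, bits)}\n")


def read_profile(path: str | os.PathLike) -> MIProfile:
    anchor = None
    residues: list[int] = []
    values: list[float] = []
    tag = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, val = token.partition("=")
                    if key == "anchor":
                        anchor = int(val) - 1
                    elif key == "estimator":
                        tag = val
                continue
            if not line or line.startswith("residue"):
                continue
            r, v = line.split("\t")
            residues.append(int(r) - 1)
            values.append(float(v))
    if anchor is None:
        raise ValueError(f"{path!r} lacks an '# anchor=' header")
    return MIProfile(anchor, np.array(residues), np.array(values), tag)


def write_convergence_table(curve: ConvergenceCurve, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("segment_length\trmsd\tpearson_r\tn_segments\n")
        for length, rmsd, r, n_seg in curve.rows:
            fh.write(f"{int(length)}\t{_FMT % rmsd}\t{_FMT % r}\t{int(n_seg)}\n")


def log(message: str, level: str = "info", min_level: str = "info") -> None:
    order = {"debug": 0, "info": 1, "warning": 2, "error": 3}
    if order[level] >= order[min_level]:
        print(f"[{level}] {message}", file=sys.stderr)
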
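"""Reading backbone traces and trajectories; writing per-frame series tables.

Structures arrive as PDB files (single- or multi-model) or as plain XYZ frame
blocks.  The in-memory objects are deliberately light: a :class:`Chain` is an
ordered open polygonal curve of labelled Cα positions, a :class:`Trajectory`
is a list of Chains sharing one label set.  All knot analysis downstream
operates on these geometric traces only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "ResidueLabel",
    "Chain",
    "Trajectory",
    "DomainMap",
    "read_backbone",
    "read_trajectory",
    "write_series",
    "read_series",
    "write_xyz",
    "read_xyz",
]

_MIN_SEP = 1e-6  # Å; consecutive points closer than this are degenerate


@dataclass(frozen=True)
class ResidueLabel:
    """Identity of one point of a backbone trace (author numbering kept as-is)."""

    res_id: int
    chain_id: str = "A"
    res_name: str = "GLY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain_id}:{self.res_name}{self.res_id}"


class Chain:
    """An ordered open polygonal curve of labelled 3D points (a Cα trace).

    Parameters
    ----------
    points:
        (n, 3) coordinates in Å, ordered by residue number.
    labels:
        Per-point residue labels, unique and monotonically increasing in
        residue number.  If omitted, residues are numbered 1..n.
    closed:
        Marks a curve whose last point connects back to the first by an
        implied segment.
    """

    def __init__(
        self,
        points: np.ndarray,
        labels: Sequence[ResidueLabel] | None = None,
        closed: bool = False,
    ):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(pts) < 3:
            raise ValueError(f"a chain needs >= 3 points, got {len(pts)}")
        seps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if closed:
            seps = np.append(seps, np.linalg.norm(pts[-1] - pts[0]))
        if np.any(seps <= _MIN_SEP):
            i = int(np.argmin(seps))
            raise ValueError(f"consecutive points {i}, {i + 1} coincide")
        if labels is None:
            labels = [ResidueLabel(i + 1) for i in range(len(pts))]
        labels = list(labels)
        if len(labels) != len(pts):
            raise ValueError("labels and points differ in length")
        res_ids = [l.res_id for l in labels]
        if any(b <= a for a, b in zip(res_ids, res_ids[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        self.points = pts
        self.labels = labels
        self.closed = bool(closed)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def res_ids(self) -> np.ndarray:
        return np.array([l.res_id for l in self.labels])

    def subchain(self, i: int, j: int) -> "Chain":
        """Open subchain from point index ``i`` to ``j`` inclusive."""
        if not (0 <= i <= j < len(self)):
            raise IndexError(f"subchain [{i}..{j}] out of bounds")
        return Chain(self.points[i : j + 1], self.labels[i : j + 1], closed=False)

    def index_of(self, res_id: int) -> int:
        for k, lab in enumerate(self.labels):
            if lab.res_id == res_id:
                return k
        raise KeyError(f"residue {res_id} not in chain")

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Chain":
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation).T
        if translation is not None:
            pts = pts + np.asarray(translation)
        return Chain(pts, self.labels, self.closed)


@dataclass
class Trajectory:
    """Ordered frames (Chains with identical labels) plus optional times in ns."""

    frames: list[Chain]
    times: np.ndarray | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory needs >= 1 frame")
        ref = self.frames[0].labels
        for k, fr in enumerate(self.frames):
            if fr.labels != ref:
                raise ValueError(f"frame {k} labels differ from frame 0")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise ValueError("times and frames differ in length")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class DomainMap:
    """Named inclusive residue ranges, e.g. ``{"a1": (10, 28), "a5": (120, 155)}``."""

    ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (a, b) in self.ranges.items():
            if b < a:
                raise ValueError(f"domain {name!r} range [{a}, {b}] is empty")

    def residues(self, name: str) -> range:
        a, b = self.ranges[name]
        return range(a, b + 1)

    def validate_against(self, chain: Chain) -> None:
        ids = set(int(r) for r in chain.res_ids)
        for name, (a, b) in self.ranges.items():
            if not any(r in ids for r in range(a, b + 1)):
                raise ValueError(f"domain {name!r} [{a}, {b}] outside chain residues")


# ---------------------------------------------------------------------------
# PDB input


def _structure_chain(atoms: struc.AtomArray, chain_id: str | None,
                     atom_name: str) -> Chain:
    chains = sorted(set(atoms.chain_id))
    if chain_id is None:
        chain_id = chains[0]
    if chain_id not in chains:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {', '.join(chains)}"
        )
    sel = atoms[(atoms.chain_id == chain_id) & (atoms.atom_name == atom_name)
                & ~atoms.hetero]
    if sel.array_length() < 3:
        raise ValueError(
            f"fewer than 3 {atom_name} atoms resolved in chain {chain_id!r}"
        )
    order = np.argsort(sel.res_id, kind="stable")
    sel = sel[order]
    # one point per residue (guard against residual duplicates)
    _, first = np.unique(sel.res_id, return_index=True)
    sel = sel[np.sort(first)]
    labels = [
        ResidueLabel(int(r), str(c), str(n))
        for r, c, n in zip(sel.res_id, sel.chain_id, sel.res_name)
    ]
    ids = [l.res_id for l in labels]
    gaps = [(a, b) for a, b in zip(ids, ids[1:]) if b - a > 1]
    if gaps:
        warnings.warn(
            "gaps in residue numbering (bridged by straight segments): "
            + ", ".join(f"{a}->{b}" for a, b in gaps),
            stacklevel=3,
        )
    return Chain(sel.coord, labels)


def read_backbone(path: str | Path, chain_id: str | None = None,
                  atom_name: str = "CA") -> Chain:
    """Read one backbone trace (default Cα) from a PDB file.

    Altloc conflicts are resolved to the highest-occupancy location; points
    are ordered by author residue number and numbering gaps are reported via
    a warning (the trace simply bridges them geometrically).
    """
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    return _structure_chain(atoms, chain_id, atom_name)


def read_trajectory(path: str | Path, chain_id: str | None = None,
                    atom_name: str = "CA") -> Trajectory:
    """Read a trajectory from a multi-model PDB or an XYZ frame-block file."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return read_xyz(path)
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(altloc="occupancy")
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    frames = []
    for m in range(stack.stack_depth()):
        frames.append(_structure_chain(stack[m], chain_id, atom_name))
    n0 = len(frames[0])
    for k, fr in enumerate(frames):
        if len(fr) != n0:
            raise ValueError(f"frame {k} has {len(fr)} points, expected {n0}")
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# XYZ frame blocks (canonical fixture format)


def write_xyz(traj: Trajectory, path: str | Path, comment: str = "frame") -> None:
    """Write frames as XYZ blocks: count line, comment line, ``name x y z`` rows."""
    with open(path, "w") as fh:
        for k, fr in enumerate(traj.frames):
            fh.write(f"{len(fr)}\n")
            t = traj.times[k] if traj.times is not None else k
            fh.write(f"{comment} {k} t= {t:.6f}\n")
            for lab, p in zip(fr.labels, fr.points):
                fh.write(
                    f"{lab.res_name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n"
                )


def read_xyz(path: str | Path) -> Trajectory:
    """Read the XYZ dialect written by :func:`write_xyz` (coordinates in Å)."""
    frames: list[Chain] = []
    times: list[float] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        comment = lines[i + 1]
        t = None
        toks = comment.split()
        if "t=" in toks:
            t = float(toks[toks.index("t=") + 1])
        rows = lines[i + 2 : i + 2 + n]
        if len(rows) < n:
            raise ValueError(f"truncated XYZ block at line {i + 1}")
        pts = np.empty((n, 3))
        names = []
        for j, row in enumerate(rows):
            f = row.split()
            names.append(f[0])
            pts[j] = [float(f[1]), float(f[2]), float(f[3])]
        labels = [ResidueLabel(j + 1, "A", nm) for j, nm in enumerate(names)]
        frames.append(Chain(pts, labels))
        if t is not None:
            times.append(t)
        i += 2 + n
    if frames and len(times) == len(frames) and len(set(times)) == len(times):
        return Trajectory(frames, np.array(times))
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# Tabular output


def write_series(table: pd.DataFrame | Iterable[dict], path: str | Path,
                 float_fmt: str = "%.4f") -> None:
    """Write a per-frame series as TSV with a header row and fixed decimals."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def read_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
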
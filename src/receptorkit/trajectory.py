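"""Trajectory container and multi-MODEL PDB input/output.

A :class:`Trajectory` is an ordered list of coordinate frames over a fixed
atom topology (chain, residue number/name, atom name, element), with frame
times in nanoseconds.  Multi-MODEL PDB files — one MODEL per frame — are the
text carrier; parsing goes through Biopython's PDB parser with cross-model
consistency checks on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HN"}

TOPOLOGY_COLUMNS = ["chain", "residue_number", "residue_name", "atom_name", "element"]


@dataclass
class Trajectory:
    """Frames of atom coordinates (Angstrom) over a fixed topology.

    Attributes
    ----------
    topology : DataFrame with columns chain, residue_number, residue_name,
        atom_name, element, is_backbone, is_heavy (one row per atom).
    frames : ndarray (n_frames, n_atoms, 3), Angstrom.
    frame_times : ndarray (n_frames,), nanoseconds, strictly increasing.
    """

    topology: pd.DataFrame
    frames: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.topology = self.topology.reset_index(drop=True)
        for col in ("is_backbone", "is_heavy"):
            if col not in self.topology.columns:
                self.topology[col] = _derived_flags(self.topology)[col]
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{len(self.topology)}"
            )
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must match number of frames")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        key = self.topology[["chain", "residue_number", "atom_name"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate atom {dup.chain}:{dup.residue_number}:{dup.atom_name}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def coords(self, frame: int) -> np.ndarray:
        return self.frames[frame]


def _derived_flags(top: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "is_backbone": top["atom_name"].isin(BACKBONE_ATOM_NAMES),
            "is_heavy": ~top["element"].isin(["H", "D"]),
        }
    )


def read_multimodel_pdb(path: str | Path, frame_dt_ns: float = 1.0) -> Trajectory:
    """Read a multi-MODEL PDB file into a Trajectory.

    Topology is taken from the first MODEL; every later MODEL must contain the
    same number of atoms.  Elements come from columns 77-78 when present,
    otherwise Biopython's atom-name inference applies (so ``" CA "`` is a
    carbon, not calcium).  Frame times are assigned as multiples of
    ``frame_dt_ns`` (PDB carries no time axis).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"{path}: unparsable PDB record: {exc}") from exc
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no MODEL records / coordinates found")

    rows = []
    coords_first = []
    for atom in models[0].get_atoms():
        _, _, chain_id, (_, resnum, _), (name, _) = atom.get_full_id()
        residue = atom.get_parent()
        rows.append(
            {
                "chain": chain_id,
                "residue_number": int(resnum),
                "residue_name": residue.get_resname().strip(),
                "atom_name": name.strip(),
                "element": (atom.element or "").strip().upper(),
            }
        )
        coords_first.append(atom.coord)
    topology = pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS)

    frames = [np.asarray(coords_first, dtype=float)]
    for k, model in enumerate(models[1:], start=2):
        coords = np.asarray([a.coord for a in model.get_atoms()], dtype=float)
        if coords.shape[0] != len(topology):
            raise ValueError(
                f"{path}: MODEL {k} has {coords.shape[0]} atoms, "
                f"MODEL 1 has {len(topology)}"
            )
        frames.append(coords)
    times = np.arange(len(frames), dtype=float) * frame_dt_ns
    return Trajectory(topology=topology, frames=np.stack(frames), frame_times=times)


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name field (cols 13-16): 1-char elements start at col 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-MODEL PDB (coordinates at 0.001 A precision)."""
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            coords = traj.frames[f]
            for i, row in enumerate(top.itertuples()):
                x, y, z = coords[i]
                name = _format_atom_name(row.atom_name, row.element)
                fh.write(
                    f"ATOM  {i + 1:5d} {name}{'':1s}{row.residue_name:>3s} "
                    f"{row.chain[:1]:1s}{row.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {row.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
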
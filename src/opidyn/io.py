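"""Reading and writing structures and trajectories.

Topology comes from a PDB file (author residue numbering preserved, waters
and the ligand flagged by residue name).  Frames come either from a binary
trajectory (DCD/XTC, read through MDAnalysis against the PDB topology) or
from a plain-text CSV dialect intended for human-inspectable fixtures:

    frame,atom_index,x,y,z

with 0-based ``frame`` and ``atom_index`` and coordinates in Å.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import FormatError
from .structure import MolecularSystem

WATER_RESNAMES = {"HOH", "WAT", "TIP", "SOL"}

CSV_HEADER = "frame,atom_index,x,y,z"


def _role(res_name: str, het: bool, ligand_resname: str) -> str:
    if res_name in WATER_RESNAMES:
        return "water"
    if res_name == ligand_resname:
        return "ligand"
    return "protein"


def read_pdb(path: str | os.PathLike, ligand_resname: str = "LIG") -> tuple[pd.DataFrame, np.ndarray]:
    """Parse a PDB file into an atom table and a single coordinate frame."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    rows, xyz = [], []
    model = st[0]
    for chain in model:
        for res in chain:
            role = _role(res.name, res.het_flag == "H", ligand_resname)
            for atom in res:
                rows.append(
                    dict(
                        name=atom.name,
                        element=atom.element.name,
                        chain_id=chain.name,
                        res_number=res.seqid.num,
                        res_name=res.name,
                        role=role,
                    )
                )
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not rows:
        raise FormatError(f"{path}: no atoms parsed")
    return pd.DataFrame(rows), np.asarray(xyz, dtype=float)


def write_pdb(system: MolecularSystem, path: str | os.PathLike,
              frame_index: int = 0) -> None:
    """Write one frame of a system as a PDB file (author numbering kept)."""
    st = gemmi.Structure()
    st.name = "opidyn"
    model = gemmi.Model("1")
    frame = system.frame(frame_index)
    for chain_id in system.atoms.chain_id.unique():
        chain = gemmi.Chain(str(chain_id))
        sub = system.atoms[system.atoms.chain_id == chain_id]
        for res_number in sub.res_number.unique():
            res_rows = sub[sub.res_number == res_number]
            res = gemmi.Residue()
            res.name = str(res_rows.iloc[0].res_name)
            res.seqid = gemmi.SeqId(int(res_number), " ")
            res.het_flag = "A" if res_rows.iloc[0].role == "protein" else "H"
            for i, row in res_rows.iterrows():
                atom = gemmi.Atom()
                atom.name = str(row["name"])
                atom.element = gemmi.Element(str(row.element))
                x, y, z = frame[i]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def read_csv_frames(path: str | os.PathLike, n_atoms: int) -> np.ndarray:
    """Read the CSV frame dialect into an (n_frames, n_atoms, 3) array."""
    df = pd.read_csv(path)
    expected = CSV_HEADER.split(",")
    if list(df.columns) != expected:
        raise FormatError(f"{path}: header must be '{CSV_HEADER}'")
    frames = df.frame.unique()
    if not np.array_equal(np.sort(frames), np.arange(len(frames))):
        raise FormatError(f"{path}: frame indices must be 0..n-1")
    counts = df.groupby("frame").size()
    if counts.nunique() != 1 or counts.iloc[0] != n_atoms:
        raise FormatError(
            f"{path}: every frame must carry exactly {n_atoms} atoms "
            f"(got counts {sorted(counts.unique())})"
        )
    df = df.sort_values(["frame", "atom_index"])
    if not np.array_equal(
        df.atom_index.to_numpy().reshape(len(frames), n_atoms),
        np.tile(np.arange(n_atoms), (len(frames), 1)),
    ):
        raise FormatError(f"{path}: atom_index must cover 0..{n_atoms - 1} per frame")
    return df[["x", "y", "z"]].to_numpy(dtype=float).reshape(len(frames), n_atoms, 3)


def write_csv_frames(coords: np.ndarray, path: str | os.PathLike) -> None:
    """Write an (n_frames, n_atoms, 3) stack in the CSV frame dialect."""
    n_frames, n_atoms, _ = coords.shape
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    atom_col = np.tile(np.arange(n_atoms), n_frames)
    flat = coords.reshape(-1, 3)
    df = pd.DataFrame(
        {"frame": frame_col, "atom_index": atom_col,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.4f")


def _read_binary_frames(topology_pdb: str | os.PathLike,
                        traj_path: str | os.PathLike, n_atoms: int) -> np.ndarray:
    import MDAnalysis as mda

    u = mda.Universe(str(topology_pdb), str(traj_path))
    if len(u.atoms) != n_atoms:
        raise FormatError(
            f"{traj_path}: trajectory has {len(u.atoms)} atoms, topology {n_atoms}"
        )
    return np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])


def write_binary_frames(system: MolecularSystem, topology_pdb: str | os.PathLike,
                        traj_path: str | os.PathLike) -> None:
    """Write the system's frames as DCD or XTC (by extension) via MDAnalysis."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology_pdb))
    with mda.Writer(str(traj_path), n_atoms=system.n_atoms) as w:
        for f in range(system.n_frames):
            u.atoms.positions = system.frame(f).astype(np.float32)
            w.write(u.atoms)


def load_structure(
    path: str | os.PathLike,
    ligand_spec: dict[str, list[str]],
    traj_path: str | os.PathLike | None = None,
    ligand_resname: str = "LIG",
    frame_interval_ps: float = 100.0,
) -> MolecularSystem:
    """Build a :class:`MolecularSystem` from a PDB file and optional trajectory.

    ``ligand_spec`` maps feature-group names to ligand atom names.  With no
    trajectory the PDB's own coordinates form a single frame; otherwise the
    trajectory (``.csv`` dialect, or ``.dcd``/``.xtc`` via MDAnalysis)
    supplies the frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms, frame0 = read_pdb(path, ligand_resname=ligand_resname)
    if traj_path is None:
        coords = frame0[None]
    else:
        traj_path = Path(traj_path)
        if not traj_path.exists():
            raise FileNotFoundError(traj_path)
        if traj_path.suffix.lower() == ".csv":
            coords = read_csv_frames(traj_path, n_atoms=len(atoms))
        elif traj_path.suffix.lower() in {".dcd", ".xtc"}:
            coords = _read_binary_frames(path, traj_path, n_atoms=len(atoms))
        else:
            raise FormatError(f"unsupported trajectory format: {traj_path.suffix}")
    return MolecularSystem(atoms, coords, ligand_spec,
                           frame_interval_ps=frame_interval_ps)
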
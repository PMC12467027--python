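"""File I/O: PDB structures, ligand topology sidecars, trajectory text format.

Trajectory format (plain text, whitespace-separated)::

    # fragsite trajectory v1
    natoms <N>
    time_per_frame_ns <dt>
    frame <t_ns>
    x y z            (N lines)
    frame <t_ns>
    ...

with a sidecar TSV atom table (columns: index resid resname atom_name element
heavy mass).  Ligands are written as a PDB (HETATM coordinate records) plus a
JSON topology sidecar holding elements, atom classes, bonds, and rotatable
dihedrals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .ligand_model import Atom, Ligand, Pose, RotatableDihedral
from .synthetic_data import ReceptorFixture
from .trajectory_metrics import Trajectory, TrajectoryError


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _atom_array(coords: np.ndarray, table: pd.DataFrame, hetero: bool) -> bst.AtomArray:
    n = len(table)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = table["resid"].to_numpy(dtype=int)
    arr.res_name = table["resname"].to_numpy(dtype="U5")
    arr.atom_name = table["atom_name"].to_numpy(dtype="U6")
    arr.element = table["element"].to_numpy(dtype="U2")
    arr.hetero = np.full(n, hetero)
    return arr


def write_receptor_pdb(fixture: ReceptorFixture, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_atom_array(fixture.coordinates, fixture.atom_table, False))
    pdb.write(str(path))


def read_structure_pdb(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read any single-model PDB into (coords, atom table)."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    table = pd.DataFrame({
        "resid": arr.res_id,
        "resname": arr.res_name,
        "atom_name": arr.atom_name,
        "element": arr.element,
        "heavy": arr.element != "H",
        "mass": [bst.info.mass(e) or 12.011 for e in arr.element],
    })
    return np.asarray(arr.coord, dtype=float), table


def write_poses_pdb(poses: list[Pose], path) -> None:
    """Ranked poses as a multi-model PDB of HETATM records."""
    pdb = PDBFile()
    stack_coords = np.stack([p.coords for p in poses]).astype(np.float32)
    lig = poses[0].ligand
    table = pd.DataFrame({
        "resid": np.ones(lig.n_atoms, dtype=int),
        "resname": "LIG",
        "atom_name": [a.name or f"{a.element}{i+1}" for i, a in enumerate(lig.atoms)],
        "element": [a.element for a in lig.atoms],
    })
    stack = bst.AtomArrayStack(len(poses), lig.n_atoms)
    stack.coord = stack_coords
    stack.chain_id = np.full(lig.n_atoms, "A")
    stack.res_id = table["resid"].to_numpy(dtype=int)
    stack.res_name = table["resname"].to_numpy(dtype="U5")
    stack.atom_name = table["atom_name"].to_numpy(dtype="U6")
    stack.element = table["element"].to_numpy(dtype="U2")
    stack.hetero = np.full(lig.n_atoms, True)
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Ligands: PDB coordinates + JSON topology sidecar
# ---------------------------------------------------------------------------

def write_ligand(ligand: Ligand, pdb_path, sidecar_path) -> None:
    table = pd.DataFrame({
        "resid": np.ones(ligand.n_atoms, dtype=int),
        "resname": "LIG",
        "atom_name": [a.name or f"{a.element}{i+1}" for i, a in enumerate(ligand.atoms)],
        "element": [a.element for a in ligand.atoms],
    })
    pdb = PDBFile()
    pdb.set_structure(_atom_array(ligand.coords, table, True))
    pdb.write(str(pdb_path))
    sidecar = {
        "name": ligand.name,
        "atoms": [
            {"element": a.element, "atom_class": a.atom_class,
             "is_hydrogen": a.is_hydrogen, "name": a.name}
            for a in ligand.atoms
        ],
        "bonds": [list(b) for b in ligand.bonds],
        "rotatable_dihedrals": [
            {"indices": list(t.indices), "downstream": sorted(t.downstream)}
            for t in ligand.rotatable_dihedrals
        ],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_ligand(pdb_path, sidecar_path) -> Ligand:
    coords, _ = read_structure_pdb(pdb_path)
    meta = json.loads(Path(sidecar_path).read_text())
    atoms = [Atom(element=a["element"], atom_class=a["atom_class"],
                  is_hydrogen=a["is_hydrogen"], name=a.get("name", ""))
             for a in meta["atoms"]]
    torsions = [RotatableDihedral(indices=tuple(t["indices"]),
                                  downstream=frozenset(t["downstream"]))
                for t in meta["rotatable_dihedrals"]]
    return Ligand(name=meta["name"], atoms=atoms, coords=coords,
                  bonds=[tuple(b) for b in meta["bonds"]],
                  rotatable_dihedrals=torsions)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, traj_path, table_path) -> None:
    with open(traj_path, "w") as fh:
        fh.write("# fragsite trajectory v1\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        fh.write(f"time_per_frame_ns {traj.time_per_frame!r}\n")
        for f, t in enumerate(traj.times()):
            fh.write(f"frame {t!r}\n")
            np.savetxt(fh, traj.coordinates[f], fmt="%.6f")
    traj.atom_table.to_csv(table_path, sep="\t", index_label="index")


def read_trajectory(traj_path, table_path) -> Trajectory:
    table = pd.read_csv(table_path, sep="\t", index_col="index")
    with open(traj_path) as fh:
        header = fh.readline()
        if not header.startswith("# fragsite trajectory"):
            raise TrajectoryError(f"{traj_path}: not a fragsite trajectory file")
        natoms = int(fh.readline().split()[1])
        dt = float(fh.readline().split()[1])
        frames = []
        line = fh.readline()
        while line:
            if not line.startswith("frame"):
                raise TrajectoryError(f"{traj_path}: expected 'frame' line, got {line!r}")
            block = [fh.readline() for _ in range(natoms)]
            frames.append(np.loadtxt(block).reshape(natoms, 3))
            line = fh.readline()
    return Trajectory(coordinates=np.stack(frames), atom_table=table,
                      time_per_frame=dt)
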
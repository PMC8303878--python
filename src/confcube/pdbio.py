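"""Multi-model PDB and manifest I/O.

Each replica trajectory is serialized as one standard multi-model PDB file
(MODEL/ENDMDL records, coordinates in angstroms); an ensemble is described by
a plain-text manifest with one ``path<TAB>dt_ps`` line per replica.  PDB has
no time field, so frame times are reconstructed as ``frame_index * dt_ps``.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import Frame, Topology, Trajectory
from .errors import ValidationError

__all__ = [
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_manifest",
    "read_manifest",
    "write_ensemble",
    "read_ensemble",
]

# %8.3f coordinate columns admit [-999.999, 9999.999] angstrom
_PDB_MIN_A = -999.999
_PDB_MAX_A = 9999.999


def _to_atom_array_stack(traj: Trajectory) -> struc.AtomArrayStack:
    coords_A = traj.coords * 10.0
    if coords_A.min() < _PDB_MIN_A or coords_A.max() > _PDB_MAX_A:
        raise ValidationError(
            "coordinates exceed the fixed-width PDB range "
            f"[{_PDB_MIN_A}, {_PDB_MAX_A}] angstrom; refusing to clamp"
        )
    top = traj.topology
    stack = struc.AtomArrayStack(traj.n_frames, top.n_atoms)
    stack.coord = coords_A
    stack.chain_id = top.chain_ids
    stack.res_id = top.res_ids
    stack.res_name = top.res_names
    stack.atom_name = top.atom_names
    stack.element = top.elements
    stack.hetero = np.zeros(top.n_atoms, dtype=bool)
    return stack


def write_trajectory_pdb(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a multi-model PDB file (coordinates in angstrom)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(traj))
    pdb.write(str(path))


def _dihedral_sidecar(pdb_path: Path) -> Path:
    """Path of the optional per-replica (phi, psi) sidecar table.

    PDB has no dihedral field and bead models have no N/CA/C backbone, so
    planted dihedral metadata travels in a plain-text sidecar next to each
    replica file.
    """
    return pdb_path.parent / (pdb_path.stem + ".phipsi.tsv")


def read_trajectory_pdb(path: str | os.PathLike, dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file; frame times become ``i * dt_ps``.

    A ``<name>.phipsi.tsv`` sidecar, when present, restores per-residue
    (phi, psi) metadata for every frame.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single MODEL
        stack = struc.stack([stack])
    top = Topology(
        atom_names=stack.atom_name,
        res_names=stack.res_name,
        res_ids=stack.res_id,
        chain_ids=stack.chain_id,
        elements=stack.element,
    )
    n_frames = stack.stack_depth()
    times = np.arange(n_frames) * float(dt_ps)
    dihedrals = None
    sidecar = _dihedral_sidecar(path)
    if sidecar.exists():
        flat = np.loadtxt(sidecar, ndmin=2)
        dihedrals = flat.reshape(n_frames, -1, 2)
    return Trajectory(
        top, np.asarray(stack.coord, dtype=float) / 10.0, times, dihedrals
    )


def write_manifest(
    manifest_path: str | os.PathLike, entries: list[tuple[str, float]]
) -> None:
    """Write the ensemble manifest: one ``relative_path<TAB>dt_ps`` line each."""
    lines = [f"{rel}\t{dt:g}" for rel, dt in entries]
    Path(manifest_path).write_text("\n".join(lines) + "\n")


def read_manifest(manifest_path: str | os.PathLike) -> list[tuple[Path, float]]:
    manifest_path = Path(manifest_path)
    entries: list[tuple[Path, float]] = []
    for lineno, line in enumerate(manifest_path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{manifest_path}:{lineno}: expected 'path<TAB>dt_ps', got {line!r}"
            )
        entries.append((manifest_path.parent / parts[0], float(parts[1])))
    if not entries:
        raise ValidationError(f"manifest {manifest_path} lists no replicas")
    return entries


def write_ensemble(
    trajectories: list[Trajectory],
    directory: str | os.PathLike,
    manifest_name: str = "manifest.txt",
) -> Path:
    """Write one multi-model PDB per replica plus a manifest; return its path."""
    if not trajectories:
        raise ValidationError("cannot write an empty ensemble")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, traj in enumerate(trajectories):
        name = f"replica_{i:04d}.pdb"
        write_trajectory_pdb(traj, directory / name)
        if traj.dihedrals is not None:
            np.savetxt(
                _dihedral_sidecar(directory / name),
                traj.dihedrals.reshape(-1, 2),
                fmt="%.4f",
                header="phi psi (degrees), one row per (frame, residue)",
            )
        dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
        entries.append((name, dt))
    manifest = directory / manifest_name
    write_manifest(manifest, entries)
    return manifest


def read_ensemble(manifest_path: str | os.PathLike) -> list[Trajectory]:
    """Read every replica listed in a manifest, in manifest order."""
    return [read_trajectory_pdb(p, dt) for p, dt in read_manifest(manifest_path)]
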
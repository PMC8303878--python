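"""In-memory containers for trajectories of a single molecular topology.

Coordinates are stored in nanometres throughout the package (the GROMACS
convention); PDB serialization converts to/from angstroms at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructureMismatchError, ValidationError

__all__ = ["Topology", "Frame", "Trajectory"]


@dataclass
class Topology:
    """Per-atom metadata shared by every frame of a trajectory.

    Parameters
    ----------
    atom_names, res_names, chain_ids, elements : arrays of str, length n_atoms
    res_ids : array of int
        1-based residue identifiers, non-decreasing within each chain.
    masses : array of float, optional
        Atomic masses (u). When absent, metrics that need masses
        (centre of mass, radius of gyration) assume equal masses.
    """

    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.res_names = np.asarray(self.res_names, dtype="U5")
        self.res_ids = np.asarray(self.res_ids, dtype=np.int64)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.elements = np.asarray(self.elements, dtype="U2")
        n = len(self.atom_names)
        if n == 0:
            raise ValidationError("topology must contain at least one atom")
        for name in ("res_names", "res_ids", "chain_ids", "elements"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length does not match atom count {n}")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != n:
                raise ValidationError("masses length does not match atom count")
        for chain in np.unique(self.chain_ids):
            ids = self.res_ids[self.chain_ids == chain]
            if np.any(np.diff(ids) < 0):
                raise ValidationError(
                    f"residue ids must be non-decreasing within chain {chain!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, res_id) pairs, in atom order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_ids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def effective_masses(self) -> np.ndarray:
        if self.masses is not None:
            return self.masses
        return np.ones(self.n_atoms)

    def same_layout(self, other: "Topology") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and bool(np.all(self.atom_names == other.atom_names))
            and bool(np.all(self.res_ids == other.res_ids))
            and bool(np.all(self.chain_ids == other.chain_ids))
        )

    def require_same_layout(self, other: "Topology") -> None:
        if not self.same_layout(other):
            raise StructureMismatchError("atom layouts differ between structures")


def _check_coords(coords: np.ndarray, n_atoms: int, ndim: int) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != ndim or coords.shape[-1] != 3 or coords.shape[-2] != n_atoms:
        raise ValidationError(f"coordinates must have shape (..., {n_atoms}, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coordinates must be finite")
    return coords


@dataclass
class Frame:
    """One conformation: coordinates (nm) + topology + time stamp (ps).

    ``dihedrals`` optionally carries per-residue (phi, psi) angles in degrees
    for bead models that have no backbone N/CA/C atoms.
    """

    topology: Topology
    coords: np.ndarray
    time_ps: float = 0.0
    dihedrals: np.ndarray | None = None

    def __post_init__(self):
        self.coords = _check_coords(self.coords, self.topology.n_atoms, 2)
        if self.dihedrals is not None:
            self.dihedrals = np.asarray(self.dihedrals, dtype=float)
            if self.dihedrals.shape != (self.topology.n_residues, 2):
                raise ValidationError(
                    "dihedrals must have shape (n_residues, 2) [phi, psi in degrees]"
                )

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


@dataclass
class Trajectory:
    """A time-ordered stack of frames sharing one topology."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    times: np.ndarray  # (n_frames,) ps
    dihedrals: np.ndarray | None = None  # (n_frames, n_residues, 2) degrees

    def __post_init__(self):
        self.coords = _check_coords(self.coords, self.topology.n_atoms, 3)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coords.shape[0],):
            raise ValidationError("times length must equal the number of frames")
        if self.dihedrals is not None:
            self.dihedrals = np.asarray(self.dihedrals, dtype=float)
            expected = (self.n_frames, self.topology.n_residues, 2)
            if self.dihedrals.shape != expected:
                raise ValidationError(f"dihedrals must have shape {expected}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        dih = None if self.dihedrals is None else self.dihedrals[i]
        return Frame(self.topology, self.coords[i], float(self.times[i]), dih)

    def duration_ps(self) -> float:
        return float(self.times[-1] - self.times[0])
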
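"""Synthetic replica ensembles with planted conformational basins.

The generator emulates the study design this package analyses: many short
replica trajectories branch from one shared reference conformation and relax
into one of ``k`` distinct final basins, with basin membership drawn once per
replica from fixed population weights. The "protein" is a coarse bead chain —
one CA-labelled bead per residue arranged as a four-helix bundle — so that
residue-level metrics (contacts, distances, helix content via planted
dihedrals) are all exercisable without any molecular-dynamics engine.

A companion generator plants a toy bilayer of phosphate marker particles in
two leaflets at a chosen mean separation, for the thickness/TM-potential
stage.

No physics is simulated: frames are basin targets plus isotropic Gaussian
jitter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Topology, Trajectory
from .errors import StructureMismatchError, ValidationError
from .membrane import BilayerModel

__all__ = [
    "BasinSpec",
    "EnsembleSpec",
    "SyntheticEnsemble",
    "make_reference_bundle",
    "make_basin_targets",
    "draw_basin_assignments",
    "generate_basin_ensemble",
    "generate_bilayer",
]

HELIX_DIHEDRAL = (-57.0, -47.0)
EXTENDED_DIHEDRAL = (-140.0, 150.0)


@dataclass(frozen=True)
class BasinSpec:
    """One planted conformational basin.

    ``target_coordinates`` is the basin's mean conformation (nm), sharing
    atom count and ordering with the ensemble reference;
    ``population_weight`` is the probability a replica ends here; ``jitter_sd``
    the per-coordinate Gaussian noise (nm). ``target_dihedrals`` optionally
    plants per-residue (phi, psi) metadata for the basin.
    """

    basin_id: int
    target_coordinates: np.ndarray
    population_weight: float
    jitter_sd: float = 0.02
    target_dihedrals: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "target_coordinates", np.asarray(self.target_coordinates, dtype=float)
        )
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")


@dataclass
class EnsembleSpec:
    """Ensemble layout: replica/frame counts, switch frame, seed, reference.

    ``switch_frame`` is the frame index at which a replica leaves the
    reference basin (frames before it sample the reference). Total frame
    count is exactly ``n_replicas * frames_per_replica`` — frame totals are
    user-chosen, and no padding to reach a foreign total is performed
    (e.g. 34 x 143 = 4862, never 4863).
    """

    n_replicas: int
    frames_per_replica: int
    switch_frame: int
    seed: int
    reference: Frame
    dt_ps: float = 500.0

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValidationError("n_replicas must be >= 1")
        if self.frames_per_replica < 2:
            raise ValidationError("frames_per_replica must be >= 2")
        if not 0 < self.switch_frame < self.frames_per_replica:
            raise ValidationError("switch_frame must satisfy 0 < switch < frames")


@dataclass
class SyntheticEnsemble:
    trajectories: list[Trajectory]
    basin_assignments: np.ndarray  # basin index per replica


def _helix_bead(k: int, center_xy, z0: float, direction: int) -> np.ndarray:
    """Idealized CA-helix geometry: 0.23 nm radius, 0.15 nm rise, 100 deg/res."""
    angle = np.radians(100.0 * k)
    return np.array(
        [
            center_xy[0] + 0.23 * np.cos(angle),
            center_xy[1] + 0.23 * np.sin(angle),
            z0 + direction * 0.15 * k,
        ]
    )


def make_reference_bundle(n_per_helix: int = 33, n_loop: int = 5) -> Frame:
    """Coarse four-helix bundle reference (one CA bead per residue).

    Four antiparallel helices at the corners of a 1.2 nm square, joined by
    straight loops; helical residues carry planted (phi, psi) = (-57, -47)
    and loop residues an extended (phi, psi).
    """
    centers = [(-0.6, -0.6), (0.6, -0.6), (0.6, 0.6), (-0.6, 0.6)]
    height = 0.15 * (n_per_helix - 1)
    coords: list[np.ndarray] = []
    helical: list[bool] = []
    for h, center in enumerate(centers):
        direction = 1 if h % 2 == 0 else -1
        z0 = 0.0 if direction == 1 else height
        start = _helix_bead(0, center, z0, direction)
        if h > 0:
            prev_end = coords[-1]
            for j in range(1, n_loop + 1):
                t = j / (n_loop + 1)
                coords.append(prev_end + t * (start - prev_end))
                helical.append(False)
        for k in range(n_per_helix):
            coords.append(_helix_bead(k, center, z0, direction))
            helical.append(True)
    coords_arr = np.asarray(coords)
    n = len(coords_arr)
    top = Topology(
        atom_names=np.full(n, "CA"),
        res_names=np.full(n, "ALA"),
        res_ids=np.arange(1, n + 1),
        chain_ids=np.full(n, "A"),
        elements=np.full(n, "C"),
    )
    dihedrals = np.array(
        [HELIX_DIHEDRAL if flag else EXTENDED_DIHEDRAL for flag in helical]
    )
    return Frame(top, coords_arr, time_ps=0.0, dihedrals=dihedrals)


def _rotate_z(points: np.ndarray, angle_deg: float, pivot: np.ndarray) -> np.ndarray:
    a = np.radians(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    return (points - pivot) @ R.T + pivot


def make_basin_targets(
    reference: Frame,
    separations=(0.8, 1.6, 2.4, 3.2),
    unfold_fractions=(0.0, 0.15, 0.30, 0.45),
    weights=(0.38, 0.24, 0.19, 0.19),
    jitter_sd: float = 0.02,
) -> list[BasinSpec]:
    """Build basin targets by sub-domain displacement plus partial unfolding.

    The bundle is split into two two-helix sub-domains; basin *i* translates
    the second sub-domain by ``separations[i]`` nm (with a compensating
    rotation) and lays out the tail ``unfold_fractions[i]`` of the chain on
    an extended line, so both the fraction of native contacts and residue
    distances discriminate basins, and discriminate them monotonically in
    the displacement.
    """
    if not (len(separations) == len(unfold_fractions) == len(weights)):
        raise ValidationError("separations, unfold_fractions, weights lengths differ")
    n = reference.n_atoms
    half = n // 2
    basins = []
    for i, (sep, unfold, w) in enumerate(zip(separations, unfold_fractions, weights)):
        coords = reference.coords.copy()
        dihedrals = reference.dihedrals.copy()
        sub = coords[half:]
        pivot = sub.mean(axis=0)
        sub = _rotate_z(sub, 25.0 * i, pivot)
        sub = sub + np.array([sep, 0.4 * i, 0.0])
        coords[half:] = sub
        n_unfold = int(round(unfold * half))
        if n_unfold > 0:
            tail = slice(n - n_unfold, n)
            origin = coords[n - n_unfold - 1]
            direction = np.array([0.9, 0.3, 0.3])
            direction /= np.linalg.norm(direction)
            steps = np.arange(1, n_unfold + 1)[:, None]
            coords[tail] = origin + 0.36 * steps * direction
            dihedrals[tail] = EXTENDED_DIHEDRAL
        basins.append(
            BasinSpec(
                basin_id=i,
                target_coordinates=coords,
                population_weight=w,
                jitter_sd=jitter_sd,
                target_dihedrals=dihedrals,
            )
        )
    return basins


def _validate_basins(spec: EnsembleSpec, basins: list[BasinSpec]) -> np.ndarray:
    if not basins:
        raise ValidationError("at least one basin is required")
    n = spec.reference.n_atoms
    for b in basins:
        if b.target_coordinates.shape != (n, 3):
            raise StructureMismatchError(
                f"basin {b.basin_id}: atom count differs from the reference"
            )
    weights = np.array([b.population_weight for b in basins], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-12:
        raise ValidationError(
            f"population weights must sum to 1 (got {weights.sum()!r})"
        )
    return weights


def draw_basin_assignments(
    n_replicas: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One categorical draw per replica (no back-transitions)."""
    return rng.choice(len(weights), size=n_replicas, p=np.asarray(weights, dtype=float))


def generate_basin_ensemble(
    spec: EnsembleSpec, basins: list[BasinSpec]
) -> SyntheticEnsemble:
    """Generate the replica ensemble.

    Each replica samples ``reference + jitter`` before ``switch_frame`` and
    ``basin_target + jitter`` from it onward, with the basin drawn once per
    replica from the population weights. Fully reproducible from
    ``spec.seed`` (bitwise-identical coordinates across runs).
    """
    weights = _validate_basins(spec, basins)
    rng = np.random.default_rng(spec.seed)
    assignments = draw_basin_assignments(spec.n_replicas, weights, rng)
    ref = spec.reference
    n_res = ref.topology.n_residues
    times = np.arange(spec.frames_per_replica) * spec.dt_ps
    trajectories = []
    for r in range(spec.n_replicas):
        basin = basins[assignments[r]]
        coords = np.empty((spec.frames_per_replica, ref.n_atoms, 3))
        jitter = rng.normal(0.0, 1.0, size=coords.shape) * basin.jitter_sd
        coords[: spec.switch_frame] = ref.coords
        coords[spec.switch_frame :] = basin.target_coordinates
        coords += jitter
        dihedrals = None
        if ref.dihedrals is not None:
            dihedrals = np.empty((spec.frames_per_replica, n_res, 2))
            dihedrals[: spec.switch_frame] = ref.dihedrals
            basin_dih = (
                basin.target_dihedrals
                if basin.target_dihedrals is not None
                else ref.dihedrals
            )
            dihedrals[spec.switch_frame :] = basin_dih
        trajectories.append(Trajectory(ref.topology, coords, times.copy(), dihedrals))
    return SyntheticEnsemble(trajectories, assignments)


def generate_bilayer(
    n_per_leaflet: int,
    separation: float,
    noise_sd: float,
    seed: int,
    n_frames: int = 1,
    box_xy: float = 8.0,
) -> BilayerModel:
    """Toy bilayer: two leaflets of markers at mean z = +/- separation / 2.

    Marker xy positions are uniform in a ``box_xy`` x ``box_xy`` patch; z
    positions get per-frame Gaussian noise of ``noise_sd`` nm.
    """
    if n_per_leaflet < 1:
        raise ValidationError("n_per_leaflet must be >= 1")
    if separation <= 0:
        raise ValidationError("separation must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_leaflet
    leaflet = np.concatenate([np.ones(n_per_leaflet, int), -np.ones(n_per_leaflet, int)])
    xy = rng.uniform(0.0, box_xy, size=(n, 2))
    z_mean = leaflet * separation / 2.0
    positions = np.empty((n_frames, n, 3))
    positions[:, :, :2] = xy
    positions[:, :, 2] = z_mean
    if noise_sd > 0:
        positions[:, :, 2] += rng.normal(0.0, noise_sd, size=(n_frames, n))
    return BilayerModel(positions=positions, leaflet=leaflet)
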
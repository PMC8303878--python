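"""Replica screening and tuple-cube construction.

The central data object is the *tuple cube*: for the ``F`` frames pooled
from all selected replicas, every ordered frame pair (X, Y) contributes one
triple ``(RMSD-XY, FNC-0X, FNC-0Y)`` — the least-squares-fit RMSD between
the two frames and each frame's fraction of native contacts relative to the
initial frame of its own replica. The cube therefore holds exactly ``F**2``
entries (diagonal and both orders included), each with full frame
provenance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory
from .errors import ValidationError
from .metrics import (
    ContactSet,
    fnc_over_frames,
    lowess_smooth,
    lsq_rmsd_to_reference,
    native_contacts,
    pairwise_lsq_rmsd,
)

__all__ = [
    "ReplicaSet",
    "TupleCube",
    "rmsd_vs_initial",
    "select_stable_replicas",
    "representative_replica",
    "rmsd_matrix",
    "fnc_series",
    "tuple_count",
    "build_tuple_cube",
]


@dataclass
class ReplicaSet:
    """Replicas plus the outcome of the stability screen.

    ``selected[i]`` is True iff replica ``i`` passed the final-window
    stability criterion; ``reasons[i]`` explains a rejection (None when
    selected).
    """

    replicas: list[Trajectory]
    selected: np.ndarray
    reasons: list[str | None]
    stability_window_ns: float
    stability_tolerance_nm: float

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)

    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass
class TupleCube:
    """(RMSD-XY, FNC-0X, FNC-0Y) triples over all ordered frame pairs.

    ``entries`` has shape (F**2, 3); provenance arrays give, per entry, the
    replica and original frame index of X and Y. Entry order is row-major in
    the pooled frame index (replica order, then frame order within replica).
    """

    entries: np.ndarray
    replica_x: np.ndarray
    frame_x: np.ndarray
    replica_y: np.ndarray
    frame_y: np.ndarray
    total_frames: int

    def __post_init__(self):
        if self.entries.shape != (self.total_frames**2, 3):
            raise ValidationError("entry count must equal total_frames**2")

    def __len__(self) -> int:
        return len(self.entries)


def rmsd_vs_initial(replica: Trajectory) -> np.ndarray:
    """Fit RMSD (nm) of every frame against the replica's first frame."""
    return lsq_rmsd_to_reference(replica.coords, replica.coords[0])


def select_stable_replicas(
    replicas: list[Trajectory],
    window_ns: float = 10.0,
    tolerance_nm: float = 0.05,
    smooth_frac: float | None = 0.1,
) -> ReplicaSet:
    """Keep replicas whose final-window RMSD stays within a tolerance band.

    The RMSD-vs-initial series (LOWESS-smoothed unless ``smooth_frac`` is
    None) must have max - min <= ``tolerance_nm`` over the last
    ``window_ns`` of the trajectory. Replicas shorter than the window are
    rejected with a reason rather than failing the run.
    """
    if window_ns <= 0:
        raise ValidationError("stability window must be positive")
    window_ps = window_ns * 1000.0
    selected = np.zeros(len(replicas), dtype=bool)
    reasons: list[str | None] = [None] * len(replicas)
    for i, rep in enumerate(replicas):
        if rep.duration_ps() < window_ps:
            reasons[i] = (
                f"trajectory spans {rep.duration_ps():.0f} ps "
                f"< stability window {window_ps:.0f} ps"
            )
            continue
        series = rmsd_vs_initial(rep)
        if smooth_frac is not None and len(series) >= 3:
            series = lowess_smooth(series, frac=smooth_frac, x=rep.times)
        in_window = rep.times >= rep.times[-1] - window_ps
        tail = series[in_window]
        spread = float(tail.max() - tail.min())
        if spread <= tolerance_nm:
            selected[i] = True
        else:
            reasons[i] = (
                f"final-window RMSD spread {spread:.4f} nm > "
                f"tolerance {tolerance_nm} nm"
            )
    return ReplicaSet(replicas, selected, reasons, window_ns, tolerance_nm)


def representative_replica(replica_set: ReplicaSet) -> int:
    """Replica whose final-frame RMSD is closest to the ensemble mean.

    Final-frame RMSD is measured against each replica's own initial frame;
    ties break to the lowest replica index.
    """
    idx = replica_set.selected_indices()
    if len(idx) == 0:
        raise ValidationError("no selected replicas")
    finals = np.array(
        [rmsd_vs_initial(replica_set.replicas[i])[-1] for i in idx]
    )
    mean = finals.mean()
    return int(idx[np.argmin(np.abs(finals - mean))])


def _pooled_frames(replica_set: ReplicaSet, stride: int, offset: int):
    if stride < 1 or offset < 0:
        raise ValidationError("stride must be >= 1 and offset >= 0")
    idx = replica_set.selected_indices()
    if len(idx) == 0:
        raise ValidationError("no selected replicas to pool")
    top = replica_set.replicas[idx[0]].topology
    coords_blocks, rep_ids, frame_ids = [], [], []
    for i in idx:
        rep = replica_set.replicas[i]
        rep.topology.require_same_layout(top)
        frames = np.arange(offset, rep.n_frames, stride)
        coords_blocks.append(rep.coords[frames])
        rep_ids.append(np.full(len(frames), i, dtype=np.int32))
        frame_ids.append(frames.astype(np.int32))
    coords = np.concatenate(coords_blocks, axis=0)
    if coords.shape[0] == 0:
        raise ValidationError("frame subsampling selected zero frames")
    return coords, np.concatenate(rep_ids), np.concatenate(frame_ids), idx


def rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-against-all fit RMSD matrix over pooled frames (F, n, 3), nm."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3:
        raise ValidationError("expected a frame stack of shape (F, n_atoms, 3)")
    return pairwise_lsq_rmsd(coords)


def fnc_series(
    replica: Trajectory,
    contacts: ContactSet | None = None,
    cutoff: float = 0.8,
    min_sequence_separation: int = 4,
    tolerance_factor: float = 1.2,
) -> np.ndarray:
    """FNC of every frame against the replica's initial frame.

    The contact set defaults to the native contacts of frame 0, so the
    series starts at exactly 1.
    """
    if contacts is None:
        contacts = native_contacts(replica.frame(0), cutoff, min_sequence_separation)
    return fnc_over_frames(replica.coords, contacts, tolerance_factor)


def tuple_count(total_frames: int) -> int:
    """Number of cube entries for ``F`` pooled frames: exactly F**2."""
    if total_frames < 0:
        raise ValidationError("total_frames must be non-negative")
    return int(total_frames) ** 2


def build_tuple_cube(
    replica_set: ReplicaSet,
    stride: int = 1,
    offset: int = 0,
    cutoff: float = 0.8,
    min_sequence_separation: int = 4,
    tolerance_factor: float = 1.2,
) -> TupleCube:
    """Construct the tuple cube from the selected replicas.

    Frames may be subsampled per replica (``offset`` then every ``stride``-th
    frame) *before* squaring; the FNC reference stays each replica's
    original first frame regardless of subsampling. Deterministic given
    replica order (manifest order).
    """
    coords, rep_ids, frame_ids, idx = _pooled_frames(replica_set, stride, offset)
    F = coords.shape[0]
    matrix = rmsd_matrix(coords)

    fnc_pooled = np.empty(F)
    for i in idx:
        rep = replica_set.replicas[i]
        contacts = native_contacts(rep.frame(0), cutoff, min_sequence_separation)
        mask = rep_ids == i
        fnc_pooled[mask] = fnc_over_frames(
            rep.coords[frame_ids[mask]], contacts, tolerance_factor
        )

    xi, yi = np.meshgrid(np.arange(F), np.arange(F), indexing="ij")
    xi = xi.ravel()
    yi = yi.ravel()
    entries = np.column_stack([matrix.ravel(), fnc_pooled[xi], fnc_pooled[yi]])
    return TupleCube(
        entries=entries,
        replica_x=rep_ids[xi],
        frame_x=frame_ids[xi],
        replica_y=rep_ids[yi],
        frame_y=frame_ids[yi],
        total_frames=F,
    )
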
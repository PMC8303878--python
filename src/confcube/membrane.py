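"""Bilayer thickness and transmembrane-potential estimation.

The membrane normal is taken along z (the external field in the simulated
systems points antiparallel to z). Thickness is the z-separation between the
centres of mass of the phosphate marker particles of the two leaflets, and
the transmembrane potential is the homogeneous-dielectric estimate
``dV = E * d`` (field magnitude in V/nm times thickness in nm).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "BilayerModel",
    "assign_leaflets",
    "bilayer_thickness",
    "thickness_series",
    "tm_potential",
]


@dataclass
class BilayerModel:
    """Marker-particle bilayer: positions (n_frames, n_markers, 3) in nm.

    ``leaflet`` holds +1 (upper) or -1 (lower) per marker; assignment is by
    the sign of z relative to the frame-0 centre of mass and is kept fixed
    for the whole trajectory (intact-leaflet assumption).
    """

    positions: np.ndarray
    leaflet: np.ndarray
    times: np.ndarray | None = None
    field_V_per_nm: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 3:
            raise ValidationError("positions must have shape (n_frames, n_markers, 3)")
        self.leaflet = np.asarray(self.leaflet, dtype=int)
        if self.leaflet.shape != (self.positions.shape[1],):
            raise ValidationError("leaflet must have one entry per marker")
        if not set(np.unique(self.leaflet)) <= {-1, 1}:
            raise ValidationError("leaflet entries must be +1 (upper) or -1 (lower)")
        if self.times is None:
            self.times = np.arange(self.positions.shape[0], dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def assign_leaflets(frame_positions: np.ndarray) -> np.ndarray:
    """Leaflet labels (+1/-1) by z-sign relative to the marker centre of mass."""
    frame_positions = np.asarray(frame_positions, dtype=float)
    z = frame_positions[:, 2]
    return np.where(z >= z.mean(), 1, -1)


def bilayer_thickness(frame_positions: np.ndarray, leaflet: np.ndarray) -> float:
    """|z(COM upper) - z(COM lower)| for one frame, nm."""
    leaflet = np.asarray(leaflet, dtype=int)
    z = np.asarray(frame_positions, dtype=float)[:, 2]
    upper = z[leaflet == 1]
    lower = z[leaflet == -1]
    if len(upper) == 0 or len(lower) == 0:
        raise ValidationError("both leaflets must contain at least one marker")
    return float(abs(upper.mean() - lower.mean()))


def thickness_series(model: BilayerModel):
    """Per-frame thickness (nm) plus its mean and sample SD.

    Returns ``(values, mean, sd)``; the SD is the sample (ddof=1) standard
    deviation, or 0 for a single frame.
    """
    values = np.array(
        [bilayer_thickness(model.positions[i], model.leaflet) for i in range(model.n_frames)]
    )
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return values, mean, sd


def tm_potential(E: float, d: float, d_sd: float | None = None):
    """Transmembrane potential dV = E * d (V), homogeneous-dielectric estimate.

    ``E`` in V/nm, ``d`` (thickness) in nm. If a thickness SD is supplied the
    propagated uncertainty ``sigma = E * d_sd`` is returned alongside.
    """
    if d < 0:
        raise ValidationError("thickness must be non-negative")
    dv = float(E) * float(d)
    if d_sd is None:
        return dv
    return dv, abs(float(E)) * float(d_sd)
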
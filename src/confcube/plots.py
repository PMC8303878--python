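"""Small static figures: RMSD series, thickness series, elbow curve."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import lowess_smooth

__all__ = ["plot_rmsd_series", "plot_thickness_series", "plot_elbow_curve"]


def plot_rmsd_series(times_ps, series_by_replica, path: str | Path, frac: float = 0.1):
    fig, ax = plt.subplots(figsize=(6, 4))
    for series in series_by_replica:
        ax.plot(np.asarray(times_ps) / 1000.0, series, color="lightblue", lw=0.6)
    mean = np.mean(series_by_replica, axis=0)
    ax.plot(np.asarray(times_ps) / 1000.0, lowess_smooth(mean, frac=frac), color="darkblue")
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("RMSD (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_thickness_series(times_ps, thickness_nm, path: str | Path, frac: float = 0.1):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.asarray(times_ps) / 1000.0, thickness_nm, lw=0.6, color="gray")
    if len(thickness_nm) >= 3:
        ax.plot(
            np.asarray(times_ps) / 1000.0,
            lowess_smooth(thickness_nm, frac=frac),
            color="black",
        )
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("thickness (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_elbow_curve(ks, explained_variance, k_selected: int, path: str | Path):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ks, explained_variance, "o-")
    ax.axvline(k_selected, color="red", ls="--", label=f"k = {k_selected}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("explained variance fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
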
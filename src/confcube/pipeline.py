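"""End-to-end staged pipeline: metrics -> selection -> cube -> clustering ->
free energies -> representatives -> characterization, with provenance-stamped
artifacts.

Every artifact written carries a header naming the package version, the
SHA-256 hash of the canonical configuration, and the seed, so a rerun with
the same configuration is attributable and (for the deterministic stages)
bitwise-identical.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ElbowKMeans,
    TupleKMeans,
    characterize_frame,
    free_energy_table,
    kde_representative,
)
from .core import Trajectory
from .cube import (
    ReplicaSet,
    build_tuple_cube,
    representative_replica,
    rmsd_vs_initial,
    select_stable_replicas,
)
from .errors import StageError, ValidationError
from .membrane import assign_leaflets, thickness_series, tm_potential, BilayerModel
from .pdbio import read_ensemble, read_trajectory_pdb, write_trajectory_pdb

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serializable, hashable for provenance)."""

    manifest: str
    output_dir: str
    field_V_per_nm: float | None = None
    bilayer_pdb: str | None = None
    temperature_K: float = 310.0
    stability_window_ns: float = 10.0
    stability_tolerance_nm: float = 0.05
    lowess_frac: float = 0.1
    fnc_cutoff_nm: float = 0.8
    fnc_min_separation: int = 4
    fnc_tolerance_factor: float = 1.2
    k_range: tuple[int, int] = (1, 10)
    fixed_k: int | None = None
    n_restarts: int = 10
    seed: int = 0
    cube_stride: int = 1
    cube_offset: int = 0
    standardize: bool = False
    cluster_init: str = "random"
    distance_pairs: tuple[tuple[int, int], ...] = ((20, 120), (40, 100), (10, 140))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} is not a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.k_range = tuple(cfg.k_range)  # type: ignore[assignment]
        cfg.distance_pairs = tuple(tuple(p) for p in cfg.distance_pairs)  # type: ignore[assignment]
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["distance_pairs"] = [list(p) for p in self.distance_pairs]
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise ValidationError(f"manifest does not exist: {self.manifest}")
        if self.bilayer_pdb is not None and not Path(self.bilayer_pdb).exists():
            raise ValidationError(f"bilayer PDB does not exist: {self.bilayer_pdb}")
        if self.seed is None:
            raise ValidationError("an explicit seed is required")
        if self.temperature_K <= 0:
            raise ValidationError("temperature must be positive")


@dataclass
class RunResult:
    """In-memory summary of a completed (or partial) run."""

    config: RunConfig
    output_dir: Path
    replica_set: ReplicaSet | None = None
    representative_index: int | None = None
    thickness_mean_nm: float | None = None
    thickness_sd_nm: float | None = None
    tm_potential_V: float | None = None
    tm_potential_sd_V: float | None = None
    total_frames: int | None = None
    n_tuples: int | None = None
    k: int | None = None
    cluster_counts: np.ndarray | None = None
    free_energy: object | None = None
    representatives: dict[int, tuple[int, int]] = field(default_factory=dict)
    characterizations: dict[str, object] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)


def _provenance_header(config: RunConfig) -> str:
    return (
        f"# confcube {__version__}\n"
        f"# config_sha256: {config.config_hash()}\n"
        f"# seed: {config.seed}\n"
    )


def _write_tsv(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> RunResult:
    """Execute the staged pipeline; artifacts land in ``output_dir``.

    ``stop_after`` truncates the run after the named stage ("metrics",
    "selection", "cube", "cluster"); the default runs everything through the
    report. A stage failure raises :class:`StageError` naming the stage;
    artifacts of completed stages are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(config=config, output_dir=out)
    (out / "config.yaml").write_text(
        _provenance_header(config) + yaml.safe_dump(config.to_dict())
    )

    stage = "load"
    try:
        replicas = read_ensemble(config.manifest)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    result.stages_completed.append(stage)

    stage = "metrics"
    try:
        rows = []
        for i, rep in enumerate(replicas):
            series = rmsd_vs_initial(rep)
            for t, v in zip(rep.times, series):
                rows.append((i, t, v))
        _write_tsv(
            out / "rmsd_series.tsv",
            pd.DataFrame(rows, columns=["replica", "time_ps", "rmsd_nm"]),
            config,
        )
        if len({rep.n_frames for rep in replicas}) == 1 and replicas[0].n_frames >= 3:
            from .plots import plot_rmsd_series

            plot_rmsd_series(
                replicas[0].times,
                [rmsd_vs_initial(rep) for rep in replicas],
                out / "rmsd_series.png",
                frac=min(1.0, config.lowess_frac),
            )
        if config.bilayer_pdb is not None:
            btraj = read_trajectory_pdb(config.bilayer_pdb)
            leaflet = assign_leaflets(btraj.coords[0])
            model = BilayerModel(positions=btraj.coords, leaflet=leaflet)
            values, mean, sd = thickness_series(model)
            _write_tsv(
                out / "thickness_series.tsv",
                pd.DataFrame(
                    {"time_ps": btraj.times, "thickness_nm": values, "unit": "nm"}
                ),
                config,
            )
            from .plots import plot_thickness_series

            plot_thickness_series(btraj.times, values, out / "thickness_series.png")
            result.thickness_mean_nm = mean
            result.thickness_sd_nm = sd
            if config.field_V_per_nm is not None:
                dv, dv_sd = tm_potential(config.field_V_per_nm, mean, sd)
                result.tm_potential_V = dv
                result.tm_potential_sd_V = dv_sd
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    result.stages_completed.append(stage)
    if stop_after == "metrics":
        return result

    stage = "selection"
    try:
        replica_set = select_stable_replicas(
            replicas,
            window_ns=config.stability_window_ns,
            tolerance_nm=config.stability_tolerance_nm,
            smooth_frac=config.lowess_frac,
        )
        result.replica_set = replica_set
        _write_tsv(
            out / "selection.tsv",
            pd.DataFrame(
                {
                    "replica": np.arange(len(replicas)),
                    "selected": replica_set.selected.astype(int),
                    "reason": [r or "" for r in replica_set.reasons],
                }
            ),
            config,
        )
        if replica_set.n_selected() == 0:
            raise StageError(stage, "no replica passed the stability screen")
        result.representative_index = representative_replica(replica_set)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    result.stages_completed.append(stage)
    if stop_after == "selection":
        return result

    stage = "cube"
    try:
        cube = build_tuple_cube(
            replica_set,
            stride=config.cube_stride,
            offset=config.cube_offset,
            cutoff=config.fnc_cutoff_nm,
            min_sequence_separation=config.fnc_min_separation,
            tolerance_factor=config.fnc_tolerance_factor,
        )
        result.total_frames = cube.total_frames
        result.n_tuples = len(cube)
        np.save(out / "tuple_cube.npy", cube.entries)
        prov = pd.DataFrame(
            {
                "entry_id": np.arange(len(cube)),
                "replica_x": cube.replica_x,
                "frame_x": cube.frame_x,
                "replica_y": cube.replica_y,
                "frame_y": cube.frame_y,
            }
        )
        _write_tsv(out / "tuple_provenance.tsv", prov, config)
        sample = pd.DataFrame(
            cube.entries[: min(len(cube), 1000)],
            columns=["rmsd_nm", "fnc_x", "fnc_y"],
        )
        _write_tsv(out / "tuple_sample.tsv", sample, config)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    result.stages_completed.append(stage)
    if stop_after == "cube":
        return result

    stage = "cluster"
    try:
        if config.fixed_k is not None:
            model = TupleKMeans(
                k=config.fixed_k,
                n_restarts=config.n_restarts,
                random_state=config.seed,
                standardize=config.standardize,
                init=config.cluster_init,
            ).fit(cube.entries)
            k = config.fixed_k
        else:
            model = ElbowKMeans(
                k_range=tuple(config.k_range),
                n_restarts=config.n_restarts,
                random_state=config.seed,
                standardize=config.standardize,
                init=config.cluster_init,
            ).fit(cube.entries)
            k = model.k_
            _write_tsv(
                out / "elbow_curve.tsv",
                pd.DataFrame(
                    {"k": model.ks_, "explained_variance": model.explained_variance_}
                ),
                config,
            )
            from .plots import plot_elbow_curve

            plot_elbow_curve(
                model.ks_, model.explained_variance_, k, out / "elbow_curve.png"
            )
        result.k = k
        result.cluster_counts = model.counts_
        _write_tsv(
            out / "cluster_assignments.tsv",
            pd.DataFrame(
                {
                    "entry_id": np.arange(len(cube)),
                    "cluster": model.labels_ + 1,
                }
            ),
            config,
        )
        fet = free_energy_table(model.counts_, config.temperature_K)
        result.free_energy = fet
        pairs = [
            (f"{i + 1}-{j + 1}", fet.dG[i, j])
            for i in range(k)
            for j in range(i + 1, k)
        ]
        _write_tsv(
            out / "free_energy.tsv",
            pd.DataFrame(pairs, columns=["clusters", "dG0_J_per_mol"]),
            config,
        )

        replicas_by_id = {i: replicas[i] for i in range(len(replicas))}
        for c in range(k):
            mask = model.labels_ == c
            prov_pairs = list(
                zip(cube.replica_x[mask], cube.frame_x[mask])
            )  # row frame of the tuple is the associated conformation
            (rep_id, frame_id), _ = kde_representative(
                cube.entries[mask], provenance=prov_pairs
            )
            result.representatives[c + 1] = (int(rep_id), int(frame_id))
            frame = replicas_by_id[int(rep_id)].frame(int(frame_id))
            single = Trajectory(
                frame.topology,
                frame.coords[None, :, :],
                np.array([frame.time_ps]),
            )
            write_trajectory_pdb(single, out / f"representative_cluster{c + 1}.pdb")
            record = characterize_frame(frame, list(config.distance_pairs))
            result.characterizations[f"cluster_{c + 1}"] = record
        initial = replicas_by_id[int(replica_set.selected_indices()[0])].frame(0)
        result.characterizations["initial"] = characterize_frame(
            initial, list(config.distance_pairs)
        )
        rows = []
        for name, rec in result.characterizations.items():
            row = {
                "frame": name,
                "rgyr_nm": rec.rgyr_nm,
                "sasa_A2": rec.sasa_A2,
                "helix_percent": rec.helix_percent,
            }
            row.update({f"dist_{k_}_A": v for k_, v in rec.distances_A.items()})
            rows.append(row)
        _write_tsv(out / "characterization.tsv", pd.DataFrame(rows), config)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    result.stages_completed.append(stage)
    if stop_after == "cluster":
        return result

    stage = "report"
    try:
        from .report import render_report

        (out / "report.md").write_text(render_report(out))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    result.stages_completed.append(stage)
    return result
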
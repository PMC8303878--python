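"""Markdown run report assembled from the artifacts of a run directory."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = ["render_report"]

_SECTIONS = [
    ("Bilayer thickness and TM potential", "thickness_series.tsv"),
    ("Replica RMSD series", "rmsd_series.tsv"),
    ("Replica stability selection", "selection.tsv"),
    ("Tuple cube", "tuple_sample.tsv"),
    ("Elbow curve", "elbow_curve.tsv"),
    ("Cluster sizes", "cluster_assignments.tsv"),
    ("Cluster free energies", "free_energy.tsv"),
    ("Representative conformations", "characterization.tsv"),
]


def _read_artifact(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#").fillna("")


def _table(df: pd.DataFrame, max_rows: int = 12) -> str:
    shown = df.head(max_rows)
    lines = ["| " + " | ".join(map(str, shown.columns)) + " |"]
    lines.append("|" + "---|" * len(shown.columns))
    for _, row in shown.iterrows():
        lines.append(
            "| "
            + " | ".join(
                f"{v:.4g}" if isinstance(v, float) else str(v) for v in row
            )
            + " |"
        )
    if len(df) > max_rows:
        lines.append(f"\n({len(df) - max_rows} further rows omitted)")
    return "\n".join(lines)


def render_report(run_dir: str | Path) -> str:
    """Assemble the Markdown report for a completed or partial run.

    Stages whose artifacts are absent are listed as such; an empty run
    directory is an error.
    """
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise ValidationError(f"run directory does not exist: {run_dir}")
    artifacts = {p.name for p in run_dir.iterdir()}
    if not artifacts - {"report.md"}:
        raise ValidationError(f"run directory {run_dir} holds no artifacts")

    parts = ["# Conformational-state analysis report\n"]
    config_path = run_dir / "config.yaml"
    if config_path.exists():
        header = [
            line
            for line in config_path.read_text().splitlines()
            if line.startswith("#")
        ]
        parts.append("```\n" + "\n".join(header) + "\n```\n")

    missing: list[str] = []
    for title, filename in _SECTIONS:
        path = run_dir / filename
        if not path.exists():
            missing.append(title)
            continue
        df = _read_artifact(path)
        parts.append(f"## {title}\n")
        if filename == "rmsd_series.tsv":
            summary = df.groupby("replica")["rmsd_nm"].agg(["last", "mean", "max"])
            summary = summary.reset_index().rename(columns={"last": "final_rmsd_nm"})
            parts.append(_table(summary))
        elif filename == "cluster_assignments.tsv":
            counts = (
                df["cluster"].value_counts().sort_index().rename("tuples").reset_index()
            )
            parts.append(_table(counts))
        elif filename == "thickness_series.tsv":
            mean = df["thickness_nm"].mean()
            sd = df["thickness_nm"].std(ddof=1) if len(df) > 1 else 0.0
            parts.append(f"Mean thickness: {mean:.3f} +/- {sd:.3f} nm\n")
            parts.append(_table(df))
        else:
            parts.append(_table(df))
        parts.append("")
    if missing:
        parts.append("## Absent stages\n")
        for title in missing:
            parts.append(f"- {title}: artifact not present in this run directory")
        parts.append("")
    return "\n".join(parts)
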
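"""Plain-text readers and writers.

Conventions: connectivity matrices and node time series are whitespace-
or comma-delimited text with a header row of 1-based node labels; cohort
tables, manifests and truth tables are CSV; motion parameter files are
6-column delimited text (SPM realignment dialect: three translations in
mm, three rotations in radians); generator configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import ConnectivityMatrix, NodeTimeSeries
from .synthetic import GeneratorConfig, SyntheticCohort

__all__ = [
    "write_connectivity",
    "read_connectivity",
    "write_time_series",
    "read_time_series",
    "read_motion_params",
    "write_cohort",
    "load_matrices",
    "write_config",
    "read_config",
]


def _delimiter(path: Path) -> str | None:
    return "," if path.suffix.lower() == ".csv" else None


def write_connectivity(m: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    header = " ".join(str(i) for i in m.node_ids)
    np.savetxt(path, m.values, fmt="%.10g", header=header, comments="")


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().replace(",", " ").split()
    node_ids = np.asarray([int(float(h)) for h in header])
    values = np.loadtxt(path, skiprows=1, delimiter=_delimiter(path))
    # exact symmetry can be lost to decimal truncation on disk
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, node_ids=node_ids)


def write_time_series(ts: NodeTimeSeries, path: str | Path) -> None:
    header = " ".join(str(i) for i in ts.node_ids)
    np.savetxt(Path(path), ts.values.T, fmt="%.10g", header=header, comments="")


def read_time_series(path: str | Path) -> NodeTimeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().replace(",", " ").split()
    node_ids = np.asarray([int(float(h)) for h in header])
    values = np.loadtxt(path, skiprows=1, delimiter=_delimiter(path))
    return NodeTimeSeries(values=values.T, node_ids=node_ids)


def read_motion_params(path: str | Path) -> np.ndarray:
    """6-column realignment estimates (tx, ty, tz mm; rx, ry, rz rad)."""
    p = np.loadtxt(Path(path), delimiter=_delimiter(Path(path)))
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameter file must have 6 columns")
    return p


def write_cohort(sc: SyntheticCohort, outdir: str | Path) -> dict:
    """Serialise a synthetic cohort: CSVs, matrix files, manifest, config.

    Returns a dict of the written paths.
    """
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "truth": outdir / "truth.csv",
        "planted_edges": outdir / "planted_edges.csv",
        "manifest": outdir / "manifest.csv",
        "config": outdir / "generator_config.yaml",
    }
    sc.cohort.to_csv(paths["cohort"], index=False)
    sc.truth_frame().to_csv(paths["truth"], index=False)
    sc.planted_frame().to_csv(paths["planted_edges"], index=False)
    rows = []
    for sid, m in zip(sc.cohort["subject_id"], sc.matrices):
        fname = f"matrices/{sid}.txt"
        write_connectivity(m, outdir / fname)
        rows.append({"subject_id": sid, "filename": fname})
    pd.DataFrame(rows).to_csv(paths["manifest"], index=False)
    write_config(sc.config, paths["config"])
    return paths


def load_matrices(manifest_path: str | Path) -> tuple[list[str], list[ConnectivityMatrix]]:
    """Load matrices listed in a manifest CSV (subject_id, filename)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    ids, mats = [], []
    for _, row in manifest.iterrows():
        ids.append(row["subject_id"])
        mats.append(read_connectivity(base / row["filename"]))
    return ids, mats


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path: str | Path) -> GeneratorConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("structural_coefficients", "age_range", "motion_params"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)
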
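"""Plain-text file formats and provenance for the pipeline.

Matrices travel as TSV with a header row of region ids (canonicalised to
sorted order at load); cohorts are one TSV per scan plus a JSON manifest;
tidy result tables are CSV; configuration and provenance are JSON.  No
binary neuroimaging formats are required once the inputs are parcellated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Cohort, ParcelCoordinates, ParcellatedTimeSeries

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_cohort",
    "read_cohort",
    "write_coords",
    "read_coords",
    "write_receptor_map",
    "read_receptor_map",
    "write_provenance",
]


def read_matrix_tsv(path, expected_shape: tuple | None = None) -> pd.DataFrame:
    """Read a labelled numeric matrix from TSV, validating as it goes.

    Raises with the offending line number on ragged rows or non-numeric
    cells, and on duplicate column ids or a missing header.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: missing header line")
        cols = header.split("\t")
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"{path}: duplicate column ids {dupes}")
        if any(_is_number(c) for c in cols):
            raise ValueError(f"{path}: header looks numeric; a header row is required")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if line.strip() == "":
                continue
            if len(parts) != len(cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                bad = next(x for x in parts if not _is_number(x))
                raise ValueError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
    df = pd.DataFrame(rows, columns=cols)
    if expected_shape is not None and df.shape != tuple(expected_shape):
        raise ValueError(f"{path}: expected shape {expected_shape}, got {df.shape}")
    return df


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_matrix_tsv(path, matrix: np.ndarray, columns) -> None:
    pd.DataFrame(np.asarray(matrix), columns=list(columns)).to_csv(
        path, sep="\t", index=False
    )


def _region_ids(n: int):
    return [f"r{j:04d}" for j in range(n)]


def write_cohort(cohort: Cohort, outdir) -> Path:
    """One TSV per scan (frames x regions) plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"scans": [], "mean_fd": cohort.mean_fd, "seed": None}
    if cohort.spec is not None:
        manifest["seed"] = cohort.spec.seed
    for scan in cohort.scans:
        fname = f"{scan.scan_id}.tsv"
        write_matrix_tsv(outdir / fname, scan.values, _region_ids(scan.n_regions))
        manifest["scans"].append(
            dict(
                scan_id=scan.scan_id,
                subject_id=scan.subject_id,
                condition=scan.condition,
                tr_seconds=scan.tr_seconds,
                file=fname,
            )
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir / "manifest.json"


def read_cohort(manifest_path) -> Cohort:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cohort = Cohort(mean_fd=manifest.get("mean_fd", {}))
    for rec in manifest["scans"]:
        df = read_matrix_tsv(manifest_path.parent / rec["file"])
        df = df[sorted(df.columns)]  # canonical region order
        cohort.scans.append(
            ParcellatedTimeSeries(
                values=df.to_numpy(),
                tr_seconds=rec["tr_seconds"],
                subject_id=rec["subject_id"],
                condition=rec["condition"],
                scan_id=rec["scan_id"],
            )
        )
    return cohort


def write_coords(path, coords: ParcelCoordinates) -> None:
    n = coords.xyz.shape[0]
    df = pd.DataFrame(
        dict(
            region_id=_region_ids(n),
            hemisphere=coords.hemisphere,
            x=coords.xyz[:, 0],
            y=coords.xyz[:, 1],
            z=coords.xyz[:, 2],
        )
    )
    df.to_csv(path, sep="\t", index=False)


def read_coords(path) -> ParcelCoordinates:
    df = pd.read_csv(path, sep="\t").sort_values("region_id")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return ParcelCoordinates(xyz=xyz, hemisphere=df["hemisphere"].to_numpy())


def write_receptor_map(path, values: np.ndarray, name: str = "receptor") -> None:
    pd.DataFrame(dict(region_id=_region_ids(len(values)), value=values)).to_csv(
        path, sep="\t", index=False
    )


def read_receptor_map(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").sort_values("region_id")
    return df["value"].to_numpy(dtype=float)


def write_provenance(path, **fields) -> None:
    """JSON sidecar recording seeds, parameters and numerical diagnostics."""
    clean = {}
    for key, val in fields.items():
        if isinstance(val, (np.floating, np.integer)):
            val = val.item()
        clean[key] = val
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, default=str)
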
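"""File formats: TSV matrices, sample sheets, manifests, JSON ledgers, YAML configs.

Matrices are stored as TSV with probes as rows (first column ``probe_id``)
and samples as columns. Round-trips preserve full float precision
(``repr``-level formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix.

    The first column holds probe identifiers; remaining columns are samples.
    Raises :class:`DataError` on an empty file, duplicate probe or sample
    identifiers, or ragged rows (reported with the 1-based line number).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DataError(f"empty matrix file: {path}")
        ncol = len(header.rstrip("\n").split("\t"))
        for lineno, line in enumerate(fh, start=2):
            if len(line.rstrip("\n").split("\t")) != ncol:
                raise DataError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"{path}: duplicate probe ids {dups}")
    if df.columns.duplicated().any():
        raise DataError(f"{path}: duplicate sample ids")
    return df


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a probes x samples matrix as TSV at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise DataError(f"{path}: duplicate sample ids")
    return df


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = sheet.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     dtype={"chr": str})
    if df.index.duplicated().any():
        raise DataError(f"{path}: duplicate probe ids in manifest")
    return df


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = manifest.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(path, sep="\t")


def write_json(path: str | Path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_config(path: str | Path) -> dict:
    """Read a YAML (or JSON — YAML superset) pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError(f"{path}: configuration must be a mapping")
    return cfg


def regions_to_bed(regions, manifest: pd.DataFrame) -> pd.DataFrame:
    """Export regions as BED intervals (0-based half-open, spanning min..max probe).

    Manifest positions are 1-based; BED start is therefore ``min(pos) - 1``.
    """
    rows = []
    for reg in regions:
        pos = manifest.loc[reg.probe_ids, "pos"]
        chrom = manifest.loc[reg.probe_ids[0], "chr"]
        rows.append((f"chr{chrom}", int(pos.min()) - 1, int(pos.max()),
                     reg.region_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
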
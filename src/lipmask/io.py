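"""Readers and writers for points, regions, releases and secret key material.

File conventions:

* points CSV — header `id,lat,lon[,qid...]`; WGS84 decimal degrees.
* distance matrix CSV — full N x N, a header row of record ids and a
  leading label column of record ids, entries in km.
* release directory — `microdata.csv` (coordinates removed) plus
  `dtilde.csv`; the row order of the microdata matches the matrix labels.
* secret directory — `refsets.json`, the custodian-only reference sets.
* region — GeoJSON Polygon/MultiPolygon file (lon-lat order per RFC 7946)
  or a 4-number bounding box (lat_min, lat_max, lon_min, lon_max).
* truth CSV — two columns `target_id,ident_id`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .attack import CandidateVertex
from .embedding import ReferenceSets
from .geometry import DistanceMatrix, Region
from .microdata import MicrodataTable

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "read_region",
    "read_matrix_csv",
    "write_matrix_csv",
    "write_release",
    "read_release",
    "write_refsets_json",
    "read_refsets_json",
    "read_truth_csv",
    "write_truth_csv",
]


def read_points_csv(path: str | Path) -> MicrodataTable:
    """Read a microdata table; errors name the offending row/id."""
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id",):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return MicrodataTable(df)


def write_points_csv(table: MicrodataTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_region(source: str | Path | Sequence[float] | dict | Region) -> Region:
    """Coerce a GeoJSON path, a parsed GeoJSON mapping, a 4-number bbox
    (lat_min, lat_max, lon_min, lon_max) or a Region into a Region."""
    if isinstance(source, Region):
        return source
    if isinstance(source, dict):
        return Region.from_geojson(source)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return Region.from_geojson(json.load(fh))
    vals = [float(v) for v in source]
    if len(vals) != 4:
        raise ValueError("bounding box must have 4 numbers: lat_min, lat_max, lon_min, lon_max")
    return Region.from_bbox(*vals)


def write_matrix_csv(dm: DistanceMatrix, path: str | Path) -> None:
    ids = dm.ids if dm.ids is not None else tuple(str(i) for i in range(dm.n))
    pd.DataFrame(dm.values, index=list(ids), columns=list(ids)).to_csv(path, index_label="id")


def read_matrix_csv(path: str | Path, kind: str = "approximate") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    return DistanceMatrix(df.to_numpy(dtype=float), kind=kind, ids=tuple(df.index))


def write_release(table: MicrodataTable, dtilde: DistanceMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the release bundle: microdata with coordinates dropped plus
    the approximate matrix. Refuses a table whose row order disagrees with
    the matrix labels."""
    if dtilde.ids is None:
        raise ValueError("release matrix must carry record ids")
    if tuple(table.ids) != dtilde.ids:
        raise ValueError("microdata row order does not match matrix labels")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    micro = out / "microdata.csv"
    matrix = out / "dtilde.csv"
    write_points_csv(table.without_coordinates(), micro)
    write_matrix_csv(dtilde, matrix)
    return {"microdata": micro, "dtilde": matrix}


def read_release(release_dir: str | Path) -> tuple[MicrodataTable, DistanceMatrix]:
    release_dir = Path(release_dir)
    table = read_points_csv(release_dir / "microdata.csv")
    dtilde = read_matrix_csv(release_dir / "dtilde.csv", kind="approximate")
    if tuple(table.ids) != dtilde.ids:
        raise ValueError(f"{release_dir}: microdata row order does not match matrix labels")
    return table, dtilde


def write_refsets_json(refs: ReferenceSets, path: str | Path) -> None:
    """Serialise the secret reference sets (custodian-only file)."""
    payload = {
        "d": refs.d,
        "k": refs.k,
        "sets": [[[float(la), float(lo)] for la, lo in s] for s in refs.latlon],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_refsets_json(path: str | Path, region: Region) -> ReferenceSets:
    with open(path) as fh:
        payload = json.load(fh)
    arr = np.asarray(payload["sets"], dtype=float)
    if arr.shape[:2] != (payload["d"], payload["k"]):
        raise ValueError(f"{path}: set shape disagrees with declared d, k")
    return ReferenceSets(arr, region)


def write_truth_csv(truth: Iterable[CandidateVertex], path: str | Path) -> None:
    rows = sorted((t, i) for t, i in truth)
    pd.DataFrame(rows, columns=["target_id", "ident_id"]).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> set[CandidateVertex]:
    df = pd.read_csv(path, dtype=str)
    for col in ("target_id", "ident_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {CandidateVertex(t, i) for t, i in zip(df["target_id"], df["ident_id"])}
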
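"""Microdata tables: record id, quasi-identifier columns, optional coordinates."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GeoPoint

__all__ = ["MicrodataTable"]

_RESERVED = ("id", "lat", "lon")


class MicrodataTable:
    """A table of records with unique ids, quasi-identifier attributes and
    optionally a WGS84 position per record.

    Thin wrapper over a pandas DataFrame with columns `id`, the
    quasi-identifiers, and (if georeferenced) `lat`/`lon` in decimal
    degrees. Row order is preserved and meaningful: a released table's row
    order matches the rows/columns of its distance matrix.
    """

    def __init__(self, df: pd.DataFrame):
        if "id" not in df.columns:
            raise ValueError("microdata requires an 'id' column")
        df = df.copy()
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate record id {dup!r}")
        has_lat, has_lon = "lat" in df.columns, "lon" in df.columns
        if has_lat != has_lon:
            raise ValueError("coordinates require both 'lat' and 'lon' columns")
        if has_lat:
            lat = pd.to_numeric(df["lat"], errors="coerce")
            lon = pd.to_numeric(df["lon"], errors="coerce")
            for col, vals, lo, hi in (("lat", lat, -90, 90), ("lon", lon, -180, 180)):
                bad = vals.isna() | (vals < lo) | (vals > hi)
                if bad.any():
                    row = df.index[bad][0]
                    raise ValueError(
                        f"record {df.loc[row, 'id']!r} (row {row}): invalid {col} {df.loc[row, col]!r}"
                    )
            df["lat"], df["lon"] = lat, lon
        self.df = df.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    @property
    def qid_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in _RESERVED]

    @property
    def has_coordinates(self) -> bool:
        return "lat" in self.df.columns

    def points_array(self) -> np.ndarray:
        """(n, 2) array of (lat, lon) rows, in table row order."""
        if not self.has_coordinates:
            raise ValueError("table carries no coordinates")
        return self.df[["lat", "lon"]].to_numpy(dtype=float)

    def point(self, record_id: str) -> GeoPoint:
        row = self.df.loc[self.df["id"] == record_id]
        if row.empty:
            raise KeyError(f"no record with id {record_id!r}")
        return GeoPoint(float(row["lat"].iloc[0]), float(row["lon"].iloc[0]))

    def require_qids(self, qid_names: Sequence[str]) -> None:
        missing = [q for q in qid_names if q not in self.df.columns]
        if missing:
            raise KeyError(f"unknown quasi-identifier column(s): {missing}")

    def without_coordinates(self) -> "MicrodataTable":
        """A copy with the lat/lon columns dropped (release form)."""
        return MicrodataTable(self.df.drop(columns=["lat", "lon"], errors="ignore"))

    def __repr__(self) -> str:  # pragma: no cover
        geo = "georeferenced" if self.has_coordinates else "no coordinates"
        return f"MicrodataTable({len(self)} records, qids={self.qid_columns}, {geo})"
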
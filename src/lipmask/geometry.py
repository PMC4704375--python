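"""Geographic primitives.

Great-circle (haversine) distances on a sphere of mean radius 6371.0088 km,
exact pairwise distance matrices, and uniform point sampling from a
geographic region. All coordinates are WGS84 decimal degrees in (lat, lon)
order; all distances are kilometres. Uniformity of sampling is with respect
to spherical surface area (longitude uniform, sine of latitude uniform on
the bounding box, rejection on polygon membership).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import box as _shapely_box, shape as _shapely_shape

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "Region",
    "DistanceMatrix",
    "haversine_km",
    "exact_distance_matrix",
    "sample_uniform_in_region",
    "pairwise_haversine_km",
    "points_to_array",
]

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

#: Proposal budget for rejection sampling, per requested point.
_REJECTION_CAP_PER_POINT = 10_000


class RegionSamplingError(RuntimeError):
    """Rejection sampling exhausted its proposal budget."""


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position in decimal degrees, (lat, lon) order."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat!r} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon!r} outside [-180, 180]")


def points_to_array(points: Iterable[GeoPoint] | np.ndarray) -> np.ndarray:
    """(n, 2) float array of (lat, lon) rows from GeoPoints or an array."""
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("coordinate array must have shape (n, 2)")
        return arr
    return np.array([(p.lat, p.lon) for p in points], dtype=float)


def pairwise_haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All great-circle distances between rows of `a` (n,2) and `b` (m,2).

    Vectorised haversine; returns an (n, m) array in km.
    """
    a = np.radians(np.asarray(a, dtype=float))
    b = np.radians(np.asarray(b, dtype=float))
    lat1 = a[:, 0][:, None]
    lat2 = b[:, 0][None, :]
    dlat = lat2 - lat1
    dlon = b[:, 1][None, :] - a[:, 1][:, None]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_km(p: GeoPoint, q: GeoPoint) -> float:
    """Great-circle distance between two points, km.

    Symmetric, and zero exactly when the coordinates coincide.
    """
    if not isinstance(p, GeoPoint):
        p = GeoPoint(*p)
    if not isinstance(q, GeoPoint):
        q = GeoPoint(*q)
    if (p.lat, p.lon) == (q.lat, q.lon):
        return 0.0
    return float(pairwise_haversine_km(np.array([[p.lat, p.lon]]), np.array([[q.lat, q.lon]]))[0, 0])


class Region:
    """A geographic sampling area: a polygon (or box) in WGS84 degrees.

    Internally backed by a shapely geometry in (lon, lat) axis order, the
    GeoJSON convention; the public API speaks (lat, lon). Membership is
    closed (boundary points belong to the region).
    """

    def __init__(self, geom: shapely.Geometry):
        if geom.is_empty or geom.area <= 0.0:
            raise ValueError("region must have nonzero area")
        self.geom = geom

    @classmethod
    def from_bbox(cls, lat_min: float, lat_max: float, lon_min: float, lon_max: float) -> "Region":
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValueError("bounding box must satisfy lat_min < lat_max and lon_min < lon_max")
        GeoPoint(lat_min, lon_min)
        GeoPoint(lat_max, lon_max)
        return cls(_shapely_box(lon_min, lat_min, lon_max, lat_max))

    @classmethod
    def from_geojson(cls, obj: dict) -> "Region":
        """Build from a GeoJSON Polygon/MultiPolygon mapping (RFC 7946,
        lon-lat order inside the file), or a Feature/FeatureCollection
        wrapping one."""
        t = obj.get("type")
        if t == "FeatureCollection":
            geoms = [_shapely_shape(f["geometry"]) for f in obj["features"]]
            geom = shapely.union_all(geoms)
        elif t == "Feature":
            geom = _shapely_shape(obj["geometry"])
        else:
            geom = _shapely_shape(obj)
        return cls(geom)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max)."""
        lon_min, lat_min, lon_max, lat_max = self.geom.bounds
        return (lat_min, lat_max, lon_min, lon_max)

    def contains(self, p: GeoPoint) -> bool:
        return bool(shapely.intersects_xy(self.geom, p.lon, p.lat))

    def contains_latlon(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Vectorised closed membership test."""
        return shapely.intersects_xy(self.geom, np.asarray(lon), np.asarray(lat))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Region(bounds={self.bounds})"


@dataclass
class DistanceMatrix:
    """An N x N matrix of pairwise distances in km.

    kind is "exact" for true great-circle distances and "approximate" for a
    released, embedding-derived matrix. Row/column order follows `ids` when
    given.
    """

    values: np.ndarray
    kind: str = "exact"
    ids: tuple[str, ...] | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if self.kind not in ("exact", "approximate"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, rtol=0, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        self.values = v
        if self.ids is not None:
            self.ids = tuple(str(i) for i in self.ids)
            if len(self.ids) != v.shape[0]:
                raise ValueError("ids length must match matrix size")
            if len(set(self.ids)) != len(self.ids):
                raise ValueError("ids must be unique")
            self._index = {i: j for j, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def entry(self, id_a: str, id_b: str) -> float:
        """Distance between two records addressed by id."""
        if self._index is None:
            raise KeyError("matrix carries no record ids")
        try:
            return float(self.values[self._index[id_a], self._index[id_b]])
        except KeyError as e:
            raise KeyError(f"record id {e.args[0]!r} not in distance matrix") from None

    def satisfies_triangle_inequality(self, atol: float = 1e-9) -> bool:
        """Check d(i,j) <= d(i,m) + d(m,j) for all triples."""
        v = self.values
        # broadcast over the intermediate index m
        lhs = v[:, None, :]  # d(i, j)
        rhs = v[:, :, None] + v[None, :, :]  # d(i, m) + d(m, j)
        return bool(np.all(lhs <= rhs + atol))


def exact_distance_matrix(points: Sequence[GeoPoint] | np.ndarray, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Exact N x N great-circle distance matrix of the given points."""
    arr = points_to_array(points)
    if arr.shape[0] < 1:
        raise ValueError("need at least one point")
    v = pairwise_haversine_km(arr, arr)
    np.fill_diagonal(v, 0.0)
    v = (v + v.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(v, kind="exact", ids=tuple(ids) if ids is not None else None)


def sample_uniform_latlon(region: Region, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) array of points uniform w.r.t. spherical area inside region.

    Rejection sampling on the bounding box with sine-latitude draws; raises
    RegionSamplingError if the proposal budget (10,000 per point) runs out,
    which flags degenerate regions loudly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lat_min, lat_max, lon_min, lon_max = region.bounds
    s0, s1 = np.sin(np.radians(lat_min)), np.sin(np.radians(lat_max))
    out = np.empty((n, 2), dtype=float)
    got = 0
    proposed = 0
    cap = _REJECTION_CAP_PER_POINT * n
    while got < n:
        if proposed >= cap:
            raise RegionSamplingError(
                f"rejection sampling produced {got}/{n} points after {proposed} proposals"
            )
        batch = min(max(4 * (n - got), 4096), cap - proposed)
        z = rng.uniform(s0, s1, size=batch)
        lat = np.degrees(np.arcsin(z))
        lon = rng.uniform(lon_min, lon_max, size=batch)
        proposed += batch
        keep = region.contains_latlon(lat, lon)
        k = int(keep.sum())
        if k:
            take = min(k, n - got)
            out[got : got + take, 0] = lat[keep][:take]
            out[got : got + take, 1] = lon[keep][:take]
            got += take
    return out


def sample_uniform_in_region(region: Region, n: int, rng: np.random.Generator) -> list[GeoPoint]:
    """n points drawn independently and uniformly (w.r.t. area) from region."""
    arr = sample_uniform_latlon(region, n, rng)
    return [GeoPoint(float(la), float(lo)) for la, lo in arr]
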
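"""Randomised Lipschitz embedding for distance-matrix anonymisation.

The custodian draws d secret reference sets R_1..R_d of k points each,
uniformly from the study region. Each location p maps to the vector
f(p) = (f_1(p), ..., f_d(p)) with

    f_i(p) = min_{j=1..k} d(p, r_ij)

(its minimum great-circle distance to each reference set), and the released
approximate distance between two records is the l_inf (Chebyshev) distance
between their embedded vectors:

    dtilde(p, q) = max_i |f_i(p) - f_i(q)|.

Because each coordinate function is 1-Lipschitz, dtilde(p,q) <= d(p,q)
always (contractivity): released distances are randomly contracted, never
inflated. Small d and large k yield heavier, more protective contraction.
The embedded coordinates themselves are key material and are never part of
a release; only the table and the approximate matrix are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import (
    DistanceMatrix,
    GeoPoint,
    Region,
    pairwise_haversine_km,
    points_to_array,
    sample_uniform_latlon,
)
from .rng import as_rng, substream

__all__ = [
    "EmbeddingParams",
    "ReferenceSets",
    "generate_reference_sets",
    "embed_points",
    "lipschitz_coordinates",
    "linf_distance",
    "approximate_distance_matrix",
    "anonymise_distance_matrix",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding parameters: d reference sets of k points each.

    d (the dimension parameter) controls how many independent coordinates
    the l_inf maximum runs over — larger d gives more accurate released
    distances. k (the size parameter) controls the minimum inside each
    coordinate — larger k contracts distances more heavily and is more
    protective. seed makes the secret reference draw reproducible.
    """

    d: int
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d < 1 or self.k < 1:
            raise ValueError("embedding parameters require d >= 1 and k >= 1")


@dataclass(frozen=True)
class ReferenceSets:
    """The d secret reference sets of k points each, as a (d, k, 2) array
    of (lat, lon) rows, plus the region they were drawn from.

    This is the anonymisation's key material: it must stay with the
    custodian and never enter a release bundle.
    """

    latlon: np.ndarray
    region: Region

    def __post_init__(self) -> None:
        arr = np.asarray(self.latlon, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("reference sets must form a (d, k, 2) array")
        object.__setattr__(self, "latlon", arr)

    @property
    def d(self) -> int:
        return self.latlon.shape[0]

    @property
    def k(self) -> int:
        return self.latlon.shape[1]

    def sets(self) -> list[list[GeoPoint]]:
        """The reference sets as lists of GeoPoints."""
        return [[GeoPoint(float(la), float(lo)) for la, lo in s] for s in self.latlon]


def generate_reference_sets(
    region: Region,
    params: EmbeddingParams,
    rng: np.random.Generator | None = None,
) -> ReferenceSets:
    """Draw d*k points independently and uniformly from region, partitioned
    into d sets of k. Reproducible from params.seed when rng is not given."""
    if rng is None:
        rng = substream(params.seed if params.seed is not None else 0, "reference-sets")
    flat = sample_uniform_latlon(region, params.d * params.k, rng)
    return ReferenceSets(flat.reshape(params.d, params.k, 2), region)


def embed_points(latlon: np.ndarray, refs: ReferenceSets) -> np.ndarray:
    """Lipschitz coordinates of many points at once: (n, d) array where
    entry (a, i) is the minimum distance from point a to reference set i."""
    pts = points_to_array(latlon)
    flat_refs = refs.latlon.reshape(-1, 2)
    dists = pairwise_haversine_km(pts, flat_refs)  # (n, d*k)
    return dists.reshape(pts.shape[0], refs.d, refs.k).min(axis=2)


def lipschitz_coordinates(p: GeoPoint, refs: ReferenceSets) -> np.ndarray:
    """f(p): length-d vector of minimum distances from p to each reference
    set. Nonnegative; internal key-side quantity, never released."""
    if not isinstance(p, GeoPoint):
        p = GeoPoint(*p)
    return embed_points(np.array([[p.lat, p.lon]]), refs)[0]


def linf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Chebyshev distance max_i |a_i - b_i| between two embedded vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate length mismatch: {a.shape} vs {b.shape}")
    return float(np.max(np.abs(a - b))) if a.size else 0.0


def approximate_distance_matrix(coords: np.ndarray, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise l_inf distances of embedded coordinate rows, as a released
    (kind="approximate") matrix."""
    coords = np.asarray(coords, dtype=float)
    v = cdist(coords, coords, metric="chebyshev")
    np.fill_diagonal(v, 0.0)
    v = (v + v.T) / 2.0
    return DistanceMatrix(v, kind="approximate", ids=tuple(ids) if ids is not None else None)


def anonymise_distance_matrix(
    points: Sequence[GeoPoint] | np.ndarray,
    region: Region,
    params: EmbeddingParams,
    rng: np.random.Generator | None = None,
    ids: Sequence[str] | None = None,
) -> tuple[DistanceMatrix, ReferenceSets]:
    """Produce the releasable approximate matrix Dtilde for the given
    points under one shared secret reference draw.

    Returns (Dtilde, reference_sets). The reference sets are returned for
    custodian-side logging only; they are never written into a release.
    """
    arr = points_to_array(points)
    if arr.shape[0] < 1:
        raise ValueError("need at least one point")
    refs = generate_reference_sets(region, params, rng=as_rng(rng) if rng is not None else None)
    coords = embed_points(arr, refs)
    return approximate_distance_matrix(coords, ids=ids), refs
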
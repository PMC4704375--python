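"""Utility metrics for a released approximate distance matrix.

Two views of how much analytic value survives the masking:

* nearest-neighbour preservation — the fraction of records whose nearest
  neighbour under the released matrix is the same as under the exact one
  (the primitive behind agglomerative clustering);
* rank preservation — the Spearman rank correlation between exact and
  released distances of all records to a fixed anchor record, computed
  separately for a central anchor and a border anchor, since contraction
  hits long distances (border anchors) harder than short ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .embedding import EmbeddingParams, anonymise_distance_matrix
from .geometry import DistanceMatrix, Region, exact_distance_matrix, points_to_array
from .rng import substream

__all__ = [
    "UtilityReport",
    "nn_preservation_rate",
    "rank_correlation_to_anchor",
    "central_border_anchors",
    "utility_report",
    "utility_sweep",
]


def _nearest_neighbours(values: np.ndarray) -> np.ndarray:
    # argmin over each row with the diagonal masked; np.argmin takes the
    # lowest index on ties, applied identically to both matrices
    v = values.copy()
    np.fill_diagonal(v, np.inf)
    return v.argmin(axis=1)


def nn_preservation_rate(D: DistanceMatrix, Dt: DistanceMatrix) -> float:
    """Fraction of records with the same nearest neighbour under Dt as
    under D. Ties break to the lowest index in both matrices, so Dt == D
    always scores 1."""
    if D.n != Dt.n:
        raise ValueError(f"matrix size mismatch: {D.n} vs {Dt.n}")
    if D.n < 2:
        raise ValueError("nearest neighbours need at least two records")
    return float(np.mean(_nearest_neighbours(D.values) == _nearest_neighbours(Dt.values)))


def rank_correlation_to_anchor(D: DistanceMatrix, Dt: DistanceMatrix, anchor: int) -> float:
    """Spearman rho between exact and released distances from every other
    record to the anchor record (average ranks on ties). Returns nan when
    either distance vector is constant, where rho is undefined."""
    if D.n != Dt.n:
        raise ValueError(f"matrix size mismatch: {D.n} vs {Dt.n}")
    if D.n < 3:
        raise ValueError("rank correlation needs at least three records")
    if not (0 <= anchor < D.n):
        raise IndexError(f"anchor index {anchor} out of range")
    others = np.arange(D.n) != anchor
    x = D.values[anchor, others]
    y = Dt.values[anchor, others]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(spearmanr(x, y).statistic)


def central_border_anchors(points: np.ndarray) -> tuple[int, int]:
    """Indices of the record nearest the coordinate centroid ("central")
    and the record nearest its farthest bounding-box corner ("border")."""
    arr = points_to_array(points)
    centroid = arr.mean(axis=0)
    central = int(np.argmin(np.linalg.norm(arr - centroid, axis=1)))
    lat0, lon0 = arr.min(axis=0)
    lat1, lon1 = arr.max(axis=0)
    corners = np.array([[lat0, lon0], [lat0, lon1], [lat1, lon0], [lat1, lon1]])
    corner = corners[np.argmax(np.linalg.norm(corners - centroid, axis=1))]
    border = int(np.argmin(np.linalg.norm(arr - corner, axis=1)))
    return central, border


@dataclass
class UtilityReport:
    """Replicate-averaged utility of one embedding parameter setting."""

    nn_rate: float
    rho_by_anchor: dict[str, float]
    params: EmbeddingParams
    replicates: int


def utility_report(
    points: np.ndarray,
    region: Region,
    params: EmbeddingParams,
    replicates: int = 10,
    seed: int = 0,
) -> UtilityReport:
    """Average nearest-neighbour preservation and anchor rank correlations
    over independent embedding replicates of the same point set."""
    arr = points_to_array(points)
    D = exact_distance_matrix(arr)
    central, border = central_border_anchors(arr)
    rng = substream(seed, f"utility-d{params.d}-k{params.k}")
    nn, rho_c, rho_b = [], [], []
    for _ in range(replicates):
        Dt, _refs = anonymise_distance_matrix(arr, region, params, rng=rng)
        nn.append(nn_preservation_rate(D, Dt))
        rho_c.append(rank_correlation_to_anchor(D, Dt, central))
        rho_b.append(rank_correlation_to_anchor(D, Dt, border))
    return UtilityReport(
        nn_rate=float(np.mean(nn)),
        rho_by_anchor={"central": float(np.nanmean(rho_c)), "border": float(np.nanmean(rho_b))},
        params=params,
        replicates=replicates,
    )


def utility_sweep(
    points: np.ndarray,
    region: Region,
    dims: list[int],
    sizes: list[int],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy table of per-replicate utility over a (d, k) grid.

    Columns: d, k, replicate, nn_rate, rho_central, rho_border.
    """
    arr = points_to_array(points)
    D = exact_distance_matrix(arr)
    central, border = central_border_anchors(arr)
    rows = []
    for d in dims:
        for k in sizes:
            params = EmbeddingParams(d=d, k=k)
            rng = substream(seed, f"utility-d{d}-k{k}")
            for rep in range(replicates):
                Dt, _refs = anonymise_distance_matrix(arr, region, params, rng=rng)
                rows.append(
                    {
                        "d": d,
                        "k": k,
                        "replicate": rep,
                        "nn_rate": nn_preservation_rate(D, Dt),
                        "rho_central": rank_correlation_to_anchor(D, Dt, central),
                        "rho_border": rank_correlation_to_anchor(D, Dt, border),
                    }
                )
    return pd.DataFrame(rows)
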
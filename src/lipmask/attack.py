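"""Graph-theoretic linkage attack on a released (table, Dtilde) pair.

The auditor plays a conservative adversary with perfect background
knowledge: an identified auxiliary table with coordinates, the study
region, and the embedding parameters d and k. The attack proceeds in four
stages:

1. Candidate matches V: all pairs (target record t, identified record i)
   agreeing exactly on every quasi-identifier.
2. Tolerance intervals: because released distances are randomly contracted,
   the adversary Monte-Carlo simulates the embedding of the identified
   points many times and summarises the distribution of each pair's
   approximate distance by its shortest interval covering a proportion
   alpha of the simulated values (an empirical alpha-tolerance interval).
3. Compatibility graph G = (V, E): two candidate matches (t1,i1), (t2,i2)
   are joined iff the released distance dtilde(t1,t2) falls inside the
   tolerance interval for (i1,i2). Matches sharing a target or an
   identified record are never adjacent, so every clique is a one-to-one
   partial matching.
4. Maximum clique: the largest mutually compatible set of matches is the
   adversary's claimed re-identification, scored by precision and recall
   against the true overlap. 1 - precision is the empirically attained
   anonymity of the release.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .clique import max_clique_bitset
from .embedding import EmbeddingParams, embed_points, generate_reference_sets
from .geometry import DistanceMatrix, Region
from .microdata import MicrodataTable
from .rng import as_rng

__all__ = [
    "CandidateVertex",
    "ToleranceInterval",
    "CompatibilityGraph",
    "AttackReport",
    "candidate_vertices",
    "tolerance_interval",
    "simulate_pair_intervals",
    "build_compatibility_graph",
    "maximum_clique",
    "evaluate_matches",
    "run_attack",
]


class CandidateVertex(NamedTuple):
    """A candidate match: one target record paired with one identified record."""

    target_id: str
    ident_id: str


@dataclass(frozen=True)
class ToleranceInterval:
    """Shortest interval covering at least a proportion alpha of the
    Monte-Carlo simulated approximate distances for one identified pair.

    Built from distance samples both endpoints are nonnegative; the
    operation itself accepts any real samples."""

    lower: float
    upper: float
    alpha: float
    n_sims: int

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("interval requires lower <= upper")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")

    def contains(self, value: float) -> bool:
        """Closed-interval membership: boundary hits count as compatible."""
        return self.lower <= value <= self.upper


def candidate_vertices(
    target: MicrodataTable,
    ident: MicrodataTable,
    qid_names: Sequence[str],
) -> set[CandidateVertex]:
    """All (target, ident) record pairs agreeing exactly on every listed
    quasi-identifier. Records with a missing value in any listed attribute
    match nothing (conservative blocking)."""
    qid_names = list(qid_names)
    if not qid_names:
        raise ValueError("at least one quasi-identifier is required")
    target.require_qids(qid_names)
    ident.require_qids(qid_names)
    t = target.df[["id", *qid_names]].dropna(subset=qid_names)
    i = ident.df[["id", *qid_names]].dropna(subset=qid_names)
    merged = t.merge(i, on=qid_names, suffixes=("_t", "_i"))
    return {CandidateVertex(a, b) for a, b in zip(merged["id_t"], merged["id_i"])}


def _interval_window(sorted_vals: np.ndarray, alpha: float) -> tuple[float, float]:
    n = sorted_vals.shape[0]
    m = math.ceil(alpha * n)
    lengths = sorted_vals[m - 1 :] - sorted_vals[: n - m + 1]
    j = int(np.argmin(lengths))  # argmin returns the first minimal window
    return float(sorted_vals[j]), float(sorted_vals[j + m - 1])


def tolerance_interval(samples: Sequence[float], alpha: float) -> ToleranceInterval:
    """Empirical alpha-tolerance interval of the samples.

    Sort ascending, let m = ceil(alpha * n); among all windows of m
    consecutive order statistics return the shortest [x_(j), x_(j+m-1)],
    breaking ties by the smallest j.
    """
    vals = np.sort(np.asarray(list(samples), dtype=float))
    if vals.size == 0:
        raise ValueError("tolerance interval requires at least one sample")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    lo, hi = _interval_window(vals, alpha)
    return ToleranceInterval(lo, hi, alpha, int(vals.size))


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def simulate_pair_intervals(
    ident: MicrodataTable,
    pairs: Iterable[tuple[str, str]],
    region: Region,
    params: EmbeddingParams,
    alpha: float,
    n_sims: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict[tuple[str, str], ToleranceInterval]:
    """Monte-Carlo tolerance intervals for identified-record pairs.

    Repeats the full Lipschitz embedding of all identified points n_sims
    times (a fresh secret reference draw each time, same region/d/k),
    records each requested pair's simulated approximate distance, and
    returns its alpha-tolerance interval. One embedding per replicate
    serves every pair at once, which is distributionally identical to
    simulating pair by pair.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = as_rng(rng)
    if not ident.has_coordinates:
        raise ValueError("identification table must carry coordinates")
    index = {rid: j for j, rid in enumerate(ident.ids)}
    keys = sorted({_pair_key(a, b) for a, b in pairs})
    for a, b in keys:
        for rid in (a, b):
            if rid not in index:
                raise KeyError(f"identified record {rid!r} has no coordinates")
    if not keys:
        return {}
    ia = np.array([index[a] for a, _ in keys])
    ib = np.array([index[b] for _, b in keys])
    pts = ident.points_array()
    sims = np.empty((len(keys), n_sims), dtype=float)
    for s in range(n_sims):
        refs = generate_reference_sets(region, params, rng=rng)
        coords = embed_points(pts, refs)
        sims[:, s] = np.abs(coords[ia] - coords[ib]).max(axis=1)
    sims.sort(axis=1)
    m = math.ceil(alpha * n_sims)
    lengths = sims[:, m - 1 :] - sims[:, : n_sims - m + 1]
    j = lengths.argmin(axis=1)
    rows = np.arange(len(keys))
    lo, hi = sims[rows, j], sims[rows, j + m - 1]
    return {
        key: ToleranceInterval(float(l), float(u), alpha, n_sims)
        for key, l, u in zip(keys, lo, hi)
    }


@dataclass
class CompatibilityGraph:
    """Simple undirected graph on candidate matches.

    Vertices are held sorted by (target_id, ident_id) so the clique
    search order — and hence tie-breaking among maximum cliques — is
    deterministic. Adjacency is stored as one bitmask per vertex.
    """

    vertices: tuple[CandidateVertex, ...]
    adj: list[int] = field(repr=False)

    @classmethod
    def from_edges(
        cls,
        vertices: Iterable[CandidateVertex],
        edges: Iterable[tuple[CandidateVertex, CandidateVertex]],
    ) -> "CompatibilityGraph":
        verts = tuple(sorted(set(vertices)))
        idx = {v: i for i, v in enumerate(verts)}
        adj = [0] * len(verts)
        for a, b in edges:
            if a == b:
                raise ValueError("self-loops are not allowed")
            i, j = idx[a], idx[b]
            adj[i] |= 1 << j
            adj[j] |= 1 << i
        return cls(verts, adj)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(m.bit_count() for m in self.adj) // 2

    def edges(self) -> set[frozenset[CandidateVertex]]:
        out = set()
        for i, mask in enumerate(self.adj):
            while mask:
                j = (mask & -mask).bit_length() - 1
                mask &= mask - 1
                if j > i:
                    out.add(frozenset((self.vertices[i], self.vertices[j])))
        return out


def build_compatibility_graph(
    V: Iterable[CandidateVertex],
    dtilde: DistanceMatrix,
    intervals: Mapping[tuple[str, str], ToleranceInterval],
) -> CompatibilityGraph:
    """Join two candidate matches (t1,i1), (t2,i2) iff t1 != t2, i1 != i2
    and the released distance dtilde(t1,t2) lies in the (closed) tolerance
    interval for the identified pair (i1,i2).

    The one-to-one rule (no shared target or identified record on an edge)
    makes every clique a consistent partial matching between the files.
    """
    verts = tuple(sorted(set(V)))
    adj = [0] * len(verts)
    for a, b in combinations(range(len(verts)), 2):
        t1, i1 = verts[a]
        t2, i2 = verts[b]
        if t1 == t2 or i1 == i2:
            continue
        key = _pair_key(i1, i2)
        if key not in intervals:
            raise KeyError(f"no tolerance interval for identified pair {key}")
        if intervals[key].contains(dtilde.entry(t1, t2)):
            adj[a] |= 1 << b
            adj[b] |= 1 << a
    return CompatibilityGraph(verts, adj)


def maximum_clique(
    graph: CompatibilityGraph, step_limit: int = 20_000_000
) -> tuple[frozenset[CandidateVertex], bool]:
    """Exact branch-and-bound maximum clique with a branching-step budget.

    If the search tree is exhausted within step_limit the result is a true
    maximum clique and exhausted=True; otherwise the best clique found so
    far is returned with exhausted=False. The result is always a clique.
    """
    members, exhausted = max_clique_bitset(graph.adj, step_limit)
    return frozenset(graph.vertices[i] for i in members), exhausted


@dataclass
class AttackReport:
    """Outcome of a linkage attack scored against the true overlap.

    precision is None (undefined, distinct from 0) when the attack claims
    no matches. clique_search_exhausted is False when the clique search hit
    its step budget, i.e. the claimed matching may be suboptimal for the
    adversary.
    """

    matches: frozenset[CandidateVertex]
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float
    clique_search_exhausted: bool = True
    n_candidates: int | None = None
    n_edges: int | None = None

    def to_dict(self) -> dict:
        return {
            "matches": sorted([list(m) for m in self.matches]),
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "clique_search_exhausted": self.clique_search_exhausted,
            "n_candidates": self.n_candidates,
            "n_edges": self.n_edges,
        }


def evaluate_matches(
    matches: Iterable[CandidateVertex],
    truth: Iterable[CandidateVertex],
    clique_search_exhausted: bool = True,
) -> AttackReport:
    """Score a claimed matching against the true overlap pairs."""
    matches = frozenset(CandidateVertex(*m) for m in matches)
    truth = frozenset(CandidateVertex(*t) for t in truth)
    tp = len(matches & truth)
    fp = len(matches - truth)
    fn = len(truth - matches)
    precision = tp / (tp + fp) if matches else None
    recall = tp / (tp + fn) if truth else 0.0
    return AttackReport(matches, tp, fp, fn, precision, recall, clique_search_exhausted)


def run_attack(
    release_table: MicrodataTable,
    dtilde: DistanceMatrix,
    ident: MicrodataTable,
    qid_names: Sequence[str],
    region: Region,
    params: EmbeddingParams,
    alpha: float = 0.5,
    n_sims: int = 100,
    step_limit: int = 20_000_000,
    rng: np.random.Generator | int | None = None,
    truth: Iterable[CandidateVertex] | None = None,
) -> AttackReport:
    """Run the full linkage attack against a release.

    Composes candidate generation, tolerance-interval simulation (only for
    identified pairs that actually occur across candidate matches),
    compatibility-graph construction, maximum-clique search and scoring.
    With truth=None the report carries the claimed matches with tp=fp=fn=0
    and recall 0 (nothing to score against).
    """
    V = candidate_vertices(release_table, ident, qid_names)
    needed = {
        _pair_key(v1.ident_id, v2.ident_id)
        for v1, v2 in combinations(sorted(V), 2)
        if v1.target_id != v2.target_id and v1.ident_id != v2.ident_id
    }
    intervals = simulate_pair_intervals(
        ident, needed, region, params, alpha=alpha, n_sims=n_sims, rng=rng
    )
    graph = build_compatibility_graph(V, dtilde, intervals)
    clique, exhausted = maximum_clique(graph, step_limit)
    report = evaluate_matches(clique, truth if truth is not None else (), exhausted)
    if truth is None:
        report.precision = None
    report.n_candidates = graph.n_vertices
    report.n_edges = graph.n_edges
    return report
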
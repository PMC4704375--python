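import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipmask import (
    CandidateVertex,
    EmbeddingParams,
    MicrodataTable,
    build_compatibility_graph,
    candidate_vertices,
    evaluate_matches,
    exact_distance_matrix,
    maximum_clique,
    run_attack,
    simulate_pair_intervals,
    tolerance_interval,
)
from lipmask.attack import CompatibilityGraph, ToleranceInterval
from lipmask.geometry import DistanceMatrix


def table(rows: list[dict]) -> MicrodataTable:
    return MicrodataTable(pd.DataFrame(rows))


class TestCandidateVertices:
    def test_disjoint_qid_values_give_empty_set(self):
        t = table([{"id": "t1", "code": "A"}])
        i = table([{"id": "i1", "code": "B"}])
        assert candidate_vertices(t, i, ["code"]) == set()

    def test_shared_constant_attribute_gives_full_cross_product(self):
        t = table([{"id": f"t{j}", "code": "X"} for j in range(3)])
        i = table([{"id": f"i{j}", "code": "X"} for j in range(4)])
        assert len(candidate_vertices(t, i, ["code"])) == 12

    def test_mixed_values_enumerate_agreeing_pairs(self):
        # target codes A,A,B against ident codes A,B,B: 2*1 + 1*2 = 4 pairs
        t = table([{"id": "t1", "code": "A"}, {"id": "t2", "code": "A"}, {"id": "t3", "code": "B"}])
        i = table([{"id": "i1", "code": "A"}, {"id": "i2", "code": "B"}, {"id": "i3", "code": "B"}])
        got = candidate_vertices(t, i, ["code"])
        assert got == {
            CandidateVertex("t1", "i1"),
            CandidateVertex("t2", "i1"),
            CandidateVertex("t3", "i2"),
            CandidateVertex("t3", "i3"),
        }

    def test_missing_values_never_match(self):
        t = table([{"id": "t1", "code": None}])
        i = table([{"id": "i1", "code": None}])
        assert candidate_vertices(t, i, ["code"]) == set()

    def test_unknown_attribute_rejected(self):
        t = table([{"id": "t1", "code": "A"}])
        with pytest.raises(KeyError):
            candidate_vertices(t, t, ["nope"])


class TestToleranceInterval:
    def test_constant_samples_give_degenerate_interval(self):
        iv = tolerance_interval([3.0, 3.0, 3.0], alpha=0.5)
        assert (iv.lower, iv.upper) == (3.0, 3.0)

    def test_alpha_one_gives_min_max(self):
        iv = tolerance_interval([5.0, 1.0, 9.0], alpha=1.0)
        assert (iv.lower, iv.upper) == (1.0, 9.0)

    def test_shortest_window_with_earliest_tie_break(self):
        # sorted {1,2,3,10}, m=2: windows [1,2],[2,3],[3,10] have lengths
        # 1,1,7 -> earliest minimal window [1,2] wins
        iv = tolerance_interval([1.0, 2.0, 3.0, 10.0], alpha=0.5)
        assert (iv.lower, iv.upper) == (1.0, 2.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            tolerance_interval([], alpha=0.5)

    @given(
        samples=st.lists(st.floats(-3, 3, allow_nan=False), min_size=2, max_size=40),
        alpha=st.floats(0.05, 1.0),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_coverage_and_minimality(self, samples, alpha):
        import math

        iv = tolerance_interval(samples, alpha)
        m = math.ceil(alpha * len(samples))
        inside = sum(iv.lower <= s <= iv.upper for s in samples)
        assert inside >= m
        srt = sorted(samples)
        shortest = min(srt[j + m - 1] - srt[j] for j in range(len(srt) - m + 1))
        assert iv.upper - iv.lower == pytest.approx(shortest)


class TestSimulatePairIntervals:
    def make_ident(self, region, rng, n=8):
        from lipmask.geometry import sample_uniform_latlon

        pts = sample_uniform_latlon(region, n, rng)
        return MicrodataTable(
            pd.DataFrame({"id": [f"i{j}" for j in range(n)], "lat": pts[:, 0], "lon": pts[:, 1]})
        )

    def test_self_pair_interval_is_zero(self, region, rng):
        ident = self.make_ident(region, rng)
        ivs = simulate_pair_intervals(
            ident, {("i0", "i0")}, region, EmbeddingParams(d=5, k=2), alpha=0.9, n_sims=10, rng=rng
        )
        assert ivs[("i0", "i0")].lower == 0.0 and ivs[("i0", "i0")].upper == 0.0

    def test_upper_bounded_by_exact_distance(self, region, rng):
        # contractivity bounds every simulated value, hence the interval
        ident = self.make_ident(region, rng)
        pairs = {("i0", "i1"), ("i2", "i5"), ("i3", "i7")}
        ivs = simulate_pair_intervals(
            ident, pairs, region, EmbeddingParams(d=10, k=3), alpha=0.9, n_sims=25, rng=rng
        )
        D = exact_distance_matrix(ident.points_array(), ids=ident.ids)
        for (a, b), iv in ivs.items():
            assert iv.upper <= D.entry(a, b) + 1e-9
            assert 0 <= iv.lower <= iv.upper

    def test_identical_rng_state_reproduces_intervals(self, region):
        rng_a, rng_b = np.random.default_rng(5), np.random.default_rng(5)
        ident = self.make_ident(region, np.random.default_rng(1))
        pairs = {("i0", "i3"), ("i1", "i2")}
        kw = dict(region=region, params=EmbeddingParams(d=6, k=2), alpha=0.5, n_sims=12)
        assert simulate_pair_intervals(ident, pairs, rng=rng_a, **kw) == simulate_pair_intervals(
            ident, pairs, rng=rng_b, **kw
        )

    def test_missing_coordinates_rejected(self, region, rng):
        ident = table([{"id": "i0", "code": "A"}])
        with pytest.raises(ValueError):
            simulate_pair_intervals(ident, {("i0", "i0")}, region, EmbeddingParams(d=2, k=1), 0.5, 5, rng)


class TestBuildCompatibilityGraph:
    def setup_method(self):
        self.dt = DistanceMatrix(
            np.array([[0.0, 5.0], [5.0, 0.0]]), kind="approximate", ids=("t1", "t2")
        )

    def vertices(self):
        return {CandidateVertex("t1", "i1"), CandidateVertex("t2", "i2")}

    def iv(self, lo, hi):
        return {("i1", "i2"): ToleranceInterval(lo, hi, 0.5, 10)}

    def test_edge_present_when_distance_inside_interval(self):
        g = build_compatibility_graph(self.vertices(), self.dt, self.iv(4.8, 5.3))
        assert g.n_edges == 1

    def test_edge_absent_when_distance_outside_interval(self):
        g = build_compatibility_graph(self.vertices(), self.dt, self.iv(5.1, 5.3))
        assert g.n_edges == 0

    def test_closed_interval_boundary_counts(self):
        g = build_compatibility_graph(self.vertices(), self.dt, self.iv(5.0, 5.3))
        assert g.n_edges == 1

    def test_shared_record_vertices_never_adjacent(self):
        wide = self.iv(0.0, 100.0)
        shared_target = {CandidateVertex("t1", "i1"), CandidateVertex("t1", "i2")}
        assert build_compatibility_graph(shared_target, self.dt, wide).n_edges == 0
        shared_ident = {CandidateVertex("t1", "i1"), CandidateVertex("t2", "i1")}
        assert build_compatibility_graph(shared_ident, self.dt, wide).n_edges == 0

    def test_missing_interval_rejected(self):
        with pytest.raises(KeyError):
            build_compatibility_graph(self.vertices(), self.dt, {})


class TestMaximumClique:
    def test_returns_vertices_and_exhausted_flag(self):
        verts = [CandidateVertex(f"t{j}", f"i{j}") for j in range(4)]
        edges = [(verts[a], verts[b]) for a in range(4) for b in range(a + 1, 4)]
        g = CompatibilityGraph.from_edges(verts, edges)
        clique, exhausted = maximum_clique(g)
        assert clique == frozenset(verts) and exhausted

    def test_clique_is_one_to_one_matching(self, region, rng):
        # on an attack-built graph every clique must pair each target and
        # ident record at most once
        from lipmask import ScenarioSpec, anonymise_distance_matrix, generate_file_pair

        spec = ScenarioSpec(n_target=30, n_ident=30, n_overlap=6, qid_scheme="sex-age", region=region, seed=11)
        target, ident, _ = generate_file_pair(spec)
        params = EmbeddingParams(d=20, k=2)
        dt, _ = anonymise_distance_matrix(target.points_array(), region, params, rng=rng, ids=target.ids)
        report = run_attack(target.without_coordinates(), dt, ident, spec.qid_names, region, params,
                            alpha=0.5, n_sims=20, rng=rng, truth=set())
        targets = [m.target_id for m in report.matches]
        idents = [m.ident_id for m in report.matches]
        assert len(set(targets)) == len(targets)
        assert len(set(idents)) == len(idents)


class TestEvaluateMatches:
    def test_formula(self):
        truth = {CandidateVertex("t1", "i1"), CandidateVertex("t2", "i2")}
        matches = truth | {CandidateVertex("t3", "i3"), CandidateVertex("t4", "i4")}
        r = evaluate_matches(matches, truth)
        assert (r.tp, r.fp, r.fn) == (2, 2, 0)
        assert r.precision == 0.5 and r.recall == 1.0

    def test_perfect_match(self):
        truth = {CandidateVertex("t1", "i1")}
        r = evaluate_matches(truth, truth)
        assert r.precision == 1.0 and r.recall == 1.0

    def test_disjoint_match_set(self):
        truth = {CandidateVertex(f"t{j}", f"i{j}") for j in range(10)}
        r = evaluate_matches({CandidateVertex("x", "y")}, truth)
        assert r.precision == 0.0 and r.recall == 0.0 and r.fn == 10

    def test_empty_matches_have_undefined_precision(self):
        r = evaluate_matches(set(), {CandidateVertex("t1", "i1")})
        assert r.precision is None and r.recall == 0.0


class TestRunAttack:
    @staticmethod
    def _identical_files(region, rng):
        # identical 5-record files with one unique qid per record, so each
        # record can only ever be matched to itself
        from lipmask.geometry import sample_uniform_latlon

        pts = sample_uniform_latlon(region, 5, rng)
        mk = lambda prefix: MicrodataTable(pd.DataFrame({
            "id": [f"{prefix}{j}" for j in range(5)],
            "code": [f"Q{j}" for j in range(5)],
            "lat": pts[:, 0], "lon": pts[:, 1],
        }))
        truth = {CandidateVertex(f"t{j}", f"i{j}") for j in range(5)}
        return mk("t"), mk("i"), pts, truth

    def test_unique_qids_make_every_claimed_match_correct(self, region, rng):
        # with exact distances released (dtilde = D) every candidate vertex
        # is a true pair, so whatever clique is claimed, precision is 1
        target, ident, pts, truth = self._identical_files(region, rng)
        D = exact_distance_matrix(pts, ids=target.ids)
        release = DistanceMatrix(D.values, kind="approximate", ids=D.ids)
        report = run_attack(target.without_coordinates(), release, ident, ["code"], region,
                            EmbeddingParams(d=40, k=1), alpha=0.9, n_sims=50, rng=rng, truth=truth)
        assert report.tp == len(report.matches)
        assert report.precision in (None, 1.0)
        assert report.clique_search_exhausted

    def test_informative_release_recovers_full_overlap(self, region):
        # an actual embedded release under accurate parameters (large d,
        # k=1) with a wide tolerance (alpha=1, many sims) lets the attack
        # reconstruct the complete matching: precision = recall = 1
        target, ident, pts, truth = self._identical_files(region, np.random.default_rng(0))
        params = EmbeddingParams(d=100, k=1)
        from lipmask import anonymise_distance_matrix

        release, _ = anonymise_distance_matrix(pts, region, params,
                                               rng=np.random.default_rng(1), ids=target.ids)
        report = run_attack(target.without_coordinates(), release, ident, ["code"], region,
                            params, alpha=1.0, n_sims=200, rng=np.random.default_rng(2), truth=truth)
        assert report.precision == 1.0 and report.recall == 1.0
        assert report.clique_search_exhausted

    def test_zero_overlap_gives_zero_true_positives(self, region, rng):
        from lipmask import ScenarioSpec, anonymise_distance_matrix, generate_file_pair

        spec = ScenarioSpec(n_target=25, n_ident=25, n_overlap=0, qid_scheme="sex-age", region=region, seed=2)
        target, ident, truth = generate_file_pair(spec)
        assert truth == set()
        params = EmbeddingParams(d=10, k=2)
        dt, _ = anonymise_distance_matrix(target.points_array(), region, params, rng=rng, ids=target.ids)
        report = run_attack(target.without_coordinates(), dt, ident, spec.qid_names, region, params,
                            alpha=0.5, n_sims=15, rng=rng, truth=truth)
        assert report.tp == 0 and report.recall == 0.0

    def test_same_seed_gives_identical_report(self, region):
        from lipmask import ScenarioSpec, anonymise_distance_matrix, generate_file_pair

        spec = ScenarioSpec(n_target=20, n_ident=20, n_overlap=5, qid_scheme="facility-code", region=region, seed=7)
        target, ident, truth = generate_file_pair(spec)
        params = EmbeddingParams(d=8, k=2)
        dt, _ = anonymise_distance_matrix(target.points_array(), region, params,
                                          rng=np.random.default_rng(3), ids=target.ids)
        reports = [
            run_attack(target.without_coordinates(), dt, ident, spec.qid_names, region, params,
                       alpha=0.5, n_sims=10, rng=np.random.default_rng(4), truth=truth)
            for _ in range(2)
        ]
        assert reports[0] == reports[1]
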
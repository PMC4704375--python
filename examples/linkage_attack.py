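"""Audit a release with the graph-theoretic linkage attack.

Simulates a custodian releasing a sex/age microdata file with a masked
distance matrix, then plays a perfect-knowledge adversary holding an
identified auxiliary file that overlaps the release in 10 records. The
attack builds candidate matches from the quasi-identifiers, Monte-Carlo
tolerance intervals for identified pair distances, a compatibility graph,
and claims the maximum clique as its re-identification.
"""

import numpy as np

from lipmask import (
    EmbeddingParams,
    ScenarioSpec,
    anonymise_distance_matrix,
    generate_file_pair,
    run_attack,
)

spec = ScenarioSpec(n_target=80, n_ident=80, n_overlap=10, qid_scheme="sex-age", seed=3)
target, ident, truth = generate_file_pair(spec)

for label, d, k in (("informative", 200, 1), ("protective", 20, 30)):
    params = EmbeddingParams(d=d, k=k)
    dtilde, _ = anonymise_distance_matrix(
        target.points_array(), spec.region, params, rng=np.random.default_rng(1), ids=target.ids
    )
    report = run_attack(
        target.without_coordinates(), dtilde, ident, spec.qid_names,
        spec.region, params, alpha=0.5, n_sims=100,
        rng=np.random.default_rng(2), truth=truth,
    )
    prec = "undefined" if report.precision is None else f"{report.precision:.2f}"
    print(
        f"{label:11s} (d={d:3d}, k={k:2d}): |V|={report.n_candidates}, "
        f"claimed {len(report.matches)} matches, TP={report.tp}, "
        f"precision={prec}, recall={report.recall:.2f}"
    )
# High precision means the release leaks identities; under protective
# parameters the clique is dominated by false matches, so 1 - precision
# (the attained anonymity) is large even though the attacker still claims
# a matching.
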
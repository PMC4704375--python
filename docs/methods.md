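# Methods

## Model

A spatial microdata file is a table of records with unique ids,
quasi-identifier attributes and a WGS84 position. The custodian's release
is the pair (T, D̃): the table with coordinates removed, plus an N×N
approximate distance matrix. D̃ is obtained by a randomised Lipschitz
embedding: draw d reference sets of k points, each point independent and
uniform over the study region 𝒜; map every record location p to
fᵢ(p) = min_j d(p, rᵢⱼ) for i = 1..d; release d̃(p,q) = ‖f(p) − f(q)‖∞.

Two structural facts carry the whole package and are enforced as tested
invariants rather than assumed:

* **Contractivity.** Each fᵢ is 1-Lipschitz with respect to the
  great-circle metric, so d̃(p,q) ≤ d(p,q) for every pair. Released
  distances are underestimates, never overestimates.
* **Pseudometric structure.** D̃ is symmetric, zero-diagonal and satisfies
  the triangle inequality (it is the ℓ∞ metric on embedded vectors);
  distinct records can collapse to distance 0, which is intended — it is
  part of the masking.

Accuracy depends on the two parameters monotonically in expectation
(stochastic, verified by replicated tests, not proved): error falls as d
grows (the ℓ∞ maximum runs over more independent coordinates, each bounded
above by the true distance), rises as k grows (minima over larger sets
decorrelate the anchor points of the two records), and short distances are
relatively better preserved than long ones. The released coordinates f(p)
and the reference sets are key material: the API returns reference sets to
the custodian for logging and `write_release` excludes them by
construction (they live in a separate secret directory).

## Distance model and sampling

All distances are spherical haversine with R = 6371.0088 km (mean Earth
radius); no datum transformations or projections anywhere, since every
comparison in the package uses the same metric and only relative accuracy
matters. "Uniform over the region" means uniform with respect to spherical
surface area: longitude uniform and sine-of-latitude uniform on the
bounding box, with rejection on polygon membership (closed: boundary points
belong). Rejection sampling is budgeted at 10,000 proposals per requested
point so a degenerate region fails loudly instead of hanging. Regions are
axis-aligned (lat, lon) boxes or GeoJSON polygons (lon-lat order inside
files, per the GeoJSON convention; (lat, lon) order everywhere in the API).

## The linkage attack

The audit adversary is deliberately over-powered (perfect background
knowledge): they hold an identified file with exact coordinates, know the
region, d, k, and the quasi-identifier schema, and quasi-identifiers agree
exactly between files (no measurement error, no missing values). Whatever
anonymity survives this adversary is a conservative estimate.

* **Candidate vertices** are exact-equality joins on the quasi-identifier
  columns; records with missing values match nothing.
* **Tolerance intervals.** For an identified pair (i₁, i₂) the adversary
  cannot compare d̃(t₁,t₂) with d(i₁,i₂) directly (contraction is random),
  so they estimate the distribution of d̃(i₁,i₂) by re-embedding the
  identified file n_sims times (default 100; a fresh reference draw per
  replicate). The empirical α-tolerance interval is the shortest window
  [x₍ⱼ₎, x₍ⱼ₊ₘ₋₁₎] of m = ⌈α·n⌉ consecutive order statistics, ties broken
  by the smallest j. One embedding per replicate serves all pairs at once;
  this is distributionally identical to per-pair simulation and removes
  the dominant cost. Membership is closed (boundary counts as compatible).
* **Compatibility graph.** Edge between (t₁,i₁) and (t₂,i₂) iff t₁≠t₂,
  i₁≠i₂ and d̃(t₁,t₂) ∈ [l,u]_{i₁,i₂}. Vertices sharing a target or an
  identified record are never adjacent: without this rule a clique could
  assert contradictory matches; with it every clique is a one-to-one
  partial matching.
* **Maximum clique.** Exact branch and bound with a greedy-colouring upper
  bound over bitmask candidate sets. Each vertex expansion counts as one
  branching step against a budget (default 20,000,000); an exhausted
  search certifies optimality, otherwise the incumbent — always a valid
  clique — is returned with `clique_search_exhausted=False`. The vertex
  order is fixed by sorting on (target id, ident id), so ties among
  maximum cliques resolve deterministically to the first clique found.
* **Scoring.** precision = TP/(TP+FP), recall = TP/(TP+FN) against the
  known overlap. An empty claimed matching has *undefined* precision
  (reported as None/NaN, never silently 0); replicate aggregation averages
  precision over replicates with ≥1 match and reports the undefined count
  separately.

## Synthetic scenarios

The generator emulates the statistical structure that the attack's
difficulty actually depends on — candidate-set size ≫ true overlap — not
any real geography. Units are uniform over a default rectangle (lat 47–53,
lon 6–14, ≈6°×8°); overlapping units appear in both files with identical
coordinates and quasi-identifiers; the two schemes are a 20-symbol
facility code (emulating 2-character truncated organisational codes) and
sex ∈ {F, M} × age ∈ {18..90}, both uniform and independent of location.
Under that independence the expected candidate count has the closed form
n_overlap + (n_t·n_i − n_overlap)·p with p = 1/20 or 1/146, used as a
sizing guard and verified by Monte-Carlo. What the generator does *not*
reproduce: real population density (addresses cluster in cities), spatial
correlation of attributes, realistic age pyramids or code frequencies, and
measurement error. Passing tests therefore demonstrate the mechanics and
the parameter dependence of privacy/utility, not attack rates on any real
registry.

## Experiments and problem sizes

`run_experiment` sweeps a (d, k, α) grid; every replicate draws a fresh
file pair, a fresh embedding and a full attack, all seeded through named
RNG substreams (one per grid cell and replicate) so any row is reproducible
in isolation. The package's privacy endpoints are computed on a 150+150
record scenario with overlap 15 — large enough that |V| (≈170) far exceeds
the overlap, the regime where the attack is hard, while keeping a full
10-replicate audit to seconds. Under the protective setting (d=20, k=30,
α=0.5) mean precision sits well below the 25% k-anonymity (k=4) benchmark;
under the informative setting (d=500, k=1) it approaches 1, and the gap
between the two is the package's headline monotonicity check.

## Numerical choices

* Haversine is clipped into [0, 1] before `arcsin` to absorb rounding at
  antipodes; exact and approximate matrices are symmetrised by averaging
  with their transpose to remove float noise before validation.
* Matrix invariants (symmetry, zero diagonal, nonnegativity) are checked at
  construction with 1e-9 km tolerances; triangle-inequality checks use the
  same tolerance.
* Nearest-neighbour ties (possible under D̃, which can be 0 for distinct
  records) break to the lowest index in both matrices, so D̃ = D always
  scores 1. Spearman ρ uses average ranks on ties and is reported as NaN
  when either distance vector is constant.
* Anchor records for the utility report: the record nearest the coordinate
  centroid ("central") and the record nearest the bounding-box corner
  farthest from the centroid ("border").
* `EmbeddingParams.seed` feeds a named substream ("reference-sets");
  passing an explicit Generator overrides it, which is how replicated
  simulations share one stream.

## Design choices that were genuinely open

* Whether repeated releases of overlapping data should reuse reference
  sets is policy, not mechanics; the seed is exposed and the decision left
  to the custodian.
* The compatibility test in the literature is purely distance-based; the
  one-to-one edge rule is our strengthening (documented above) and makes
  the clique interpretable as a matching.
* Experiment replicates redraw the file pair, not just the embedding, so
  reported means average over data realisations as well as embedding
  randomness.
* The replicate mean of precision excludes undefined (no-match) replicates
  rather than imputing 0; an attack that claims nothing has not been
  *wrong*, it has failed, and the two are reported separately.

## Limitations

Spherical rather than ellipsoidal distances (≈0.3% scale error, irrelevant
for relative comparisons); uniform synthetic geography (see above); the
exact clique search is exponential in the worst case — on large, dense
compatibility graphs the step budget truncates it and results become lower
bounds on the adversary's power; and the tolerance-interval adversary is
one specific (if natural) attack — the audit bounds that attack's success,
not all conceivable attacks.
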
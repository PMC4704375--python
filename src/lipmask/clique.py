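"""Exact maximum-clique search by branch and bound.

Tomita-style algorithm: at each node the candidate set is greedily
coloured; the number of colours bounds the best clique extending the
current one, and branches that cannot beat the incumbent are pruned.
Vertices and candidate sets are Python-int bitmasks, which keeps the inner
loops to a handful of word-level operations per step.

The search is budgeted: each vertex expansion counts as one branching step,
and when the budget runs out the incumbent (always a valid clique) is
returned with exhausted=False. An exhausted search certifies a true maximum
clique. The search order is deterministic, so ties among maximum cliques
resolve to the first one found.
"""

from __future__ import annotations

__all__ = ["max_clique_bitset"]


def max_clique_bitset(adj: list[int], step_limit: int = 20_000_000) -> tuple[list[int], bool]:
    """Maximum clique of a simple undirected graph given as bitmask rows.

    adj[v] has bit u set iff {v, u} is an edge; diagonals must be clear.
    Returns (sorted vertex list, exhausted). An empty graph yields ([], True).
    """
    n = len(adj)
    if n == 0:
        return [], True
    for v in range(n):
        if adj[v] >> n:
            raise ValueError("adjacency mask references a vertex out of range")
        if adj[v] & (1 << v):
            raise ValueError(f"self-loop on vertex {v}")

    best: list[int] = []
    steps = 0
    exhausted = True

    def expand(clique: list[int], cand: int) -> None:
        nonlocal best, steps, exhausted
        # Greedy colouring of cand; order holds vertices by nondecreasing
        # colour so iterating from the back visits high-colour vertices
        # (weakest bound) first.
        order: list[int] = []
        colours: list[int] = []
        uncoloured = cand
        colour = 0
        while uncoloured:
            colour += 1
            q = uncoloured
            while q:
                v = (q & -q).bit_length() - 1
                bit = 1 << v
                q &= ~adj[v]
                q &= ~bit
                uncoloured &= ~bit
                order.append(v)
                colours.append(colour)
        for i in range(len(order) - 1, -1, -1):
            if len(clique) + colours[i] <= len(best):
                return  # colour bound prunes this and all earlier vertices
            if steps >= step_limit:
                exhausted = False
                return
            steps += 1
            v = order[i]
            clique.append(v)
            sub = cand & adj[v]
            if sub:
                expand(clique, sub)
            elif len(clique) > len(best):
                best = clique.copy()
            clique.pop()
            if not exhausted:
                return
            cand &= ~(1 << v)

    expand([], (1 << n) - 1)
    return sorted(best), exhausted
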
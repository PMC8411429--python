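"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the implementation: the
transitive closure is computed by repeated boolean matrix squaring over an
adjacency matrix, and value-set expansion by naive set arithmetic over
that closure.
"""

from __future__ import annotations

import numpy as np


def random_dag(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.15):
    """A random DAG on nodes "n0".."n{k-1}"; edges only from lower to
    higher index (guaranteed acyclic), returned as (codes, parent-of map).

    Edge direction: child -> parent means the LOWER-index node is the
    parent, so descendants flow toward higher indices.
    """
    codes = [f"n{i}" for i in range(n_nodes)]
    parents: dict[str, set[str]] = {c: set() for c in codes}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                parents[codes[j]].add(codes[i])
    return codes, parents


def closure_by_squaring(codes: list[str], parents: dict[str, set[str]]
                        ) -> dict[str, set[str]]:
    """Reflexive-free transitive closure parent -> all descendants, via
    repeated squaring of the boolean adjacency matrix."""
    n = len(codes)
    idx = {c: i for i, c in enumerate(codes)}
    adj = np.zeros((n, n), dtype=bool)  # adj[p, c]: c is a child of p
    for child, ps in parents.items():
        for p in ps:
            adj[idx[p], idx[child]] = True
    reach = adj.copy()
    for _ in range(max(1, int(np.ceil(np.log2(max(n, 2))))) + 1):
        reach = reach | (reach @ reach)
    return {c: {codes[j] for j in np.flatnonzero(reach[i])}
            for c, i in idx.items()}


def expand_by_brute_force(
    closure: dict[str, set[str]],
    includes: list[tuple[str, bool]],
    excludes: list[tuple[str, bool]],
) -> set[str]:
    """Naive include/exclude set arithmetic over a precomputed closure."""

    def term(code: str, with_desc: bool) -> set[str]:
        return {code} | (closure[code] if with_desc else set())

    inc: set[str] = set()
    for code, wd in includes:
        inc |= term(code, wd)
    exc: set[str] = set()
    for code, wd in excludes:
        exc |= term(code, wd)
    return inc - exc
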
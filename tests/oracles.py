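"""Independent oracles used to validate the statistical core.

Everything here is deliberately naive: exact rational arithmetic, literal
enumeration, or exhaustive search.  None of it shares code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def exact_pair_tails(N: int, N1: int, N2: int, j_obs: int) -> tuple[Fraction, Fraction]:
    """Exact (p_gt, p_lt) by rational summation of the co-occurrence PMF."""
    lo = max(0, N1 + N2 - N)
    hi = min(N1, N2)
    denom = comb(N, N2)
    pmf = {j: Fraction(comb(N1, j) * comb(N - N1, N2 - j), denom) for j in range(lo, hi + 1)}
    p_gt = sum(p for j, p in pmf.items() if j >= j_obs)
    p_lt = sum(p for j, p in pmf.items() if j <= j_obs)
    return p_gt, p_lt


def enumerate_pair_p_gt(N: int, N1: int, N2: int, j_obs: int) -> Fraction:
    """p_gt by literal enumeration of all C(N,N1)·C(N,N2) placements (tiny N)."""
    total = 0
    hits = 0
    for a in combinations(range(N), N1):
        sa = set(a)
        for b in combinations(range(N), N2):
            total += 1
            if len(sa & set(b)) >= j_obs:
                hits += 1
    return Fraction(hits, total)


def exact_hypergeom_upper(k: int, M: int, K: int, n: int) -> Fraction:
    """Exact upper tail P(X >= k) for X ~ Hypergeom(M, K, n)."""
    denom = comb(M, n)
    return sum(
        Fraction(comb(K, i) * comb(M - K, n - i), denom)
        for i in range(k, min(n, K) + 1)
        if n - i <= M - K
    )


def enumerate_hypergeom_upper(k: int, M: int, K: int, n: int) -> Fraction:
    """Upper tail by literal enumeration of all C(M, n) query draws."""
    successes = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(M), n):
        total += 1
        if len(successes & set(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def stepup_bh(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up computed by the textbook loop."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def naive_betweenness(nodes: list, edges: list[tuple]) -> dict:
    """Betweenness by BFS + explicit enumeration of all shortest paths."""
    adj: dict = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    score = {v: 0.0 for v in nodes}
    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        for t in node_list[i + 1 :]:
            if t not in dist:
                continue
            # enumerate all shortest s->t paths by walking the BFS DAG
            paths: list[tuple] = []
            stack = [(t, (t,))]
            while stack:
                u, path = stack.pop()
                if u == s:
                    paths.append(path)
                    continue
                for w in adj[u]:
                    if w in dist and dist[w] == dist[u] - 1:
                        stack.append((w, (w,) + path))
            n_paths = len(paths)
            if n_paths == 0:
                continue
            interior: dict = {}
            for path in paths:
                for v in path[1:-1]:
                    interior[v] = interior.get(v, 0) + 1
            for v, count in interior.items():
                score[v] += count / n_paths
    return score


def set_partitions(items: list):
    """All partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1 :]
        yield [[first]] + partition


def exhaustive_cpm_optimum(nodes: list, edges: list[tuple], gamma: float) -> float:
    """Best CPM quality over every partition of the node set."""
    edge_set = {frozenset(e) for e in edges}
    best = float("-inf")
    for partition in set_partitions(list(nodes)):
        q = 0.0
        for block in partition:
            block_set = set(block)
            e_c = sum(
                1 for e in edge_set if len(e & block_set) == 2
            )
            n_c = len(block)
            q += e_c - gamma * n_c * (n_c - 1) / 2
        if q > best:
            best = q
    return best
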
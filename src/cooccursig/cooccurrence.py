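"""Exact probabilistic model of species co-occurrence on presence/absence data.

For two species occupying N1 and N2 of N samples, the number of jointly
occupied samples under random, independent placement follows the
hypergeometric law

    P(j) = C(N1, j) · C(N − N1, N2 − j) / C(N, N2)

over the feasible range max(0, N1 + N2 − N) ≤ j ≤ min(N1, N2).  The
significance of a positive association is the upper tail
p_gt = P(J ≥ j_obs); the lower tail p_lt = P(J ≤ j_obs).  Both tails include
the observed term, so p_gt + p_lt = 1 + P(j_obs).  Probabilities are computed
in log space from log-factorials so panels up to N ≈ 10⁴ remain accurate, and
each tail is accumulated from its far end inward (smallest terms first).

An unweighted, undirected network is built by drawing an edge for every pair
with p_gt < alpha; by default pairs whose expected co-occurrence N1·N2/N is
below 1 are not tested, mirroring the usual screening of uninformative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .preprocess import PresenceMatrix

__all__ = [
    "CooccurrencePair",
    "pair_probability",
    "all_pairs",
    "build_network",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class CooccurrencePair:
    """One unordered species pair's occupancy counts and exact tail tests."""

    species_a: str
    species_b: str
    n_samples: int
    occ_a: int
    occ_b: int
    obs: int
    expected: float
    p_gt: float
    p_lt: float
    significant: bool

    def __post_init__(self) -> None:
        if self.species_a >= self.species_b:
            raise ValueError("species_a must sort before species_b")
        lo = max(0, self.occ_a + self.occ_b - self.n_samples)
        hi = min(self.occ_a, self.occ_b)
        if not lo <= self.obs <= hi:
            raise ValueError(
                f"observed co-occurrence {self.obs} outside feasible [{lo}, {hi}]"
            )


def _log_pmf_terms(N: int, N1: int, N2: int) -> tuple[np.ndarray, int]:
    """Log P(j) for all feasible j; returns (terms, lo) with j = lo..lo+len-1."""
    lo = max(0, N1 + N2 - N)
    hi = min(N1, N2)
    j = np.arange(lo, hi + 1)
    logs = (
        _lchoose(N1, j)
        + _lchoose(N - N1, N2 - j)
        - _lchoose(N, N2)
    )
    return logs, lo


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def pair_probability(N: int, N1: int, N2: int, j_obs: int) -> tuple[float, float, float]:
    """Exact (p_gt, p_lt, expected) for observed joint occupancy ``j_obs``.

    Both tails include the observed term.  Raises if ``j_obs`` is outside the
    feasible range for the given occupancies.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValueError(f"occupancies must satisfy 0 <= N1, N2 <= N (got {N1}, {N2}, N={N})")
    lo = max(0, N1 + N2 - N)
    hi = min(N1, N2)
    if not lo <= j_obs <= hi:
        raise ValueError(f"j_obs={j_obs} infeasible for N={N}, N1={N1}, N2={N2}")
    logs, lo = _log_pmf_terms(N, N1, N2)
    pmf = np.exp(logs)
    i = j_obs - lo
    # accumulate each tail from its far end so small terms add first
    p_gt = float(pmf[i:][::-1].sum())
    p_lt = float(pmf[: i + 1].sum())
    expected = N1 * N2 / N
    return min(p_gt, 1.0), min(p_lt, 1.0), expected


def all_pairs(
    matrix: PresenceMatrix,
    alpha: float = 0.05,
    expected_threshold: float = 1.0,
) -> list[CooccurrencePair]:
    """Test every unordered species pair with expected co-occurrence ≥ threshold.

    Returns one record per tested pair in lexicographic pair order, flagged
    significant iff p_gt < alpha (strict).  Set ``expected_threshold=0`` to
    test all C(S, 2) pairs.
    """
    cells = matrix.cells.to_numpy(dtype=np.int64)
    species = matrix.species
    if len(species) < 2 or len(matrix.samples) < 1:
        return []
    N = len(matrix.samples)
    order = np.argsort(np.asarray(species, dtype=object))
    cells = cells[order]
    names = [species[i] for i in order]
    occ = cells.sum(axis=1)
    joint = cells @ cells.T
    out: list[CooccurrencePair] = []
    for ia, ib in combinations(range(len(names)), 2):
        n1, n2 = int(occ[ia]), int(occ[ib])
        expected = n1 * n2 / N
        if expected < expected_threshold:
            continue
        j_obs = int(joint[ia, ib])
        p_gt, p_lt, _ = pair_probability(N, n1, n2, j_obs)
        out.append(
            CooccurrencePair(
                species_a=names[ia],
                species_b=names[ib],
                n_samples=N,
                occ_a=n1,
                occ_b=n2,
                obs=j_obs,
                expected=expected,
                p_gt=p_gt,
                p_lt=p_lt,
                significant=p_gt < alpha,
            )
        )
    return out


def build_network(
    pairs: list[CooccurrencePair],
    phenotype: str,
    dataset: str = "",
    alpha: float = 0.05,
    *,
    all_species: list[str] | None = None,
) -> nx.Graph:
    """Unweighted network of significantly positively co-occurring species.

    Nodes are the species incident to at least one significant edge; pass
    ``all_species`` to retain every tested species as (possibly isolated)
    nodes for diagnostics.  Graph attributes record phenotype, dataset and
    the alpha used.
    """
    g = nx.Graph(phenotype=phenotype, dataset=dataset, alpha=alpha)
    if all_species is not None:
        g.add_nodes_from(sorted(all_species))
    for pair in pairs:
        if pair.significant:
            g.add_edge(pair.species_a, pair.species_b)
    return g


def pairs_to_frame(pairs: list[CooccurrencePair]) -> pd.DataFrame:
    """Pair table with one row per tested pair, in deterministic order."""
    columns = [
        "species_a", "species_b", "N", "N1", "N2",
        "obs", "expected", "p_gt", "p_lt", "significant",
    ]
    records = [
        (p.species_a, p.species_b, p.n_samples, p.occ_a, p.occ_b,
         p.obs, p.expected, p.p_gt, p.p_lt, p.significant)
        for p in pairs
    ]
    return pd.DataFrame(records, columns=columns)
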
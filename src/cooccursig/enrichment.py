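"""Species→KO mapping and hypergeometric KEGG-pathway enrichment.

A species of interest contributes every KO whose stratified abundance is
positive in at least one sample of the phenotype subset.  For a query of n
KOs (intersected with the annotation universe of M KOs) and a pathway
annotating K of them, the enrichment p-value is the upper hypergeometric
tail

    p = Σ_{i=k}^{min(n,K)} C(K, i) · C(M−K, n−i) / C(M, n)

including the observed overlap k.  P-values are Benjamini–Hochberg adjusted
across all pathways with at least one hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import KOProfile, PathwayAnnotation, UNSTRATIFIED

__all__ = [
    "EnrichmentRow",
    "species_to_kos",
    "hypergeom_upper_tail",
    "enrich",
    "bh_adjust",
    "significant_pathways",
]


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), including the observed term."""
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValueError("require 0 <= K, n <= M")
    return float(min(hypergeom.sf(k - 1, M, K, n), 1.0))

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    """One pathway's hypergeometric enrichment result."""

    pathway_id: str
    description: str
    k: int  # query KOs in the pathway
    n: int  # query KOs in the universe
    K: int  # pathway KOs in the universe
    M: int  # universe size
    pvalue: float
    p_adjust: float
    ko_hits: frozenset[str]

    @property
    def gene_ratio(self) -> str:
        return f"{self.k}/{self.n}"

    @property
    def bg_ratio(self) -> str:
        return f"{self.K}/{self.M}"


def species_to_kos(
    ko_profile: KOProfile,
    species_set: Iterable[str],
    sample_subset: Sequence[str],
) -> dict[str, frozenset[str]]:
    """Map each species to the KOs it contributes in the given samples.

    A KO counts when its stratified abundance for the species is positive in
    at least one subset sample.  Species without any stratified entry are
    dropped with a warning.
    """
    sample_subset = list(sample_subset)
    if not sample_subset:
        raise ValueError("sample_subset must be non-empty")
    wanted = set(species_set)
    entries = ko_profile.entries
    mask = (
        (entries["species"] != UNSTRATIFIED)
        & entries["species"].isin(wanted)
        & entries["sample"].isin(set(sample_subset))
        & (entries["abundance"] > 0)
    )
    grouped = entries.loc[mask].groupby("species")["ko"]
    mapping = {species: frozenset(kos) for species, kos in grouped}
    missing = wanted - set(mapping)
    if missing:
        logger.warning(
            "%d species had no stratified KO entries in the subset: %s",
            len(missing), sorted(missing)[:5],
        )
    return mapping


def bh_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, returned in input order.

    ``'bh'`` is the Benjamini–Hochberg step-up (adj_i = min_{j≥i} m·p_j/j on
    the sorted scale, capped at 1); ``'bonferroni'`` is also available.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


def enrich(
    query_kos: Iterable[str],
    annotation: PathwayAnnotation,
    universe_mode: str = "annotation",
    observed_kos: Iterable[str] | None = None,
    adjust_method: str = "bh",
) -> list[EnrichmentRow]:
    """Hypergeometric pathway enrichment of a KO query set.

    ``universe_mode='annotation'`` uses every annotated KO as the background;
    ``'observed'`` restricts the background (and each pathway) to KOs also
    seen in the dataset's KO profile, supplied as ``observed_kos``.  Only
    pathways with at least one query hit are returned, sorted by p-value
    then pathway id.
    """
    query = set(query_kos)
    universe = set(annotation.universe)
    if universe_mode == "observed":
        if observed_kos is None:
            raise ValueError("universe_mode='observed' requires observed_kos")
        universe &= set(observed_kos)
    elif universe_mode != "annotation":
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    n_query = len(query & universe)
    if n_query == 0:
        raise ValueError(
            "query KO set does not intersect the annotation universe; "
            "check that the KO profile and annotation use the same identifiers"
        )
    M = len(universe)
    rows: list[tuple[str, int, int, frozenset[str], float]] = []
    for pid, kos in annotation.pathways.items():
        pathway_kos = kos & universe
        K = len(pathway_kos)
        hits = frozenset(query & pathway_kos)
        k = len(hits)
        if k == 0:
            continue
        pvalue = hypergeom_upper_tail(k, M, K, n_query)
        rows.append((pid, k, K, hits, pvalue))
    adjusted = bh_adjust([r[4] for r in rows], method=adjust_method)
    out = [
        EnrichmentRow(
            pathway_id=pid,
            description=annotation.descriptions.get(pid, pid),
            k=k,
            n=n_query,
            K=K,
            M=M,
            pvalue=pvalue,
            p_adjust=float(adj),
            ko_hits=hits,
        )
        for (pid, k, K, hits, pvalue), adj in zip(rows, adjusted)
    ]
    out.sort(key=lambda r: (r.pvalue, r.pathway_id))
    return out


def significant_pathways(
    rows: Iterable[EnrichmentRow], alpha: float = 0.05, use_adjusted: bool = True
) -> set[str]:
    """Pathways whose (adjusted, by default) p-value is strictly below alpha."""
    return {
        r.pathway_id
        for r in rows
        if (r.p_adjust if use_adjusted else r.pvalue) < alpha
    }
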
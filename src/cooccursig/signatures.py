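"""Cross-phenotype and cross-dataset signature extraction.

A signature pathway is one that is (i) significantly enriched in the
disease phenotype's co-occurring species, (ii) absent from the control
phenotype's enriched set, and (iii) replicated across independent datasets.
These set operations are applied at each analysis level (global network,
community, top-hub, top-betweenness); the community level additionally
records, per robust pathway, which clusters carried it and how many of each
cluster's species contributed KOs to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import EnrichmentRow, significant_pathways
from .io import PathwayAnnotation

__all__ = [
    "ClusterContribution",
    "SignatureReport",
    "disease_unique",
    "robust_intersection",
    "community_level_signature",
    "ko_contribution_counts",
    "network_jaccard",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterContribution:
    """One cluster's contribution to a pathway: the 'Cluster No. / Total
    Species / Contrib. Species' triple."""

    cluster_id: int
    total_species: int
    contributing_species: tuple[str, ...]

    @property
    def n_contributing(self) -> int:
        return len(self.contributing_species)


@dataclass
class SignatureReport:
    """Robust (cross-dataset, disease-unique) pathways at one analysis level."""

    level: str  # global | community | centrality-hub | centrality-betweenness
    phenotype: str
    robust_pathways: set[str]
    per_dataset_unique: dict[str, set[str]] = field(default_factory=dict)
    # pathway -> dataset -> contributing clusters (community level only)
    cluster_detail: dict[str, dict[str, list[ClusterContribution]]] = field(
        default_factory=dict
    )
    # pathway -> dataset -> list of (species, k_s, K) contribution counts
    species_counts: dict[str, dict[str, list[tuple[str, int, int]]]] = field(
        default_factory=dict
    )


def disease_unique(
    disease_pathways: Iterable[str], control_pathways: Iterable[str]
) -> set[str]:
    """Pathways enriched in the disease phenotype but not in the control."""
    return set(disease_pathways) - set(control_pathways)


def robust_intersection(per_dataset_unique: Sequence[Iterable[str]]) -> set[str]:
    """Pathways shared by every dataset's disease-unique set."""
    sets = [set(s) for s in per_dataset_unique]
    if not sets:
        return set()
    if len(sets) == 1:
        logger.warning("robust_intersection called with a single dataset")
        return sets[0]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def ko_contribution_counts(
    pathway_id: str,
    species_ko_map: Mapping[str, frozenset[str]],
    annotation: PathwayAnnotation,
) -> tuple[list[tuple[str, int, int]], int]:
    """Per-species KO counts for a pathway, plus the union coverage.

    Returns ``([(species, k_s, K), ...], union_coverage)`` where
    k_s = |KOs of species s ∩ pathway| (species with k_s = 0 omitted),
    K = pathway size, and union_coverage = |∪_s (KOs of s ∩ pathway)| — how
    much of the pathway the community covers collectively.  Rendered
    downstream as the familiar "k_s/K" strings.
    """
    pathway_kos = annotation.pathways[pathway_id]
    K = len(pathway_kos)
    counts: list[tuple[str, int, int]] = []
    union: set[str] = set()
    for species in sorted(species_ko_map):
        hits = species_ko_map[species] & pathway_kos
        if hits:
            counts.append((species, len(hits), K))
            union |= hits
    counts.sort(key=lambda item: (-item[1], item[0]))
    return counts, len(union)


def community_level_signature(
    disease_clusters: Mapping[str, Mapping[int, tuple[list[str], list[EnrichmentRow]]]],
    control_clusters: Mapping[str, Mapping[int, tuple[list[str], list[EnrichmentRow]]]],
    annotation: PathwayAnnotation,
    species_ko_maps: Mapping[str, Mapping[str, frozenset[str]]],
    *,
    phenotype: str,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    subtract_control: bool = True,
) -> SignatureReport:
    """Community-level signature across datasets.

    ``disease_clusters[dataset][cluster_id] = (cluster species, enrichment
    rows)``; likewise for the control phenotype.  Per dataset the disease
    pathway pool is the union of significant pathways over disease clusters;
    with ``subtract_control`` the union over control clusters is subtracted
    before intersecting across datasets (set False for the pure
    cross-dataset-consistency reading).  For every robust pathway and
    dataset, each contributing cluster is recorded with its total species
    count and the species that carry at least one pathway KO.
    """
    per_dataset_unique: dict[str, set[str]] = {}
    for dataset, clusters in disease_clusters.items():
        pool: set[str] = set()
        for _, rows in clusters.values():
            pool |= significant_pathways(rows, alpha=alpha, use_adjusted=use_adjusted)
        if subtract_control:
            control_pool: set[str] = set()
            for _, rows in control_clusters.get(dataset, {}).values():
                control_pool |= significant_pathways(
                    rows, alpha=alpha, use_adjusted=use_adjusted
                )
            pool = disease_unique(pool, control_pool)
        per_dataset_unique[dataset] = pool
    robust = robust_intersection(
        [per_dataset_unique[d] for d in sorted(per_dataset_unique)]
    )
    report = SignatureReport(
        level="community",
        phenotype=phenotype,
        robust_pathways=robust,
        per_dataset_unique=per_dataset_unique,
    )
    for pathway in sorted(robust):
        pathway_kos = annotation.pathways[pathway]
        report.cluster_detail[pathway] = {}
        report.species_counts[pathway] = {}
        for dataset, clusters in disease_clusters.items():
            contributions: list[ClusterContribution] = []
            for cid in sorted(clusters):
                members, rows = clusters[cid]
                if pathway not in significant_pathways(
                    rows, alpha=alpha, use_adjusted=use_adjusted
                ):
                    continue
                ko_map = species_ko_maps[dataset]
                contributing = tuple(
                    s for s in sorted(members) if ko_map.get(s, frozenset()) & pathway_kos
                )
                contributions.append(
                    ClusterContribution(
                        cluster_id=cid,
                        total_species=len(members),
                        contributing_species=contributing,
                    )
                )
            report.cluster_detail[pathway][dataset] = contributions
            members_union: dict[str, frozenset[str]] = {}
            for contrib in contributions:
                for s in contrib.contributing_species:
                    members_union[s] = species_ko_maps[dataset].get(s, frozenset())
            counts, _ = ko_contribution_counts(pathway, members_union, annotation)
            report.species_counts[pathway][dataset] = counts
    return report


def network_jaccard(net1: nx.Graph, net2: nx.Graph, elements: str = "nodes") -> float:
    """Jaccard index of two networks' species (or edge) sets; 0 if both empty."""
    if elements == "nodes":
        a, b = set(net1.nodes()), set(net2.nodes())
    elif elements == "edges":
        a = {tuple(sorted(e)) for e in net1.edges()}
        b = {tuple(sorted(e)) for e in net2.edges()}
    else:
        raise ValueError(f"unknown elements {elements!r}")
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
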
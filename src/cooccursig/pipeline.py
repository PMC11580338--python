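"""End-to-end orchestration: filter → network → analyze → enrich → compare.

The pipeline runs per (dataset, phenotype): the filter cascade produces a
presence/absence matrix, the exact pair test produces the co-occurrence
network, the network is analyzed at the global, community, and key-element
levels, each level's species set is mapped to KOs and enriched against the
pathway annotation, and finally disease-vs-control subtraction plus
cross-dataset intersection yields the robust signature pathways.

Every stage is a pure function of (inputs, config, seed); file outputs are
deterministic so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as io_formats
from .cooccurrence import all_pairs, build_network, pairs_to_frame
from .enrichment import EnrichmentRow, enrich, significant_pathways, species_to_kos
from .io import AbundanceTable, KOProfile, PathwayAnnotation, PHENOTYPES
from .network import (
    CommunityPartition,
    centrality_report,
    default_resolution,
    leiden_cpm,
)
from .preprocess import FilterCriteria, binarize, run_filter_cascade
from .signatures import (
    SignatureReport,
    community_level_signature,
    disease_unique,
    ko_contribution_counts,
    network_jaccard,
    robust_intersection,
)

__all__ = ["DatasetInputs", "RunConfig", "run_all", "analyze_dataset", "compare_datasets"]

LEVELS = ("global", "community", "hub", "betweenness")


@dataclass
class DatasetInputs:
    """In-memory inputs for one cohort."""

    name: str
    abundance: AbundanceTable
    ko_profile: KOProfile
    metadata: pd.DataFrame
    annotation: PathwayAnnotation

    @classmethod
    def from_paths(
        cls, name: str, taxonomic, ko, metadata, annotation
    ) -> "DatasetInputs":
        return cls(
            name=name,
            abundance=io_formats.read_taxonomic_profile(taxonomic),
            ko_profile=io_formats.read_ko_profile(ko),
            metadata=io_formats.read_metadata(metadata),
            annotation=io_formats.read_pathway_annotation(annotation),
        )


@dataclass
class RunConfig:
    """All knobs of a pipeline run; ambiguity-prone ones are explicit."""

    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    alpha_cooccur: float = 0.05
    expected_threshold: float = 1.0
    alpha_enrich: float = 0.05
    use_adjusted: bool = True
    universe_mode: str = "annotation"
    adjust_method: str = "bh"
    resolution: float | None = None  # None → degree-quartile heuristic
    resolution_quantile: float = 0.25
    resolution_denominator: str = "n-1"
    leiden_seed: int = 42
    leiden_iterations: int = 10
    top_k: int = 5
    min_cluster_size: int = 2
    control_label: str = "control"
    community_subtract_control: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_cooccur", "alpha_enrich"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"]["excluded_kingdoms"] = sorted(
            self.criteria.excluded_kingdoms
        )
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        crit = data.pop("criteria", {})
        if isinstance(crit, dict):
            if "excluded_kingdoms" in crit:
                crit["excluded_kingdoms"] = frozenset(crit["excluded_kingdoms"])
            crit = FilterCriteria(**crit)
        return cls(criteria=crit, **data)

    @classmethod
    def from_yaml(cls, path) -> tuple["RunConfig", list[dict]]:
        """Load (config, dataset path entries) from a YAML run file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        datasets = raw.pop("datasets", [])
        if not datasets:
            raise ValueError("run config lists no datasets")
        return cls.from_dict(raw.get("options", {})), datasets


@dataclass
class PhenotypeResult:
    """Everything computed for one (dataset, phenotype)."""

    phenotype: str
    presence: object
    pairs: list
    network: object
    partition: CommunityPartition | None
    centrality: object | None
    species_ko_map: dict[str, frozenset[str]]
    enrichment: dict[str, list[EnrichmentRow]]  # level -> rows (community: pooled)
    cluster_enrichment: dict[int, tuple[list[str], list[EnrichmentRow]]]


@dataclass
class DatasetResult:
    name: str
    filter_report: object
    metadata: pd.DataFrame
    annotation: PathwayAnnotation
    phenotypes: dict[str, PhenotypeResult]


@dataclass
class ComparisonResult:
    """Signature reports per (disease phenotype, level) + network overlap."""

    signatures: dict[str, dict[str, SignatureReport]]  # phenotype -> level -> report
    jaccard: dict[str, dict[str, float]]  # phenotype -> "nodes"/"edges" -> value
    control_significant: dict[str, dict[str, set[str]]]  # dataset -> level -> sig set

    def robust_union(self, phenotype: str) -> set[str]:
        """Robust pathways for a phenotype across all analysis levels."""
        out: set[str] = set()
        for report in self.signatures.get(phenotype, {}).values():
            out |= report.robust_pathways
        return out


def _safe_enrich(query, annotation, config: RunConfig, observed):
    if not query:
        return []
    try:
        return enrich(
            query,
            annotation,
            universe_mode=config.universe_mode,
            observed_kos=observed,
            adjust_method=config.adjust_method,
        )
    except ValueError:
        return []


def analyze_dataset(inputs: DatasetInputs, config: RunConfig) -> DatasetResult:
    """Stages A–C plus enrichment for one cohort."""
    table, metadata, report = run_filter_cascade(
        inputs.abundance, inputs.metadata, config.criteria
    )
    observed = set(inputs.ko_profile.entries["ko"]) if config.universe_mode == "observed" else None
    phenotypes: dict[str, PhenotypeResult] = {}
    present_phens = [p for p in PHENOTYPES if p in set(metadata["phenotype"])]
    for phen in present_phens:
        presence = binarize(table, phen, metadata, dataset=inputs.name)
        pairs = all_pairs(
            presence,
            alpha=config.alpha_cooccur,
            expected_threshold=config.expected_threshold,
        )
        network = build_network(
            pairs, phenotype=phen, dataset=inputs.name, alpha=config.alpha_cooccur
        )
        partition = None
        centrality = None
        if network.number_of_nodes() >= 2:
            gamma = (
                config.resolution
                if config.resolution is not None
                else default_resolution(
                    network,
                    quantile=config.resolution_quantile,
                    denominator=config.resolution_denominator,
                )
            )
            partition = leiden_cpm(
                network,
                gamma=gamma,
                seed=config.leiden_seed,
                n_iterations=config.leiden_iterations,
            )
        if network.number_of_nodes() >= 1:
            centrality = centrality_report(network, k=config.top_k)

        phen_samples = metadata.loc[
            metadata["phenotype"] == phen, "sample_id"
        ].tolist()
        nodes = sorted(network.nodes())
        ko_map = (
            species_to_kos(inputs.ko_profile, nodes, phen_samples)
            if nodes and phen_samples
            else {}
        )

        def query_for(species_list):
            q: set[str] = set()
            for s in species_list:
                q |= ko_map.get(s, frozenset())
            return q

        enrichment: dict[str, list[EnrichmentRow]] = {}
        enrichment["global"] = _safe_enrich(query_for(nodes), inputs.annotation, config, observed)
        cluster_enrichment: dict[int, tuple[list[str], list[EnrichmentRow]]] = {}
        if partition is not None:
            for cid, members in partition.clusters().items():
                if len(members) < config.min_cluster_size:
                    continue
                rows = _safe_enrich(query_for(members), inputs.annotation, config, observed)
                cluster_enrichment[cid] = (members, rows)
        pooled: list[EnrichmentRow] = []
        for _, rows in cluster_enrichment.values():
            pooled.extend(rows)
        enrichment["community"] = pooled
        if centrality is not None:
            enrichment["hub"] = _safe_enrich(
                query_for(centrality.top_hub), inputs.annotation, config, observed
            )
            enrichment["betweenness"] = _safe_enrich(
                query_for(centrality.top_betweenness), inputs.annotation, config, observed
            )
        else:
            enrichment["hub"] = []
            enrichment["betweenness"] = []

        phenotypes[phen] = PhenotypeResult(
            phenotype=phen,
            presence=presence,
            pairs=pairs,
            network=network,
            partition=partition,
            centrality=centrality,
            species_ko_map=ko_map,
            enrichment=enrichment,
            cluster_enrichment=cluster_enrichment,
        )
    return DatasetResult(
        name=inputs.name,
        filter_report=report,
        metadata=metadata,
        annotation=inputs.annotation,
        phenotypes=phenotypes,
    )


def compare_datasets(results: list[DatasetResult], config: RunConfig) -> ComparisonResult:
    """Stage D: disease-vs-control subtraction and cross-dataset intersection."""
    control = config.control_label
    annotation = results[0].annotation
    phens = [
        p
        for p in PHENOTYPES
        if p != control and all(p in r.phenotypes for r in results)
    ]

    def sig(rows):
        return significant_pathways(
            rows, alpha=config.alpha_enrich, use_adjusted=config.use_adjusted
        )

    control_significant: dict[str, dict[str, set[str]]] = {}
    for r in results:
        if control in r.phenotypes:
            control_significant[r.name] = {
                level: sig(r.phenotypes[control].enrichment[level]) for level in LEVELS
            }
        else:
            control_significant[r.name] = {level: set() for level in LEVELS}

    signatures: dict[str, dict[str, SignatureReport]] = {}
    for phen in phens:
        signatures[phen] = {}
        # global / hub / betweenness: plain set algebra on significant sets
        for level in ("global", "hub", "betweenness"):
            per_dataset: dict[str, set[str]] = {}
            for r in results:
                disease_sig = sig(r.phenotypes[phen].enrichment[level])
                per_dataset[r.name] = disease_unique(
                    disease_sig, control_significant[r.name][level]
                )
            robust = robust_intersection([per_dataset[r.name] for r in results])
            label = level if level == "global" else f"centrality-{level}"
            report = SignatureReport(
                level=label,
                phenotype=phen,
                robust_pathways=robust,
                per_dataset_unique=per_dataset,
            )
            for pathway in sorted(robust):
                report.species_counts[pathway] = {}
                for r in results:
                    counts, _ = ko_contribution_counts(
                        pathway, r.phenotypes[phen].species_ko_map, annotation
                    )
                    report.species_counts[pathway][r.name] = counts
            signatures[phen][report.level] = report
        # community level with cluster detail
        disease_clusters = {r.name: r.phenotypes[phen].cluster_enrichment for r in results}
        control_clusters = {
            r.name: (
                r.phenotypes[control].cluster_enrichment
                if control in r.phenotypes
                else {}
            )
            for r in results
        }
        ko_maps = {r.name: r.phenotypes[phen].species_ko_map for r in results}
        signatures[phen]["community"] = community_level_signature(
            disease_clusters,
            control_clusters,
            annotation,
            ko_maps,
            phenotype=phen,
            alpha=config.alpha_enrich,
            use_adjusted=config.use_adjusted,
            subtract_control=config.community_subtract_control,
        )

    jaccard: dict[str, dict[str, float]] = {}
    if len(results) >= 2:
        first, second = results[0], results[1]
        for phen in PHENOTYPES:
            if phen in first.phenotypes and phen in second.phenotypes:
                jaccard[phen] = {
                    "nodes": network_jaccard(
                        first.phenotypes[phen].network, second.phenotypes[phen].network
                    ),
                    "edges": network_jaccard(
                        first.phenotypes[phen].network,
                        second.phenotypes[phen].network,
                        elements="edges",
                    ),
                }
    return ComparisonResult(
        signatures=signatures,
        jaccard=jaccard,
        control_significant=control_significant,
    )


# ---------------------------------------------------------------------------
# file outputs


def _write_partition(result: PhenotypeResult, path: Path) -> None:
    part = result.partition
    with open(path, "w") as fh:
        fh.write(f"# gamma={part.gamma!r}\n# quality={part.quality!r}\n# seed={part.seed}\n")
        fh.write("species\tcluster_id\n")
        for species in sorted(part.assignment):
            fh.write(f"{species}\t{part.assignment[species]}\n")


def _write_centrality(result: PhenotypeResult, path: Path) -> None:
    cent = result.centrality
    records = []
    for species in sorted(cent.hub):
        records.append(
            {
                "species": species,
                "hub": cent.hub[species],
                "betweenness": cent.betweenness[species],
                "top_hub": species in cent.top_hub,
                "top_betweenness": species in cent.top_betweenness,
            }
        )
    pd.DataFrame(
        records, columns=["species", "hub", "betweenness", "top_hub", "top_betweenness"]
    ).to_csv(path, sep="\t", index=False)


def _write_signatures(comparison: ComparisonResult, outdir: Path) -> None:
    sigdir = outdir / "signatures"
    sigdir.mkdir(parents=True, exist_ok=True)
    lines = ["# Signature pathways", ""]
    for phen in sorted(comparison.signatures):
        for level, report in sorted(comparison.signatures[phen].items()):
            lines.append(f"## {phen} — {level}")
            if report.robust_pathways:
                for pathway in sorted(report.robust_pathways):
                    lines.append(f"- {pathway}")
            else:
                lines.append("- None")
            lines.append("")
            records = []
            for pathway in sorted(report.robust_pathways):
                for dataset in sorted(report.per_dataset_unique):
                    if pathway in report.cluster_detail:
                        for contrib in report.cluster_detail[pathway].get(dataset, []):
                            records.append(
                                {
                                    "pathway": pathway,
                                    "dataset": dataset,
                                    "cluster_no": f"CL {contrib.cluster_id}",
                                    "total_species": contrib.total_species,
                                    "contrib_species": contrib.n_contributing,
                                }
                            )
            if records:
                pd.DataFrame(records).to_csv(
                    sigdir / f"{phen}_{level}_clusters.tsv", sep="\t", index=False
                )
            count_records = []
            for pathway in sorted(report.species_counts):
                for dataset in sorted(report.species_counts[pathway]):
                    for species, k_s, K in report.species_counts[pathway][dataset]:
                        count_records.append(
                            {
                                "pathway": pathway,
                                "dataset": dataset,
                                "species": species,
                                "n_kos": f"{k_s}/{K}",
                            }
                        )
            if count_records:
                pd.DataFrame(count_records).to_csv(
                    sigdir / f"{phen}_{level}_species_kos.tsv", sep="\t", index=False
                )
    if comparison.jaccard:
        lines.append("## Cross-dataset species overlap (Jaccard)")
        for phen in sorted(comparison.jaccard):
            j = comparison.jaccard[phen]
            lines.append(
                f"- {phen}: nodes {j['nodes']:.4f}, edges {j['edges']:.4f}"
            )
        lines.append("")
    (sigdir / "report.md").write_text("\n".join(lines))


def write_outputs(
    results: list[DatasetResult],
    comparison: ComparisonResult,
    config: RunConfig,
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    for sub in ("preprocess", "cooccurrence", "networks", "partitions", "centrality", "enrichment"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "datasets": {}}
    for r in results:
        prefix = r.name
        r.filter_report.to_frame().to_csv(
            outdir / "preprocess" / f"{prefix}_filter_report.tsv", sep="\t", index=False
        )
        r.metadata.to_csv(
            outdir / "preprocess" / f"{prefix}_metadata.tsv", sep="\t", index=False
        )
        ds_report: dict = {"filter_stages": r.filter_report.stages, "phenotypes": {}}
        for phen, pres in r.phenotypes.items():
            stem = f"{prefix}_{phen}"
            pres.presence.cells.to_csv(
                outdir / "preprocess" / f"{stem}_presence.tsv", sep="\t"
            )
            pairs_to_frame(pres.pairs).to_csv(
                outdir / "cooccurrence" / f"{stem}_pairs.tsv", sep="\t", index=False
            )
            io_formats.write_network(
                pres.network, outdir / "networks" / f"{stem}.edgelist.tsv"
            )
            io_formats.write_network(
                pres.network, outdir / "networks" / f"{stem}.graphml", format="graphml"
            )
            if pres.partition is not None:
                _write_partition(pres, outdir / "partitions" / f"{stem}_partition.tsv")
                pres.partition.summary().to_csv(
                    outdir / "partitions" / f"{stem}_clusters.tsv", sep="\t", index=False
                )
            if pres.centrality is not None:
                _write_centrality(pres, outdir / "centrality" / f"{stem}_centrality.tsv")
            for level in ("global", "hub", "betweenness"):
                io_formats.write_enrichment(
                    pres.enrichment[level],
                    outdir / "enrichment" / f"{stem}_{level}.tsv",
                )
            rows, clusters = [], []
            for cid in sorted(pres.cluster_enrichment):
                _, cluster_rows = pres.cluster_enrichment[cid]
                rows.extend(cluster_rows)
                clusters.extend([cid] * len(cluster_rows))
            io_formats.write_enrichment(
                rows, outdir / "enrichment" / f"{stem}_community.tsv", cluster=clusters
            )
            ds_report["phenotypes"][phen] = {
                "n_samples": len(pres.presence.samples),
                "n_species_present": len(pres.presence.species),
                "n_pairs_tested": len(pres.pairs),
                "n_significant_pairs": sum(p.significant for p in pres.pairs),
                "n_network_nodes": pres.network.number_of_nodes(),
                "n_network_edges": pres.network.number_of_edges(),
                "n_clusters": (
                    len(pres.partition.clusters()) if pres.partition else 0
                ),
                "resolution": pres.partition.gamma if pres.partition else None,
            }
        report["datasets"][r.name] = ds_report
    _write_signatures(comparison, outdir)
    report["jaccard"] = comparison.jaccard
    report["signatures"] = {
        phen: {
            level: sorted(rep.robust_pathways)
            for level, rep in comparison.signatures[phen].items()
        }
        for phen in comparison.signatures
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(
    datasets: list[DatasetInputs],
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[DatasetResult], ComparisonResult]:
    """Run the full pipeline over all cohorts; optionally write outputs."""
    if not datasets:
        raise ValueError("run_all requires at least one dataset")
    config = config or RunConfig()
    results = [analyze_dataset(ds, config) for ds in datasets]
    comparison = compare_datasets(results, config)
    if outdir is not None:
        write_outputs(results, comparison, config, outdir)
    return results, comparison


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
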
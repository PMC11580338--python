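"""Synthetic paired metagenome datasets with planted co-occurrence blocks.

The generator emulates the outputs of taxonomic + stratified functional
profiling for two independent cohorts, each with control/CD/UC phenotypes:

* background species occur independently per sample, with per-species
  occupancy probabilities spread over a realistic range, so null networks
  contain only sporadic false-positive edges;
* each disease phenotype carries a planted block of species that co-occur
  through a shared latent per-sample indicator (probability ``q``) with
  independent species dropout, and occur only at a low baseline ``p0``
  elsewhere;
* every block is tied to a planted pathway whose KOs are split disjointly
  across the block's species — no single species carries the whole pathway —
  so the pathway can only be recovered by the community acting together;
* the two datasets share the pathway annotation and background species pool
  but use disjoint block species names, reproducing the situation where
  species-level networks barely overlap across cohorts while the pathway
  signal replicates.

Abundance magnitudes are cosmetic (downstream analysis only uses positivity)
and are drawn log-uniformly when a species is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AbundanceTable,
    KOProfile,
    PathwayAnnotation,
    SpeciesId,
    UNSTRATIFIED,
)

__all__ = [
    "PlantedBlock",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "planted_truth",
    "write_dataset",
]

_GENERA = [
    "Bacteroides", "Prevotella", "Faecalibacterium", "Roseburia", "Blautia",
    "Alistipes", "Ruminococcus", "Clostridium", "Eubacterium", "Streptococcus",
]


@dataclass(frozen=True)
class PlantedBlock:
    """A co-occurring species block planted in one disease phenotype."""

    phenotype: str
    size: int = 5
    # moderate latent co-presence: at occupancy near 1 a presence/absence
    # test has no power (the null already predicts near-total overlap)
    q: float = 0.6
    # default blocks are disease-specific; the ubiquitous flora is modelled
    # by the background species, which occur in every phenotype
    p0: float = 0.0
    pathway_id: str = ""
    n_kos: int = 12

    def __post_init__(self) -> None:
        if not 0 <= self.p0 < self.q <= 1:
            raise ValueError("blocks require 0 <= p0 < q <= 1")
        if self.size < 2:
            raise ValueError("block size must be >= 2")
        if self.n_kos < self.size:
            raise ValueError(
                "planted pathway must have at least as many KOs as block species"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a paired synthetic experiment."""

    n_datasets: int = 2
    samples_per_phenotype: tuple[tuple[str, int], ...] = (
        ("control", 30), ("CD", 30), ("UC", 30),
    )
    n_background_species: int = 60
    blocks: tuple[PlantedBlock, ...] = (
        PlantedBlock(phenotype="CD", pathway_id="map99001"),
        PlantedBlock(phenotype="UC", pathway_id="map99002"),
    )
    n_background_pathways: int = 60
    kos_per_pathway: int = 12
    background_ko_pool: int = 1000
    background_kos_per_species: int = 5
    dropout: float = 0.9  # per-species survival given the latent indicator
    background_occupancy: tuple[float, float] = (0.05, 0.6)
    age_range: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        phenotypes = [p for p, _ in self.samples_per_phenotype]
        if len(set(phenotypes)) != len(phenotypes):
            raise ValueError("duplicate phenotype in samples_per_phenotype")
        for block in self.blocks:
            if block.phenotype not in phenotypes:
                raise ValueError(f"block phenotype {block.phenotype!r} has no samples")
        ids = [b.pathway_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValueError("planted pathway ids must be distinct")
        lo, hi = self.background_occupancy
        if not 0 <= lo <= hi <= 1:
            raise ValueError("background_occupancy bounds must satisfy 0<=lo<=hi<=1")


@dataclass
class SyntheticDataset:
    """One simulated cohort in the pipeline's input representation."""

    name: str
    abundance: AbundanceTable
    ko_profile: KOProfile
    metadata: pd.DataFrame
    annotation: PathwayAnnotation
    block_species: dict[str, list[str]] = field(default_factory=dict)


def _planted_kos(block_index: int, n_kos: int) -> list[str]:
    return [f"K9{block_index}{j:03d}" for j in range(1, n_kos + 1)]


def _background_pool(config: SimulationConfig) -> list[str]:
    return [f"K{j:05d}" for j in range(1, config.background_ko_pool + 1)]


def build_annotation(config: SimulationConfig) -> PathwayAnnotation:
    """The shared pathway→KO annotation (a function of the seed only)."""
    rng = np.random.default_rng([config.seed % 2**31, 11])
    pool = np.array(_background_pool(config))
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(config.n_background_pathways):
        pid = f"map8{i + 1:04d}"
        kos = rng.choice(pool, size=config.kos_per_pathway, replace=False)
        pathways[pid] = frozenset(kos.tolist())
        descriptions[pid] = f"background pathway {i + 1}"
    for b, block in enumerate(config.blocks):
        pathways[block.pathway_id] = frozenset(_planted_kos(b, block.n_kos))
        descriptions[block.pathway_id] = f"planted {block.phenotype} signature pathway"
    return PathwayAnnotation(pathways=pathways, descriptions=descriptions)


def _background_species_names(config: SimulationConfig) -> list[str]:
    names = []
    for i in range(config.n_background_species):
        genus = _GENERA[i % len(_GENERA)]
        names.append(f"{genus}_synthsp{i + 1:03d}")
    return names


def _background_repertoires(
    config: SimulationConfig, annotation: PathwayAnnotation
) -> dict[str, frozenset[str]]:
    """Background species gene content (shared across datasets).

    Drawn from the annotated background universe only; planted KOs never
    appear in background species, which is what makes the planted signal
    attributable to the blocks.
    """
    rng = np.random.default_rng([config.seed % 2**31, 12])
    planted = {ko for b, block in enumerate(config.blocks) for ko in _planted_kos(b, block.n_kos)}
    universe = np.array(sorted(annotation.universe - planted))
    out: dict[str, frozenset[str]] = {}
    for name in _background_species_names(config):
        kos = rng.choice(universe, size=config.background_kos_per_species, replace=False)
        out[name] = frozenset(kos.tolist())
    return out


def _block_species_names(config: SimulationConfig, dataset_index: int) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for block in config.blocks:
        out[block.phenotype] = [
            f"Synthcoccus_{block.phenotype.lower()}_d{dataset_index + 1}_{i + 1:02d}"
            for i in range(block.size)
        ]
    return out


def _lineage_for(name: str) -> SpeciesId:
    genus = name.split("_")[0]
    lineage = {
        "k": "Bacteria", "p": "Synthetica", "c": "Synthetica",
        "o": "Synthetica", "f": "Syntheticaceae", "g": genus, "s": name,
    }
    return SpeciesId(kingdom="Bacteria", lineage=lineage, canonical_name=name)


def simulate_dataset(config: SimulationConfig, dataset_index: int) -> SyntheticDataset:
    """Simulate one cohort; deterministic given (config.seed, dataset_index)."""
    if not 0 <= dataset_index < config.n_datasets:
        raise ValueError(f"dataset_index {dataset_index} out of range")
    rng = np.random.default_rng([config.seed % 2**31, 1000 + dataset_index])
    name = f"dataset{dataset_index + 1}"
    annotation = build_annotation(config)
    repertoires = dict(_background_repertoires(config, annotation))

    phenotypes = list(config.samples_per_phenotype)
    sample_ids: list[str] = []
    sample_phenotype: list[str] = []
    for phen, count in phenotypes:
        for k in range(count):
            sample_ids.append(f"D{dataset_index + 1}{phen}S{k + 1:03d}")
            sample_phenotype.append(phen)
    n_samples = len(sample_ids)
    phen_array = np.array(sample_phenotype)

    species: list[str] = list(_background_species_names(config))
    lo, hi = config.background_occupancy
    occupancy = rng.uniform(lo, hi, size=len(species))
    presence_rows = [rng.random(n_samples) < occupancy[i] for i in range(len(species))]

    block_names = _block_species_names(config, dataset_index)
    for b, block in enumerate(config.blocks):
        target = phen_array == block.phenotype
        planted = _planted_kos(b, block.n_kos)
        # disjoint, round-robin split of the pathway's KOs over block species
        slices: list[list[str]] = [[] for _ in range(block.size)]
        for j, ko in enumerate(planted):
            slices[j % block.size].append(ko)
        latent = rng.random(n_samples) < block.q
        for i, sp in enumerate(block_names[block.phenotype]):
            present = np.where(
                target,
                latent & (rng.random(n_samples) < config.dropout),
                rng.random(n_samples) < block.p0,
            )
            species.append(sp)
            presence_rows.append(present)
            extra = rng.choice(
                np.array(sorted(annotation.universe - set(planted))),
                size=config.background_kos_per_species,
                replace=False,
            )
            repertoires[sp] = frozenset(slices[i]) | frozenset(extra.tolist())

    presence = np.vstack(presence_rows)
    abundance = np.where(
        presence, 10.0 ** rng.uniform(-4, 1, size=presence.shape), 0.0
    )
    values = pd.DataFrame(abundance, index=species, columns=sample_ids)
    table = AbundanceTable(
        values=values, species_ids={s: _lineage_for(s) for s in species}
    )

    # stratified KO abundances: each (species, ko) gets a fixed positive factor
    records: list[tuple[str, str, str, float]] = []
    sample_arr = np.array(sample_ids)
    for i, sp in enumerate(species):
        present_samples = sample_arr[presence[i]]
        present_abund = abundance[i][presence[i]]
        for ko in sorted(repertoires[sp]):
            factor = rng.uniform(0.1, 1.0)
            for s, a in zip(present_samples, present_abund):
                records.append((ko, sp, s, a * factor))
    entries = pd.DataFrame(records, columns=["ko", "species", "sample", "abundance"])
    ko_profile = KOProfile(entries=entries, samples=sample_ids)

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n_samples)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"D{dataset_index + 1}subj{k + 1:03d}" for k in range(n_samples)],
            "phenotype": sample_phenotype,
            "age": ages,
            "visit_index": 1,
            "medication_excluded": False,
        }
    )
    return SyntheticDataset(
        name=name,
        abundance=table,
        ko_profile=ko_profile,
        metadata=metadata,
        annotation=annotation,
        block_species=block_names,
    )


def planted_truth(config: SimulationConfig) -> dict:
    """The signature the pipeline should recover, for use by tests."""
    return {
        "planted_pathways": {b.phenotype: b.pathway_id for b in config.blocks},
        "planted_kos": {
            b.phenotype: _planted_kos(i, b.n_kos) for i, b in enumerate(config.blocks)
        },
        "block_species": {
            f"dataset{d + 1}": _block_species_names(config, d)
            for d in range(config.n_datasets)
        },
    }


def _lineage_string(sid: SpeciesId) -> str:
    return "|".join(f"{r}__{sid.lineage[r]}" for r in ("k", "p", "c", "o", "f", "g", "s"))


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort in the pipeline's input file formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomic": directory / "taxonomic_profile.tsv",
        "ko": directory / "ko_profile.tsv",
        "metadata": directory / "metadata.tsv",
        "annotation": directory / "pathway_annotation.tsv",
    }
    samples = dataset.abundance.samples
    with open(paths["taxonomic"], "w") as fh:
        fh.write("#synthetic merged taxonomic profile\n")
        fh.write("clade_name\t" + "\t".join(samples) + "\n")
        for sp in dataset.abundance.species:
            sid = dataset.abundance.species_ids[sp]
            row = dataset.abundance.values.loc[sp]
            fh.write(_lineage_string(sid) + "\t" + "\t".join(repr(v) for v in row) + "\n")

    entries = dataset.ko_profile.entries
    strat = entries[entries["species"] != UNSTRATIFIED]
    wide = strat.pivot_table(
        index=["ko", "species"], columns="sample", values="abundance", fill_value=0.0
    ).reindex(columns=samples, fill_value=0.0)
    totals = strat.groupby("ko")[["abundance"]].sum()  # per-sample totals below
    totals_wide = strat.pivot_table(
        index="ko", columns="sample", values="abundance", aggfunc="sum", fill_value=0.0
    ).reindex(columns=samples, fill_value=0.0)
    del totals
    with open(paths["ko"], "w") as fh:
        fh.write("# Gene Family\t" + "\t".join(samples) + "\n")
        fh.write("UNMAPPED\t" + "\t".join(["1.0"] * len(samples)) + "\n")
        for ko in totals_wide.index:
            fh.write(ko + "\t" + "\t".join(repr(v) for v in totals_wide.loc[ko]) + "\n")
            block = wide.loc[ko]
            for sp in block.index:
                genus = sp.split("_")[0]
                key = f"{ko}|g__{genus}.s__{sp}"
                fh.write(key + "\t" + "\t".join(repr(v) for v in block.loc[sp]) + "\n")

    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)

    with open(paths["annotation"], "w") as fh:
        for pid in sorted(dataset.annotation.pathways):
            desc = dataset.annotation.descriptions[pid]
            for ko in sorted(dataset.annotation.pathways[pid]):
                fh.write(f"{pid}\t{ko}\t{desc}\n")
    return paths


def default_config(seed: int = 0) -> SimulationConfig:
    """The standard two-cohort study conditions with the given seed."""
    return SimulationConfig(seed=seed)


def vary_block_strength(config: SimulationConfig, q: float, p0: float) -> SimulationConfig:
    """Config with every block's (q, p0) replaced — used for trend checks."""
    return replace(
        config, blocks=tuple(replace(b, q=q, p0=p0) for b in config.blocks)
    )
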
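"""Sample/species filter cascade and binarization to presence/absence.

The cascade runs in a fixed order: metadata-based sample selection, taxonomic
(kingdom) filtering, zero-prevalence species removal, zero-Shannon-diversity
sample removal, then per-phenotype binarization.  The order matters only for
the per-stage counts in the filter report; the surviving set is the same and
the cascade is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceTable

__all__ = [
    "FilterCriteria",
    "PresenceMatrix",
    "select_samples",
    "filter_taxa",
    "shannon_index",
    "drop_zero_diversity_samples",
    "binarize",
    "run_filter_cascade",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterCriteria:
    """Exclusion criteria applied to samples and taxa.

    Age bounds are inclusive: subjects strictly younger than ``min_age`` or
    strictly older than ``max_age`` are excluded.  Archaea and eukaryotes are
    dropped by default for their low prevalence in stool metagenomes; viruses
    are retained unless added to ``excluded_kingdoms``.
    """

    min_age: float = 18.0
    max_age: float = 65.0
    exclude_medicated: bool = True
    first_visit_only: bool = True
    drop_duplicate_ids: bool = True
    excluded_kingdoms: frozenset[str] = frozenset({"Archaea", "Eukaryota"})

    def __post_init__(self) -> None:
        if self.min_age > self.max_age:
            raise ValueError("min_age must be <= max_age")


@dataclass
class PresenceMatrix:
    """Binary species × sample occurrence matrix for one phenotype."""

    cells: pd.DataFrame  # 0/1 ints, index = canonical species, columns = samples
    phenotype: str
    dataset: str = ""

    def __post_init__(self) -> None:
        values = self.cells.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence matrix cells must be 0/1")

    @property
    def species(self) -> list[str]:
        return list(self.cells.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cells.columns)


def select_samples(metadata: pd.DataFrame, criteria: FilterCriteria) -> list[str]:
    """Apply the metadata exclusion criteria, returning surviving sample ids."""
    df = metadata
    df = df[(df["age"] >= criteria.min_age) & (df["age"] <= criteria.max_age)]
    if criteria.exclude_medicated:
        df = df[~df["medication_excluded"].astype(bool)]
    if criteria.first_visit_only and len(df):
        first = df.groupby("subject_id")["visit_index"].transform("min")
        df = df[df["visit_index"] == first]
    if criteria.drop_duplicate_ids:
        df = df.drop_duplicates(subset="sample_id", keep="first")
    kept = df["sample_id"].tolist()
    if not kept:
        logger.warning("sample selection left no samples")
    return kept


def filter_taxa(table: AbundanceTable, criteria: FilterCriteria) -> AbundanceTable:
    """Drop excluded kingdoms, then species absent from every sample.

    Zero-prevalence removal is computed on the union of all phenotype samples
    present in the table, not per phenotype.
    """
    keep = [
        name
        for name in table.species
        if table.species_ids.get(name) is None
        or table.species_ids[name].kingdom not in criteria.excluded_kingdoms
    ]
    values = table.values.loc[keep]
    prevalent = values.index[(values.to_numpy() > 0).any(axis=1)]
    values = values.loc[prevalent]
    ids = {s: table.species_ids[s] for s in values.index if s in table.species_ids}
    return AbundanceTable(values=values, species_ids=ids)


def shannon_index(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i with 0·ln0 = 0 (natural log).

    An all-zero vector is defined to have H = 0 so the zero-diversity rule
    removes it rather than dividing by zero.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        return 0.0
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def drop_zero_diversity_samples(table: AbundanceTable) -> AbundanceTable:
    """Remove samples whose Shannon index is zero (at most one species present)."""
    keep = [s for s in table.samples if shannon_index(table.values[s]) > 0.0]
    return AbundanceTable(values=table.values[keep], species_ids=table.species_ids)


def binarize(
    table: AbundanceTable, phenotype: str, metadata: pd.DataFrame, dataset: str = ""
) -> PresenceMatrix:
    """Binary presence/absence matrix restricted to one phenotype's samples.

    Any strictly positive abundance counts as present.  Species absent from
    every sample of the phenotype are dropped so no all-zero rows remain.
    """
    wanted = metadata.loc[metadata["phenotype"] == phenotype, "sample_id"]
    columns = [s for s in table.samples if s in set(wanted)]
    cells = (table.values[columns] > 0).astype("int8")
    cells = cells.loc[cells.to_numpy().any(axis=1)]
    return PresenceMatrix(cells=cells, phenotype=phenotype, dataset=dataset)


@dataclass
class FilterReport:
    """Per-stage survivor counts, mirroring a filtering flowchart."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_samples: int, n_species: int) -> None:
        self.stages.append(
            {"stage": stage, "n_samples": n_samples, "n_species": n_species}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_samples", "n_species"])


def run_filter_cascade(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    criteria: FilterCriteria,
) -> tuple[AbundanceTable, pd.DataFrame, FilterReport]:
    """Full cascade: sample selection → taxa filters → diversity filter.

    Returns the filtered table, the metadata restricted to surviving samples,
    and a per-stage report.
    """
    report = FilterReport()
    report.add("input", len(table.samples), len(table.species))

    kept_samples = select_samples(metadata, criteria)
    columns = [s for s in table.samples if s in set(kept_samples)]
    table = AbundanceTable(values=table.values[columns], species_ids=table.species_ids)
    report.add("sample_selection", len(table.samples), len(table.species))

    table = filter_taxa(table, criteria)
    report.add("taxon_filter", len(table.samples), len(table.species))

    table = drop_zero_diversity_samples(table)
    report.add("zero_diversity", len(table.samples), len(table.species))

    metadata = metadata[metadata["sample_id"].isin(set(table.samples))]
    return table, metadata, report
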
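"""Readers and writers for the external file formats the pipeline touches.

Taxonomic profiles arrive in MetaPhlAn-style merged form (rows are full
``|``-separated lineage strings, columns are samples, values are percent
relative abundance).  Functional profiles arrive in HUMAnN-style KO tables
where a row key is either a bare ``K#####`` (community total) or
``K#####|g__Genus.s__Genus_species`` (per-species stratification).  The one
identifier shared between the two formats is the underscored species binomial
carried by the ``s__`` token, so that token — verbatim — is the canonical
species key used for every cross-file join.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SpeciesId",
    "AbundanceTable",
    "KOProfile",
    "PathwayAnnotation",
    "UNSTRATIFIED",
    "ProfileParseError",
    "read_taxonomic_profile",
    "read_ko_profile",
    "read_metadata",
    "read_pathway_annotation",
    "write_network",
    "read_network",
    "write_enrichment",
]

#: Marker for community-total (unstratified) KO rows.
UNSTRATIFIED = "__unstratified__"

PHENOTYPES = ("control", "CD", "UC")

_KO_RE = re.compile(r"^K\d{5}$")
_RANKS = ("k", "p", "c", "o", "f", "g", "s", "t")


class ProfileParseError(ValueError):
    """Raised when a profile file violates its format contract."""


@dataclass(frozen=True)
class SpeciesId:
    """A species-level taxon parsed from a lineage string.

    ``canonical_name`` is the underscored binomial from the ``s__`` token
    (e.g. ``"Escherichia_coli"``); it is the join key across all profiles.
    """

    kingdom: str
    lineage: Mapping[str, str]
    canonical_name: str

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValueError("canonical_name must be non-empty")


def parse_lineage(lineage: str, *, line_no: int | None = None) -> SpeciesId:
    """Parse a ``k__...|p__...|...|s__...`` lineage string into a SpeciesId."""
    ranks: dict[str, str] = {}
    for token in lineage.split("|"):
        if "__" not in token:
            where = f" at line {line_no}" if line_no is not None else ""
            raise ProfileParseError(
                f"malformed lineage token {token!r}{where} (expected 'x__Name')"
            )
        rank, _, name = token.partition("__")
        if rank not in _RANKS:
            where = f" at line {line_no}" if line_no is not None else ""
            raise ProfileParseError(f"unknown rank prefix {rank!r}{where}")
        ranks[rank] = name
    if "s" not in ranks:
        raise ProfileParseError(f"lineage has no species rank: {lineage!r}")
    return SpeciesId(
        kingdom=ranks.get("k", ""), lineage=ranks, canonical_name=ranks["s"]
    )


def is_species_level(lineage: str) -> bool:
    """True for rows resolved to species but not strain ('s__' without 't__')."""
    tokens = {t.partition("__")[0] for t in lineage.split("|") if "__" in t}
    return "s" in tokens and "t" not in tokens


@dataclass
class AbundanceTable:
    """Species-by-sample relative abundances.

    ``values`` is indexed by canonical species name with sample-id columns.
    Abundances may be on either a 0–100 or 0–1 scale; downstream steps only
    ever use the strictly-positive predicate, so no rescaling is applied.
    """

    values: pd.DataFrame
    species_ids: dict[str, SpeciesId] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate species ids: {dupes}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundance values")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class KOProfile:
    """Long-form KO abundances, stratified by contributing species.

    ``entries`` has columns (ko, species, sample, abundance); ``species`` is a
    canonical name or :data:`UNSTRATIFIED` for community-total rows.
    """

    entries: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        bad = self.entries.loc[~self.entries["ko"].str.match(_KO_RE), "ko"]
        if len(bad):
            raise ValueError(f"invalid KO ids: {sorted(set(bad))[:5]}")
        if (self.entries["abundance"] < 0).any():
            raise ValueError("negative KO abundance")

    def stratified(self) -> pd.DataFrame:
        return self.entries[self.entries["species"] != UNSTRATIFIED]


@dataclass
class PathwayAnnotation:
    """Pathway → KO membership and the enrichment universe."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for pid, kos in self.pathways.items():
            if not kos:
                raise ValueError(f"pathway {pid} has an empty KO set")
        for pid in self.pathways:
            self.descriptions.setdefault(pid, pid)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for kos in self.pathways.values():
            out |= kos
        return frozenset(out)


def _read_table_lines(path: str | Path) -> tuple[list[str], list[int]]:
    lines, numbers = [], []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line:
                lines.append(line)
                numbers.append(i)
    return lines, numbers


def read_taxonomic_profile(path: str | Path) -> AbundanceTable:
    """Read a merged MetaPhlAn-style table, keeping species-level rows only.

    Comment lines (``#``-prefixed) are skipped; the first remaining line is
    the header.  Rows above species level (no ``s__``) and strain rows
    (``t__`` present) are dropped.
    """
    lines, numbers = _read_table_lines(path)
    body = [(n, l) for n, l in zip(numbers, lines) if not l.startswith("#")]
    if not body:
        raise ProfileParseError(f"{path}: no header line found")
    header = body[0][1].split("\t")
    samples = header[1:]
    rows: list[list[float]] = []
    index: list[str] = []
    ids: dict[str, SpeciesId] = {}
    for line_no, line in body[1:]:
        fields = line.split("\t")
        lineage = fields[0]
        if not is_species_level(lineage):
            continue
        sid = parse_lineage(lineage, line_no=line_no)
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{line_no}: non-numeric abundance") from exc
        if any(v < 0 for v in values):
            raise ProfileParseError(
                f"{path}:{line_no}: negative abundance for {sid.canonical_name}"
            )
        if sid.canonical_name in ids:
            raise ProfileParseError(
                f"{path}:{line_no}: duplicate species {sid.canonical_name}"
            )
        index.append(sid.canonical_name)
        ids[sid.canonical_name] = sid
        rows.append(values)
    values_df = pd.DataFrame(rows, index=index, columns=samples, dtype=float)
    return AbundanceTable(values=values_df, species_ids=ids)


_STRAT_RE = re.compile(r"^(K\d{5})\|g__[^.]+\.s__(.+)$")


def parse_ko_row_key(key: str) -> tuple[str, str] | None:
    """Split a HUMAnN row key into (ko, canonical species or UNSTRATIFIED).

    Returns None for UNMAPPED/UNGROUPED rows; raises for anything else.
    """
    if key in ("UNMAPPED", "UNGROUPED") or key.startswith(("UNMAPPED|", "UNGROUPED|")):
        return None
    if _KO_RE.match(key):
        return key, UNSTRATIFIED
    m = _STRAT_RE.match(key)
    if m:
        return m.group(1), m.group(2)
    # stratified-but-unclassified rows ("K#####|unclassified") are tolerated
    ko, _, rest = key.partition("|")
    if _KO_RE.match(ko) and rest == "unclassified":
        return None
    raise ProfileParseError(f"unrecognized KO row key: {key!r}")


def read_ko_profile(path: str | Path) -> KOProfile:
    """Read a HUMAnN-style (possibly stratified) KO abundance table.

    The first line is the header even when ``#``-prefixed (HUMAnN writes
    ``# Gene Family<TAB>...``).  Zero abundances are dropped from the long
    form; only positive cells ever matter downstream.
    """
    lines, numbers = _read_table_lines(path)
    if not lines:
        raise ProfileParseError(f"{path}: empty file")
    header = lines[0].lstrip("#").strip().split("\t")
    samples = header[1:]
    records: list[tuple[str, str, str, float]] = []
    for line_no, line in zip(numbers[1:], lines[1:]):
        fields = line.split("\t")
        parsed = parse_ko_row_key(fields[0])
        if parsed is None:
            continue
        ko, species = parsed
        for sample, raw in zip(samples, fields[1:]):
            value = float(raw)
            if value < 0:
                raise ProfileParseError(f"{path}:{line_no}: negative abundance")
            if value > 0:
                records.append((ko, species, sample, value))
    entries = pd.DataFrame(
        records, columns=["ko", "species", "sample", "abundance"]
    )
    if entries.duplicated(["ko", "species", "sample"]).any():
        raise ProfileParseError(f"{path}: duplicate (ko, species, sample) rows")
    return KOProfile(entries=entries, samples=samples)


_METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "phenotype",
    "age",
    "visit_index",
    "medication_excluded",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dupes}")
    bad = set(df["phenotype"]) - set(PHENOTYPES)
    if bad:
        raise ValueError(f"unknown phenotypes {sorted(bad)}; expected {PHENOTYPES}")
    if df["medication_excluded"].dtype != bool:
        df["medication_excluded"] = df["medication_excluded"].astype(str).str.lower().isin(
            ("true", "1", "yes")
        )
    df["visit_index"] = df["visit_index"].astype(int)
    if (df["visit_index"] < 1).any():
        raise ValueError("visit_index must be >= 1")
    return df


def read_pathway_annotation(path: str | Path) -> PathwayAnnotation:
    """Read a pathway→KO annotation TSV (pathway_id, ko_id[, description])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty pathway annotation")
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pid, ko = row[0], row[1]
        pathways.setdefault(pid, set()).add(ko)
        if len(row) > 2 and isinstance(row[2], str) and row[2]:
            descriptions[pid] = row[2]
    return PathwayAnnotation(
        pathways={p: frozenset(k) for p, k in pathways.items()},
        descriptions=descriptions,
    )


_GRAPH_ATTRS = ("phenotype", "dataset", "alpha")


def write_network(network: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write a co-occurrence network as a TSV edge list or GraphML.

    The edge list carries graph-level attributes as ``# key=value`` comment
    lines so that a read-back reproduces the node set, edge set and graph
    attributes; GraphML is the richer export.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
        return
    if format != "edgelist":
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        for key in sorted(network.graph):
            fh.write(f"# {key}={network.graph[key]}\n")
        fh.write("species_a\tspecies_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(n for n in network.nodes() if network.degree(n) == 0):
            fh.write(f"{node}\t\n")


def read_network(path: str | Path, format: str = "edgelist") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        if "alpha" in g.graph:
            g.graph["alpha"] = float(g.graph["alpha"])
        return g
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                g.graph[key.strip()] = float(value) if key.strip() == "alpha" else value
                continue
            if not line or line.startswith("species_a\t"):
                continue
            a, _, b = line.partition("\t")
            if b:
                g.add_edge(a, b)
            else:
                g.add_node(a)
    return g


ENRICHMENT_COLUMNS = [
    "pathway_id",
    "description",
    "GeneRatio",
    "BgRatio",
    "pvalue",
    "p.adjust",
    "geneID",
]


def write_enrichment(rows: Iterable, path: str | Path, *, cluster: Sequence | None = None) -> None:
    """Write enrichment rows as a TSV with the standard result columns."""
    rows = list(rows)
    records = []
    for i, r in enumerate(rows):
        rec = {
            "pathway_id": r.pathway_id,
            "description": r.description,
            "GeneRatio": r.gene_ratio,
            "BgRatio": r.bg_ratio,
            "pvalue": r.pvalue,
            "p.adjust": r.p_adjust,
            "geneID": ";".join(sorted(r.ko_hits)),
        }
        if cluster is not None:
            rec["cluster"] = cluster[i]
        records.append(rec)
    columns = ENRICHMENT_COLUMNS + (["cluster"] if cluster is not None else [])
    pd.DataFrame(records, columns=columns).to_csv(path, sep="\t", index=False)
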
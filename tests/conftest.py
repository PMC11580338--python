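import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cooccursig.io import AbundanceTable, SpeciesId  # noqa: E402


TAXONOMIC_FIXTURE = """\
#synthetic merged taxonomic profile
clade_name\tS1\tS2\tS3
k__Bacteria|p__Proteobacteria|g__Escherichia\t10.0\t5.0\t0.0
k__Bacteria|p__Proteobacteria|g__Escherichia|s__Escherichia_coli\t9.0\t4.0\t0.0
k__Bacteria|p__Bacteroidota|g__Bacteroides|s__Bacteroides_fragilis\t1.0\t0.0\t2.0
k__Bacteria|p__Firmicutes|g__Roseburia\t3.0\t0.0\t1.0
k__Bacteria|p__Firmicutes|g__Roseburia|s__Roseburia_intestinalis\t3.0\t0.0\t1.0
k__Bacteria|p__Firmicutes|g__Roseburia|s__Roseburia_intestinalis|t__SGB4940\t3.0\t0.0\t1.0
"""

KO_FIXTURE = """\
# Gene Family\tS1\tS2\tS3
UNMAPPED\t100.0\t90.0\t80.0
K02010\t5.0\t2.0\t0.0
K02010|g__Escherichia.s__Escherichia_coli\t4.0\t2.0\t0.0
K02010|g__Bacteroides.s__Bacteroides_fragilis\t1.0\t0.0\t0.0
K00001\t1.0\t0.0\t3.0
K00001|g__Roseburia.s__Roseburia_intestinalis\t1.0\t0.0\t3.0
K00002|g__Escherichia.s__Escherichia_coli\t0.5\t0.0\t0.0
"""

METADATA_FIXTURE = """\
sample_id\tsubject_id\tphenotype\tage\tvisit_index\tmedication_excluded
S1\tsubjA\tCD\t30\t1\tFalse
S2\tsubjB\tUC\t45\t1\tFalse
S3\tsubjC\tcontrol\t50\t1\tFalse
"""

ANNOTATION_FIXTURE = """\
map02010\tK02010\tABC transporters
map02010\tK00001\tABC transporters
map00001\tK00001
map00001\tK00002
"""


@pytest.fixture
def taxonomic_file(tmp_path):
    path = tmp_path / "taxonomic_profile.tsv"
    path.write_text(TAXONOMIC_FIXTURE)
    return path


@pytest.fixture
def ko_file(tmp_path):
    path = tmp_path / "ko_profile.tsv"
    path.write_text(KO_FIXTURE)
    return path


@pytest.fixture
def metadata_file(tmp_path):
    path = tmp_path / "metadata.tsv"
    path.write_text(METADATA_FIXTURE)
    return path


@pytest.fixture
def annotation_file(tmp_path):
    path = tmp_path / "annotation.tsv"
    path.write_text(ANNOTATION_FIXTURE)
    return path


def make_table(data: dict[str, list[float]], samples: list[str], kingdom="Bacteria"):
    """AbundanceTable from {species: abundances} with synthetic lineages."""
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples, dtype=float)
    ids = {
        name: SpeciesId(
            kingdom=kingdom,
            lineage={"k": kingdom, "g": name.split("_")[0], "s": name},
            canonical_name=name,
        )
        for name in data
    }
    return AbundanceTable(values=values, species_ids=ids)
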
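import numpy as np
import pandas as pd
import pytest

from commdecay.core_io import (
    DistanceMatrix,
    InfectionTable,
    SequenceAlignment,
    SiteTable,
)


def make_table(counts: dict, species: dict, sites: dict, groups: dict | None = None):
    """Build an InfectionTable from nested dicts: counts[ind][taxon] = n."""
    taxa = sorted({t for row in counts.values() for t in row})
    frame = pd.DataFrame(
        [[row.get(t, 0) for t in taxa] for row in counts.values()],
        index=list(counts),
        columns=taxa,
        dtype=np.int64,
    )
    return InfectionTable(
        counts=frame,
        host_species_of=pd.Series(species),
        site_of=pd.Series(sites),
        group_of_taxon=dict(groups or {}),
    )


@pytest.fixture
def tiny_table():
    """Two species x two individuals, three taxa, one uninfected host."""
    return make_table(
        counts={
            "a1": {"t1": 2, "t2": 3},
            "a2": {"t1": 1},
            "b1": {"t2": 4, "t3": 1},
            "b2": {},
        },
        species={"a1": "AAA", "a2": "AAA", "b1": "BBB", "b2": "BBB"},
        sites={"a1": "S1", "a2": "S1", "b1": "S2", "b2": "S2"},
        groups={"t1": "digenean", "t2": "cestode", "t3": "nematode"},
    )


@pytest.fixture
def tiny_sites():
    return SiteTable({"S1": (-43.0, 177.0), "S2": (-44.0, 178.5)})


@pytest.fixture
def tiny_alignment():
    return SequenceAlignment({"AAA": "ACGTACGT", "BBB": "ACGTACGA"})


@pytest.fixture
def dataset_dir(tmp_path, tiny_table, tiny_sites, tiny_alignment):
    """The tiny dataset written to disk in the standard file formats."""
    tiny_table.write_csv(tmp_path / "infections.csv")
    tiny_sites.write_csv(tmp_path / "sites.csv")
    tiny_alignment.write_fasta(tmp_path / "alignment.fasta")
    return tmp_path


def random_dissimilarity(n: int, rng: np.random.Generator, labels=None) -> DistanceMatrix:
    """Random symmetric dissimilarity matrix with zero diagonal."""
    m = rng.uniform(0.05, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    labels = labels or [f"L{i}" for i in range(n)]
    return DistanceMatrix(labels, m, "dissimilarity")
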
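import pandas as pd
import pytest

from strandrepair import SimConfig, simulate_dataset
from strandrepair._rng import substream
from strandrepair.genome import GenomeRef


@pytest.fixture(scope="session")
def default_bundle():
    """A full default-conditions simulation shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=11, n_reads_per_assay=20_000))


@pytest.fixture(scope="session")
def clean_bundle():
    """Background-free, all-MAPQ-passing simulation for round-trip tests."""
    cfg = SimConfig(seed=13, background_read_fraction=0.0, low_mapq_fraction=0.0,
                    n_reads_per_assay=20_000)
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_genome():
    """Hand-written two-chromosome genome with known GG placements."""
    #            0123456789...
    chr1 = "ATGGATACCATGGGATTCCGGA" * 10  # GG at 2, 11, 12 (overlap), 19 (+); CC at 7,8, 17,18
    chrm = "ATATATATAT" * 20
    return GenomeRef({"chr1": chr1, "chrM": chrm})


def rng(label: str, seed: int = 5):
    return substream(seed, label)


@pytest.fixture()
def simple_genes():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "start": [10, 120],
            "end": [100, 200],
            "strand": ["+", "-"],
        }
    )
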
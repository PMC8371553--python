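import numpy as np
import pandas as pd
import pytest

from methylwindow import simulate
from methylwindow.io import GeneModel


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        genome_length=10_000,
        n_chromosomes=2,
        gc_content=0.4,
        n_genes=4,
        gene_length=800,
        n_islands=4,
        island_length=300,
        island_cpg_boost=5.0,
        group_sizes={("Y", "C"): 2, ("Y", "T"): 2},
        coverage_mean=20.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genome, genes, islands = simulate.generate_genome(small_config)
    matrix, truth = simulate.simulate_methylomes(genome, genes, islands, small_config)
    return genome, genes, islands, matrix, truth


@pytest.fixture
def toy_genes():
    return [
        GeneModel("geneA", "chr1", 5_000, 9_000, "+",
                  exons=[(5_000, 5_800), (8_200, 9_000)]),
        GeneModel("geneB", "chr1", 20_000, 24_000, "-",
                  exons=[(20_000, 20_800), (23_200, 24_000)]),
    ]


def make_counts_matrix(meth, total, group_sizes=None, kits=None, contexts=None):
    """Build a SiteCountsMatrix from raw arrays for unit tests.

    Samples are named s1..sN, split into a test group ('T') followed by a
    reference group ('C') of equal size unless group_sizes is given.
    """
    meth = np.asarray(meth)
    total = np.asarray(total)
    n_sites, n_samples = total.shape
    if group_sizes is None:
        group_sizes = (n_samples // 2, n_samples - n_samples // 2)
    n_test, n_ref = group_sizes
    if kits is None:
        kits = ["kitA" if i % 2 == 0 else "kitB" for i in range(n_samples)]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "age": ["Y"] * n_samples,
            "treatment": ["T"] * n_test + ["C"] * n_ref,
            "kit": kits,
        }
    )
    if contexts is None:
        contexts = ["CpG"] * n_sites
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": np.arange(n_sites) * 10,
            "strand": ["+"] * n_sites,
            "context": contexts,
        }
    )
    return simulate.SiteCountsMatrix(sites, samples, meth, total, sheet)
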
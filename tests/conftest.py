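import numpy as np
import pandas as pd
import pytest

import eaclock as ea
from eaclock import simdata


@pytest.fixture(scope="session")
def small_cohort():
    """4,000-site two-group cohort (D=0 vs D=16, 3 vs 3), seed 1."""
    cfg = ea.SimConfig(n_sites=4000, samples=simdata.two_group_design(), seed=1)
    cm, table, truth = ea.simulate_cohort(cfg)
    return cfg, cm, table, truth


@pytest.fixture(scope="session")
def small_stats(small_cohort):
    cfg, cm, table, truth = small_cohort
    cmf = ea.filter_coverage(cm)
    young = table.loc[table["group"] == "young", "sample_id"].tolist()
    ml = table.loc[table["group"] == "ml", "sample_id"].tolist()
    return cmf, ea.test_sites(cmf, young, ml)


def random_count_matrix(rng, n_sites=50, n_samples=4, chroms=("chr1", "chr2")):
    chrom = np.sort(rng.choice(chroms, size=n_sites))
    pos = np.zeros(n_sites, dtype=np.int64)
    for c in chroms:
        m = chrom == c
        pos[m] = np.sort(rng.choice(np.arange(100, 100000, 7), size=m.sum(), replace=False))
    sites = pd.DataFrame({"chrom": chrom, "pos": pos}).sort_values(
        ["chrom", "pos"], ignore_index=True
    )
    total = rng.integers(0, 40, size=(n_sites, n_samples))
    meth = rng.binomial(total, rng.uniform(0, 1, size=(n_sites, 1)))
    return ea.CountMatrix(sites, [f"s{i}" for i in range(n_samples)], meth, total)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_annotation():
    """Two genes on chr1 (one per strand, with CDS) plus one CpG island."""
    genes = [
        ea.Gene("geneA", "chr1", "+", 10_000, 20_000,
                exons=((10_000, 12_000), (15_000, 17_000), (19_000, 20_000)),
                cds_start=11_000, cds_end=19_500),
        ea.Gene("geneB", "chr1", "-", 40_000, 50_000,
                exons=((40_000, 42_000), (48_000, 50_000)),
                cds_start=41_000, cds_end=49_000),
        ea.Gene("geneC", "chr2", "+", 5_000, 9_000,
                exons=((5_000, 9_000),)),
    ]
    islands = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [30_000, 1_000], "end": [31_000, 2_000]}
    )
    return ea.GenomeAnnotation(genes, islands, {"chr1": 100_000, "chr2": 50_000})
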
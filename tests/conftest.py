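import numpy as np
import pytest

from promotermine.coverage import PileupColumn
from promotermine.genome import GeneModel, build_windows
from promotermine.simulate import SimConfig, simulate


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", "chr1", "+", 10_000)


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", "chr1", "-", 30_000)


@pytest.fixture
def windows(plus_gene, minus_gene):
    return build_windows([plus_gene, minus_gene])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_columns(chrom, start, depths, ref_base="A"):
    """Consecutive pileup columns with the given depths, all reference."""
    return [
        PileupColumn(chrom, start + i, int(d), {ref_base: int(d)})
        for i, d in enumerate(depths)
        if d > 0
    ]


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact seeded bundle shared by simulator/population tests."""
    cfg = SimConfig(seed=11, n_genes=40, n_variants_per_group=200,
                    n_individuals=6, n_coverage_samples=2)
    out = tmp_path_factory.mktemp("bundle")
    return simulate(cfg, out_dir=str(out))
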
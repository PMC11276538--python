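import numpy as np
import pytest

from crossmp.io_formats import CellByFeatureMatrix, FeatureAxis, GenomicInterval
from crossmp.preprocess_rna import RnaFilterConfig
from crossmp.synthetic_multiome import SimConfig, worked_fixture


@pytest.fixture
def fixture_pair():
    """Tiny literal paired multiome: (rna, atac, gene_models)."""
    return worked_fixture()


@pytest.fixture
def small_sim_cfg():
    """A fast simulation exercising all chromosomes and cell types."""
    return SimConfig(n_cells=250, n_genes=80, n_peaks=160, n_chromosomes=3, seed=11)


@pytest.fixture
def small_rna_filter():
    """QC bounds scaled to the small simulated gene panels used in tests."""
    return RnaFilterConfig(min_genes_per_cell=10, max_genes_per_cell=5000)


def random_matrix(rng, n_cells, n_features, density=0.3, with_intervals=False,
                  binary=False, prefix="f"):
    """Random CellByFeatureMatrix helper shared across test modules."""
    vals = (rng.random((n_cells, n_features)) < density).astype(float)
    if not binary:
        vals *= rng.integers(1, 9, size=vals.shape)
    barcodes = [f"bc{i}" for i in range(n_cells)]
    if with_intervals:
        ivs = []
        for j in range(n_features):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 100_000))
            ivs.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 500))))
        # names must be unique even if intervals collide
        ids = [f"{prefix}{j}_{iv.chrom}:{iv.start}-{iv.end}" for j, iv in enumerate(ivs)]
        features = FeatureAxis(ids=ids, intervals=ivs)
    else:
        features = FeatureAxis(ids=[f"{prefix}{j}" for j in range(n_features)])
    return CellByFeatureMatrix(barcodes=barcodes, features=features, values=vals)
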
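import numpy as np
import pytest

from vnocode import CountMatrix, GeneClass, GeneRecord


@pytest.fixture
def small_annotation():
    """Five receptors on two chromosomes plus one TF and one AG gene."""
    return [
        GeneRecord("V1R_001", GeneClass.V1R, "chr1", 1_000, 1_999),
        GeneRecord("V1R_002", GeneClass.V1R, "chr1", 201_000, 201_999),
        GeneRecord("V1R_003", GeneClass.V1R, "chr2", 1_000, 1_999),
        GeneRecord("V2R_001", GeneClass.V2R, "chr2", 401_000, 401_999),
        GeneRecord("V2R_002", GeneClass.V2R, "chr2", 801_000, 801_999),
        GeneRecord("TF_001", GeneClass.TF, "chr1", 50_000_000, 50_000_999),
        GeneRecord("AG_001", GeneClass.AG, "chr2", 50_000_000, 50_000_999),
    ]


def make_counts(matrix, gene_ids=None, barcodes=None):
    matrix = np.asarray(matrix)
    gene_ids = gene_ids or [f"g{i}" for i in range(matrix.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(matrix.shape[1])]
    return CountMatrix(matrix, gene_ids, barcodes)


@pytest.fixture
def counts_factory():
    return make_counts
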
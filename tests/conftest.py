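import numpy as np
import pytest
import scipy.sparse as sp

from emptydropsmultiome import MultiomeCounts


@pytest.fixture
def toy_mc() -> MultiomeCounts:
    """3 genes x 2 peaks x 4 barcodes with hand-written counts."""
    rna = np.array(
        [
            [7, 0, 1, 0],
            [0, 2, 0, 0],
            [3, 0, 0, 0],
        ]
    )
    atac = np.array(
        [
            [0, 5, 0, 0],
            [1, 0, 4, 0],
        ]
    )
    return MultiomeCounts(
        rna_counts=sp.csc_matrix(rna),
        atac_counts=sp.csc_matrix(atac),
        barcodes=np.array(["AAA-1", "AAC-1", "AAG-1", "AAT-1"], dtype=object),
        gene_ids=np.array(["G1", "G2", "G3"], dtype=object),
        region_ids=np.array(["chr1:100-200", "chr2:5-99"], dtype=object),
        gene_names=np.array(["Gene1", "Gene2", "Gene3"], dtype=object),
        region_names=np.array(["chr1:100-200", "chr2:5-99"], dtype=object),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240521)
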
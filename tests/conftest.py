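import numpy as np
import pytest

from chromocall.intervals import GeneModel, GenomicInterval
from chromocall.simulate import make_annotation


@pytest.fixture(scope="session")
def annotation_small():
    """600 genes on two 40-Mb chromosomes; shared across tests."""
    return make_annotation(600, {"chr1": 40_000_000, "chr2": 40_000_000}, seed=11)


@pytest.fixture(scope="session")
def annotation_compact():
    """120 genes on one 6-Mb chromosome for single-cell tests."""
    return make_annotation(120, {"chr1": 6_000_000}, seed=11)


@pytest.fixture
def toy_genes():
    """Two hand-placed genes used for category / window boundary checks."""
    return [
        GeneModel("gA", GenomicInterval("chr1", 10_000, 30_000, "gA", None, "+")),
        GeneModel("gB", GenomicInterval("chr1", 50_000, 80_000, "gB", None, "-")),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
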
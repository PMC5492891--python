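import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from rbptargets.clip import AnnotationBundle
from rbptargets.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def toy_bundle():
    """One gene with two exons (the first carrying a UTR) and one lncRNA."""
    genes = IntervalSet([GenomicInterval("chr1", 100, 1000, "+", name="geneA")])
    exons = IntervalSet(
        [
            GenomicInterval("chr1", 100, 300, "+", name="geneA_ex1"),
            GenomicInterval("chr1", 700, 1000, "+", name="geneA_ex2"),
        ]
    )
    utrs = IntervalSet([GenomicInterval("chr1", 100, 180, "+", name="geneA_utr")])
    lncrnas = IntervalSet([GenomicInterval("chr1", 2000, 2500, "-", name="lnc1")])
    return AnnotationBundle(
        genes=genes.normalized(),
        exons=exons.normalized(),
        utrs=utrs.normalized(),
        lncrnas=lncrnas.normalized(),
    )
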
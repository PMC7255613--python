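import numpy as np
import pandas as pd
import pytest

from deepsav.features import ANNOTATION_COLUMNS, GeneData
from deepsav.msa import Alignment


@pytest.fixture
def tiny_alignment() -> Alignment:
    # column 1 invariant A; column 2 split A/C; column 3 variable; column 4 has gaps/X
    seqs = [
        "AACD",
        "AAWD",
        "ACFD",
        "ACY-",
        "AAVX",
    ]
    return Alignment(seqs, reference_index=0)


@pytest.fixture
def gene_data() -> GeneData:
    rng = np.random.default_rng(7)
    L = 40
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L))
    profile = rng.dirichlet(np.ones(20), size=L)
    conservation = rng.random(L)
    ann = pd.DataFrame(
        rng.random((L, len(ANNOTATION_COLUMNS))), columns=list(ANNOTATION_COLUMNS)
    )
    return GeneData("GENE1", seq, profile, conservation, ann)
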
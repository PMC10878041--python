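import numpy as np
import pandas as pd
import pytest

from assemblage import CommunityMatrix


def make_cm(counts, otus=None, samples=None) -> CommunityMatrix:
    counts = np.asarray(counts)
    otus = otus or [f"otu{i+1}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(counts.shape[1])]
    return CommunityMatrix(pd.DataFrame(counts, index=otus, columns=samples))


@pytest.fixture
def tiny_cm():
    """3 OTUs x 2 samples with column sums (6, 9)."""
    return make_cm([[5, 0], [1, 2], [0, 7]])


@pytest.fixture
def three_taxon_tree(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    return p
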
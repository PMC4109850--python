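import numpy as np
import pytest

from treegl.core_io import ExpressionPanel, StateTree


@pytest.fixture
def toy_tree():
    """The five-state tree: root, one internal state, three leaves anchored
    to the root."""
    states = ("S1", "T4", "R_EGFR", "R_PI3K", "R_MMP")
    parent = {"S1": None, "T4": "S1", "R_EGFR": "T4", "R_PI3K": "T4", "R_MMP": "T4"}
    anchors = (("R_EGFR", "S1"), ("R_PI3K", "S1"), ("R_MMP", "S1"))
    return StateTree(states, parent, anchors)


@pytest.fixture
def toy_panel():
    """4 genes x 6 samples in 3 chained states."""
    rng = np.random.default_rng(7)
    genes = ("gA", "gB", "gC", "gD")
    blocks = {s: rng.standard_normal((2, 4)) for s in ("S1", "S2", "S3")}
    ids = {s: (f"{s}a", f"{s}b") for s in blocks}
    return ExpressionPanel(genes=genes, blocks=blocks, sample_ids=ids)


@pytest.fixture
def chain_tree():
    return StateTree(("S1", "S2", "S3"), {"S1": None, "S2": "S1", "S3": "S2"})
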
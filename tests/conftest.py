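import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from phytocolon.containers import CountTable
from phytocolon.synth import SynthConfig, generate_dataset


def make_star_tree(tip_names, branch_length=1.0):
    """Rooted star tree with unit (or given) branch lengths."""
    parts = ",".join(f"{t}:{branch_length}" for t in tip_names)
    return TreeNode.read(io.StringIO(f"({parts});"))


def make_table(matrix, asv_ids=None, sample_ids=None):
    matrix = np.asarray(matrix)
    asv_ids = asv_ids or [f"A{i + 1}" for i in range(matrix.shape[0])]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(matrix.shape[1])]
    return CountTable(pd.DataFrame(matrix, index=asv_ids, columns=sample_ids))


@pytest.fixture
def star_tree_factory():
    return make_star_tree


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def small_synth():
    """A small but full-design synthetic dataset shared across tests."""
    cfg = SynthConfig(n_asvs=60, samples_per_cell=2, seed=42)
    table, meta, taxonomy, tree, truth = generate_dataset(cfg)
    return {"config": cfg, "table": table, "meta": meta, "taxonomy": taxonomy,
            "tree": tree, "truth": truth}
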
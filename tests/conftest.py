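import sys
from pathlib import Path

import dendropy
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from symtrace.alignio import GeneAlignment


def make_alignment(seqs: dict[str, str], locus: str = "test") -> GeneAlignment:
    ids = list(seqs)
    data = np.vstack(
        [np.frombuffer(seqs[i].encode("ascii"), dtype=np.uint8) for i in ids]
    )
    return GeneAlignment(locus, ids, data)


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across tests that only read it."""
    from symtrace.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        refs_per_region=4,
        focal_plan=tuple((f"focal_{k:02d}", 1 + (k - 1) % 4) for k in range(1, 9)),
        core_loci=(("gene_a", 300), ("gene_b", 300)),
        sym_loci=(("sym_a", 400),),
        seed=7,
    )
    return cfg, simulate_dataset(cfg)
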
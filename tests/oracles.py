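"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against set/enumeration primitives,
not the package's bitmask or pruning code paths, so agreement between the
two is meaningful.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def random_binary_tree(
    labels: list[str], rng: np.random.Generator, min_len: float = 0.1, max_len: float = 1.0
) -> dendropy.Tree:
    """Random unrooted binary tree with positive branch lengths."""
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        leaf.edge.length = float(rng.uniform(min_len, max_len))
        nodes.append(leaf)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.uniform(min_len, max_len))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    for n in nodes:
        tree.seed_node.add_child(n)
    tree.update_taxon_namespace()
    return tree


def path_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths by explicit root-path comparison."""
    paths: dict[str, list] = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf
        while node.parent_node is not None:
            chain.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    out = {}
    labs = sorted(paths)
    for a, b in itertools.combinations(labs, 2):
        pa, pb = paths[a], paths[b]
        sa, sb = set(id(n) for n in pa), set(id(n) for n in pb)
        d = sum((n.edge.length or 0.0) for n in pa if id(n) not in sb)
        d += sum((n.edge.length or 0.0) for n in pb if id(n) not in sa)
        out[(a, b)] = out[(b, a)] = d
    return out


def splits_as_sets(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the lighter/canonical side."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else all_labels - below
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(side)
    return out


def brute_force_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    return len(splits_as_sets(t1) ^ splits_as_sets(t2))


def all_edge_sides(tree: dendropy.Tree) -> list[frozenset]:
    """One side of every branch (trivial ones included), as label sets."""
    return [
        frozenset(lf.taxon.label for lf in node.leaf_iter())
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]


def brute_force_tbe(ref: dendropy.Tree, reps: list[dendropy.Tree]) -> dict[frozenset, float]:
    """TBE per internal split of ref, by exhaustive transfer-distance search."""
    all_labels = frozenset(lf.taxon.label for lf in ref.leaf_node_iter())
    n = len(all_labels)
    anchor = min(all_labels)
    out = {}
    for node in ref.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        p = min(len(below), n - len(below))
        if p < 2:
            continue
        side = below if anchor not in below else all_labels - below
        total = 0.0
        for rep in reps:
            best = n
            for other in all_edge_sides(rep):
                h = len(below ^ other)
                best = min(best, h, n - h)
            total += best
        out[side] = 1.0 - (total / len(reps)) / (p - 1)
    return out


def brute_force_site_likelihood(
    tree: dendropy.Tree,
    tip_states: dict[str, int | None],
    transition,
    freqs: np.ndarray,
) -> float:
    """One site's likelihood by summation over all internal-state assignments.

    ``tip_states``: base code 0..3 or None for missing; ``transition(t)``
    returns the 4x4 matrix for a branch of length t.
    """
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    P_of = {id(nd): transition(nd.edge.length or 0.0) for nd in edges}
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        states = dict(zip((id(nd) for nd in internals), assign))
        prob = freqs[states[id(tree.seed_node)]]
        for nd in edges:
            P = P_of[id(nd)]
            parent_state = states[id(nd.parent_node)]
            if nd.is_leaf():
                obs = tip_states[nd.taxon.label]
                prob *= 1.0 if obs is None else P[parent_state, obs]
            else:
                prob *= P[parent_state, states[id(nd)]]
        total += prob
    return total
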
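"""Distance-based tree inference and branch-support statistics.

Trees are ``dendropy.Tree`` objects throughout.  Inference is
neighbor-joining on JC69 (or raw p-) distances; branch support is either the
classical Felsenstein bootstrap proportion (FBP: fraction of replicate trees
containing the identical bipartition) or the transfer bootstrap expectation
(TBE: one minus the mean minimum transfer distance to each replicate,
normalised by the branch's lighter-side size minus one).  Support values
live on ``node.support`` of each internal node (written as internal node
labels in newick, as decimals in [0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import nnls

from .alignio import GeneAlignment

logger = logging.getLogger(__name__)

DEFAULT_SATURATION_CAP = 5.0


@dataclass
class DistanceMatrix:
    strain_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.strain_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.strain_ids) + "\n")
            for sid, row in zip(self.strain_ids, self.d):
                fh.write(sid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def pairwise_distances(
    aln: GeneAlignment,
    model: str = "JC69",
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N sites.

    ``p_distance`` is the mismatch fraction over sites where both sequences
    carry an unambiguous base; ``JC69`` applies d = -(3/4) ln(1 - 4p/3).
    Pairs at or beyond saturation (p >= 3/4) or with no comparable sites get
    ``saturation_cap``.
    """
    if model not in ("p_distance", "JC69"):
        raise ValueError(f"unknown model {model!r}")
    if aln.n_strains < 2:
        raise ValueError("need at least 2 strains")
    codes = aln.codes()
    valid = codes != 255
    # one-hot over the 4 bases; matmul counts matching valid sites per pair
    onehot = np.zeros((aln.n_strains, aln.length, 4), dtype=np.float32)
    for b in range(4):
        onehot[:, :, b] = codes == b
    flat = onehot.reshape(aln.n_strains, -1)
    matches = flat @ flat.T
    v = valid.astype(np.float32)
    n_valid = v @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_valid > 0, (n_valid - matches) / n_valid, np.nan)
    np.fill_diagonal(p, 0.0)
    if model == "p_distance":
        d = np.where(np.isnan(p), saturation_cap, p)
    else:
        sat = np.isnan(p) | (p >= 0.75)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = -0.75 * np.log1p(-4.0 / 3.0 * np.where(sat, 0.0, p))
        d = np.where(sat, saturation_cap, d)
        np.fill_diagonal(d, 0.0)
        n_sat = int(np.triu(sat, 1).sum())
        if n_sat:
            logger.info("%d saturated pair(s) set to cap %.3g", n_sat, saturation_cap)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(aln.strain_ids), d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with Studier-Keppler updates.

    Negative limb lengths are clamped to zero.  Ties in the Q criterion are
    broken by the lexicographically smallest (then second-smallest) tip label
    contained in the joined clusters, so output is deterministic.
    """
    n = len(dm.strain_ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 strains")
    tns = dendropy.TaxonNamespace(dm.strain_ids)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    nodes: list[dendropy.Node] = []
    minlab: list[str] = []
    for sid in dm.strain_ids:
        leaf = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(leaf)
        minlab.append(sid)
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q is symmetric up to rounding of the summation order, so a minimum
        # can surface in one orientation only; normalise to a < b
        cand = {(min(a, b), max(a, b)) for a, b in np.argwhere(Q == qmin)}
        best = None
        for a, b in sorted(cand):
            la, lb = minlab[idx[a]], minlab[idx[b]]
            key = (min(la, lb), max(la, lb))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, a, b = best
        i, j = idx[a], idx[b]
        dij = D[i, j]
        vi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        vj = dij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        ks = [k for k in active if k != i and k != j]
        D[nxt, ks] = D[ks, nxt] = 0.5 * (D[i, ks] + D[j, ks] - dij)
        nodes.append(parent)
        minlab.append(min(minlab[i], minlab[j]))
        active = ks + [nxt]
        nxt += 1

    a, b, c = active
    va = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    vb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    vc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    center = tree.seed_node
    for k, v in ((a, va), (b, vb), (c, vc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = v
    tree.update_taxon_namespace()
    return tree


# ---------------------------------------------------------------------------
# bipartition machinery (label-based bitmasks, independent of taxon namespaces)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _taxon_bits(labels) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(sorted(labels))}


def _node_masks(tree: dendropy.Tree, bits: dict[str, int]) -> dict[dendropy.Node, int]:
    masks: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << bits[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[ch]
            masks[node] = m
    return masks


def _normalize(mask: int, full: int) -> int:
    return (full ^ mask) if (mask & 1) else mask


def internal_edges(tree: dendropy.Tree, bits: dict[str, int] | None = None):
    """Yield (node, normalized_mask, lighter_side_size) for non-trivial edges.

    Deduplicates the twin edges below a bifurcating root, which induce the
    same bipartition.
    """
    labels = tip_labels(tree)
    if bits is None:
        bits = _taxon_bits(labels)
    n = len(bits)
    full = (1 << n) - 1
    masks = _node_masks(tree, bits)
    seen: set[int] = set()
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        raw = masks[node]
        pc = raw.bit_count()
        p = min(pc, n - pc)
        if p < 2:
            continue
        norm = _normalize(raw, full)
        if norm in seen:
            continue
        seen.add(norm)
        out.append((node, norm, p))
    return out


def _all_edge_masks(tree: dendropy.Tree, bits: dict[str, int]) -> list[int]:
    """Raw masks of every edge (including trivial leaf edges)."""
    masks = _node_masks(tree, bits)
    return [masks[nd] for nd in tree.preorder_node_iter() if nd.parent_node is not None]


def _check_same_tips(t1: dendropy.Tree, t2: dendropy.Tree) -> None:
    a, b = set(tip_labels(t1)), set(tip_labels(t2))
    if a != b:
        raise ValueError(
            f"tip sets differ: only-in-first={sorted(a - b)}, only-in-second={sorted(b - a)}"
        )


def felsenstein_support(
    ref: dendropy.Tree, reps: list[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate each internal edge with its classical bootstrap proportion."""
    if not reps:
        raise ValueError("need at least one replicate tree")
    for rep in reps:
        _check_same_tips(ref, rep)
    bits = _taxon_bits(tip_labels(ref))
    full = (1 << len(bits)) - 1
    rep_sets = []
    for rep in reps:
        rep_sets.append({norm for _, norm, _ in internal_edges(rep, bits)})
    out = ref.clone(depth=1)
    for node, norm, _p in internal_edges(out, bits):
        node.support = sum(norm in s for s in rep_sets) / len(reps)
    return out


def transfer_bootstrap_expectation(
    ref: dendropy.Tree, reps: list[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate internal edges with the transfer bootstrap expectation.

    For edge b with lighter side p, the transfer distance to a replicate is
    the minimum bipartition Hamming distance over all replicate branches and
    both orientations; TBE = 1 - mean(distance)/(p - 1).
    """
    if not reps:
        raise ValueError("need at least one replicate tree")
    for rep in reps:
        _check_same_tips(ref, rep)
    bits = _taxon_bits(tip_labels(ref))
    n = len(bits)
    rep_masks = [_all_edge_masks(rep, bits) for rep in reps]
    out = ref.clone(depth=1)
    for node, norm, p in internal_edges(out, bits):
        total = 0.0
        for masks in rep_masks:
            delta = min(
                min((norm ^ m).bit_count(), n - (norm ^ m).bit_count()) for m in masks
            )
            total += delta
        node.support = 1.0 - (total / len(reps)) / (p - 1)
    return out


def collapse_low_support(
    tree: dendropy.Tree, threshold: float
) -> tuple[dendropy.Tree, float]:
    """Contract internal edges with support strictly below ``threshold``.

    Returns the collapsed tree and the fraction of internal edges removed.
    """
    out = tree.clone(depth=1)
    edges = internal_edges(out)
    if not edges:
        return out, 0.0
    for node, _, _ in edges:
        if getattr(node, "support", None) is None:
            raise ValueError("internal edge without support; annotate supports first")
    to_collapse = [node for node, _, _ in edges if node.support < threshold]
    for node in to_collapse:
        if node.parent_node is not None:
            node.edge.collapse()
    return out, len(to_collapse) / len(edges)


def collapse_short_branches(tree: dendropy.Tree, min_length: float) -> dendropy.Tree:
    """Contract internal edges shorter than ``min_length``.

    A topology decision carried by a near-zero branch rests on a handful of
    sites and is as likely to reflect realized homoplasy as history;
    contracting such branches before a topology test keeps the test about
    resolvable conflict.
    """
    out = tree.clone(depth=1)
    short = [
        node
        for node, _, _ in internal_edges(out)
        if (node.edge.length or 0.0) < min_length
    ]
    for node in short:
        if node.parent_node is not None:
            node.edge.collapse()
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds: symmetric difference of internal bipartition sets."""
    _check_same_tips(t1, t2)
    bits = _taxon_bits(tip_labels(t1))
    s1 = {norm for _, norm, _ in internal_edges(t1, bits)}
    s2 = {norm for _, norm, _ in internal_edges(t2, bits)}
    return len(s1 ^ s2)


# ---------------------------------------------------------------------------
# branch-length fitting, rooting, newick IO


def tree_from_splits(
    labels: list[str], masks: set[int], tns: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Build the unrooted tree displaying a pairwise-compatible split set.

    ``masks`` are bipartition bitmasks normalised to exclude the
    lexicographically smallest label's bit (bit 0 of the sorted labels).
    """
    bits = _taxon_bits(labels)
    order = sorted(labels)
    if tns is None:
        tns = dendropy.TaxonNamespace(labels)
    leaf_nodes = {}
    for lab in order:
        leaf_nodes[lab] = dendropy.Node(taxon=tns.get_taxon(lab))
    root = dendropy.Node()
    root.add_child(leaf_nodes[order[0]])
    rest = dendropy.Node()
    root.add_child(rest)
    for lab in order[1:]:
        rest.add_child(leaf_nodes[lab])
    node_mask = {rest: ((1 << len(order)) - 1) ^ 1}
    nodes = [rest]
    child_masks = {rest: {leaf_nodes[lab]: 1 << bits[lab] for lab in order[1:]}}
    for m in sorted(masks, key=lambda x: -x.bit_count()):
        host = None
        for nd in nodes:
            if node_mask[nd] & m == m and (host is None or node_mask[nd] < node_mask[host]):
                host = nd
        if host is None or node_mask[host] == m:
            continue
        moved = [ch for ch, cm in child_masks[host].items() if cm & m == cm]
        if sum(child_masks[host][ch].bit_count() for ch in moved) != m.bit_count():
            raise ValueError("incompatible split set")
        new = dendropy.Node()
        for ch in moved:
            host.remove_child(ch)
            new.add_child(ch)
        host.add_child(new)
        child_masks[new] = {ch: child_masks[host].pop(ch) for ch in moved}
        child_masks[host][new] = m
        node_mask[new] = m
        nodes.append(new)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def _compatible(a: int, b: int) -> bool:
    # both masks exclude bit 0, so the A|B == full case cannot arise
    return (a & b == 0) or (a & b == a) or (a & b == b)


def refine_compatible(tree: dendropy.Tree, donor: dendropy.Tree) -> dendropy.Tree:
    """Add the donor's splits that conflict with nothing in ``tree``.

    The result displays every split of ``tree`` plus each donor split
    compatible with all of them, so two refined trees differ only at
    genuinely conflicting branches — resolution differences (polytomies in
    one tree that the other resolves) are equalised.  Branch lengths and
    supports are not carried over.
    """
    _check_same_tips(tree, donor)
    labels = tip_labels(tree)
    bits = _taxon_bits(labels)
    own = {norm for _, norm, _ in internal_edges(tree, bits)}
    extra = {
        m
        for _, m, _ in internal_edges(donor, bits)
        if m not in own and all(_compatible(m, o) for o in own)
    }
    return tree_from_splits(labels, own | extra, tns=tree.taxon_namespace)


def ls_branch_lengths(tree: dendropy.Tree, dm: DistanceMatrix) -> dendropy.Tree:
    """Non-negative least-squares branch lengths for a fixed topology.

    Fits leaf-to-leaf path lengths to the distance matrix; used to score a
    rival topology against an alignment it was not inferred from.
    """
    missing = set(tip_labels(tree)) - set(dm.strain_ids)
    if missing:
        raise ValueError(f"tips absent from distance matrix: {sorted(missing)}")
    out = tree.clone(depth=1)
    bits = _taxon_bits(tip_labels(out))
    masks = _node_masks(out, bits)
    edge_nodes = [nd for nd in out.preorder_node_iter() if nd.parent_node is not None]
    pos = {sid: bits[sid] for sid in dm.strain_ids if sid in bits}
    ids = [sid for sid in dm.strain_ids if sid in bits]
    pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    A = np.zeros((len(pairs), len(edge_nodes)))
    dvec = np.zeros(len(pairs))
    iid = {sid: k for k, sid in enumerate(dm.strain_ids)}
    for row, (i, j) in enumerate(pairs):
        bi, bj = 1 << pos[ids[i]], 1 << pos[ids[j]]
        for col, nd in enumerate(edge_nodes):
            m = masks[nd]
            A[row, col] = bool(m & bi) != bool(m & bj)
        dvec[row] = dm.d[iid[ids[i]], iid[ids[j]]]
    lengths, _ = nnls(A, dvec)
    for nd, ln in zip(edge_nodes, lengths):
        nd.edge.length = float(ln)
    return out


def root_tree(
    tree: dendropy.Tree, outgroup: str | None = None
) -> dendropy.Tree:
    """Root a copy of the tree at an outgroup tip, or at the midpoint."""
    out = tree.clone(depth=1)
    out.is_rooted = True
    if outgroup is not None:
        node = None
        for leaf in out.leaf_node_iter():
            if leaf.taxon.label == outgroup:
                node = leaf
                break
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not found among tips")
        length = node.edge.length or 0.0
        out.reroot_at_edge(node.edge, update_bipartitions=False)
        for child in out.seed_node.child_nodes():
            child.edge.length = length / 2.0
    else:
        out.reroot_at_midpoint(update_bipartitions=False)
    return out


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write newick with supports as internal node labels (decimals)."""
    out = tree.clone(depth=1)
    for node in out.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None and node.parent_node is not None:
            node.label = f"{sup:.6g}"
    txt = out.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )
    with open(path, "w") as fh:
        fh.write(txt)


def read_newick(path) -> dendropy.Tree:
    """Read newick; numeric internal node labels become support values."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree
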
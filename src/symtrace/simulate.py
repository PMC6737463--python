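"""Synthetic region-structured datasets with planted symbiont histories.

The generator builds a reference "backbone" phylogeny — one ultrametric
clade per geographic region, joined at a deep divergence — shared by the
core-gene tree and the symbiotic-gene tree.  Each focal strain is grafted
onto that backbone according to its planted scenario:

    1  co-introduction:      native clade in both trees
    2  local acquisition:    local clade in both trees
    3  chimera (local core): local clade in core, native in symbiotic
    4  chimera (native core): native clade in core, local in symbiotic

A scenario-3/4 strain is therefore a re-graft in exactly one tree — the
signature of a horizontal transfer of the symbiosis loci.  Sequences are
then evolved along each tree, giving per-locus alignments plus a truth
table, so every downstream stage (tree inference, support, congruence
testing, scenario classification) can be validated against known history.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignio import GeneAlignment, MetadataTable, write_alignment
from .sitelik import SubstitutionModel, make_model

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_focal_plan() -> tuple:
    plan = []
    k = 0
    for scen in (1, 2, 3, 4):
        for _ in range(5):
            k += 1
            plan.append((f"focal_{k:02d}", scen))
    return tuple(plan)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Heights are in expected substitutions per site; the between-region
    divergence is deep relative to the shallow within-region radiation, the
    regime in which regional affinity is phylogenetically identifiable.
    """

    regions: tuple = ("SouthAmerica", "EastAsia", "Africa")
    native_region: str = "SouthAmerica"
    local_region: str = "EastAsia"
    refs_per_region: int = 5
    focal_plan: tuple = field(default_factory=_default_focal_plan)
    core_loci: tuple = (("16S", 500), ("recA", 500), ("dnaK", 500), ("glnII", 500))
    sym_loci: tuple = (("nodC", 600), ("nifH", 600))
    within_region_height: float = 0.02
    between_region_height: float = 0.3
    model: str = "JC69"
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise ValueError("need at least 2 regions")
        if self.native_region not in self.regions or self.local_region not in self.regions:
            raise ValueError("native and local regions must be in the region list")
        if self.native_region == self.local_region:
            raise ValueError("native and local regions must differ")
        if self.refs_per_region < 2:
            raise ValueError("refs_per_region must be >= 2 (affinity needs references)")
        if not (0 < self.within_region_height < self.between_region_height):
            raise ValueError("need 0 < within_region_height < between_region_height")
        for _, scen in self.focal_plan:
            if scen not in (1, 2, 3, 4):
                raise ValueError(f"planted scenario must be 1..4, got {scen}")


@dataclass
class FocalTruth:
    strain_id: str
    scenario: int
    core_region: str
    sym_region: str
    core_donor: str
    sym_donor: str
    core_height: float
    sym_height: float


@dataclass
class TruthTable:
    rows: list[FocalTruth]

    def scenario_of(self, strain_id: str) -> int:
        for r in self.rows:
            if r.strain_id == strain_id:
                return r.scenario
        raise KeyError(strain_id)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "strain_id\tscenario\tcore_region\tsym_region\t"
                "core_donor\tsym_donor\tcore_height\tsym_height\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.strain_id}\t{r.scenario}\t{r.core_region}\t{r.sym_region}\t"
                    f"{r.core_donor}\t{r.sym_donor}\t{r.core_height:.6g}\t{r.sym_height:.6g}\n"
                )

    @classmethod
    def read(cls, path) -> "TruthTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                FocalTruth(
                    str(r.strain_id), int(r.scenario), str(r.core_region),
                    str(r.sym_region), str(r.core_donor), str(r.sym_donor),
                    float(r.core_height), float(r.sym_height),
                )
                for r in df.itertuples()
            ]
        )


# ---------------------------------------------------------------------------
# backbone construction (lightweight node records; converted to dendropy last)


class _BNode:
    __slots__ = ("nid", "label", "height", "children")

    def __init__(self, nid, label, height, children=()):
        self.nid = nid
        self.label = label
        self.height = height
        self.children = list(children)


def _yule_clade(labels: list[str], height: float, rng, nid_counter) -> _BNode:
    """Random ultrametric clade: sequential random joins at sorted heights."""
    clusters = [_BNode(next(nid_counter), lab, 0.0) for lab in labels]
    if len(clusters) == 1:
        return clusters[0]
    join_heights = np.sort(rng.uniform(0.0, height, size=len(labels) - 1))
    join_heights[-1] = height  # clade root sits at the stated height
    for h in join_heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        node = _BNode(next(nid_counter), None, float(h), [clusters[i], clusters[j]])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [node]
    return clusters[0]


def _collect_edges(node: _BNode, region_edges: list) -> None:
    for ch in node.children:
        region_edges.append((node, ch))
        _collect_edges(ch, region_edges)


def _leaves_below(node: _BNode) -> list[str]:
    if not node.children:
        return [node.label]
    out = []
    for ch in node.children:
        out.extend(_leaves_below(ch))
    return out


def _to_dendropy(root: _BNode, grafts_by_edge: dict, tns) -> dendropy.Tree:
    """Materialise the backbone plus focal grafts as a dendropy tree.

    ``grafts_by_edge`` maps a child-node id to the list of
    (focal_id, attach_height) grafts on the edge above that child, applied
    top-down so multiple grafts on one edge nest correctly.
    """

    def build(bnode: _BNode, parent_height: float) -> dendropy.Node:
        grafts = sorted(
            grafts_by_edge.get(bnode.nid, []), key=lambda g: (-g[1], g[0])
        )
        top = dendropy.Node() if bnode.children else dendropy.Node(
            taxon=tns.require_taxon(bnode.label)
        )
        for ch in bnode.children:
            top.add_child(build(ch, bnode.height))
        # wrap in graft nodes from highest attachment down
        node = top
        upper = parent_height
        chain_parent = None
        result = None
        for focal_id, h in grafts:
            g = dendropy.Node()
            leaf = dendropy.Node(taxon=tns.require_taxon(focal_id))
            leaf.edge.length = h
            g.add_child(leaf)
            g.edge.length = upper - h
            if chain_parent is None:
                result = g
            else:
                chain_parent.add_child(g)
            chain_parent = g
            upper = h
        node.edge.length = upper - bnode.height
        if chain_parent is None:
            result = node
        else:
            chain_parent.add_child(node)
        return result

    seed = dendropy.Node()
    for ch in root.children:
        seed.add_child(build(ch, root.height))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = seed
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def simulate_trees(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, dendropy.Tree, TruthTable]:
    """Core and symbiotic trees with planted focal histories, plus truth.

    The two trees restricted to reference tips are identical; transfers
    touch focal tips only.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    nid_counter = iter(range(10**9))
    region_roots = {}
    region_edges: dict[str, list] = {}
    for region in cfg.regions:
        labels = [f"{region}_ref{i + 1}" for i in range(cfg.refs_per_region)]
        clade = _yule_clade(labels, cfg.within_region_height, rng, nid_counter)
        region_roots[region] = clade
        edges: list = []
        _collect_edges(clade, edges)
        region_edges[region] = edges
    root = _BNode(
        next(nid_counter), None, cfg.between_region_height,
        [region_roots[r] for r in cfg.regions],
    )

    def draw_graft(region: str):
        edges = region_edges[region]
        if edges:
            k = int(rng.integers(0, len(edges)))
            parent, child = edges[k]
            h = float(rng.uniform(child.height, parent.height))
        else:  # single-reference region: graft onto its pendant edge
            child = region_roots[region]
            h = float(rng.uniform(0.0, cfg.within_region_height))
        donor = ",".join(sorted(_leaves_below(child)))
        return child.nid, h, donor

    core_grafts: dict[int, list] = {}
    sym_grafts: dict[int, list] = {}
    truth_rows = []
    for focal_id, scen in cfg.focal_plan:
        core_region = cfg.native_region if scen in (1, 4) else cfg.local_region
        sym_region = cfg.native_region if scen in (1, 3) else cfg.local_region
        edge_id, h, donor = draw_graft(core_region)
        core_grafts.setdefault(edge_id, []).append((focal_id, h))
        if sym_region == core_region:
            sym_edge, sym_h, sym_donor = edge_id, h, donor
        else:
            sym_edge, sym_h, sym_donor = draw_graft(sym_region)
        sym_grafts.setdefault(sym_edge, []).append((focal_id, sym_h))
        truth_rows.append(
            FocalTruth(focal_id, scen, core_region, sym_region, donor, sym_donor, h, sym_h)
        )

    tns = dendropy.TaxonNamespace()
    core_tree = _to_dendropy(root, core_grafts, tns)
    sym_tree = _to_dendropy(root, sym_grafts, tns)
    return core_tree, sym_tree, TruthTable(truth_rows)


def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    model: str | SubstitutionModel = "JC69",
    seed: int | np.random.Generator = 0,
    locus_name: str = "locus",
    kappa: float = 2.0,
    base_freqs=None,
) -> GeneAlignment:
    """Evolve sequences down the tree under the substitution model.

    Branch lengths are expected substitutions/site; the root sequence is
    drawn from the stationary frequencies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not isinstance(model, SubstitutionModel):
        if model == "HKY85" and base_freqs is None:
            base_freqs = (0.25, 0.25, 0.25, 0.25)
        model = make_model(model, kappa=kappa, base_freqs=base_freqs)
    seqs: dict = {}
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[node] = rng.choice(4, size=length, p=model.freqs)
        else:
            t = node.edge.length or 0.0
            if t < 0:
                raise ValueError("negative branch length")
            parent_seq = seqs[node.parent_node]
            if t == 0:
                child_seq = parent_seq.copy()
            else:
                cum = np.cumsum(model.transition(t), axis=1)
                u = rng.random(length)
                child_seq = (u[:, None] <= cum[parent_seq]).argmax(axis=1)
            seqs[node] = child_seq
        if node.is_leaf():
            ids.append(node.taxon.label)
            rows.append(_BASES[seqs[node]])
    order = np.argsort(ids)
    data = np.vstack([rows[i] for i in order])
    return GeneAlignment(locus_name, [ids[i] for i in order], data)


def simulate_dataset(cfg: SimConfig):
    """In-memory dataset: (alignments, metadata, truth, core_tree, sym_tree).

    ``alignments`` maps locus name to a GeneAlignment; core loci evolve on
    the core tree, symbiotic loci on the symbiotic tree.  Fully determined
    by ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n_loci = len(cfg.core_loci) + len(cfg.sym_loci)
    children = ss.spawn(1 + n_loci)
    core_tree, sym_tree, truth = simulate_trees(cfg, np.random.default_rng(children[0]))
    alignments: dict[str, GeneAlignment] = {}
    k = 1
    for name, length in cfg.core_loci:
        alignments[name] = evolve_sequences(
            core_tree, length, cfg.model, np.random.default_rng(children[k]),
            locus_name=name, kappa=cfg.kappa,
        )
        k += 1
    for name, length in cfg.sym_loci:
        alignments[name] = evolve_sequences(
            sym_tree, length, cfg.model, np.random.default_rng(children[k]),
            locus_name=name, kappa=cfg.kappa,
        )
        k += 1
    rows = []
    for region in cfg.regions:
        for i in range(cfg.refs_per_region):
            rows.append(
                (f"{region}_ref{i + 1}", f"host_{region}", region, "reference")
            )
    for focal_id, _scen in cfg.focal_plan:
        rows.append((focal_id, "focal_host", cfg.local_region, "focal"))
    meta = MetadataTable.from_rows(rows)
    return alignments, meta, truth, core_tree, sym_tree


def generate_dataset(cfg: SimConfig, outdir, overwrite: bool = False) -> dict:
    """Write FASTA per locus, metadata TSV, truth TSV, trees and config echo."""
    from .treebuild import write_newick

    outdir = str(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (use overwrite)")
    os.makedirs(outdir, exist_ok=True)
    alignments, meta, truth, core_tree, sym_tree = simulate_dataset(cfg)
    paths = {}
    for name, aln in alignments.items():
        p = os.path.join(outdir, f"{name}.fasta")
        write_alignment(aln, p)
        paths[name] = p
    meta.write(os.path.join(outdir, "metadata.tsv"))
    truth.write(os.path.join(outdir, "truth.tsv"))
    write_newick(core_tree, os.path.join(outdir, "core_tree.nwk"))
    write_newick(sym_tree, os.path.join(outdir, "sym_tree.nwk"))
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=list)
    paths.update(
        metadata=os.path.join(outdir, "metadata.tsv"),
        truth=os.path.join(outdir, "truth.tsv"),
        core_tree=os.path.join(outdir, "core_tree.nwk"),
        sym_tree=os.path.join(outdir, "sym_tree.nwk"),
        config=os.path.join(outdir, "config.json"),
    )
    return paths
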
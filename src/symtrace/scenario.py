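"""Phylogeographic scenario classification of focal strains.

For each focal strain we ask, on the core-gene tree and on each
symbiotic-gene tree separately: which regional group of *reference* strains
does it cluster with?  The affinity rule walks rootward from the focal tip
to the smallest clade containing at least one reference strain and takes a
majority vote over the regions of the reference tips in that clade.  The
pair (core affinity, symbiotic affinity) then maps onto four scenarios:

    (native, native) -> 1  co-introduction with the host
    (local,  local)  -> 2  acquisition of a local symbiont
    (local,  native) -> 3  local strain carrying the original symbiosis genes
    (native, local)  -> 4  co-introduced strain with locally acquired
                           symbiosis genes

Any unresolved or out-of-range affinity, or disagreement between symbiotic
loci, yields ``unclassified``.  Affinity is decided on the support-collapsed
tree, so weakly supported attachments dissolve into polytomies and tend
toward unresolved rather than overconfident calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy

from .alignio import MetadataTable

AFFINITIES = ("native", "local", "other", "unresolved")
SCENARIOS = ("1", "2", "3", "4", "unclassified")

_SCENARIO_MAP = {
    ("native", "native"): "1",
    ("local", "local"): "2",
    ("local", "native"): "3",
    ("native", "local"): "4",
}


@dataclass
class AffinityCall:
    tree_id: str
    focal_strain_id: str
    affinity: str
    evidence: list  # (reference tip, region) pairs in the supporting clade
    region_tally: dict
    clade_support: float | None


@dataclass
class ScenarioCall:
    focal_strain_id: str
    core_affinity: str
    sym_affinities: dict  # locus -> affinity
    scenario: str
    rationale: str


def reference_affinity(
    tree: dendropy.Tree,
    meta: MetadataTable,
    focal: str,
    native_region: str,
    local_region: str,
    majority: float = 0.5,
    max_depth: int | None = None,
    tree_id: str = "tree",
) -> AffinityCall:
    """Regional affinity of one focal tip on a rooted (collapsed) tree.

    Walks rootward to the smallest clade holding >= 1 reference tip, then
    requires one region's share of the reference tally to exceed
    ``majority``; ties or an exhausted walk give ``unresolved``.
    """
    roles = dict(zip(meta.df["strain_id"], meta.df["role"]))
    regions = dict(zip(meta.df["strain_id"], meta.df["region"]))
    focal_node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == focal:
            focal_node = leaf
            break
    if focal_node is None:
        raise ValueError(f"focal strain {focal!r} not found in tree {tree_id!r}")

    node = focal_node.parent_node
    depth = 0
    ref_tips: list = []
    support = None
    while node is not None:
        if max_depth is not None and depth >= max_depth:
            node = None
            break
        ref_tips = [
            lf.taxon.label
            for lf in node.leaf_iter()
            if roles.get(lf.taxon.label) == "reference"
        ]
        if ref_tips:
            support = getattr(node, "support", None)
            break
        node = node.parent_node
        depth += 1

    tally = Counter(regions[t] for t in ref_tips)
    evidence = sorted((t, regions[t]) for t in ref_tips)
    if not tally:
        return AffinityCall(tree_id, focal, "unresolved", evidence, {}, None)
    total = sum(tally.values())
    (top_region, top_count), *rest = tally.most_common()
    tied = rest and rest[0][1] == top_count
    if tied or top_count / total <= majority:
        affinity = "unresolved"
    elif top_region == native_region:
        affinity = "native"
    elif top_region == local_region:
        affinity = "local"
    else:
        affinity = "other"
    return AffinityCall(tree_id, focal, affinity, evidence, dict(tally), support)


def classify_scenario(core: AffinityCall, sym: AffinityCall) -> ScenarioCall:
    """Map a (core affinity, symbiotic affinity) pair to a scenario."""
    if core.focal_strain_id != sym.focal_strain_id:
        raise ValueError("affinity calls refer to different focal strains")
    key = (core.affinity, sym.affinity)
    scenario = _SCENARIO_MAP.get(key, "unclassified")
    if scenario == "unclassified":
        rationale = f"no scenario for affinity pair {key}"
    else:
        rationale = f"core={core.affinity}, symbiotic={sym.affinity}"
    return ScenarioCall(
        core.focal_strain_id, core.affinity, {sym.tree_id: sym.affinity},
        scenario, rationale,
    )


def classify_all(
    core_tree: dendropy.Tree,
    sym_trees: dict[str, dendropy.Tree],
    meta: MetadataTable,
    native_region: str,
    local_region: str,
    majority: float = 0.5,
    max_depth: int | None = None,
) -> tuple[list[ScenarioCall], dict]:
    """One scenario call per focal strain, plus summary counts.

    Symbiotic loci must agree on affinity; a conflict yields
    ``unclassified`` with the per-locus affinities recorded.
    """
    focal_ids = meta.focal_ids
    trees = {"core": core_tree, **sym_trees}
    for name, tree in trees.items():
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        missing = [f for f in focal_ids if f not in tips]
        if missing:
            raise ValueError(f"tree {name!r} lacks focal strains: {missing}")
    calls = []
    for focal in focal_ids:
        core_call = reference_affinity(
            core_tree, meta, focal, native_region, local_region,
            majority=majority, max_depth=max_depth, tree_id="core",
        )
        sym_calls = {
            locus: reference_affinity(
                t, meta, focal, native_region, local_region,
                majority=majority, max_depth=max_depth, tree_id=locus,
            )
            for locus, t in sym_trees.items()
        }
        sym_affs = {locus: c.affinity for locus, c in sym_calls.items()}
        distinct = set(sym_affs.values())
        if len(distinct) > 1:
            calls.append(
                ScenarioCall(
                    focal, core_call.affinity, sym_affs, "unclassified",
                    f"symbiotic loci conflict: {sym_affs}",
                )
            )
            continue
        sym_aff = next(iter(distinct)) if distinct else "unresolved"
        key = (core_call.affinity, sym_aff)
        scenario = _SCENARIO_MAP.get(key, "unclassified")
        rationale = (
            f"core={core_call.affinity}, symbiotic={sym_aff}"
            if scenario != "unclassified"
            else f"no scenario for affinity pair {key}"
        )
        calls.append(ScenarioCall(focal, core_call.affinity, sym_affs, scenario, rationale))
    summary = {s: sum(1 for c in calls if c.scenario == s) for s in SCENARIOS}
    return calls, summary


def write_calls(calls: list[ScenarioCall], summary: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\tcore_affinity\tsym_affinities\tscenario\trationale\n")
        for c in calls:
            sym = ";".join(f"{k}={v}" for k, v in sorted(c.sym_affinities.items()))
            fh.write(
                f"{c.focal_strain_id}\t{c.core_affinity}\t{sym}\t{c.scenario}\t{c.rationale}\n"
            )
        fh.write("# summary\t" + "\t".join(f"{k}:{v}" for k, v in summary.items()) + "\n")
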
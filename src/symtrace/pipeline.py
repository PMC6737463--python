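"""End-to-end orchestration: alignments in, scenario calls out.

Stages, in order: concatenate core loci -> distances -> neighbor joining per
data set (core concatenation plus each symbiotic locus) -> bootstrap
replicates -> FBP and TBE support -> low-support collapse -> per-site
log-likelihoods -> reciprocal AU congruence verdicts -> scenario
classification.  ``analyze`` runs everything in memory; ``run_all`` adds
file IO and writes a manifest with per-artifact hashes so reruns are
byte-comparable.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``: child 0 drives the bootstrap
(consumed data-set by data-set in configuration order), child 1 the AU
resampling (one grandchild per symbiotic locus, in order).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .alignio import (
    GeneAlignment,
    MetadataTable,
    bootstrap_resample,
    concatenate_core,
    read_alignment,
    write_alignment,
)
from .autest import DEFAULT_B, DEFAULT_SCALES, congruence_verdict
from .scenario import classify_all, write_calls
from .sitelik import SiteLogLikMatrix
from .treebuild import (
    collapse_low_support,
    collapse_short_branches,
    felsenstein_support,
    ls_branch_lengths,
    neighbor_joining,
    pairwise_distances,
    refine_compatible,
    rf_distance,
    root_tree,
    transfer_bootstrap_expectation,
    write_newick,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    loci_paths: dict
    metadata_path: str
    outdir: str
    core_loci: list
    sym_loci: list
    native_region: str
    local_region: str
    outgroup: str | None = None
    bootstrap_n: int = 100
    support_stat: str = "fbp"
    collapse_threshold: float = 0.6
    au_scales: tuple = DEFAULT_SCALES
    au_B: int = DEFAULT_B
    alpha: float = 0.05
    min_loci: int | None = None
    distance_model: str = "JC69"
    lik_model: str = "JC69"
    majority: float = 0.5
    min_conflict_subs: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.core_loci or not self.sym_loci:
            raise ValueError("core_loci and sym_loci must be non-empty")
        if set(self.core_loci) & set(self.sym_loci):
            raise ValueError("core_loci and sym_loci must be disjoint")
        if not 0.0 <= self.collapse_threshold <= 1.0:
            raise ValueError("collapse_threshold must be in [0, 1]")
        if self.support_stat not in ("fbp", "tbe"):
            raise ValueError("support_stat must be 'fbp' or 'tbe'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class DatasetResult:
    name: str
    alignment: GeneAlignment
    tree: object  # NJ tree with branch lengths
    fbp_tree: object
    tbe_tree: object
    collapsed_tree: object
    collapsed_fraction: float


@dataclass
class PipelineResult:
    datasets: dict
    partition: object
    rf_core_vs_sym: dict
    au_results: dict  # sym locus -> (verdict, {dataset: AUResult})
    verdict: str
    scenario_calls: list
    scenario_summary: dict
    seed: int
    support_stat: str = "fbp"
    collapse_threshold: float = 0.6


def _infer_with_support(
    name: str,
    aln: GeneAlignment,
    n_boot: int,
    rng: np.random.Generator,
    distance_model: str,
    support_stat: str,
    collapse_threshold: float,
) -> DatasetResult:
    t0 = time.perf_counter()
    dm = pairwise_distances(aln, model=distance_model)
    tree = neighbor_joining(dm)
    reps = []
    for _ in range(n_boot):
        baln = bootstrap_resample(aln, rng)
        reps.append(neighbor_joining(pairwise_distances(baln, model=distance_model)))
    fbp_tree = felsenstein_support(tree, reps)
    tbe_tree = transfer_bootstrap_expectation(tree, reps)
    chosen = fbp_tree if support_stat == "fbp" else tbe_tree
    collapsed, fraction = collapse_low_support(chosen, collapse_threshold)
    logger.info(
        "dataset %s: %d strains, %d sites, %d bootstraps, %.1f%% branches collapsed "
        "(%.2fs)",
        name, aln.n_strains, aln.length, n_boot, 100 * fraction,
        time.perf_counter() - t0,
    )
    return DatasetResult(name, aln, tree, fbp_tree, tbe_tree, collapsed, fraction)


def analyze(
    alignments: dict,
    meta: MetadataTable,
    core_loci: list,
    sym_loci: list,
    native_region: str,
    local_region: str,
    outgroup: str | None = None,
    bootstrap_n: int = 100,
    support_stat: str = "fbp",
    collapse_threshold: float = 0.6,
    au_scales=DEFAULT_SCALES,
    au_B: int = DEFAULT_B,
    alpha: float = 0.05,
    min_loci: int | None = None,
    distance_model: str = "JC69",
    lik_model: str = "JC69",
    majority: float = 0.5,
    min_conflict_subs: float = 10.0,
    seed: int = 0,
) -> PipelineResult:
    """Run the whole analysis in memory and return every intermediate."""
    missing = [l for l in list(core_loci) + list(sym_loci) if l not in alignments]
    if missing:
        raise ValueError(f"loci missing from input: {missing}")
    ss = np.random.SeedSequence(seed)
    boot_ss, au_ss = ss.spawn(2)
    boot_rng = np.random.default_rng(boot_ss)

    concat, partition = concatenate_core(
        [alignments[l] for l in core_loci], min_loci=min_loci
    )
    # every data set is restricted to the strains shared by all of them, so
    # tree tip sets are comparable across core and symbiotic data sets
    common = [
        sid
        for sid in concat.strain_ids
        if all(sid in alignments[l].strain_ids for l in sym_loci)
    ]
    if len(common) < 4:
        raise ValueError("fewer than 4 strains shared across core and symbiotic loci")
    datasets_in = {"core": concat.subset(common)}
    for l in sym_loci:
        datasets_in[l] = alignments[l].subset(common)

    datasets: dict = {}
    for name, aln in datasets_in.items():
        datasets[name] = _infer_with_support(
            name, aln, bootstrap_n, boot_rng, distance_model,
            support_stat, collapse_threshold,
        )

    # reciprocal AU congruence between the core tree and each symbiotic tree.
    # Topologies enter the test support-collapsed, so weakly supported
    # (estimation-noise) disagreements dissolve into polytomies and only
    # well-supported conflict can reject; every candidate topology is scored
    # with branch lengths re-fitted to the scoring data set's distances
    # (least squares), so the test compares topologies rather than
    # penalising foreign branch lengths
    core = datasets["core"]
    core_dm = pairwise_distances(core.alignment, model=distance_model)
    core_topo_base = collapse_short_branches(
        core.collapsed_tree, min_conflict_subs / core.alignment.length
    )
    au_results: dict = {}
    verdict_overall = "congruent"
    rf_core_vs_sym = {}
    au_rngs = au_ss.spawn(len(sym_loci))
    for k, l in enumerate(sym_loci):
        sym = datasets[l]
        rf_core_vs_sym[l] = rf_distance(core.tree, sym.tree)
        sym_dm = pairwise_distances(sym.alignment, model=distance_model)
        sym_topo_base = collapse_short_branches(
            sym.collapsed_tree, min_conflict_subs / sym.alignment.length
        )
        core_topo = refine_compatible(core_topo_base, sym_topo_base)
        sym_topo = refine_compatible(sym_topo_base, core_topo_base)
        L_core = SiteLogLikMatrix.from_trees(
            {
                "core": ls_branch_lengths(core_topo, core_dm),
                l: ls_branch_lengths(sym_topo, core_dm),
            },
            core.alignment, lik_model,
        )
        L_sym = SiteLogLikMatrix.from_trees(
            {
                l: ls_branch_lengths(sym_topo, sym_dm),
                "core": ls_branch_lengths(core_topo, sym_dm),
            },
            sym.alignment, lik_model,
        )
        verdict, details = congruence_verdict(
            {"core": L_core, l: L_sym},
            own_tree={"core": "core", l: l},
            alpha=alpha, scales=au_scales, B=au_B,
            seed=int(np.random.default_rng(au_rngs[k]).integers(0, 2**31 - 1)),
        )
        au_results[l] = (verdict, details)
        if verdict == "incongruent":
            verdict_overall = "incongruent"

    rooted = {
        name: root_tree(ds.collapsed_tree, outgroup=outgroup)
        for name, ds in datasets.items()
    }
    calls, summary = classify_all(
        rooted["core"], {l: rooted[l] for l in sym_loci}, meta,
        native_region, local_region, majority=majority,
    )
    return PipelineResult(
        datasets=datasets,
        partition=partition,
        rf_core_vs_sym=rf_core_vs_sym,
        au_results=au_results,
        verdict=verdict_overall,
        scenario_calls=calls,
        scenario_summary=summary,
        seed=seed,
        support_stat=support_stat,
        collapse_threshold=collapse_threshold,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> PipelineResult:
    """File-based pipeline run: read inputs, analyze, write artifacts."""
    os.makedirs(cfg.outdir, exist_ok=True)
    alignments = {
        name: read_alignment(path, locus_name=name)
        for name, path in cfg.loci_paths.items()
    }
    meta = MetadataTable.read(cfg.metadata_path)
    result = analyze(
        alignments, meta,
        core_loci=cfg.core_loci, sym_loci=cfg.sym_loci,
        native_region=cfg.native_region, local_region=cfg.local_region,
        outgroup=cfg.outgroup, bootstrap_n=cfg.bootstrap_n,
        support_stat=cfg.support_stat, collapse_threshold=cfg.collapse_threshold,
        au_scales=cfg.au_scales, au_B=cfg.au_B, alpha=cfg.alpha,
        min_loci=cfg.min_loci, distance_model=cfg.distance_model,
        lik_model=cfg.lik_model, majority=cfg.majority,
        min_conflict_subs=cfg.min_conflict_subs, seed=cfg.seed,
    )
    out = cfg.outdir
    artifacts = []

    def emit(name):
        artifacts.append(name)
        return os.path.join(out, name)

    write_alignment(result.datasets["core"].alignment, emit("core_concat.fasta"))
    result.partition.write(emit("core_partition.tsv"))
    for name, ds in result.datasets.items():
        write_newick(ds.fbp_tree, emit(f"{name}_fbp.nwk"))
        write_newick(ds.tbe_tree, emit(f"{name}_tbe.nwk"))
        write_newick(ds.collapsed_tree, emit(f"{name}_collapsed.nwk"))
    with open(emit("collapse_report.tsv"), "w") as fh:
        fh.write("dataset\tsupport_stat\tthreshold\tcollapsed_fraction\n")
        for name, ds in result.datasets.items():
            fh.write(
                f"{name}\t{result.support_stat}\t{result.collapse_threshold}\t"
                f"{ds.collapsed_fraction:.6g}\n"
            )
    with open(emit("congruence.tsv"), "w") as fh:
        fh.write("sym_locus\trf_vs_core\tverdict\tmin_rival_au_p\n")
        for l, (verdict, details) in result.au_results.items():
            pmin = min(
                res.au_p[res.tree_ids.index(t)]
                for ds_name, res in details.items()
                for t in res.tree_ids
                if t != ({"core": "core"}.get(ds_name, ds_name))
            )
            fh.write(f"{l}\t{result.rf_core_vs_sym[l]}\t{verdict}\t{pmin:.6g}\n")
    write_calls(result.scenario_calls, result.scenario_summary, emit("scenario_calls.tsv"))

    manifest = {
        "symtrace_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "verdict": result.verdict,
        "scenario_summary": result.scenario_summary,
        "artifacts": {a: _sha256(os.path.join(out, a)) for a in sorted(artifacts)},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result
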
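# Methods

## The inference problem

A focal bacterial strain isolated from an introduced host plant carries two
partly independent historical signals: its core genome (16S rRNA plus
housekeeping loci) records vertical descent, while its symbiosis loci
(*nodC*, *nifH*) can be acquired horizontally.  Given per-locus alignments
of focal strains together with reference strains of known geographic
origin, the pipeline asks, for each focal strain and each signal, *which
regional group of references does it cluster with?* — and reads the pair
of answers as one of four phylogeographic scenarios (co-introduction,
local acquisition, or one of two chimera configurations).  A reciprocal
topology test between the core tree and each symbiotic tree provides a
genome-wide verdict on whether the symbiosis loci have a history of their
own.

## Tree inference

Trees are inferred by neighbor joining on JC69-corrected distances
(p-distances are available).  Distances use pairwise deletion: a site
enters a pair's comparison only when both sequences carry an unambiguous
base.  Pairs at or beyond the JC69 saturation point (p ≥ 3/4), or sharing
no comparable sites, receive a fixed cap (default 5.0 substitutions/site)
rather than an infinite or undefined value; substitutions of the cap are
logged.  NJ follows the Saitou–Nei criterion with Studier–Keppler updates;
negative limb estimates are clamped to zero and Q-ties are broken by the
lexicographically smallest tip labels of the joined clusters, making the
output deterministic.  Distance-based inference was chosen over
maximum-likelihood search because it is exactly specifiable, fast enough
for hundreds of bootstrap replicates per run, and statistically consistent
on the generator's additive-in-expectation data — the properties the test
suite leans on.

Branch support comes from the non-parametric bootstrap (default 100
replicates, resampling alignment columns): both the classical Felsenstein
proportion (FBP — fraction of replicates containing the identical
bipartition) and the transfer bootstrap expectation (TBE — one minus the
mean minimum bipartition Hamming distance to each replicate, normalised by
lighter-side size minus one; the minimum runs over all replicate branches
and both orientations).  TBE ≥ FBP everywhere and the two coincide on
cherries.  Branches with support strictly below the collapse threshold
(default 0.6, FBP) are contracted to polytomies; the collapsed fraction is
reported per data set.  Which statistic drives the collapse is a
configuration switch (`support_stat`), since both conventions are current
in practice.

## Congruence testing

Per-site log-likelihoods are computed by Felsenstein pruning on fixed
trees under JC69 or HKY85 (empirical base frequencies by default),
with per-node rescaling against underflow; gaps and ambiguity codes are
missing data.  The AU test resamples site log-likelihoods (RELL) at ten
scales r ∈ {0.5, …, 1.4} with B = 1,000 replicates per scale, credits the
best tree per replicate (ties split fractionally, which makes exact
symmetries exact), clamps bootstrap proportions to [1/(2B), 1 − 1/(2B)],
and fits z_k = Φ⁻¹(1 − BP_k) ≈ d√r_k + c/√r_k by weighted least squares
with delta-method binomial weights; p_AU = 1 − Φ(d − c).  Trees whose
proportions are degenerate (0 or 1 at every scale) get the corresponding
boundary p-value and a flag.

The reciprocal verdict between the core data set and a symbiotic locus
scores both topologies on both alignments and declares incongruence when a
rival topology is rejected (p_AU < α, default 0.05) on either side.  Two
preparation steps make this a test of *history* rather than of estimation
noise:

1. **Conflict must be supported and attested.**  Candidate topologies
   enter the test support-collapsed, and additionally with internal
   branches attested by fewer than `min_conflict_subs` substitutions
   (default 10; i.e. estimated length × locus length < 10) contracted.
   Resolution of near-simultaneous divergences is driven by a handful of
   realized mutations; each locus resolves them in its own arbitrary but
   internally consistent way, so such branches can carry high bootstrap
   support and still disagree across loci without any transfer having
   occurred.  The planted transfer signal, by contrast, involves
   between-region divergence (≈ 0.3 × 600 ≈ 180 substitutions for the
   default symbiotic locus), an order of magnitude above the cut.
2. **Resolution differences are equalised.**  Each candidate topology is
   refined with the other's compatible splits before scoring, so the two
   candidates differ only at genuinely conflicting branches; otherwise the
   better-resolved tree (typically the longer concatenated core) would be
   preferred for resolution alone.  When refinement makes the topologies
   identical, both p-values are ~0.5 and the verdict is congruent, as it
   should be.

Every candidate topology is scored with branch lengths re-fitted to the
scoring alignment's distance matrix by non-negative least squares — the
test compares topologies, not foreign branch-length sets.  No
likelihood-based branch-length optimization is performed anywhere;
externally supplied branch lengths are accepted by the scoring functions.

## Scenario classification

Affinity of a focal tip is decided on the support-collapsed tree, rooted
at a configured outgroup or (default) at the midpoint: walk rootward to
the smallest clade containing at least one reference strain, tally the
reference tips' regions, and require one region's share to exceed the
majority threshold (default 0.5, strict).  Ties, walks that exhaust the
tree, or clades dominated by neither the native nor the introduced region
give `unresolved`/`other`; any such affinity, or disagreement between
symbiotic loci, yields `unclassified` rather than a forced call.  Host
species labels ride along in the evidence but never enter the decision —
the scenarios are geographic statements.  Calls are per strain; reports
may group identical calls per clade.

## Synthetic data

The generator emulates the regional structure of a reference strain panel:
one ultrametric clade per region (random joins at heights uniform within
the within-region height, default 0.02 substitutions/site) joined at a
deep divergence (default 0.3), identical in the core and symbiotic trees.
Focal strains are grafted at uniform heights onto the native or introduced
("local") region clade according to their planted scenario; a scenario-3/4
strain is re-grafted in exactly one tree, which is precisely a
symbiotic-module transfer at the strain level.  Sequences evolve site-wise
along each tree from stationary-frequency roots (JC69 by default; HKY85
available).  Default problem size — 3 regions × 5 references, 20 focal
strains (5 per scenario), four 500-site core loci and two 600-site
symbiotic loci — keeps a full pipeline run under ~10 s while leaving the
between/within divergence ratio (15×) in the regime where regional
affinity is identifiable.

What the generator does *not* model bounds what passing tests show:
within-locus recombination, indels and alignment error, rate variation
across sites and lineages, unsampled source populations, and
coalescent/population processes are all absent.  On real data the same
pipeline can therefore be expected to produce more `unresolved` affinities
and noisier verdicts than on the simulator; the tests demonstrate
correctness of the machinery and identifiability under clean geographic
structure, not field-data power.

## Numerical choices and edge cases

- Saturated distance pairs: fixed cap (default 5.0), logged.
- NJ negative limb lengths clamped at 0; deterministic lexicographic
  tie-breaks.
- Pruning uses per-node max-rescaling with accumulated log-scalers; a
  zero-probability site yields −inf cleanly, and RELL floors site scores
  at −1e15 so an impossible site loses every replicate that draws it
  without poisoning replicates that skip it.
- Bootstrap proportions are clamped before the probit transform; the AU
  fit refuses fewer than two scales.
- Support collapse uses strict inequality ("lower than" the threshold).
- Strains missing from some core loci are retained if present in at least
  `min_loci` of them (default: all), with gap fill; concatenation then
  slicing is lossless for retained strains.
- A single global seed fans out to stage seeds via
  `numpy.random.SeedSequence.spawn`, so reruns are byte-identical and
  stages are individually reproducible.

## Known limitations

- Affinity is a topology-only majority rule; it does not weigh branch
  lengths or support *within* the supporting clade beyond the collapse
  step, and can differ from an expert's by-eye reading of the same tree.
- The AU implementation follows the standard multiscale-RELL recipe but
  is not a replacement for dedicated topology-test software on large
  candidate sets; candidate sets here are pairs by construction.
- The congruence verdict aggregates reciprocal tests without multiplicity
  correction; with many symbiotic loci the family-wise error of the
  incongruence call grows accordingly.
- NJ on heavily saturated or highly rate-heterogeneous data inherits the
  usual distance-method biases; the capped-distance fallback keeps runs
  alive but such pairs carry no signal.
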
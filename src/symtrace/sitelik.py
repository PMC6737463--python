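"""Per-site log-likelihoods of an alignment on fixed trees.

Felsenstein's pruning algorithm under JC69 or HKY85, on trees with fixed
branch lengths (expected substitutions/site).  The per-site scores for a set
of candidate trees feed the RELL bootstrap and the approximate-unbiased
topology test.  Gaps and ambiguous bases are treated as missing data
(partial likelihood vector of ones); the root is weighted by the model's
stationary frequencies, so the likelihood is invariant to the rooting of
these reversible models.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

from .alignio import GeneAlignment


def jc69_transition(t: float) -> np.ndarray:
    """JC69 P(t): P_same = 1/4 + 3/4 e^{-4t/3}, P_diff = 1/4 - 1/4 e^{-4t/3}."""
    e = np.exp(-4.0 * t / 3.0)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    P = np.full((4, 4), p_diff)
    np.fill_diagonal(P, p_same)
    return P


def hky85_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 generator, normalised to one expected substitution per unit time."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0) or np.any(freqs <= 0):
        raise ValueError("base_freqs must be 4 positive values summing to 1")
    # order A, C, G, T; transitions A<->G and C<->T
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(freqs, np.diag(Q))
    return Q / mu


@dataclass
class SubstitutionModel:
    """Model spec for pruning: name, stationary frequencies, P(t) factory."""

    name: str
    freqs: np.ndarray
    kappa: float | None = None

    def transition(self, t: float) -> np.ndarray:
        if self.name == "JC69":
            return jc69_transition(t)
        return expm(hky85_rate_matrix(self.kappa, self.freqs) * t)


def make_model(
    model: str = "JC69",
    kappa: float = 2.0,
    base_freqs=None,
    aln: GeneAlignment | None = None,
) -> SubstitutionModel:
    if model == "JC69":
        return SubstitutionModel("JC69", np.full(4, 0.25))
    if model == "HKY85":
        if base_freqs is None:
            if aln is None:
                raise ValueError("HKY85 needs base_freqs or an alignment")
            base_freqs = empirical_base_freqs(aln)
        return SubstitutionModel("HKY85", np.asarray(base_freqs, float), kappa)
    raise ValueError(f"unknown model {model!r}")


def empirical_base_freqs(aln: GeneAlignment) -> np.ndarray:
    codes = aln.codes()
    counts = np.array([(codes == b).sum() for b in range(4)], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    # mild pseudocount keeps frequencies strictly positive
    counts += 1.0
    return counts / counts.sum()


def site_log_likelihoods(
    tree: dendropy.Tree,
    aln: GeneAlignment,
    model: str | SubstitutionModel = "JC69",
    kappa: float = 2.0,
    base_freqs=None,
) -> np.ndarray:
    """Per-site log-likelihood vector by post-order pruning.

    Underflow is controlled by per-node rescaling with accumulated
    log-scalers.  Tips of the tree must all be present in the alignment;
    branch lengths must be non-negative (``None`` counts as zero).
    """
    if not isinstance(model, SubstitutionModel):
        model = make_model(model, kappa=kappa, base_freqs=base_freqs, aln=aln)
    strains = set(aln.strain_ids)
    codes = aln.codes()
    row_of = {sid: i for i, sid in enumerate(aln.strain_ids)}
    S = aln.length
    log_scale = np.zeros(S)
    partials: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in strains:
                raise ValueError(f"tip {label!r} absent from alignment")
            part = np.zeros((4, S))
            c = codes[row_of[label]]
            obs = c != 255
            part[:, ~obs] = 1.0
            part[c[obs], np.nonzero(obs)[0]] = 1.0
        else:
            part = np.ones((4, S))
            for child in node.child_nodes():
                t = child.edge.length
                if t is None:
                    t = 0.0
                if t < 0:
                    raise ValueError(f"negative branch length {t}")
                P = model.transition(t)
                part *= P @ partials.pop(child)
            scaler = part.max(axis=0)
            ok = scaler > 0
            part[:, ok] /= scaler[ok]
            with np.errstate(divide="ignore"):
                log_scale += np.where(ok, np.log(np.where(ok, scaler, 1.0)), -np.inf)
        partials[node] = part
    root_part = partials[tree.seed_node]
    site_l = model.freqs @ root_part
    with np.errstate(divide="ignore"):
        return np.log(site_l) + log_scale


@dataclass
class SiteLogLikMatrix:
    """Candidate trees x alignment sites of per-site log-likelihoods."""

    tree_ids: list[str]
    L: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if len(self.tree_ids) != self.L.shape[0]:
            raise ValueError("tree_ids length does not match matrix rows")
        if len(set(self.tree_ids)) != len(self.tree_ids):
            raise ValueError("duplicate tree ids")

    @property
    def n_trees(self) -> int:
        return self.L.shape[0]

    @property
    def n_sites(self) -> int:
        return self.L.shape[1]

    @classmethod
    def from_trees(
        cls,
        trees: dict[str, dendropy.Tree],
        aln: GeneAlignment,
        model: str | SubstitutionModel = "JC69",
        **model_kw,
    ) -> "SiteLogLikMatrix":
        ids = list(trees)
        L = np.vstack(
            [site_log_likelihoods(trees[tid], aln, model, **model_kw) for tid in ids]
        )
        return cls(ids, L)

    def write(self, path) -> None:
        """Plain-text layout: header '<n_trees> <n_sites>', one row per tree."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_trees} {self.n_sites}\n")
            for tid, row in zip(self.tree_ids, self.L):
                fh.write("# " + tid + "\n")
                fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def read(cls, path) -> "SiteLogLikMatrix":
        with open(path) as fh:
            header = fh.readline().split()
            n_trees, n_sites = int(header[0]), int(header[1])
            ids, rows = [], []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    ids.append(line[1:].strip())
                else:
                    rows.append(np.fromstring(line, sep=" "))
        if len(rows) != n_trees:
            raise ValueError("row count does not match header")
        L = np.vstack(rows)
        if L.shape[1] != n_sites:
            raise ValueError("site count does not match header")
        if len(ids) != n_trees:
            ids = [f"tree{i}" for i in range(n_trees)]
        return cls(ids, L)
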
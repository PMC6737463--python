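"""Multiscale RELL bootstrap and the approximate-unbiased topology test.

RELL (resampling estimated log-likelihoods) redraws alignment sites with
replacement and credits, per replicate, the candidate tree with the highest
resampled log-likelihood — without re-optimising anything.  Running RELL at
several resampling scales r (replicate length r*n) and fitting

    z_k = Phi^{-1}(1 - BP_k)  ~  d*sqrt(r_k) + c/sqrt(r_k)

by weighted least squares yields the signed distance d and curvature c of
the boundary of the region where a tree is optimal; the AU p-value is
1 - Phi(d - c).  A tree with AU p below alpha is rejected as an explanation
of the data, which is how pairwise tree congruence is decided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .sitelik import SiteLogLikMatrix

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))
DEFAULT_B = 1000


def rell_proportions(
    L: SiteLogLikMatrix,
    scale: float = 1.0,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Bootstrap proportions of each tree being best, at one scale.

    Each of B replicates draws round(scale*n_sites) sites with replacement
    and sums per-tree log-likelihoods over the draw; argmax ties are split
    equally.  Proportions sum to 1 exactly.  With ``exhaustive=True`` all
    n_sites**n' equally likely ordered draws are enumerated instead of
    sampled (only viable for tiny inputs).
    """
    if L.n_trees < 2:
        raise ValueError("need at least 2 candidate trees")
    n_prime = int(round(scale * L.n_sites))
    if n_prime < 1:
        raise ValueError(f"scale {scale} gives empty replicates")
    if exhaustive:
        import itertools

        if L.n_sites**n_prime > 200_000:
            raise ValueError("exhaustive enumeration infeasible at this size")
        counts = np.zeros((L.n_sites**n_prime, L.n_sites), dtype=np.int64)
        for row, draw in enumerate(
            itertools.product(range(L.n_sites), repeat=n_prime)
        ):
            for s in draw:
                counts[row, s] += 1
        B = counts.shape[0]
    else:
        rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        pvals = np.full(L.n_sites, 1.0 / L.n_sites)
        counts = rng.multinomial(n_prime, pvals, size=B)  # B x n_sites
    # a -inf site score (zero-probability site) must lose every replicate it
    # is drawn into, but must not poison replicates that skip it (0 * -inf)
    Lmat = np.maximum(L.L, -1e15)
    totals = counts @ Lmat.T  # B x n_trees
    best = totals.max(axis=1, keepdims=True)
    winners = totals == best
    credit = winners / winners.sum(axis=1, keepdims=True)
    return credit.sum(axis=0) / B


@dataclass
class AUResult:
    """AU-test output for a candidate tree set."""

    tree_ids: list[str]
    bp: np.ndarray  # naive bootstrap proportion at scale 1
    au_p: np.ndarray
    d: np.ndarray
    c: np.ndarray
    degenerate: np.ndarray
    scales: tuple
    B: int
    seed: int
    bp_by_scale: np.ndarray = field(repr=False)  # scales x trees

    def as_dict(self, tree_id: str) -> dict:
        i = self.tree_ids.index(tree_id)
        return {
            "tree_id": tree_id,
            "bp": float(self.bp[i]),
            "au_p": float(self.au_p[i]),
            "d": float(self.d[i]),
            "c": float(self.c[i]),
            "degenerate": bool(self.degenerate[i]),
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tree_id\tbp_scale1\tau_p\td\tc\tdegenerate\n")
            for i, tid in enumerate(self.tree_ids):
                fh.write(
                    f"{tid}\t{self.bp[i]:.6g}\t{self.au_p[i]:.6g}\t"
                    f"{self.d[i]:.6g}\t{self.c[i]:.6g}\t{int(self.degenerate[i])}\n"
                )


def _fit_au(r: np.ndarray, bp: np.ndarray, B: int) -> tuple[float, float, float]:
    """WLS fit of z ~ d*sqrt(r) + c/sqrt(r); returns (p, d, c)."""
    lo, hi = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    bpc = np.clip(bp, lo, hi)
    z = norm.ppf(1.0 - bpc)
    # delta-method variance of z from the binomial variance of BP
    w = B * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    d, c = float(beta[0]), float(beta[1])
    return float(1.0 - norm.cdf(d - c)), d, c


def au_test(
    L: SiteLogLikMatrix,
    scales=DEFAULT_SCALES,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> AUResult:
    """Approximate-unbiased p-value per candidate tree.

    Needs at least two scales (the two-parameter fit is otherwise
    under-determined).  Trees whose bootstrap proportion is 0 or 1 at every
    scale get the corresponding boundary p-value and a degenerate-fit flag.
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) < 2:
        raise ValueError("AU fit needs at least 2 resampling scales")
    rng = np.random.default_rng(seed)
    n = L.n_sites
    bp_by_scale = np.zeros((len(scales), L.n_trees))
    r_actual = np.zeros(len(scales))
    for k, s in enumerate(scales):
        bp_by_scale[k] = rell_proportions(L, scale=s, B=B, seed=rng)
        r_actual[k] = round(s * n) / n
    au_p = np.zeros(L.n_trees)
    d = np.zeros(L.n_trees)
    c = np.zeros(L.n_trees)
    degenerate = np.zeros(L.n_trees, dtype=bool)
    scale1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    for i in range(L.n_trees):
        bps = bp_by_scale[:, i]
        if np.all((bps == 0.0) | (bps == 1.0)):
            degenerate[i] = True
            au_p[i] = 1.0 if bps[scale1] == 1.0 else 0.0
            d[i] = -np.inf if au_p[i] == 1.0 else np.inf
            c[i] = 0.0
        else:
            au_p[i], d[i], c[i] = _fit_au(r_actual, bps, B)
    return AUResult(
        tree_ids=list(L.tree_ids),
        bp=bp_by_scale[scale1].copy(),
        au_p=au_p,
        d=d,
        c=c,
        degenerate=degenerate,
        scales=scales,
        B=B,
        seed=seed if isinstance(seed, int) else -1,
        bp_by_scale=bp_by_scale,
    )


def congruence_verdict(
    lnl_by_dataset: dict[str, SiteLogLikMatrix],
    own_tree: dict[str, str],
    alpha: float = 0.05,
    scales=DEFAULT_SCALES,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> tuple[str, dict]:
    """Reciprocal AU verdict between two (or more) data sets.

    ``lnl_by_dataset`` maps each alignment to a site log-likelihood matrix
    scoring its own tree and every rival topology; ``own_tree`` names the
    tree native to each data set.  The verdict is ``incongruent`` if any
    rival topology is rejected (AU p < alpha) on any data set.
    """
    details: dict = {}
    incongruent = False
    rng = np.random.default_rng(seed)
    for ds, L in lnl_by_dataset.items():
        if ds not in own_tree:
            raise ValueError(f"no own tree declared for data set {ds!r}")
        own = own_tree[ds]
        if own not in L.tree_ids:
            raise ValueError(f"data set {ds!r} does not score its own tree {own!r}")
        rivals = [t for t in L.tree_ids if t != own]
        if not rivals:
            raise ValueError(f"data set {ds!r} scores no rival topology")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = au_test(L, scales=scales, B=B, seed=sub_seed)
        details[ds] = res
        for t in rivals:
            if res.au_p[res.tree_ids.index(t)] < alpha:
                incongruent = True
    return ("incongruent" if incongruent else "congruent"), details
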
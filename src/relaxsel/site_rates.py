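"""Per-site relative evolutionary rates under an HKY nucleotide model with a
discrete-gamma rate mixture.

The analogue of a baseml rates analysis: kappa, the gamma shape and a global
tree scale are fit by maximum likelihood, then each alignment column gets
its posterior-mean category rate, normalized to mean 1 over non-missing
columns. A rate well below 1 marks a conserved position (the deleterious-
site rule downstream uses rate < 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .alignment import CodonAlignment
from .genetics import NUC_INDEX
from .trees import TreeArrays, tree_to_arrays

KAPPA_BOUNDS = (1e-2, 100.0)
ALPHA_BOUNDS = (0.05, 50.0)
SCALE_BOUNDS = (1e-3, 100.0)


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability bins of a
    Gamma(alpha, alpha) distribution (unit mean)."""
    k = n_categories
    bounds = stats.gamma.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    # E[X | bin] via the regularized incomplete gamma at shape alpha+1
    cum = special.gammainc(alpha + 1.0, alpha * bounds)
    cum[-1] = 1.0
    return k * np.diff(cum)


def _hky_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    ts = np.zeros((4, 4), dtype=bool)  # order ACGT
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
        ts[i, j] = True
    q = np.tile(freqs, (4, 1)) * np.where(ts, kappa, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(freqs * np.diag(q)).sum()
    return q / rate


class _NucPropagator:
    def __init__(self, q: np.ndarray, freqs: np.ndarray) -> None:
        sqrt_pi = np.sqrt(freqs)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        val, vec = np.linalg.eigh((sym + sym.T) / 2.0)
        self.val = val
        self.left = vec / sqrt_pi[:, None]
        self.right = vec.T * sqrt_pi[None, :]

    def matrix(self, t: float) -> np.ndarray:
        return np.clip((self.left * np.exp(self.val * t)) @ self.right, 0.0, None)


@dataclass
class SiteRateProfile:
    """Per-position relative rates (NaN where the column is entirely
    missing), normalized to mean 1 over non-missing positions."""

    rates: np.ndarray
    kappa: float
    alpha: float
    tree_scale: float
    lnl: float
    n_categories: int

    def __post_init__(self) -> None:
        finite = self.rates[np.isfinite(self.rates)]
        if finite.size and abs(finite.mean() - 1.0) > 1e-6:
            raise ValueError("rates must average 1 over non-missing sites")


class _NucLikelihood:
    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree | TreeArrays):
        self.tree = tree if isinstance(tree, TreeArrays) else tree_to_arrays(tree)
        labels = set(self.tree.tip_labels)
        if labels != set(alignment.sequence_ids):
            raise ValueError("tree tips and alignment ids differ")
        n_sites = len(alignment)
        codes = np.full((self.tree.n_tips, n_sites), -1, dtype=np.int64)
        for t, label in enumerate(self.tree.tip_labels):
            seq = alignment.sequence(label)
            for s, ch in enumerate(seq):
                codes[t, s] = NUC_INDEX.get(ch, -1)
        counts = np.zeros((4,))
        for v in range(4):
            counts[v] = (codes == v).sum()
        self.freqs = (counts + 1.0) / (counts + 1.0).sum()
        patterns, inverse, weights = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T
        self.pattern_index = inverse
        self.weights = weights.astype(float)
        self.all_missing = (self.patterns < 0).all(axis=0)

    def category_likelihoods(
        self, kappa: float, alpha: float, scale: float, n_categories: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(n_categories, n_patterns) per-category site likelihoods (as
        log), plus the category rates."""
        rates = discrete_gamma_rates(alpha, n_categories)
        prop = _NucPropagator(_hky_matrix(kappa, self.freqs), self.freqs)
        tree = self.tree
        n_pat = self.patterns.shape[1]
        out = np.empty((n_categories, n_pat))
        for k, r in enumerate(rates):
            partials: list[np.ndarray | None] = [None] * tree.n_nodes
            log_scale = np.zeros(n_pat)
            for node in tree.postorder:
                if node < tree.n_tips:
                    continue
                partial = np.ones((n_pat, 4))
                for child in tree.children[node]:
                    p = prop.matrix(tree.length[child] * scale * r)
                    if child < tree.n_tips:
                        obs = self.patterns[child]
                        cont = p.T[obs]
                        cont[obs < 0] = 1.0
                    else:
                        cont = partials[child] @ p.T
                        partials[child] = None
                    partial *= cont
                sc = partial.max(axis=1)
                sc[sc == 0] = 1.0
                partial /= sc[:, None]
                log_scale += np.log(sc)
                partials[node] = partial
            out[k] = np.log(partials[tree.root] @ self.freqs) + log_scale
        return out, rates

    def log_likelihood(self, kappa, alpha, scale, n_categories) -> float:
        log_cat, _ = self.category_likelihoods(kappa, alpha, scale, n_categories)
        m = log_cat.max(axis=0)
        site_lnl = m + np.log(np.exp(log_cat - m).mean(axis=0))
        return float(self.weights @ site_lnl)


def site_rates(
    alignment: CodonAlignment,
    tree: dendropy.Tree | TreeArrays,
    n_categories: int = 4,
) -> SiteRateProfile:
    """Fit HKY+gamma by ML and return posterior-mean relative rates per
    alignment column; entirely-missing columns get NaN."""
    if alignment.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    engine = _NucLikelihood(alignment, tree)

    def neg_lnl(x: np.ndarray) -> float:
        kappa, alpha, scale = np.exp(x)
        return -engine.log_likelihood(kappa, alpha, scale, n_categories)

    res = optimize.minimize(
        neg_lnl,
        np.log([2.0, 1.0, 1.0]),
        method="L-BFGS-B",
        bounds=[np.log(KAPPA_BOUNDS), np.log(ALPHA_BOUNDS), np.log(SCALE_BOUNDS)],
        options={"maxiter": 300},
    )
    kappa, alpha, scale = np.exp(res.x)
    log_cat, rates = engine.category_likelihoods(kappa, alpha, scale, n_categories)
    m = log_cat.max(axis=0)
    post = np.exp(log_cat - m)  # proportional to category posteriors
    mean_rate = (rates[:, None] * post).sum(axis=0) / post.sum(axis=0)
    mean_rate[engine.all_missing] = np.nan
    per_site = mean_rate[engine.pattern_index]
    finite = np.isfinite(per_site)
    if finite.any():
        per_site = per_site / np.nanmean(per_site)
    return SiteRateProfile(
        rates=per_site,
        kappa=float(kappa),
        alpha=float(alpha),
        tree_scale=float(scale),
        lnl=-float(res.fun),
        n_categories=n_categories,
    )
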
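"""GY94-style codon substitution model: rate matrix, pruning likelihood,
one-ratio and two-ratio (foreground branch) maximum-likelihood fits, and the
branch likelihood-ratio test.

Model
-----
The instantaneous rate from sense codon *i* to *j* is nonzero only for
single-nucleotide exchanges and proportional to the target codon frequency
``pi_j``, multiplied by ``kappa`` for transitions and by ``omega`` (dN/dS)
for nonsynonymous exchanges. The matrix is scaled so one unit of branch
length equals one expected substitution per codon site at stationarity.

The two-ratio model gives a single flagged ("foreground") branch its own
omega, as in the codeml branch test contrasting a focal lineage against the
rest of the tree. Input branch lengths are kept proportional; only a global
``tree_scale`` multiplier is re-estimated during fitting, which keeps the
optimization low-dimensional (a documented departure from codeml's full
per-branch re-estimation).

Gap- or N-containing codons are treated as missing data (partial likelihood
of ones); stop codons in the data are an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats

from .alignment import CodonAlignment
from .genetics import (
    CODON_INDEX,
    IS_NONSYN_PAIR,
    IS_TRANSITION_PAIR,
    N_CODONS,
    SINGLE_STEP,
    STOP_CODONS,
)
from .trees import TreeArrays, tree_to_arrays

OMEGA_BOUNDS = (1e-4, 10.0)
KAPPA_BOUNDS = (1e-2, 100.0)
SCALE_BOUNDS = (1e-3, 100.0)
DEFAULT_OMEGA_STARTS = (0.1, 1.0, 2.0)
DNDS_CAP = 2.0


@dataclass
class CodonModelParams:
    """Parameters of the codon model.

    kappa
        Transition/transversion rate ratio, > 0.
    omega
        dN/dS ratio on (background) branches, > 0.
    codon_freqs
        Stationary frequencies over the 61 sense codons, summing to 1.
    tree_scale
        Global multiplier applied to input branch lengths.
    """

    kappa: float
    omega: float
    codon_freqs: np.ndarray
    tree_scale: float = 1.0

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_CODONS,):
            raise ValueError(f"codon_freqs must have shape ({N_CODONS},)")
        if np.any(self.codon_freqs < 0):
            raise ValueError("codon_freqs must be nonnegative")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1 (within 1e-9)")
        for name in ("kappa", "omega", "tree_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(alignment: CodonAlignment, floor: float = 1e-6) -> np.ndarray:
    """Empirical codon frequencies from position-specific nucleotide counts.

    The product of the three positional nucleotide frequency vectors is taken
    over sense codons and renormalized (stop-codon mass discarded), the
    standard F3x4 estimate. A small floor keeps unobserved codons at nonzero
    frequency so the likelihood stays finite.
    """
    from .genetics import NUC_INDEX, SENSE_CODONS

    counts = np.zeros((3, 4))
    for seq in alignment.sequences:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            for k in range(3):
                idx = NUC_INDEX.get(seq[i + k])
                if idx is not None:
                    counts[k, idx] += 1
    if counts.sum() == 0:
        return uniform_codon_freqs()
    pos_freqs = (counts + 1e-12) / (counts + 1e-12).sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freqs[0, NUC_INDEX[c[0]]]
            * pos_freqs[1, NUC_INDEX[c[1]]]
            * pos_freqs[2, NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


def build_rate_matrix(params: CodonModelParams) -> np.ndarray:
    """61x61 instantaneous rate matrix Q.

    Rows sum to zero; scaled so the expected substitution rate at
    stationarity is 1 per unit branch length. Detailed balance
    ``pi_i q_ij = pi_j q_ji`` holds because the exchangeabilities
    (kappa/omega factors) are symmetric.
    """
    return _rate_matrix(params.kappa, params.omega, params.codon_freqs)


def _rate_matrix(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    q = np.where(SINGLE_STEP, freqs[None, :], 0.0)
    q = q * np.where(IS_TRANSITION_PAIR, kappa, 1.0)
    q = q * np.where(IS_NONSYN_PAIR, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(freqs * np.diag(q)).sum()
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / rate


class _Propagator:
    """Eigendecomposition of a reversible Q for fast P(t) = expm(Q t).

    Q is similar to the symmetric matrix ``D^1/2 Q D^-1/2`` (D = diag(pi)),
    so one `eigh` serves every branch length.
    """

    def __init__(self, q: np.ndarray, freqs: np.ndarray) -> None:
        sqrt_pi = np.sqrt(freqs)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
        self.eigval = eigval
        self.left = eigvec / sqrt_pi[:, None]  # D^-1/2 U
        self.right = eigvec.T * sqrt_pi[None, :]  # U^T D^1/2

    def transition_matrix(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.eigval * t)) @ self.right
        return np.clip(p, 0.0, None)


def _encode_tips(alignment: CodonAlignment, tree_arrays: TreeArrays) -> np.ndarray:
    """Codon-state codes per (tip, site); -1 = missing (gap/N codon)."""
    labels = set(tree_arrays.tip_labels)
    seq_ids = set(alignment.sequence_ids)
    if labels != seq_ids:
        raise ValueError(
            f"tree tips and alignment ids differ: only in tree {sorted(labels - seq_ids)}, "
            f"only in alignment {sorted(seq_ids - labels)}"
        )
    n_codons = alignment.n_codons
    codes = np.full((tree_arrays.n_tips, n_codons), -1, dtype=np.int64)
    for t, label in enumerate(tree_arrays.tip_labels):
        seq = alignment.sequence(label)
        for s in range(n_codons):
            codon = seq[3 * s : 3 * s + 3]
            if codon in STOP_CODONS:
                raise ValueError(
                    f"stop codon {codon} in sequence {label!r} at codon site {s}"
                )
            codes[t, s] = CODON_INDEX.get(codon, -1)
    return codes


class CodonLikelihood:
    """Felsenstein pruning likelihood for a codon alignment on a fixed tree.

    Site patterns are compressed once at construction; evaluation then costs
    one (or two, with a foreground omega) eigendecomposition plus a matrix
    product per branch.
    """

    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree | TreeArrays):
        self.tree = tree if isinstance(tree, TreeArrays) else tree_to_arrays(tree)
        codes = _encode_tips(alignment, self.tree)
        patterns, inverse, weights = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_tips, n_patterns)
        self.pattern_index = inverse  # site -> pattern
        self.weights = weights.astype(float)
        self.n_sites = codes.shape[1]

    @property
    def n_foreground_edges(self) -> int:
        return int(self.tree.foreground.sum())

    def log_likelihood(
        self,
        params: CodonModelParams,
        omega_foreground: float | None = None,
        per_site: bool = False,
    ) -> float | tuple[float, np.ndarray]:
        """Log-likelihood; ``omega_foreground`` gives flagged branches their
        own dN/dS (the two-ratio model)."""
        freqs = params.codon_freqs
        prop_bg = _Propagator(_rate_matrix(params.kappa, params.omega, freqs), freqs)
        if omega_foreground is not None and omega_foreground != params.omega:
            if self.n_foreground_edges == 0:
                raise ValueError(
                    "omega_foreground given but the tree has no flagged branch"
                )
            prop_fg = _Propagator(
                _rate_matrix(params.kappa, omega_foreground, freqs), freqs
            )
        else:
            prop_fg = prop_bg

        tree = self.tree
        n_pat = self.patterns.shape[1]
        partials: list[np.ndarray | None] = [None] * tree.n_nodes
        log_scale = np.zeros(n_pat)
        for node in tree.postorder:
            if node < tree.n_tips:
                continue
            partial = np.ones((n_pat, N_CODONS))
            for child in tree.children[node]:
                prop = prop_fg if tree.foreground[child] else prop_bg
                p = prop.transition_matrix(tree.length[child] * params.tree_scale)
                if child < tree.n_tips:
                    codes = self.patterns[child]
                    cont = p.T[codes]  # cont[s, a] = P[a, codes[s]]
                    cont[codes < 0] = 1.0
                else:
                    cont = partials[child] @ p.T
                    partials[child] = None
                partial *= cont
            scale = partial.max(axis=1)
            scale[scale == 0] = 1.0
            partial /= scale[:, None]
            log_scale += np.log(scale)
            partials[node] = partial
        root = tree.root
        site_l = partials[root] @ freqs
        pattern_lnl = np.log(site_l) + log_scale
        total = float(self.weights @ pattern_lnl)
        if per_site:
            return total, pattern_lnl[self.pattern_index]
        return total


def log_likelihood(
    alignment: CodonAlignment,
    tree: dendropy.Tree | TreeArrays,
    params: CodonModelParams,
    omega_foreground: float | None = None,
) -> float:
    """Pruning log-likelihood of the alignment on the tree (convenience
    wrapper; build a :class:`CodonLikelihood` directly for repeated
    evaluation)."""
    return CodonLikelihood(alignment, tree).log_likelihood(params, omega_foreground)


@dataclass
class CodonFit:
    params: CodonModelParams
    omega_foreground: float | None
    lnl: float
    converged: bool
    grad_norm: float
    n_evals: int
    flags: list[str] = field(default_factory=list)
    n_taxa: int = 0
    n_codons: int = 0

    @property
    def omega_background(self) -> float:
        return self.params.omega


def _bound_flags(values: dict[str, tuple[float, tuple[float, float]]]) -> list[str]:
    flags = []
    for name, (value, (lo, hi)) in values.items():
        if value <= lo * 1.05:
            flags.append(f"{name}_at_lower_bound")
        elif value >= hi * 0.95:
            flags.append(f"{name}_at_upper_bound")
    return flags


def _maximize(fun, starts, bounds_log):
    best = None
    n_evals = 0
    for x0 in starts:
        res = optimize.minimize(
            fun,
            np.log(np.asarray(x0, dtype=float)),
            method="L-BFGS-B",
            bounds=bounds_log,
            options={"maxiter": 500},
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    return best, n_evals


def fit_one_ratio(
    alignment: CodonAlignment,
    tree: dendropy.Tree | TreeArrays,
    *,
    freqs: np.ndarray | None = None,
    omega_starts: tuple[float, ...] = DEFAULT_OMEGA_STARTS,
) -> CodonFit:
    """Maximize the likelihood over (kappa, omega, tree_scale), one omega for
    the whole tree; codon frequencies fixed at the F3x4 empirical estimate.

    Multi-start bounded quasi-Newton (L-BFGS-B in log-parameters) from
    dispersed omega starting points; non-convergence and at-bound parameters
    are flagged on the result, never silent.
    """
    if alignment.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    if freqs is None:
        freqs = f3x4_frequencies(alignment)
    engine = CodonLikelihood(alignment, tree)
    bounds_log = [np.log(KAPPA_BOUNDS), np.log(OMEGA_BOUNDS), np.log(SCALE_BOUNDS)]

    def neg_lnl(x: np.ndarray) -> float:
        kappa, omega, scale = np.exp(x)
        return -engine.log_likelihood(
            CodonModelParams(kappa, omega, freqs, tree_scale=scale)
        )

    starts = [(2.0, w, 1.0) for w in omega_starts]
    best, n_evals = _maximize(neg_lnl, starts, bounds_log)
    kappa, omega, scale = np.exp(best.x)
    flags = _bound_flags(
        {
            "kappa": (kappa, KAPPA_BOUNDS),
            "omega": (omega, OMEGA_BOUNDS),
            "tree_scale": (scale, SCALE_BOUNDS),
        }
    )
    if not best.success:
        flags.append("not_converged")
    return CodonFit(
        params=CodonModelParams(kappa, omega, freqs, tree_scale=scale),
        omega_foreground=None,
        lnl=-best.fun,
        converged=bool(best.success),
        grad_norm=float(np.linalg.norm(best.jac)),
        n_evals=n_evals,
        flags=flags,
        n_taxa=alignment.n_sequences,
        n_codons=alignment.n_codons,
    )


def fit_two_ratio(
    alignment: CodonAlignment,
    tree: dendropy.Tree | TreeArrays,
    *,
    freqs: np.ndarray | None = None,
    omega_starts: tuple[float, ...] = DEFAULT_OMEGA_STARTS,
    warm_start: CodonFit | None = None,
) -> CodonFit:
    """As :func:`fit_one_ratio` with omega split into background and
    foreground; the foreground is the single flagged branch. A one-ratio fit
    may be passed as ``warm_start`` to seed kappa/omega/scale."""
    if alignment.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    if freqs is None:
        freqs = warm_start.params.codon_freqs if warm_start else f3x4_frequencies(alignment)
    engine = CodonLikelihood(alignment, tree)
    if engine.n_foreground_edges != 1:
        raise ValueError(
            f"two-ratio model needs exactly one flagged branch, "
            f"found {engine.n_foreground_edges}"
        )
    bounds_log = [
        np.log(KAPPA_BOUNDS),
        np.log(OMEGA_BOUNDS),
        np.log(OMEGA_BOUNDS),
        np.log(SCALE_BOUNDS),
    ]

    def neg_lnl(x: np.ndarray) -> float:
        kappa, om_bg, om_fg, scale = np.exp(x)
        return -engine.log_likelihood(
            CodonModelParams(kappa, om_bg, freqs, tree_scale=scale),
            omega_foreground=om_fg,
        )

    if warm_start is not None:
        p = warm_start.params
        starts = [(p.kappa, p.omega, w, p.tree_scale) for w in omega_starts]
    else:
        starts = [(2.0, 0.5, w, 1.0) for w in omega_starts]
    best, n_evals = _maximize(neg_lnl, starts, bounds_log)
    kappa, om_bg, om_fg, scale = np.exp(best.x)
    flags = _bound_flags(
        {
            "kappa": (kappa, KAPPA_BOUNDS),
            "omega": (om_bg, OMEGA_BOUNDS),
            "omega_foreground": (om_fg, OMEGA_BOUNDS),
            "tree_scale": (scale, SCALE_BOUNDS),
        }
    )
    if not best.success:
        flags.append("not_converged")
    return CodonFit(
        params=CodonModelParams(kappa, om_bg, freqs, tree_scale=scale),
        omega_foreground=float(om_fg),
        lnl=-best.fun,
        converged=bool(best.success),
        grad_norm=float(np.linalg.norm(best.jac)),
        n_evals=n_evals,
        flags=flags,
        n_taxa=alignment.n_sequences,
        n_codons=alignment.n_codons,
    )


def cap_dnds(omega: float, cap: float = DNDS_CAP) -> float:
    """Threshold dN/dS at ``cap`` (reporting convention for dN/dS >> 1)."""
    return min(float(omega), cap)


@dataclass
class BranchTestResult:
    """One-ratio vs two-ratio branch contrast for one gene.

    ``delta_dnds`` is the tree-wide (one-ratio) dN/dS minus the foreground
    dN/dS, both capped at 2; a negative value means the focal branch evolves
    with the higher dN/dS (relaxed or positive selection on that lineage).
    """

    gene_id: str
    lnl_one_ratio: float
    lnl_two_ratio: float
    omega_tree: float
    omega_background: float
    omega_foreground: float
    delta_dnds: float
    lrt_stat: float
    p_value: float
    n_taxa: int
    n_codons: int
    converged: bool
    flags: list[str] = field(default_factory=list)


def branch_lrt(
    fit_one: CodonFit,
    fit_two: CodonFit,
    gene_id: str = "",
    cap: float = DNDS_CAP,
) -> BranchTestResult:
    """Likelihood-ratio test of the two-ratio against the one-ratio model.

    The statistic 2(lnL2 - lnL1) is clamped to zero (allowing ~1e-6
    numerical slack) and referred to chi-square with 1 df.
    """
    if fit_two.omega_foreground is None:
        raise ValueError("fit_two must be a two-ratio fit")
    raw = 2.0 * (fit_two.lnl - fit_one.lnl)
    if raw < -1e-4:
        raise ValueError(
            f"two-ratio lnL below one-ratio lnL by {-raw / 2:.6g}: "
            "optimizer failure (models are nested)"
        )
    lrt = max(0.0, raw)
    return BranchTestResult(
        gene_id=gene_id,
        lnl_one_ratio=fit_one.lnl,
        lnl_two_ratio=fit_two.lnl,
        omega_tree=fit_one.params.omega,
        omega_background=fit_two.params.omega,
        omega_foreground=fit_two.omega_foreground,
        delta_dnds=cap_dnds(fit_one.params.omega, cap)
        - cap_dnds(fit_two.omega_foreground, cap),
        lrt_stat=lrt,
        p_value=float(stats.chi2.sf(lrt, df=1)),
        n_taxa=fit_one.n_taxa,
        n_codons=fit_one.n_codons,
        converged=fit_one.converged and fit_two.converged,
        flags=sorted(set(fit_one.flags) | set(fit_two.flags)),
    )


def branch_test(
    alignment: CodonAlignment,
    tree: dendropy.Tree | TreeArrays,
    gene_id: str = "",
) -> BranchTestResult:
    """Convenience: one-ratio fit, warm-started two-ratio fit, then the LRT."""
    fit1 = fit_one_ratio(alignment, tree)
    fit2 = fit_two_ratio(alignment, tree, warm_start=fit1)
    return branch_lrt(fit1, fit2, gene_id=gene_id)
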
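"""Synthetic inputs with known ground truth.

Three generators emulate the statistical structure the downstream analyses
assume:

* codon alignments evolved on a tree under a GY94-style process with a
  branch-specific dN/dS on one designated foreground branch (exact
  stochastic simulation per branch, so true substitution counts per branch
  are available as counting oracles);
* per-gene SNP panels in which nonsynonymous counts scale linearly with
  total counts plus Gaussian noise, with planted intolerance outliers — the
  regression structure behind RVIS/DRVIS;
* gene→GO-term universes with one planted over-represented term and a small
  acyclic parent graph.

Every generator is a pure function of (config, seed): same inputs, same
bytes out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .alignment import CodonAlignment, write_fasta_alignment
from .codon_model import _rate_matrix
from .genetics import (
    IS_NONSYN_PAIR,
    IS_TRANSITION_PAIR,
    N_CODONS,
    SENSE_CODONS,
)
from .trees import TreeArrays, random_tree, set_foreground, tree_to_arrays, write_newick

__all__ = [
    "SimulationConfig",
    "SnpPanelConfig",
    "SimulatedAlignment",
    "GoUniverse",
    "random_tree",
    "simulate_codon_alignment",
    "simulate_gene_family",
    "simulate_snp_panel",
    "simulate_go_universe",
]


@dataclass
class SimulationConfig:
    """Conditions for one simulated codon alignment.

    Branch lengths are expected substitutions per codon site under the
    parameterized model (the rate matrix is normalized to unit mean rate at
    stationarity). Codon frequencies default to uniform 1/61.
    """

    seed: int
    n_taxa: int = 8
    n_codons: int = 500
    kappa: float = 2.0
    omega_background: float = 0.2
    omega_foreground: float = 0.2
    codon_freqs: np.ndarray | None = None
    branch_length_mean: float = 0.1

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0 or self.branch_length_mean <= 0:
            raise ValueError("kappa and branch_length_mean must be positive")
        if self.omega_background < 0 or self.omega_foreground < 0:
            raise ValueError("omega values must be nonnegative")
        if self.codon_freqs is None:
            self.codon_freqs = np.full(N_CODONS, 1.0 / N_CODONS)
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_CODONS,):
            raise ValueError(f"codon_freqs must have shape ({N_CODONS},)")
        if np.any(self.codon_freqs <= 0):
            raise ValueError("codon_freqs must be positive")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1 within 1e-9")


class _GillespieKernel:
    """Exact stochastic simulation of the codon process along one branch."""

    def __init__(self, kappa: float, omega: float, freqs: np.ndarray) -> None:
        if omega > 0:
            q = _rate_matrix(kappa, omega, freqs)
        else:
            # omega=0 removes all nonsynonymous flow; normalize by the
            # synonymous-only mean rate
            q = np.where(
                IS_NONSYN_PAIR, 0.0, _rate_matrix(kappa, max(omega, 1.0), freqs)
            )
            np.fill_diagonal(q, 0.0)
            rate = (freqs[:, None] * q).sum()
            if rate > 0:
                q /= rate
        rates = q.copy()
        np.fill_diagonal(rates, 0.0)
        self.exit_rate = rates.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = rates / self.exit_rate[:, None]
        probs[self.exit_rate == 0] = 0.0
        self.cum_probs = np.cumsum(probs, axis=1)

    def evolve(
        self, states: np.ndarray, t: float, rng: np.random.Generator
    ) -> tuple[np.ndarray, dict[str, int]]:
        out = states.copy()
        counts = {"n_events": 0, "n_transitions": 0, "n_transversions": 0,
                  "n_synonymous": 0, "n_nonsynonymous": 0}
        for s in range(out.size):
            c = out[s]
            elapsed = 0.0
            while True:
                rate = self.exit_rate[c]
                if rate <= 0:
                    break
                elapsed += rng.exponential(1.0 / rate)
                if elapsed >= t:
                    break
                nxt = int(np.searchsorted(self.cum_probs[c], rng.random()))
                counts["n_events"] += 1
                if IS_TRANSITION_PAIR[c, nxt]:
                    counts["n_transitions"] += 1
                else:
                    counts["n_transversions"] += 1
                if IS_NONSYN_PAIR[c, nxt]:
                    counts["n_nonsynonymous"] += 1
                else:
                    counts["n_synonymous"] += 1
                c = nxt
            out[s] = c
        return out, counts


@dataclass
class SimulatedAlignment:
    alignment: CodonAlignment
    tree: dendropy.Tree
    branch_counts: pd.DataFrame  # one row per edge with true event counts
    config: SimulationConfig


def simulate_codon_alignment(
    tree: dendropy.Tree | TreeArrays,
    config: SimulationConfig,
    reference_id: str | None = None,
) -> SimulatedAlignment:
    """Evolve one in-frame codon alignment along ``tree``.

    Root codons are drawn from the stationary frequencies; each branch is
    simulated event-by-event (Gillespie) under the background rate matrix,
    or the foreground matrix on the flagged branch. True per-branch counts
    of transitions/transversions and synonymous/nonsynonymous events are
    returned alongside the tip sequences. No stop codon can appear since the
    state space is the 61 sense codons.
    """
    arrays = tree if isinstance(tree, TreeArrays) else tree_to_arrays(tree)
    if arrays.n_tips < 3:
        raise ValueError("tree must have at least 3 tips")
    if (
        config.omega_foreground != config.omega_background
        and arrays.foreground.sum() != 1
    ):
        raise ValueError(
            "omega_foreground differs from omega_background but the tree does "
            "not have exactly one flagged branch"
        )
    rng = np.random.default_rng(config.seed)
    kernel_bg = _GillespieKernel(config.kappa, config.omega_background, config.codon_freqs)
    kernel_fg = (
        _GillespieKernel(config.kappa, config.omega_foreground, config.codon_freqs)
        if config.omega_foreground != config.omega_background
        else kernel_bg
    )
    root = arrays.root
    states: dict[int, np.ndarray] = {
        root: rng.choice(N_CODONS, size=config.n_codons, p=config.codon_freqs)
    }
    rows = []
    for node in arrays.postorder[::-1]:  # preorder
        if node == root:
            continue
        kernel = kernel_fg if arrays.foreground[node] else kernel_bg
        child_states, counts = kernel.evolve(
            states[arrays.parent[node]], arrays.length[node], rng
        )
        states[node] = child_states
        label = arrays.tip_labels[node] if node < arrays.n_tips else f"node{node}"
        rows.append(
            {
                "node": label,
                "is_tip": node < arrays.n_tips,
                "branch_length": arrays.length[node],
                "foreground": bool(arrays.foreground[node]),
                **counts,
            }
        )
    codon_strings = np.asarray(SENSE_CODONS)
    alignment = CodonAlignment(
        sequence_ids=list(arrays.tip_labels),
        sequences=[
            "".join(codon_strings[states[i]]) for i in range(arrays.n_tips)
        ],
        reference_id=reference_id,
    )
    if not isinstance(tree, dendropy.Tree):
        tree = None  # arrays were passed directly; no dendropy object to return
    return SimulatedAlignment(
        alignment=alignment,
        tree=tree,
        branch_counts=pd.DataFrame(rows),
        config=config,
    )


def simulate_gene_family(
    config: SimulationConfig, foreground_tip: str = "t1"
) -> SimulatedAlignment:
    """Random tree (foreground flag on ``foreground_tip``) plus one simulated
    alignment; tree topology and sequences both derive from ``config.seed``."""
    tree = random_tree(config.n_taxa, config.branch_length_mean, seed=config.seed)
    set_foreground(tree, foreground_tip)
    sim = simulate_codon_alignment(tree, config, reference_id=foreground_tip)
    sim.tree = tree
    return sim


@dataclass
class SnpPanelConfig:
    """Conditions for a per-gene SNP panel with the RVIS regression structure.

    ``slope`` is the expected number of (common) nonsynonymous SNPs per total
    SNP; planted outliers get ``outlier_shift`` extra nonsynonymous SNPs
    (clipped so the count never exceeds the gene's total). Deleterious sites
    are a binomial thinning of the nonsynonymous sites.
    """

    seed: int
    n_genes: int = 2000
    total_mean: float = 50.0
    slope: float = 0.3
    noise_sd: float = 2.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    deleterious_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.total_mean <= 0:
            raise ValueError("total_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if not 0.0 <= self.deleterious_fraction <= 1.0:
            raise ValueError("deleterious_fraction must be in [0, 1]")
        if not 0.0 <= self.slope <= 1.0:
            raise ValueError("slope must be in [0, 1]")


def simulate_snp_panel(config: SnpPanelConfig) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene SNP count table plus the planted-outlier gene list.

    Totals are Poisson; nonsynonymous counts are ``round(slope * total +
    Normal(0, noise_sd))`` plus ``outlier_shift`` for planted outliers,
    clipped to ``[0, total]``.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    total = rng.poisson(config.total_mean, size=config.n_genes).astype(np.int64)
    noise = (
        rng.normal(0.0, config.noise_sd, size=config.n_genes)
        if config.noise_sd > 0
        else np.zeros(config.n_genes)
    )
    raw = np.rint(config.slope * total + noise)
    n_outliers = int(round(config.outlier_fraction * config.n_genes))
    outlier_idx = (
        rng.choice(config.n_genes, size=n_outliers, replace=False)
        if n_outliers
        else np.array([], dtype=np.int64)
    )
    raw[outlier_idx] += round(config.outlier_shift)
    nonsyn = np.clip(raw, 0, total).astype(np.int64)
    deleterious = rng.binomial(nonsyn, config.deleterious_fraction)
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "n_total_snps": total,
            "n_nonsyn_common": nonsyn,
            "n_deleterious": deleterious,
        }
    )
    outliers = sorted(gene_ids[i] for i in outlier_idx)
    return table, outliers


def _calibrate_enrichment_odds(
    n_genes: int, n_study: int, term_size: int, factor: float
) -> float:
    """Odds for Fisher's noncentral hypergeometric giving a mean study
    overlap of ``factor`` times the null expectation (capped at the
    feasible range); the mean is monotone in the odds, so bisection on the
    log-odds converges."""
    if factor == 1.0:
        return 1.0
    null_mean = term_size * n_study / n_genes
    k_max = min(term_size, n_study)
    k_min = max(0, term_size - (n_genes - n_study))
    target = min(max(factor * null_mean, k_min + 1e-9), k_max - 1e-9)

    def mean_at(log_odds: float) -> float:
        return float(
            stats.nchypergeom_fisher.mean(n_genes, n_study, term_size, np.exp(log_odds))
        )

    lo, hi = -25.0, 25.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return float(np.exp((lo + hi) / 2.0))


@dataclass
class GoUniverse:
    gene_terms: pd.DataFrame  # columns: gene_id, term_id
    term_parents: pd.DataFrame  # columns: term_id, parent_id
    planted_term: str | None
    study_set: list[str]
    universe: list[str] = field(default_factory=list)


def simulate_go_universe(
    n_genes: int,
    n_terms: int,
    planted_term_size: int,
    study_set: list[str],
    enrichment_factor: float,
    seed: int,
    mean_term_size: float = 10.0,
) -> GoUniverse:
    """Gene→term assignments with one planted over-represented term.

    Background term sizes are Poisson(``mean_term_size``) and their genes
    sampled uniformly. ``enrichment_factor`` is the fold over-representation
    of the planted term in ``study_set``: the term's study overlap is drawn
    from Fisher's noncentral hypergeometric with odds calibrated so its mean
    is ``enrichment_factor`` times the null expectation (capped at the
    feasible maximum). At factor 1 the odds are 1 and the overlap is exactly
    hypergeometric. Parent links form a small random DAG (each term may
    point to an earlier term), acyclic by construction.
    """
    if planted_term_size > n_genes:
        raise ValueError("planted_term_size cannot exceed n_genes")
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    rng = np.random.default_rng(seed)
    universe = [f"gene{i + 1:05d}" for i in range(n_genes)]
    missing = set(study_set) - set(universe)
    if missing:
        raise ValueError(f"study genes outside the universe: {sorted(missing)}")
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    rows: list[tuple[str, str]] = []

    planted_term: str | None = None
    if planted_term_size > 0 and n_terms > 0:
        planted_term = term_ids[0]
        n_study = len(study_set)
        k_max = min(planted_term_size, n_study)
        k_min = max(0, planted_term_size - (n_genes - n_study))
        if k_max > k_min:
            odds = _calibrate_enrichment_odds(
                n_genes, n_study, planted_term_size, enrichment_factor
            )
            overlap = int(
                stats.nchypergeom_fisher.rvs(
                    n_genes, n_study, planted_term_size, odds, random_state=rng
                )
            )
        else:
            overlap = k_max
        inside = rng.choice(n_study, size=overlap, replace=False)
        others = [g for g in universe if g not in set(study_set)]
        outside = rng.choice(len(others), size=planted_term_size - overlap, replace=False)
        members = sorted(study_set[i] for i in inside) + sorted(others[i] for i in outside)
        rows.extend((g, planted_term) for g in members)

    background = term_ids[1:] if planted_term else term_ids
    for term in background:
        size = min(max(int(rng.poisson(mean_term_size)), 0), n_genes)
        if size == 0:
            continue
        genes = rng.choice(n_genes, size=size, replace=False)
        rows.extend((universe[g], term) for g in sorted(genes))

    parent_rows = []
    for i, term in enumerate(term_ids[1:], start=1):
        if rng.random() < 0.5:
            parent_rows.append((term, term_ids[int(rng.integers(0, i))]))
    return GoUniverse(
        gene_terms=pd.DataFrame(rows, columns=["gene_id", "term_id"]),
        term_parents=pd.DataFrame(parent_rows, columns=["term_id", "parent_id"]),
        planted_term=planted_term,
        study_set=list(study_set),
        universe=universe,
    )


def write_simulation(sim: SimulatedAlignment, outdir: str | Path, stem: str = "gene") -> None:
    """Write FASTA + Newick + TSV counts + JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta_alignment(sim.alignment, outdir / f"{stem}.fasta")
    if sim.tree is not None:
        (outdir / f"{stem}.nwk").write_text(write_newick(sim.tree))
    sim.branch_counts.to_csv(outdir / f"{stem}.branch_counts.tsv", sep="\t", index=False)
    truth = {
        "seed": sim.config.seed,
        "n_taxa": sim.config.n_taxa,
        "n_codons": sim.config.n_codons,
        "kappa": sim.config.kappa,
        "omega_background": sim.config.omega_background,
        "omega_foreground": sim.config.omega_foreground,
        "branch_length_mean": sim.config.branch_length_mean,
    }
    (outdir / f"{stem}.truth.json").write_text(json.dumps(truth, indent=2) + "\n")
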
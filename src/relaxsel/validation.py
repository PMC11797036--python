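"""Self-validation drivers: oracle cross-checks and statistical calibration.

Each function runs one of the package's quality checks end to end on
synthetic data and returns the measured quantity:

* exact-oracle comparisons — the pruning likelihood against exhaustive
  enumeration over internal-node states, and the Fisher enrichment p-value
  against a binomial-coefficient enumeration of the hypergeometric tail;
* statistical calibration — dN/dS recovery from simulated alignments, the
  null rejection rate of the branch LRT, its power under a relaxed
  foreground, planted-outlier recovery by the intolerance score, and
  planted-term recovery by the enrichment test.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.linalg import expm

from .alignment import CodonAlignment
from .codon_model import (
    CodonModelParams,
    branch_lrt,
    build_rate_matrix,
    fit_one_ratio,
    fit_two_ratio,
    log_likelihood,
)
from .enrichment import fisher_enrichment
from .genetics import CODON_INDEX, N_CODONS
from .popgen import intolerance_scores
from .synthetic_data import (
    SimulationConfig,
    SnpPanelConfig,
    simulate_gene_family,
    simulate_go_universe,
    simulate_snp_panel,
)
from .trees import random_tree, tree_to_arrays


def derive_seed(base: int, stream: int, index: int = 0) -> int:
    """Independent child seed for (stream, index), stable in ``base``."""
    ss = np.random.SeedSequence(entropy=base, spawn_key=(stream, index))
    return int(ss.generate_state(1)[0] % (2**31))


def _enumeration_log_likelihood(alignment, tree, params) -> float:
    """Exhaustive sum over internal-node codon assignments (oracle;
    independent of the pruning implementation)."""
    arrays = tree_to_arrays(tree)
    q = build_rate_matrix(params)
    p_mats = {
        i: expm(q * arrays.length[i] * params.tree_scale)
        for i in range(arrays.n_nodes)
    }
    internals = [i for i in range(arrays.n_nodes) if i >= arrays.n_tips]
    tip_codes = {
        i: [
            CODON_INDEX[alignment.sequence(lab)[3 * s : 3 * s + 3]]
            for s in range(alignment.n_codons)
        ]
        for i, lab in enumerate(arrays.tip_labels)
    }
    lnl = 0.0
    for site in range(alignment.n_codons):
        total = 0.0
        for assign in itertools.product(range(N_CODONS), repeat=len(internals)):
            states = dict(zip(internals, assign))
            for tip, codes in tip_codes.items():
                states[tip] = codes[site]
            pr = params.codon_freqs[states[arrays.root]]
            for node in range(arrays.n_nodes):
                if node != arrays.root:
                    pr *= p_mats[node][states[arrays.parent[node]], states[node]]
            total += pr
        lnl += np.log(total)
    return lnl


def pruning_enumeration_error(seed: int, n_instances: int = 3) -> float:
    """Max |pruning - enumeration| log-likelihood over random 4-taxon
    instances of 3-5 codons."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n_codons = int(rng.integers(3, 6))
        sim = simulate_gene_family(
            SimulationConfig(
                seed=derive_seed(seed, 1, i), n_taxa=4, n_codons=n_codons,
                kappa=2.0, omega_background=0.5, omega_foreground=0.5,
                branch_length_mean=0.2,
            )
        )
        params = CodonModelParams(
            kappa=float(rng.uniform(1, 4)),
            omega=float(rng.uniform(0.1, 2)),
            codon_freqs=np.full(N_CODONS, 1.0 / N_CODONS),
            tree_scale=float(rng.uniform(0.5, 2)),
        )
        fast = log_likelihood(sim.alignment, sim.tree, params)
        slow = _enumeration_log_likelihood(sim.alignment, sim.tree, params)
        worst = max(worst, abs(fast - slow))
    return worst


def omega_recovery_rate(
    seed: int,
    n_reps: int = 50,
    n_taxa: int = 8,
    n_codons: int = 1000,
    kappa: float = 2.0,
    omega: float = 0.2,
    tolerance: float = 0.05,
) -> float:
    """Fraction of replicates whose one-ratio dN/dS estimate lands within
    ``tolerance`` of the simulated value."""
    hits = 0
    for i in range(n_reps):
        sim = simulate_gene_family(
            SimulationConfig(
                seed=derive_seed(seed, 2, i), n_taxa=n_taxa, n_codons=n_codons,
                kappa=kappa, omega_background=omega, omega_foreground=omega,
            )
        )
        fit = fit_one_ratio(sim.alignment, sim.tree)
        hits += abs(fit.params.omega - omega) <= tolerance
    return hits / n_reps


def lrt_null_rejection_rate(
    seed: int,
    n_reps: int = 200,
    n_taxa: int = 8,
    n_codons: int = 500,
    omega: float = 0.2,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of the branch LRT when foreground and
    background dN/dS are equal (should sit near the nominal level)."""
    rejections = 0
    for i in range(n_reps):
        sim = simulate_gene_family(
            SimulationConfig(
                seed=derive_seed(seed, 3, i), n_taxa=n_taxa, n_codons=n_codons,
                omega_background=omega, omega_foreground=omega,
            )
        )
        fit1 = fit_one_ratio(sim.alignment, sim.tree)
        fit2 = fit_two_ratio(sim.alignment, sim.tree, warm_start=fit1)
        rejections += branch_lrt(fit1, fit2).p_value < alpha
    return rejections / n_reps


def branch_power_rate(
    seed: int,
    n_reps: int = 50,
    n_taxa: int = 8,
    n_codons: int = 2000,
    omega_background: float = 0.2,
    omega_foreground: float = 1.5,
    alpha: float = 0.05,
) -> float:
    """Fraction of relaxed-foreground replicates with negative delta dN/dS
    and LRT p below ``alpha``."""
    hits = 0
    for i in range(n_reps):
        sim = simulate_gene_family(
            SimulationConfig(
                seed=derive_seed(seed, 4, i), n_taxa=n_taxa, n_codons=n_codons,
                omega_background=omega_background,
                omega_foreground=omega_foreground,
            )
        )
        fit1 = fit_one_ratio(sim.alignment, sim.tree)
        fit2 = fit_two_ratio(sim.alignment, sim.tree, warm_start=fit1)
        res = branch_lrt(fit1, fit2)
        hits += (res.delta_dnds < 0) and (res.p_value < alpha)
    return hits / n_reps


def rvis_planted_recovery_rate(
    seed: int,
    n_genes: int = 1000,
    outlier_fraction: float = 0.05,
    outlier_shift: float = 25.0,
    noise_sd: float = 2.0,
) -> float:
    """Fraction of planted intolerance outliers captured by the top-5%
    flag of the studentized-residual score."""
    table, outliers = simulate_snp_panel(
        SnpPanelConfig(
            seed=seed, n_genes=n_genes, noise_sd=noise_sd,
            outlier_fraction=outlier_fraction, outlier_shift=outlier_shift,
        )
    )
    scores = intolerance_scores(
        table["gene_id"], table["n_total_snps"], table["n_nonsyn_common"]
    )
    top = set(scores.loc[scores["top5"], "gene_id"])
    return len(set(outliers) & top) / len(outliers)


def rvis_zero_noise_max_residual(seed: int, n_genes: int = 500) -> float:
    """Largest |studentized residual| on an exactly collinear (zero-noise,
    unit-slope) panel; should be exactly 0."""
    table, _ = simulate_snp_panel(
        SnpPanelConfig(seed=seed, n_genes=n_genes, noise_sd=0.0, slope=1.0)
    )
    scores = intolerance_scores(
        table["gene_id"], table["n_total_snps"], table["n_nonsyn_common"]
    )
    return float(scores["residual"].abs().max())


def fisher_enumeration_error(seed: int, n_instances: int = 30) -> float:
    """Max |implementation - enumeration| over random enrichment instances
    with universes of at most 25 genes."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_universe = int(rng.integers(5, 26))
        universe = {f"g{i}" for i in range(n_universe)}
        n_study = int(rng.integers(1, n_universe + 1))
        study = set(rng.choice(sorted(universe), n_study, replace=False))
        n_term = int(rng.integers(2, n_universe + 1))
        term = set(rng.choice(sorted(universe), n_term, replace=False))
        out = fisher_enrichment(study, universe, {"T": term})
        k = len(term & study)
        total = comb(n_universe, n_study)
        oracle = sum(
            comb(n_term, i) * comb(n_universe - n_term, n_study - i)
            for i in range(k, min(n_term, n_study) + 1)
        ) / total
        worst = max(worst, abs(float(out.iloc[0].p_value) - oracle))
    return worst


def planted_term_recovery_rate(
    seed: int,
    n_runs: int = 100,
    n_genes: int = 500,
    n_terms: int = 30,
    planted_term_size: int = 20,
    study_size: int = 50,
    enrichment_factor: float = 5.0,
) -> float:
    """Fraction of synthetic GO universes in which the planted term attains
    the minimal enrichment p-value."""
    study = [f"gene{i + 1:05d}" for i in range(study_size)]
    hits = 0
    for i in range(n_runs):
        go = simulate_go_universe(
            n_genes, n_terms, planted_term_size, study, enrichment_factor,
            seed=derive_seed(seed, 5, i),
        )
        term_genes = {
            t: set(sub["gene_id"]) for t, sub in go.gene_terms.groupby("term_id")
        }
        out = fisher_enrichment(set(study), set(go.universe), term_genes)
        hits += bool(len(out)) and out.iloc[0].term_id == go.planted_term
    return hits / n_runs
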
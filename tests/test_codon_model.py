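import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from relaxsel.alignment import CodonAlignment
from relaxsel.codon_model import (
    CodonFit,
    CodonLikelihood,
    CodonModelParams,
    branch_lrt,
    branch_test,
    build_rate_matrix,
    cap_dnds,
    f3x4_frequencies,
    fit_one_ratio,
    fit_two_ratio,
    log_likelihood,
    uniform_codon_freqs,
)
from relaxsel.genetics import CODON_INDEX, N_CODONS, SINGLE_STEP
from relaxsel.synthetic_data import SimulationConfig, simulate_gene_family
from relaxsel.trees import parse_newick, tree_to_arrays


class TestRateMatrix:
    def test_rows_sum_to_zero_for_random_params(self, rng):
        for _ in range(5):
            freqs = rng.dirichlet(np.ones(N_CODONS))
            q = build_rate_matrix(
                CodonModelParams(
                    kappa=float(rng.uniform(0.5, 5)),
                    omega=float(rng.uniform(0.05, 3)),
                    codon_freqs=freqs,
                )
            )
            assert np.abs(q.sum(axis=1)).max() < 1e-10

    def test_equal_input_limit_single_rate(self):
        # kappa=1, omega=1, uniform frequencies: every allowed exchange
        # shares one rate and Q is symmetric
        q = build_rate_matrix(
            CodonModelParams(kappa=1.0, omega=1.0, codon_freqs=uniform_codon_freqs())
        )
        off = q[SINGLE_STEP]
        assert np.allclose(off, off[0])
        assert np.allclose(q, q.T)

    def test_detailed_balance(self, rng):
        freqs = rng.dirichlet(np.ones(N_CODONS))
        params = CodonModelParams(kappa=3.0, omega=0.4, codon_freqs=freqs)
        q = build_rate_matrix(params)
        flow = freqs[:, None] * q
        assert np.abs(flow - flow.T).max() < 1e-15

    def test_unit_mean_rate_at_stationarity(self, rng):
        freqs = rng.dirichlet(np.ones(N_CODONS))
        q = build_rate_matrix(CodonModelParams(kappa=2.5, omega=0.3, codon_freqs=freqs))
        assert abs(-(freqs * np.diag(q)).sum() - 1.0) < 1e-12


def _brute_force_lnl(alignment, tree, params):
    """Exhaustive sum over all internal-node codon assignments."""
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


class TestLogLikelihood:
    def test_matches_exhaustive_enumeration(
        self, four_taxon_tree, four_taxon_alignment
    ):
        params = CodonModelParams(
            kappa=2.0, omega=0.5, codon_freqs=f3x4_frequencies(four_taxon_alignment)
        )
        pruned = log_likelihood(four_taxon_alignment, four_taxon_tree, params)
        brute = _brute_force_lnl(four_taxon_alignment, four_taxon_tree, params)
        assert abs(pruned - brute) < 1e-8

    def test_zero_branch_star_tree_gives_stationary_probability(self):
        tree = parse_newick("(A:0.0,B:0.0,C:0.0);")
        aln = CodonAlignment(["A", "B", "C"], ["ATGAAA"] * 3)
        freqs = uniform_codon_freqs()
        params = CodonModelParams(kappa=2.0, omega=0.5, codon_freqs=freqs)
        expected = sum(
            np.log(freqs[CODON_INDEX[c]]) for c in ("ATG", "AAA")
        )
        assert log_likelihood(aln, tree, params) == pytest.approx(expected, abs=1e-10)

    def test_duplicating_zero_length_tip_leaves_lnl_unchanged(self):
        # replace tip A with the zero-length cherry (A:0, B:0) carrying two
        # copies of A's sequence: B's state is forced equal to the junction
        # state with probability 1, so the likelihood cannot change
        seqs = {"A": "ATGGCT", "C": "ATAGCT", "D": "ATGGAT"}
        aln = CodonAlignment(list(seqs), list(seqs.values()))
        params = CodonModelParams(kappa=2.0, omega=0.5, codon_freqs=uniform_codon_freqs())
        base = log_likelihood(aln, parse_newick("(A:0.1,C:0.3,D:0.2);"), params)
        dup_tree = parse_newick("((A:0.0,B:0.0):0.1,C:0.3,D:0.2);")
        dup_aln = CodonAlignment(
            ["A", "B", "C", "D"], [seqs["A"], seqs["A"], seqs["C"], seqs["D"]]
        )
        assert log_likelihood(dup_aln, dup_tree, params) == pytest.approx(
            base, abs=1e-9
        )

    def test_invariant_to_tip_reordering(self, four_taxon_tree, four_taxon_alignment):
        params = CodonModelParams(
            kappa=1.7, omega=0.8, codon_freqs=uniform_codon_freqs()
        )
        base = log_likelihood(four_taxon_alignment, four_taxon_tree, params)
        ids = four_taxon_alignment.sequence_ids[::-1]
        shuffled = CodonAlignment(
            ids, [four_taxon_alignment.sequence(i) for i in ids]
        )
        assert log_likelihood(shuffled, four_taxon_tree, params) == pytest.approx(
            base, abs=1e-10
        )

    def test_invariant_to_rerooting_along_unflagged_path(self, four_taxon_alignment):
        # reversible model: likelihood does not depend on root placement
        params = CodonModelParams(kappa=2.0, omega=0.5, codon_freqs=uniform_codon_freqs())
        a = log_likelihood(
            four_taxon_alignment, parse_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.12);"),
            params,
        )
        b = log_likelihood(
            four_taxon_alignment, parse_newick("((C:0.3,D:0.12):0.05,A:0.1,B:0.2);"),
            params,
        )
        assert a == pytest.approx(b, abs=1e-9)

    def test_gap_codons_marginalized(self, four_taxon_tree):
        aln = CodonAlignment(["A", "B", "C", "D"], ["ATG---", "ATGGCC", "ATAGCT", "ATGGAT"])
        params = CodonModelParams(kappa=2.0, omega=0.5, codon_freqs=uniform_codon_freqs())
        lnl = log_likelihood(aln, four_taxon_tree, params)
        assert np.isfinite(lnl)

    def test_stop_codon_in_data_errors_with_site(self, four_taxon_tree):
        aln = CodonAlignment(["A", "B", "C", "D"], ["TAAGCC"] * 4)
        params = CodonModelParams(kappa=2.0, omega=0.5, codon_freqs=uniform_codon_freqs())
        with pytest.raises(ValueError, match="codon site 0"):
            log_likelihood(aln, four_taxon_tree, params)

    def test_label_mismatch_errors(self, four_taxon_tree):
        aln = CodonAlignment(["A", "B", "C", "X"], ["ATG"] * 4)
        params = CodonModelParams(kappa=2.0, omega=0.5, codon_freqs=uniform_codon_freqs())
        with pytest.raises(ValueError, match="differ"):
            log_likelihood(aln, four_taxon_tree, params)


@pytest.fixture(scope="module")
def simulated():
    return simulate_gene_family(
        SimulationConfig(
            seed=42, n_taxa=8, n_codons=400, kappa=2.0,
            omega_background=0.2, omega_foreground=0.2,
        )
    )


class TestFits:
    def test_one_ratio_recovers_simulated_omega(self, simulated):
        fit = fit_one_ratio(simulated.alignment, simulated.tree)
        assert fit.converged
        assert fit.params.omega == pytest.approx(0.2, abs=0.07)

    def test_optimum_at_least_truth_likelihood(self, simulated):
        fit = fit_one_ratio(simulated.alignment, simulated.tree)
        truth = CodonModelParams(
            kappa=2.0, omega=0.2, codon_freqs=fit.params.codon_freqs
        )
        lnl_truth = log_likelihood(simulated.alignment, simulated.tree, truth)
        assert fit.lnl >= lnl_truth - 1e-6

    def test_identical_sequences_flagged_unidentifiable(self):
        tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        aln = CodonAlignment(["A", "B", "C"], ["ATGGCTAAACCT"] * 3)
        fit = fit_one_ratio(aln, tree)
        assert "tree_scale_at_lower_bound" in fit.flags

    def test_two_ratio_constrained_matches_one_ratio(self, simulated):
        fit1 = fit_one_ratio(simulated.alignment, simulated.tree)
        engine = CodonLikelihood(simulated.alignment, simulated.tree)
        constrained = engine.log_likelihood(
            fit1.params, omega_foreground=fit1.params.omega
        )
        assert constrained == pytest.approx(fit1.lnl, abs=1e-6)

    def test_two_ratio_lnl_dominates_one_ratio(self, simulated):
        fit1 = fit_one_ratio(simulated.alignment, simulated.tree)
        fit2 = fit_two_ratio(simulated.alignment, simulated.tree, warm_start=fit1)
        assert fit2.lnl >= fit1.lnl - 1e-6

    def test_two_ratio_requires_single_flagged_branch(self, simulated):
        tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        aln = CodonAlignment(["A", "B", "C"], ["ATGGCTAAACCT"] * 3)
        with pytest.raises(ValueError, match="exactly one flagged branch"):
            fit_two_ratio(aln, tree)

    def test_relaxed_foreground_detected(self):
        sim = simulate_gene_family(
            SimulationConfig(
                seed=7, n_taxa=8, n_codons=800, omega_background=0.2,
                omega_foreground=1.5,
            )
        )
        res = branch_test(sim.alignment, sim.tree)
        assert res.omega_foreground > res.omega_background
        assert res.delta_dnds < 0


class TestBranchLrt:
    def _fit(self, lnl, omega, omega_fg=None):
        return CodonFit(
            params=CodonModelParams(
                kappa=2.0, omega=omega, codon_freqs=uniform_codon_freqs()
            ),
            omega_foreground=omega_fg, lnl=lnl, converged=True,
            grad_norm=0.0, n_evals=0, n_taxa=4, n_codons=100,
        )

    def test_equal_likelihoods_give_zero_statistic(self):
        res = branch_lrt(self._fit(-100.0, 0.3), self._fit(-100.0, 0.3, 0.3))
        assert res.lrt_stat == 0.0
        assert res.p_value == 1.0

    def test_chi2_quantile(self):
        res = branch_lrt(
            self._fit(-100.0, 0.3), self._fit(-100.0 + 3.841459 / 2, 0.3, 0.5)
        )
        assert res.p_value == pytest.approx(0.05, abs=1e-6)
        assert res.p_value == pytest.approx(chi2.sf(3.841459, 1), abs=1e-12)

    def test_cap_applied_to_delta(self):
        res = branch_lrt(self._fit(-100.0, 0.3), self._fit(-99.0, 0.25, 3.5))
        assert res.delta_dnds == pytest.approx(0.3 - 2.0)
        assert cap_dnds(3.5) == 2.0
        assert cap_dnds(1.2) == 1.2

    def test_negative_statistic_beyond_slack_errors(self):
        with pytest.raises(ValueError, match="nested"):
            branch_lrt(self._fit(-100.0, 0.3), self._fit(-101.0, 0.3, 0.5))
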
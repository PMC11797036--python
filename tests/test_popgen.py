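import numpy as np
import pandas as pd
import pytest
from scipy import stats

from relaxsel.popgen import (
    GeneModel,
    VariantRecord,
    classify_deleterious,
    classify_effect,
    filter_variants,
    intolerance_scores,
    mk_alpha,
    summarize_gene_variants,
)


def _variant(ref="A", alts=("G",), gts=None, n=10, n_minor=3, n_missing=0):
    """Biallelic site with the requested minor-allele and missing counts."""
    if gts is None:
        alleles = [1] * n_minor + [0] * (2 * (n - n_missing) - n_minor)
        gts = [[alleles[2 * i], alleles[2 * i + 1]] for i in range(n - n_missing)]
        gts += [[-1, -1]] * n_missing
    return VariantRecord(
        chrom="chr1", pos=100, ref_allele=ref, alt_alleles=alts,
        genotypes=np.asarray(gts, dtype=np.int64),
    )


class TestVariantFilters:
    def test_triallelic_removed(self):
        kept, removed = filter_variants([_variant(alts=("G", "T"))])
        assert kept == [] and removed["not_biallelic"] == 1

    def test_indel_removed(self):
        kept, removed = filter_variants([_variant(ref="AT")])
        assert kept == [] and removed["not_snp"] == 1

    def test_exact_20_percent_missingness_removed(self):
        # 10 samples with 2 missing genotypes sits exactly at the strict bound
        v = _variant(n=10, n_missing=2)
        kept, removed = filter_variants([v])
        assert v.missingness == pytest.approx(0.2)
        assert kept == [] and removed["missingness"] == 1
        v_ok = _variant(n=10, n_missing=1)
        kept, _ = filter_variants([v_ok])
        assert kept == [v_ok]

    def test_mac_two_removed_three_kept(self):
        kept, removed = filter_variants([_variant(n_minor=2)])
        assert kept == [] and removed["mac"] == 1
        v3 = _variant(n_minor=3)
        kept, _ = filter_variants([v3])
        assert kept == [v3]

    def test_order_independent_and_idempotent(self):
        variants = [_variant(n_minor=k) for k in (1, 3, 5, 2)]
        kept_fwd, _ = filter_variants(variants)
        kept_rev, _ = filter_variants(variants[::-1])
        assert {id(v) for v in kept_fwd} == {id(v) for v in kept_rev}
        again, removed = filter_variants(kept_fwd)
        assert again == kept_fwd and sum(removed.values()) == 0

    def test_maf_over_observed_alleles_only(self):
        v = _variant(n=10, n_minor=3, n_missing=2)
        assert v.maf == pytest.approx(3 / 16)
        assert v.mac == 3


class TestClassifyEffect:
    # chrom: 1-based; gene CDS at 11..19 encodes AAA AAA AAA on '+'
    chrom_seq = "G" * 10 + "AAAAAAAAA" + "G" * 10

    def _gene(self, strand="+"):
        return GeneModel(
            gene_id="g", chrom="chr1", strand=strand, cds_segments=((11, 19),)
        )

    def _v(self, pos, ref, alt):
        return VariantRecord(
            chrom="chr1", pos=pos, ref_allele=ref, alt_alleles=(alt,),
            genotypes=np.asarray([[0, 1]] * 4),
        )

    def test_third_position_synonymous(self):
        # AAA -> AAG is Lys -> Lys
        assert classify_effect(self._v(13, "A", "G"), self._gene(), self.chrom_seq) == "synonymous"

    def test_first_position_nonsynonymous(self):
        # AAA -> GAA is Lys -> Glu
        assert classify_effect(self._v(11, "A", "G"), self._gene(), self.chrom_seq) == "nonsynonymous"

    def test_intronic_is_non_coding(self):
        assert classify_effect(self._v(5, "G", "A"), self._gene(), self.chrom_seq) == "non-coding"

    def test_minus_strand_uses_reverse_complement(self):
        # '-' strand CDS reads TTT TTT TTT (Phe); genomic A>G at the last
        # CDS base is mRNA position 1: TTT -> CTT (Phe -> Leu)
        effect = classify_effect(self._v(19, "A", "G"), self._gene("-"), self.chrom_seq)
        assert effect == "nonsynonymous"

    def test_partial_codon_non_assessable(self):
        gene = GeneModel(gene_id="g", chrom="chr1", strand="+", cds_segments=((11, 17),))
        assert classify_effect(self._v(17, "A", "G"), gene, self.chrom_seq) == "non-assessable"

    def test_reference_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_effect(self._v(11, "C", "G"), self._gene(), self.chrom_seq)


class TestClassifyDeleterious:
    @pytest.mark.parametrize(
        "rate,sift,maf,expected",
        [
            (0.4, 0.05, 0.10, True),   # SIFT boundary is inclusive
            (0.5, 0.01, 0.10, False),  # rate boundary is strict
            (0.4, 0.01, 0.20, False),  # MAF boundary is strict
            (0.49, 0.051, 0.10, False),
            (0.1, 0.0, 0.0, True),
        ],
    )
    def test_rule_boundaries(self, rate, sift, maf, expected):
        assert classify_deleterious(rate, sift, maf) is expected

    def test_missing_annotation_non_assessable(self):
        assert classify_deleterious(None, 0.01, 0.1) is None
        assert classify_deleterious(0.4, float("nan"), 0.1) is None


class TestIntoleranceScores:
    def test_exact_collinear_gives_zero_residuals(self):
        x = np.arange(10, 60, dtype=float)
        y = 3.0 + 0.4 * x
        out = intolerance_scores([f"g{i}" for i in range(50)], x, y)
        np.testing.assert_array_equal(out.residual.to_numpy(), 0.0)

    def test_permutation_invariance(self, rng):
        x = rng.poisson(50, 100).astype(float)
        y = 0.3 * x + rng.normal(0, 2, 100)
        ids = [f"g{i}" for i in range(100)]
        base = intolerance_scores(ids, x, y).set_index("gene_id")
        perm = rng.permutation(100)
        shuffled = intolerance_scores(
            [ids[i] for i in perm], x[perm], y[perm]
        ).set_index("gene_id")
        for g in ids:
            assert shuffled.loc[g, "residual"] == pytest.approx(
                base.loc[g, "residual"], abs=1e-10
            )

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            intolerance_scores(["a", "b", "c"], [5, 5, 5], [1, 2, 3])

    def test_external_studentization_follows_t_distribution(self):
        # Gaussian noise: leave-one-out studentized residuals are t with
        # n - 3 degrees of freedom; KS must not reject at 0.01
        rng = np.random.default_rng(2024)
        n = 5000
        x = rng.poisson(50, n).astype(float)
        y = 0.3 * x + rng.normal(0, 2, n)
        out = intolerance_scores([f"g{i}" for i in range(n)], x, y)
        stat, p = stats.kstest(out.residual, stats.t(df=n - 3).cdf)
        assert p > 0.01

    def test_top_flag_size_and_ties(self):
        scores = intolerance_scores(
            [f"g{i}" for i in range(40)],
            np.arange(40, dtype=float) + 10,
            np.arange(40, dtype=float) * 0.3 + np.r_[np.zeros(39), 10.0],
        )
        assert scores.top5.sum() >= int(np.ceil(0.05 * 40))
        assert scores.loc[scores.residual.idxmax(), "top5"]


class TestMKAlpha:
    def test_neutral_expectation_zero(self):
        assert mk_alpha(10, 10, 5, 5).alpha == pytest.approx(0.0)

    def test_printed_formula_arithmetic(self):
        assert mk_alpha(5, 10, 10, 10).alpha == pytest.approx(0.5)

    def test_ps_zero_flagged_undefined(self):
        res = mk_alpha(5, 0, 10, 10)
        assert not res.defined and res.alpha is None and res.reason == "pS=0"

    def test_zero_divergence_ratio_flagged(self):
        assert not mk_alpha(5, 10, 0, 10).defined
        assert not mk_alpha(5, 10, 10, 0).defined

    def test_alpha_negative_when_polymorphism_ratio_exceeds_divergence(self):
        res = mk_alpha(20, 10, 5, 10)
        assert res.alpha < 0

    def test_alpha_never_exceeds_one(self, rng):
        for _ in range(50):
            pn, ps, dn, ds = rng.integers(0, 30, 4)
            res = mk_alpha(float(pn), float(ps), float(dn), float(ds))
            if res.defined:
                assert res.alpha <= 1.0


class TestSummarizeGeneVariants:
    def test_counts_and_maf_thresholds(self):
        sites = pd.DataFrame(
            {
                "gene_id": ["g1"] * 5 + ["g2"] * 2,
                "maf": [0.005, 0.05, 0.15, 0.3, 0.02, 0.12, 0.4],
                "effect": [
                    "nonsynonymous", "nonsynonymous", "nonsynonymous",
                    "synonymous", "non-coding", "nonsynonymous", "synonymous",
                ],
                "rate": [0.4, 0.4, 0.6, 0.1, 0.1, 0.3, 0.2],
                "sift": [0.05, 0.2, 0.01, 0.01, 0.01, 0.02, 0.9],
            }
        )
        out = summarize_gene_variants(sites).set_index("gene_id")
        g1 = out.loc["g1"]
        assert g1.n_total_snps == 5
        # maf>=0.01 nonsynonymous: 0.05 and 0.15
        assert g1.n_nonsyn_common == 2
        # deleterious: rate<0.5 & sift<=0.05 & maf<0.2 -> only the first site
        assert g1.n_deleterious == 1
        # MK counts at maf>=0.10
        assert g1.pN == 1 and g1.pS == 1
        g2 = out.loc["g2"]
        assert g2.pN == 1 and g2.pS == 1 and g2.n_deleterious == 1

    def test_deleterious_never_exceeds_nonsynonymous(self):
        rng = np.random.default_rng(5)
        sites = pd.DataFrame(
            {
                "gene_id": rng.choice(["a", "b", "c"], 200),
                "maf": rng.uniform(0, 0.5, 200),
                "effect": rng.choice(
                    ["synonymous", "nonsynonymous", "non-coding"], 200
                ),
                "rate": rng.uniform(0, 2, 200),
                "sift": rng.uniform(0, 1, 200),
            }
        )
        out = summarize_gene_variants(sites)
        nonsyn_total = (
            sites[sites.effect == "nonsynonymous"].groupby("gene_id").size()
        )
        for row in out.itertuples():
            assert row.n_deleterious <= nonsyn_total.get(row.gene_id, 0)
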
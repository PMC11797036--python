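"""Intraspecific selection signatures from a clone panel.

Variant filtering (biallelic SNPs, missingness < 20%, minor-allele count
>= 3), synonymous/nonsynonymous classification against gene models, the
deleterious-site rule (per-site evolutionary rate < 0.5, SIFT-type score
<= 0.05, MAF < 20%), residual variation intolerance scores (RVIS on common
nonsynonymous counts, DRVIS on deleterious counts; externally studentized
residuals of an OLS of outcome counts on total SNP counts), and the
McDonald-Kreitman alpha combining within-species polymorphism with
between-species divergence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from .genetics import NUCLEOTIDES, translate_codon

MAX_MISSING = 0.20
MIN_MAC = 3
MAF_COMMON = 0.01
MAF_MK = 0.10
RATE_CUT = 0.5
SIFT_CUT = 0.05
MAF_DELETERIOUS = 0.20
TOP_FRACTION = 0.05


@dataclass
class VariantRecord:
    """One VCF site with diploid genotype calls (allele index, -1 missing)."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: np.ndarray  # (n_samples, 2) of allele indices, -1 = missing

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValueError("genotypes must have shape (n_samples, 2)")
        if isinstance(self.alt_alleles, str):
            raise TypeError("alt_alleles must be a sequence of alleles, not a string")
        self.alt_alleles = tuple(self.alt_alleles)

    @property
    def is_snp(self) -> bool:
        ok = set(NUCLEOTIDES)
        return len(self.ref_allele) == 1 and self.ref_allele in ok and all(
            len(a) == 1 and a in ok for a in self.alt_alleles
        )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def missingness(self) -> float:
        missing = (self.genotypes < 0).any(axis=1)
        return float(missing.mean()) if len(missing) else 1.0

    def _allele_counts(self) -> np.ndarray:
        observed = self.genotypes[self.genotypes >= 0]
        n_alleles = 1 + len(self.alt_alleles)
        return np.bincount(observed, minlength=n_alleles)

    @property
    def mac(self) -> int:
        """Minor-allele count over observed (non-missing) allele copies."""
        counts = self._allele_counts()
        if counts.sum() == 0 or (counts > 0).sum() < 2:
            return 0
        return int(np.sort(counts)[-2])

    @property
    def maf(self) -> float:
        counts = self._allele_counts()
        total = counts.sum()
        return float(self.mac / total) if total else 0.0


def filter_variants(
    records: Iterable[VariantRecord],
    max_missing: float = MAX_MISSING,
    min_mac: int = MIN_MAC,
) -> tuple[list[VariantRecord], Counter]:
    """Keep biallelic SNPs with missingness strictly below ``max_missing``
    and minor-allele count of at least ``min_mac``.

    Returns the surviving records and a tally of removals by first failing
    rule. Order-independent and idempotent.
    """
    kept: list[VariantRecord] = []
    removed: Counter = Counter()
    for rec in records:
        if not rec.is_snp:
            removed["not_snp"] += 1
        elif not rec.is_biallelic:
            removed["not_biallelic"] += 1
        elif not rec.missingness < max_missing:
            removed["missingness"] += 1
        elif rec.mac < min_mac:
            removed["mac"] += 1
        else:
            kept.append(rec)
    return kept, removed


@dataclass(frozen=True)
class GeneModel:
    """Minimal strand-aware gene model: CDS segments in genomic coordinates
    (1-based closed, ascending) on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    span: tuple[int, int] | None = None  # gene body; defaults to CDS extent

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for start, end in self.cds_segments:
            if start > end:
                raise ValueError(f"segment {start}-{end} has start > end")

    @property
    def gene_span(self) -> tuple[int, int]:
        if self.span is not None:
            return self.span
        return (
            min(s for s, _ in self.cds_segments),
            max(e for _, e in self.cds_segments),
        )

    def cds_position(self, pos: int) -> int | None:
        """0-based position within the spliced CDS (mRNA 5'->3'), or None
        if ``pos`` is not in any CDS segment."""
        offset = 0
        for start, end in sorted(self.cds_segments):
            if start <= pos <= end:
                plus_index = offset + (pos - start)
                total = sum(e - s + 1 for s, e in self.cds_segments)
                return plus_index if self.strand == "+" else total - 1 - plus_index
            offset += end - start + 1
        return None

    def cds_sequence(self, chrom_seq: str) -> str:
        parts = [chrom_seq[s - 1 : e] for s, e in sorted(self.cds_segments)]
        seq = "".join(parts)
        return seq if self.strand == "+" else _revcomp(seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_effect(
    variant: VariantRecord, gene: GeneModel, chrom_seq: str
) -> str:
    """'synonymous' | 'nonsynonymous' | 'non-coding' | 'non-assessable'.

    The alternate allele is substituted into its codon in the spliced,
    strand-oriented CDS and translated with the standard code; a stop
    gain/loss counts as nonsynonymous. A variant in a trailing partial
    codon (splice-truncated model) is non-assessable.
    """
    if variant.chrom != gene.chrom:
        return "non-coding"
    cds_pos = gene.cds_position(variant.pos)
    if cds_pos is None:
        return "non-coding"
    cds = gene.cds_sequence(chrom_seq)
    codon_start = 3 * (cds_pos // 3)
    codon = cds[codon_start : codon_start + 3]
    if len(codon) < 3 or any(ch not in NUCLEOTIDES for ch in codon):
        return "non-assessable"
    ref = variant.ref_allele
    alt = variant.alt_alleles[0]
    if gene.strand == "-":
        ref, alt = _revcomp(ref), _revcomp(alt)
    within = cds_pos - codon_start
    if codon[within] != ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos} "
            f"(CDS has {codon[within]}, VCF says {ref})"
        )
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    return (
        "synonymous"
        if translate_codon(codon) == translate_codon(alt_codon)
        else "nonsynonymous"
    )


def classify_deleterious(
    rate: float | None,
    sift: float | None,
    maf: float | None,
    rate_cut: float = RATE_CUT,
    sift_cut: float = SIFT_CUT,
    maf_cut: float = MAF_DELETERIOUS,
) -> bool | None:
    """Deleterious-site rule for a nonsynonymous site: evolutionary rate
    strictly below 0.5, SIFT-type score at most 0.05 (inclusive), and MAF
    strictly below 20%. Returns None (non-assessable) when any annotation
    is missing."""
    values = (rate, sift, maf)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
        return None
    return rate < rate_cut and sift <= sift_cut and maf < maf_cut


def summarize_gene_variants(
    sites: pd.DataFrame,
    maf_common: float = MAF_COMMON,
    maf_mk: float = MAF_MK,
    rate_cut: float = RATE_CUT,
    sift_cut: float = SIFT_CUT,
    maf_del: float = MAF_DELETERIOUS,
) -> pd.DataFrame:
    """Per-gene variant summary from a per-site table.

    ``sites`` needs columns gene_id, maf, effect ('synonymous' /
    'nonsynonymous' / other), and optionally rate and sift for the
    deleterious rule. Output columns: n_total_snps, n_nonsyn_common
    (MAF >= ``maf_common``), n_deleterious, pN and pS (site counts at
    MAF >= ``maf_mk``).
    """
    df = sites.copy()
    nonsyn = df["effect"] == "nonsynonymous"
    syn = df["effect"] == "synonymous"
    df["_common_nonsyn"] = nonsyn & (df["maf"] >= maf_common)
    if {"rate", "sift"} <= set(df.columns):
        deleterious = [
            bool(classify_deleterious(r, s, m, rate_cut, sift_cut, maf_del))
            for r, s, m in zip(df["rate"], df["sift"], df["maf"])
        ]
        df["_deleterious"] = nonsyn & np.asarray(deleterious, dtype=bool)
    else:
        df["_deleterious"] = False
    df["_pn"] = nonsyn & (df["maf"] >= maf_mk)
    df["_ps"] = syn & (df["maf"] >= maf_mk)
    out = (
        df.groupby("gene_id")
        .agg(
            n_total_snps=("gene_id", "size"),
            n_nonsyn_common=("_common_nonsyn", "sum"),
            n_deleterious=("_deleterious", "sum"),
            pN=("_pn", "sum"),
            pS=("_ps", "sum"),
        )
        .reset_index()
    )
    return out


def intolerance_scores(
    gene_ids: Iterable[str],
    total_snps: Iterable[float],
    outcome_counts: Iterable[float],
    top_fraction: float = TOP_FRACTION,
) -> pd.DataFrame:
    """Studentized-residual intolerance scores (RVIS/DRVIS).

    OLS of the outcome count (common nonsynonymous SNPs for RVIS,
    deleterious SNPs for DRVIS) on the total SNP count, with intercept;
    the score is each gene's externally (leave-one-out) studentized
    residual. Positive scores mark genes with an excess of functional
    variation (tolerant), strongly negative scores intolerant genes.

    Returns a frame with residual, percentile (0-100) and top/bottom
    5% flags (``ceil(fraction * n)`` genes, boundary ties included).
    """
    gene_ids = list(gene_ids)
    x = np.asarray(list(total_snps), dtype=float)
    y = np.asarray(list(outcome_counts), dtype=float)
    if len(gene_ids) < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all total-SNP counts identical")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if model.ssr <= 1e-9 * max(1.0, float(np.square(y).sum())):
        # perfect fit: all residuals exactly zero
        residuals = np.zeros_like(y)
    else:
        residuals = np.asarray(OLSInfluence(model).resid_studentized_external)
    percentile = 100.0 * stats.rankdata(residuals, method="average") / len(residuals)
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "residual": residuals,
            "percentile": percentile,
        }
    )
    scores = dict(zip(gene_ids, residuals))
    top = _extreme_set(scores, top_fraction, "high")
    bottom = _extreme_set(scores, top_fraction, "low")
    out["top5"] = out["gene_id"].isin(top)
    out["bottom5"] = out["gene_id"].isin(bottom)
    return out


def _extreme_set(scores: dict[str, float], fraction: float, direction: str) -> set[str]:
    from .enrichment import top_fraction as _top

    return _top(scores, fraction=fraction, direction=direction)


@dataclass
class MKResult:
    """McDonald-Kreitman alpha for one gene: ``1 - (pN/pS) / (dN/dS)``.

    pN and pS are within-species polymorphism counts (sites at the MK MAF
    cutoff); dN/dS is the between-species rate ratio. Undefined (flagged,
    alpha None) when pS = 0 or the divergence ratio is 0 or undefined.
    """

    gene_id: str
    pn: float
    ps: float
    dn: float
    ds: float
    alpha: float | None = field(init=False)
    reason: str | None = field(init=False)

    def __post_init__(self) -> None:
        if min(self.pn, self.ps, self.dn, self.ds) < 0:
            raise ValueError("MK inputs must be nonnegative")
        if self.ps == 0:
            self.alpha, self.reason = None, "pS=0"
        elif self.ds == 0:
            self.alpha, self.reason = None, "dS=0"
        elif self.dn == 0:
            self.alpha, self.reason = None, "dN/dS=0"
        else:
            self.alpha = 1.0 - (self.pn / self.ps) / (self.dn / self.ds)
            self.reason = None

    @property
    def defined(self) -> bool:
        return self.alpha is not None


def mk_alpha(pn: float, ps: float, dn: float, ds: float, gene_id: str = "") -> MKResult:
    """Convenience constructor for :class:`MKResult`."""
    return MKResult(gene_id=gene_id, pn=pn, ps=ps, dn=dn, ds=ds)
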
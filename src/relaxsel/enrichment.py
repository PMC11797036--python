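"""Gene-set statistics downstream of the selection scores.

GO annotations are propagated up the term parent graph so a gene annotated
at a leaf term counts for every ancestor; enrichment of a study set against
a universe is a one-sided Fisher exact (hypergeometric upper-tail) test per
term, with terms annotating fewer than two universe genes removed;
significance uses a Bonferroni-corrected threshold. Orthogroup
consolidation records the least extreme value across gene copies (smallest
|delta dN/dS|, largest p), and the duplication-confound filter keeps a
significant gene only when its orthogroup is single-copy in the focal
species or all copies are significant. Distribution contrasts (e.g. pollen
vs non-pollen genes) use a Pearson chi-square over pooled-decile bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_TERM_GENES = 2
DEFAULT_ALPHA = 0.05


def propagate_annotations(
    gene_terms: dict[str, set[str]], parents: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Add every ancestor of each directly assigned term to each gene.

    ``parents`` maps a term to its direct parent terms (a DAG); a cycle is
    an error naming the terms involved.
    """
    ancestors: dict[str, set[str]] = {}

    def _ancestors(term: str, stack: tuple[str, ...]) -> set[str]:
        if term in stack:
            cycle = stack[stack.index(term):] + (term,)
            raise ValueError(f"cycle in term parent graph: {' -> '.join(cycle)}")
        if term not in ancestors:
            acc: set[str] = set()
            for p in parents.get(term, ()):
                acc.add(p)
                acc |= _ancestors(p, stack + (term,))
            ancestors[term] = acc
        return ancestors[term]

    out: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        full = set(terms)
        for t in terms:
            full |= _ancestors(t, ())
        out[gene] = full
    return out


@dataclass
class EnrichmentRow:
    """One GO term's enrichment line: Annotated / Significant / Expected /
    Fisher p, the layout of a topGO-style result table."""

    term_id: str
    annotated: int
    significant: int
    expected: float
    p_value: float


def fisher_enrichment(
    study: set[str],
    universe: set[str],
    term_genes: dict[str, set[str]],
    min_term_genes: int = MIN_TERM_GENES,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``study`` within ``universe``.

    For each term annotating at least ``min_term_genes`` universe genes
    (the "present in more than 1 gene" filter), the upper-tail
    hypergeometric probability of drawing at least the observed overlap.
    Rows sorted by p ascending, ties by term id.
    """
    offenders = study - universe
    if offenders:
        raise ValueError(f"study genes outside universe: {sorted(offenders)}")
    n_universe = len(universe)
    n_study = len(study)
    rows = []
    for term in sorted(term_genes):
        annotated_genes = term_genes[term] & universe
        annotated = len(annotated_genes)
        if annotated < min_term_genes:
            continue
        significant = len(annotated_genes & study)
        expected = annotated * n_study / n_universe
        p = float(stats.hypergeom.sf(significant - 1, n_universe, annotated, n_study))
        rows.append(
            {
                "term_id": term,
                "annotated": annotated,
                "significant": significant,
                "expected": expected,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "annotated", "significant", "expected", "p_value"]
    )
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
        drop=True
    )


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, n_tests: int = 1) -> float:
    """Family-wise significance threshold alpha / n_tests (e.g. 0.05 over
    5,828 term tests gives 8.58e-6)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


def top_fraction(
    scores: dict[str, float], fraction: float = 0.05, direction: str = "high"
) -> set[str]:
    """The ``ceil(fraction * n)`` genes at the chosen extreme, including all
    genes tied with the boundary value (so the set may exceed the ceiling)."""
    if not scores:
        raise ValueError("empty score table")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    k = math.ceil(fraction * len(scores))
    ordered = sorted(scores.items(), key=lambda kv: kv[1], reverse=(direction == "high"))
    boundary = ordered[k - 1][1]
    if direction == "high":
        return {g for g, v in scores.items() if v >= boundary}
    return {g for g, v in scores.items() if v <= boundary}


@dataclass
class OrthogroupSummary:
    """Least-extreme consolidation of one orthogroup's branch-test metrics.

    The consolidated delta dN/dS is the member value of smallest magnitude
    and the consolidated p the largest (least significant); the two may come
    from different member genes.
    """

    orthogroup_id: str
    gene_ids: list[str]
    delta_dnds: float
    p_value: float


def consolidate_orthogroup(
    orthogroup_id: str, members: dict[str, tuple[float, float]]
) -> OrthogroupSummary:
    """``members`` maps gene_id -> (delta_dnds, p_value)."""
    if not members:
        raise ValueError("orthogroup has no members")
    deltas = {g: d for g, (d, _) in members.items()}
    pvals = {g: p for g, (_, p) in members.items()}
    least_delta = min(deltas.values(), key=abs)
    return OrthogroupSummary(
        orthogroup_id=orthogroup_id,
        gene_ids=sorted(members),
        delta_dnds=least_delta,
        p_value=max(pvals.values()),
    )


def duplication_confound_filter(
    orthogroups: dict[str, list[str]], significant: dict[str, bool]
) -> set[str]:
    """Keep a significant focal-species gene iff its orthogroup has exactly
    one focal-species member, or every member is significant.

    ``orthogroups`` maps orthogroup id -> focal-species member gene ids;
    ``significant`` must cover every member.
    """
    kept: set[str] = set()
    for members in orthogroups.values():
        missing = [g for g in members if g not in significant]
        if missing:
            raise KeyError(f"significance flags missing for {missing}")
        if len(members) == 1:
            if significant[members[0]]:
                kept.add(members[0])
        elif members and all(significant[g] for g in members):
            kept.update(members)
    return kept


def chi2_distribution_test(
    values_a: np.ndarray, values_b: np.ndarray, n_bins: int = 10
) -> tuple[float, int, float]:
    """Pearson chi-square contrast of two empirical distributions.

    Bin edges are deciles (``n_bins`` quantiles) of the pooled sample;
    adjacent bins are merged until every expected count is at least 5; the
    statistic is computed on the resulting 2 x k table with k - 1 degrees
    of freedom. Returns (statistic, df, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0], edges[-1] = -np.inf, np.inf
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    table = np.vstack([counts_a, counts_b]).astype(float)

    # merge adjacent bins until all expected counts reach 5
    def expected(t: np.ndarray) -> np.ndarray:
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    while table.shape[1] > 2:
        exp = expected(table)
        if exp.min() >= 5:
            break
        j = int(np.argmin(exp.min(axis=0)))
        merge_with = j - 1 if j == table.shape[1] - 1 else j + 1
        lo, hi = sorted((j, merge_with))
        table[:, lo] += table[:, hi]
        table = np.delete(table, hi, axis=1)
    exp = expected(table)
    if table.shape[1] < 2 or exp.min() <= 0:
        raise ValueError("fewer than 2 usable bins after merging")
    statistic = float(((table - exp) ** 2 / exp).sum())
    df = table.shape[1] - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))
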
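"""Alignment conditioning and transcript selection.

The rules applied before any model fitting: choosing the best homolog per
target genome (coverage >= 90% of the reference transcript, then highest
alignment score), stripping columns gapped in the reference so the
reference frame defines codon coordinates, extracting and concatenating
4-fold-degenerate third positions for neutral-tree estimation, dropping
genes aligned in too few genomes, and collapsing each gene's transcripts to
a single representative (UTR evidence, cross-species homology, lowest
dN/dS, then longest CDS).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np

from .alignment import CodonAlignment
from .genetics import FOURFOLD_PREFIXES

MIN_ALIGNED_FRACTION = 0.90
MIN_TAXA = 4


@dataclass(frozen=True)
class HomologCandidate:
    """One candidate alignment of the reference transcript into a target
    genome."""

    genome_id: str
    candidate_id: str
    aligned_fraction: float
    alignment_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must be in [0, 1]")


def select_best_homolog(
    candidates: list[HomologCandidate],
    min_fraction: float = MIN_ALIGNED_FRACTION,
) -> HomologCandidate | None:
    """Best candidate from one target genome: among those covering at least
    ``min_fraction`` of the transcript (inclusive), the highest alignment
    score; ties broken by smallest candidate id. None if no candidate
    qualifies."""
    qualified = [c for c in candidates if c.aligned_fraction >= min_fraction]
    if not qualified:
        return None
    return min(qualified, key=lambda c: (-c.alignment_score, c.candidate_id))


def strip_reference_gaps(alignment: CodonAlignment) -> CodonAlignment:
    """Delete every column where the reference holds a gap.

    The output reference is its ungapped input sequence, so downstream codon
    coordinates are reference-frame coordinates. Idempotent.
    """
    if alignment.reference_id is None:
        raise KeyError("alignment has no reference sequence")
    ref = alignment.reference
    keep = [i for i, ch in enumerate(ref) if ch != "-"]
    return CodonAlignment(
        sequence_ids=list(alignment.sequence_ids),
        sequences=["".join(seq[i] for i in keep) for seq in alignment.sequences],
        reference_id=alignment.reference_id,
    )


def fourfold_site_indices(alignment: CodonAlignment) -> list[int]:
    """Reference-frame codon indices whose third position is 4-fold
    degenerate in every sequence.

    Strict rule: the codon must be ungapped and unambiguous in all
    sequences, all sequences must share the same first two nucleotides, and
    that two-base prefix must start a 4-fold family — so any third-position
    state change is synonymous alignment-wide.
    """
    if len(alignment) % 3 != 0:
        raise ValueError(f"alignment length {len(alignment)} is not divisible by 3")
    indices = []
    for i in range(alignment.n_codons):
        codons = [seq[3 * i : 3 * i + 3] for seq in alignment.sequences]
        prefixes = {c[:2] for c in codons}
        if len(prefixes) != 1:
            continue
        (prefix,) = prefixes
        if prefix not in FOURFOLD_PREFIXES:
            continue
        if any("-" in c or "N" in c for c in codons):
            continue
        indices.append(i)
    return indices


def extract_fourfold_sites(alignment: CodonAlignment) -> CodonAlignment:
    """Nucleotide alignment of the third positions of 4-fold-degenerate
    codon columns (see :func:`fourfold_site_indices`), in input order."""
    idx = fourfold_site_indices(alignment)
    return CodonAlignment(
        sequence_ids=list(alignment.sequence_ids),
        sequences=[
            "".join(seq[3 * i + 2] for i in idx) for seq in alignment.sequences
        ],
        reference_id=alignment.reference_id,
    )


def min_taxa_filter(
    alignments: dict[str, CodonAlignment], min_taxa: int = MIN_TAXA
) -> dict[str, CodonAlignment]:
    """Keep genes whose alignment holds at least ``min_taxa`` non-reference
    sequences (the reference itself is not counted as an aligned genome)."""
    kept = {}
    for gene_id, aln in alignments.items():
        n_targets = aln.n_sequences - (1 if aln.reference_id is not None else 0)
        if n_targets >= min_taxa:
            kept[gene_id] = aln
    return kept


def concatenate_alignments(
    alignments: dict[str, CodonAlignment],
    sample_size: int | None = None,
    seed: int = 0,
) -> tuple[CodonAlignment, dict[str, tuple[int, int]]]:
    """Concatenate (a seeded random sample of) per-gene alignments over the
    union of their taxa, gap-padding taxa absent from a gene.

    Returns the concatenated alignment and the per-gene half-open column
    block map. Used with 4D-site alignments to build the neutral
    concatenation behind the species tree.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    gene_ids = sorted(alignments)
    if sample_size is not None:
        if sample_size > len(gene_ids):
            raise ValueError(
                f"sample_size {sample_size} exceeds available genes {len(gene_ids)}"
            )
        rng = np.random.default_rng(seed)
        gene_ids = sorted(rng.choice(gene_ids, size=sample_size, replace=False))
    taxa: list[str] = []
    for gid in gene_ids:
        for sid in alignments[gid].sequence_ids:
            if sid not in taxa:
                taxa.append(sid)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    blocks: dict[str, tuple[int, int]] = {}
    offset = 0
    for gid in gene_ids:
        aln = alignments[gid]
        width = len(aln)
        for t in taxa:
            parts[t].append(
                aln.sequence(t) if t in aln.sequence_ids else "-" * width
            )
        blocks[gid] = (offset, offset + width)
        offset += width
    reference_ids = {alignments[g].reference_id for g in gene_ids}
    ref = reference_ids.pop() if len(reference_ids) == 1 else None
    return (
        CodonAlignment(
            sequence_ids=taxa,
            sequences=["".join(parts[t]) for t in taxa],
            reference_id=ref,
        ),
        blocks,
    )


@dataclass(frozen=True)
class TranscriptRecord:
    gene_id: str
    transcript_id: str
    has_utr: bool
    cds_length: int
    dnds: float | None
    n_species_with_ortholog: int

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError("cds_length must be positive")
        if self.dnds is not None and (self.dnds < 0 or isnan(self.dnds)):
            raise ValueError("dnds must be nonnegative when present")


def select_best_transcript(
    records: list[TranscriptRecord],
) -> TranscriptRecord | None:
    """Collapse one gene's transcripts to a single representative.

    Order of filters: transcripts without annotated UTRs are dropped (no
    RNA evidence); the gene is dropped entirely if no surviving transcript
    has an ortholog in any other species; among survivors the lowest dN/dS
    (most conserved) wins, then the longest CDS, then the smallest
    transcript id. Missing dN/dS sorts after any observed value.
    """
    if not records:
        raise ValueError("empty record list")
    gene_ids = {r.gene_id for r in records}
    if len(gene_ids) != 1:
        raise ValueError(f"records span multiple genes: {sorted(gene_ids)}")
    with_utr = [r for r in records if r.has_utr]
    survivors = [r for r in with_utr if r.n_species_with_ortholog >= 1]
    if not survivors:
        return None
    return min(
        survivors,
        key=lambda r: (
            r.dnds if r.dnds is not None else float("inf"),
            -r.cds_length,
            r.transcript_id,
        ),
    )
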
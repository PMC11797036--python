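"""Standard-format adapters: VCF, GFF3, FASTA and the TSV tables the
pipeline consumes.

Coordinate conventions: VCF and GFF3 are 1-based closed on disk and stay
that way in :class:`~relaxsel.popgen.VariantRecord` / gene-model segments
(conversion to 0-based happens only inside sequence slicing). Malformed
input raises with the file and line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .msa import HomologCandidate, TranscriptRecord
from .popgen import GeneModel, VariantRecord

from .alignment import (  # noqa: F401  (re-exported convenience)
    read_fasta_alignment,
    write_fasta_alignment,
)
from .trees import parse_newick, write_newick  # noqa: F401


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a (plain or bgzipped) VCF into variant records plus the sample
    list. Uses cyvcf2 when importable, falling back to a minimal text parser
    for uncompressed files."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        gts = np.asarray([g[:2] for g in v.genotypes], dtype=np.int64)
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=int(v.POS),
                ref_allele=v.REF,
                alt_alleles=tuple(v.ALT),
                genotypes=gts,
            )
        )
    return records, samples


def _read_vcf_text(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    samples: list[str] = []
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: expected >=10 VCF columns")
            gts = []
            for cell in fields[9:]:
                gt = cell.split(":")[0].replace("|", "/")
                alleles = gt.split("/")
                if len(alleles) != 2:
                    raise ValueError(f"{path}:{lineno}: non-diploid genotype {gt!r}")
                gts.append([-1 if a == "." else int(a) for a in alleles])
            records.append(
                VariantRecord(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    ref_allele=fields[3],
                    alt_alleles=tuple(fields[4].split(",")) if fields[4] != "." else (),
                    genotypes=np.asarray(gts, dtype=np.int64),
                )
            )
    return records, samples


def read_gff3(
    path: str | Path,
) -> tuple[dict[str, GeneModel], list[TranscriptRecord]]:
    """Parse gene models from GFF3.

    Returns one strand-aware :class:`GeneModel` per mRNA (keyed by
    transcript id) and one :class:`TranscriptRecord` skeleton per mRNA with
    UTR presence and CDS length filled in (dN/dS and ortholog counts join
    later from analysis tables, so they start as None/0).
    """
    mrna_parent: dict[str, str] = {}
    mrna_info: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                tid = attr.get("ID")
                if tid is None:
                    raise ValueError(f"{path}:{lineno}: mRNA without ID")
                mrna_parent[tid] = attr.get("Parent", tid)
                mrna_info[tid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "span": (int(start), int(end)),
                    "cds": [],
                    "utr": False,
                }
            elif ftype in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent")
                if parent is None or parent not in mrna_info:
                    continue
                if ftype == "CDS":
                    mrna_info[parent]["cds"].append((int(start), int(end)))
                else:
                    mrna_info[parent]["utr"] = True
    models: dict[str, GeneModel] = {}
    transcripts: list[TranscriptRecord] = []
    for tid, info in mrna_info.items():
        if not info["cds"]:
            continue
        gene_id = mrna_parent[tid]
        models[tid] = GeneModel(
            gene_id=gene_id,
            chrom=info["chrom"],
            strand=info["strand"],
            cds_segments=tuple(sorted(info["cds"])),
            span=info["span"],
        )
        transcripts.append(
            TranscriptRecord(
                gene_id=gene_id,
                transcript_id=tid,
                has_utr=info["utr"],
                cds_length=sum(e - s + 1 for s, e in info["cds"]),
                dnds=None,
                n_species_with_ortholog=0,
            )
        )
    return models, transcripts


def read_homolog_candidates(path: str | Path) -> dict[str, list[HomologCandidate]]:
    """TSV with columns gene_id, genome_id, candidate_id, aligned_fraction,
    alignment_score -> per-gene candidate lists."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "genome_id", "candidate_id", "aligned_fraction", "alignment_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[HomologCandidate]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, []).append(
            HomologCandidate(
                genome_id=row.genome_id,
                candidate_id=row.candidate_id,
                aligned_fraction=float(row.aligned_fraction),
                alignment_score=float(row.alignment_score),
            )
        )
    return out


def read_site_scores(path: str | Path) -> pd.DataFrame:
    """Per-site annotation table keyed by (chrom, pos, alt): site rates
    and/or SIFT-like scores, 1-based positions."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError(f"{path}: needs at least chrom and pos columns")
    return df


def read_gene_terms(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV gene_id <tab> term_id -> gene to term-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"],
                     comment="#")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene_id), set()).add(str(row.term_id))
    return out


def read_term_parents(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "parent_id"],
                     comment="#")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.term_id), set()).add(str(row.parent_id))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
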
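"""In-frame codon alignment container.

Sequences are equal-length strings over ``{A, C, G, T, N, -}``; one sequence
may be designated the reference (the focal species' transcript, whose frame
defines codon coordinates after reference gaps are stripped). Ambiguity
codes other than N are rejected at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED_CHARS = frozenset("ACGTN-")


@dataclass
class CodonAlignment:
    sequence_ids: list[str]
    sequences: list[str]
    reference_id: str | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.sequences):
            raise ValueError("sequence_ids and sequences must have equal length")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("duplicate sequence ids")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, seq in zip(self.sequence_ids, self.sequences):
            bad = set(seq) - ALLOWED_CHARS
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains unsupported characters {sorted(bad)}; "
                    "only A, C, G, T, N and '-' are accepted"
                )
        if self.reference_id is not None and self.reference_id not in self.sequence_ids:
            raise KeyError(f"reference {self.reference_id!r} not in alignment")
        self._index = {sid: i for i, sid in enumerate(self.sequence_ids)}

    def __len__(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    def sequence(self, sid: str) -> str:
        return self.sequences[self._index[sid]]

    @property
    def reference(self) -> str:
        if self.reference_id is None:
            raise KeyError("alignment has no reference sequence")
        return self.sequence(self.reference_id)

    def codon(self, sid: str, codon_index: int) -> str:
        return self.sequence(sid)[3 * codon_index : 3 * codon_index + 3]

    @property
    def n_codons(self) -> int:
        if len(self) % 3 != 0:
            raise ValueError(f"alignment length {len(self)} is not divisible by 3")
        return len(self) // 3


def read_fasta_alignment(path, reference_id: str | None = None) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return CodonAlignment(
        sequence_ids=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
        reference_id=reference_id,
    )


def write_fasta_alignment(alignment: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.sequence_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
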
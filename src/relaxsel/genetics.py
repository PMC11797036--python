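"""Standard genetic code tables for codon models.

The codon state space is the 61 sense codons of the standard nuclear code
(stop codons TAA, TAG, TGA excluded), in lexicographic order over ACGT.
Pairwise classification arrays (single-nucleotide difference, transition vs
transversion, synonymous vs nonsynonymous) are precomputed once at import;
they parameterize both the GY94-style rate matrix and the stochastic
simulator.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))

SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in _STANDARD_TABLE.stop_codons
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

CODON_AA = {c: _STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS}

#: two-nucleotide prefixes whose codon family is 4-fold degenerate
#: (any third base encodes the same amino acid)
FOURFOLD_PREFIXES: frozenset[str] = frozenset(
    pre
    for pre in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2))
    if all(pre + b in CODON_AA for b in NUCLEOTIDES)
    and len({CODON_AA[pre + b] for b in NUCLEOTIDES}) == 1
)


def translate_codon(codon: str) -> str:
    """Translate a sense codon; '*' for stop."""
    codon = codon.upper()
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return CODON_AA[codon]


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    diff_pos = np.full((N_CODONS, N_CODONS), -1, dtype=np.int8)
    is_ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            (k,) = diffs
            diff_pos[i, j] = k
            is_ts[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = CODON_AA[ci] != CODON_AA[cj]
    return diff_pos, is_ts, nonsyn


#: DIFF_POS[i, j] = codon position (0..2) where sense codons i and j differ,
#: or -1 when they differ at zero or more than one position.
DIFF_POS, IS_TRANSITION_PAIR, IS_NONSYN_PAIR = _pair_tables()
SINGLE_STEP = DIFF_POS >= 0
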
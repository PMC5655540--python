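"""Shared genetic-code primitives used across the package.

Standard genetic code (NCBI table 1), amino-acid ordering used by count
matrices, and small DNA string helpers. Kept internal; public modules
re-export what they need.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable, IUPACData

#: Canonical amino-acid ordering for matrix columns (alphabetical one-letter).
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

#: Stop symbol used throughout.
STOP: str = "*"

#: Mutation-type column ordering: 20 amino acids then stop (21 columns).
MUTATION_COLUMNS: str = AA20 + STOP

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stop codons mapped to "*".
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = STOP

#: amino acid -> deterministic representative codon (lexicographically first).
AA_TO_CODON: dict[str, str] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODON.setdefault(CODON_TO_AA[_codon], _codon)

#: IUPAC ambiguity code -> concrete bases (standard 15 DNA codes only;
#: Biopython's table also carries the non-IUPAC "X", which we reject).
IUPAC_DNA: dict[str, str] = {
    k.upper(): v.upper()
    for k, v in IUPACData.ambiguous_dna_values.items()
    if k.upper() in "ACGTRYSWKMBDHVN"
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base <-> uint8 encodings used by the vectorized pipeline paths
BASE_ORDER = "ACGT"
_B2I = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _B2I[ord(_b)] = _i
    _B2I[ord(_b.lower())] = _i
I2B = np.frombuffer(b"ACGTN", dtype=np.uint8).copy()

# 64-entry codon translation table indexed by 16*b0 + 4*b1 + b2
CODON_LUT = np.zeros(64, dtype="U1")
for _i0, _b0 in enumerate(BASE_ORDER):
    for _i1, _b1 in enumerate(BASE_ORDER):
        for _i2, _b2 in enumerate(BASE_ORDER):
            CODON_LUT[16 * _i0 + 4 * _i1 + _i2] = CODON_TO_AA[_b0 + _b1 + _b2]

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(MUTATION_COLUMNS)}

#: amino-acid index (into MUTATION_COLUMNS) for each of the 64 codons
CODON_AA_INDEX = np.array([AA_INDEX[a] for a in CODON_LUT], dtype=np.int64)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA into uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _B2I[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 renders as N."""
    return I2B[codes].tobytes().decode("ascii")


def translate_codon(codon: str) -> str | None:
    """Translate one concrete codon; None if it contains a non-ACGT base."""
    return CODON_TO_AA.get(codon.upper())
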
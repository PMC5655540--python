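"""Site-saturation mutagenesis (SSM) library design.

Enumerates the single-mutant variant space of an ORF (every included
position crossed with all 20 amino acids) and emits NNK degenerate primer
sets for a two-step overlap-PCR mutagenesis scheme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio import SeqIO

from ._genetics import AA20, CODON_TO_AA, IUPAC_DNA, STOP, revcomp

__all__ = [
    "CodingSequence",
    "SSMVariantSpec",
    "PrimerSet",
    "enumerate_ssm",
    "expand_degenerate",
    "design_nnk_primers",
    "reconstruct_template",
]


@dataclass(frozen=True)
class CodingSequence:
    """A validated protein-coding DNA sequence.

    Must start with ATG, have length divisible by 3, and translate without
    internal stop codons.
    """

    id: str
    nt: str
    protein: str = field(init=False)

    def __post_init__(self) -> None:
        nt = self.nt.upper()
        object.__setattr__(self, "nt", nt)
        if set(nt) - set("ACGT"):
            raise ValueError(f"{self.id}: non-ACGT characters in coding sequence")
        if len(nt) % 3 != 0:
            raise ValueError(f"{self.id}: length {len(nt)} not divisible by 3")
        if not nt.startswith("ATG"):
            raise ValueError(f"{self.id}: ORF does not begin with ATG")
        protein = "".join(
            CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3)
        )
        if STOP in protein[:-1]:
            pos = protein.index(STOP) + 1
            raise ValueError(f"{self.id}: internal stop codon at residue {pos}")
        if protein.endswith(STOP):
            protein = protein[:-1]
        object.__setattr__(self, "protein", protein)

    @classmethod
    def from_fasta(cls, path) -> "CodingSequence":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(id=record.id, nt=str(record.seq))

    def codon(self, position: int) -> str:
        """Codon for a 1-based protein position."""
        return self.nt[(position - 1) * 3 : position * 3]


@dataclass(frozen=True)
class SSMVariantSpec:
    """One position x amino-acid cell of the SSM design space."""

    position: int  # 1-based protein index
    wt_aa: str
    mut_aa: str
    codon: str = "NNK"

    @property
    def is_wt_synonymous(self) -> bool:
        return self.mut_aa == self.wt_aa


@dataclass(frozen=True)
class PrimerSet:
    """NNK primer pair for one mutagenized position (two-step overlap PCR)."""

    position: int
    fwd_nnk: str
    rev_overlap: str
    flank_len: int


def enumerate_ssm(
    protein: str, exclude: set[int] | frozenset[int] = frozenset()
) -> list[SSMVariantSpec]:
    """Enumerate the full SSM design space of ``protein``.

    Every position not in ``exclude`` (1-based) is paired with each of the
    20 standard amino acids, wild-type identity included (tagged via
    :attr:`SSMVariantSpec.is_wt_synonymous`).

    Raises ``ValueError`` on an empty protein, invalid amino-acid characters
    (position reported), or excluded positions outside the protein.
    """
    if not protein:
        raise ValueError("protein sequence is empty")
    for i, aa in enumerate(protein, start=1):
        if aa not in AA20:
            raise ValueError(f"invalid amino acid {aa!r} at position {i}")
    bad = {p for p in exclude if not (1 <= p <= len(protein))}
    if bad:
        raise ValueError(f"excluded positions outside protein: {sorted(bad)}")
    return [
        SSMVariantSpec(position=pos, wt_aa=protein[pos - 1], mut_aa=aa)
        for pos in range(1, len(protein) + 1)
        if pos not in exclude
        for aa in AA20
    ]


def expand_degenerate(codon_template: str) -> dict[str, str]:
    """Expand an IUPAC degenerate codon into {concrete codon: amino acid}.

    ``expand_degenerate("NNK")`` yields 32 codons whose translations cover
    all 20 amino acids plus exactly one stop (TAG).
    """
    template = codon_template.upper()
    if len(template) != 3:
        raise ValueError(f"codon template must be 3 nt, got {codon_template!r}")
    try:
        choices = [IUPAC_DNA[b] for b in template]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in template") from None
    return {
        "".join(bases): CODON_TO_AA["".join(bases)]
        for bases in itertools.product(*choices)
    }


def design_nnk_primers(
    cds: CodingSequence, position: int, flank_len: int = 18
) -> PrimerSet:
    """Design the NNK forward primer and overlapping reverse primer for one site.

    The forward primer carries ``flank_len`` template nucleotides on either
    side of the NNK codon. The reverse primer reverse-complements a template
    window ending immediately 5' of the mutated codon, long enough to span
    the forward primer's upstream flank plus an extra upstream stretch
    (the "partial overlap" of the two step-1 products).
    """
    n_codons = len(cds.nt) // 3
    if not (2 <= position <= n_codons):
        raise ValueError(
            f"position {position} out of range (2..{n_codons}; start Met excluded)"
        )
    start = (position - 1) * 3
    end = start + 3
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    rev_len = flank_len + max(flank_len // 2, 1)
    if start - rev_len < 0 or end + flank_len > len(cds.nt):
        raise ValueError(
            f"flank extends past template at position {position} "
            f"(need {rev_len} nt upstream, {flank_len} nt downstream)"
        )
    fwd_nnk = cds.nt[start - flank_len : start] + "NNK" + cds.nt[end : end + flank_len]
    rev_overlap = revcomp(cds.nt[start - rev_len : start])
    return PrimerSet(
        position=position, fwd_nnk=fwd_nnk, rev_overlap=rev_overlap, flank_len=flank_len
    )


def reconstruct_template(cds: CodingSequence, primers: PrimerSet) -> str:
    """Splice the primer pieces back onto the template (verification aid).

    Replaces NNK in the forward primer with the wild-type codon and merges it
    with the reverse-primer window; the result must be a contiguous template
    substring, which is how primer correctness is checked in tests.
    """
    wt_codon = cds.codon(primers.position)
    fwd_concrete = primers.fwd_nnk.replace("NNK", wt_codon)
    rev_window = revcomp(primers.rev_overlap)  # template-strand window
    start = (primers.position - 1) * 3
    upstream_extra = rev_window[: len(rev_window) - primers.flank_len]
    assembled = upstream_extra + fwd_concrete
    expected_start = start - len(rev_window)
    if cds.nt[expected_start : expected_start + len(assembled)] != assembled:
        raise AssertionError("primer pieces do not reassemble the template")
    return assembled
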
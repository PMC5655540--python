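"""Translate merged reads, classify variants, and accumulate count matrices.

Each full-length (or amplicon-window) read is translated and compared to
the wild-type protein: zero differences is WT, exactly one is a single
mutant contributing to the position x mutation-type count matrix f_ij,
and everything else (multiple mutations, length mismatches, untranslatable
reads) is tallied separately for QC and excluded from f_ij.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._genetics import (
    AA_INDEX,
    CODON_AA_INDEX,
    CODON_TO_AA,
    MUTATION_COLUMNS,
    STOP,
    encode,
)

__all__ = [
    "VariantCall",
    "CountMatrix",
    "AmpliconWindow",
    "translate_orf",
    "classify_read",
    "count_mutations",
    "count_merged_reads",
]

CLASSES = ("WT", "SINGLE", "MULTI", "INDEL_OR_LEN", "UNTRANSLATABLE")


@dataclass(frozen=True)
class VariantCall:
    read_id: str
    cls: str
    position: int | None = None  # 1-based protein index, SINGLE only
    mut_aa: str | None = None  # amino acid or "*", SINGLE only

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")
        has_site = self.position is not None or self.mut_aa is not None
        if (self.cls == "SINGLE") != has_site:
            raise ValueError("SINGLE calls (and only SINGLE) carry (position, mut_aa)")


@dataclass(frozen=True)
class AmpliconWindow:
    """Codon-aligned half-open nucleotide window [start, end) of the ORF.

    Merged reads are assigned to a window by exact length match; the window
    defines the frame and the global protein positions of its codons.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start % 3 or self.end % 3 or self.end <= self.start:
            raise ValueError("amplicon window must be codon-aligned and non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def first_position(self) -> int:
        return self.start // 3 + 1


@dataclass
class CountMatrix:
    """Per-position x per-mutation-type single-mutant counts f_ij.

    Columns are the 20 amino acids plus stop (21 mutation types); the cell
    matching the wild-type identity at each position is flagged in
    ``wt_mask`` and never counted as a mutation.
    """

    counts: np.ndarray  # (N, 21) non-negative ints
    wt_mask: np.ndarray  # (N, 21) bool, True at wild-type identity cells
    library_label: str = ""
    n_reads_classified: int = 0
    tallies: dict[str, int] = field(default_factory=dict)

    columns = MUTATION_COLUMNS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.wt_mask = np.asarray(self.wt_mask, dtype=bool)
        if self.counts.shape != self.wt_mask.shape or self.counts.shape[1] != 21:
            raise ValueError("counts and wt_mask must share shape (N, 21)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts[self.wt_mask].any():
            raise ValueError("wild-type identity cells must stay zero")

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def empty(cls, wt_protein: str, library_label: str = "") -> "CountMatrix":
        n = len(wt_protein)
        wt_mask = np.zeros((n, 21), dtype=bool)
        for i, aa in enumerate(wt_protein):
            wt_mask[i, AA_INDEX[aa]] = True
        return cls(
            counts=np.zeros((n, 21), dtype=np.int64),
            wt_mask=wt_mask,
            library_label=library_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.RangeIndex(1, self.n_positions + 1, name="position"),
            columns=list(self.columns),
        )

    def to_tsv(self, path, long_path=None) -> None:
        """Write the wide matrix; optionally also a long (tidy) form."""
        self.to_frame().to_csv(path, sep="\t")
        if long_path is not None:
            long = self.to_frame().reset_index().melt(
                id_vars="position", var_name="mut_aa", value_name="count"
            )
            long.to_csv(long_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, wt_protein: str, library_label: str = "") -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="position")
        matrix = cls.empty(wt_protein, library_label)
        counts = frame[list(cls.columns)].to_numpy(dtype=np.int64)
        counts[matrix.wt_mask] = 0
        matrix.counts = counts
        return matrix

    def write_tallies(self, path) -> None:
        with open(path, "w") as out:
            json.dump(
                {
                    "library_label": self.library_label,
                    "n_reads_classified": self.n_reads_classified,
                    "tallies": self.tallies,
                },
                out,
                indent=2,
            )


def translate_orf(seq: str, frame_offset: int = 0) -> str | None:
    """Translate DNA from ``frame_offset`` in codon steps.

    Returns None when the trimmed length is not a codon multiple or a codon
    contains an ambiguous base (callers classify such reads UNTRANSLATABLE
    or INDEL_OR_LEN).
    """
    trimmed = seq[frame_offset:].upper()
    if len(trimmed) % 3 != 0:
        return None
    aa = []
    for i in range(0, len(trimmed), 3):
        codon = trimmed[i : i + 3]
        res = CODON_TO_AA.get(codon)
        if res is None:
            return None
        aa.append(res)
    return "".join(aa)


def classify_read(
    protein: str, wt: str, read_id: str = "", position_offset: int = 0
) -> VariantCall:
    """Classify a translated read against the wild-type protein (segment).

    ``position_offset`` shifts reported SINGLE positions so amplicon windows
    map onto global protein coordinates.
    """
    if len(protein) != len(wt):
        return VariantCall(read_id, "INDEL_OR_LEN")
    diffs = [i for i, (a, b) in enumerate(zip(protein, wt)) if a != b]
    if not diffs:
        return VariantCall(read_id, "WT")
    if len(diffs) == 1:
        i = diffs[0]
        return VariantCall(
            read_id, "SINGLE", position=position_offset + i + 1, mut_aa=protein[i]
        )
    return VariantCall(read_id, "MULTI")


def count_mutations(
    calls: Iterable[VariantCall], N: int, wt: str | None = None, library_label: str = ""
) -> CountMatrix:
    """Accumulate VariantCalls into a CountMatrix over ``N`` positions.

    Stop-codon mutants accumulate in the stop column. When ``wt`` is given,
    its identity cells are flagged (SINGLE calls can never land there by
    construction).
    """
    if wt is not None:
        if len(wt) != N:
            raise ValueError("wt length must equal N")
        matrix = CountMatrix.empty(wt, library_label)
    else:
        matrix = CountMatrix(
            counts=np.zeros((N, 21), dtype=np.int64),
            wt_mask=np.zeros((N, 21), dtype=bool),
            library_label=library_label,
        )
    tallies = dict.fromkeys(CLASSES, 0)
    n = 0
    for call in calls:
        n += 1
        tallies[call.cls] += 1
        if call.cls == "SINGLE":
            if not (1 <= call.position <= N):
                raise ValueError(f"SINGLE position {call.position} outside 1..{N}")
            matrix.counts[call.position - 1, AA_INDEX[call.mut_aa]] += 1
    matrix.n_reads_classified = n
    matrix.tallies = tallies
    return matrix


# ---------------------------------------------------------------------------
# Batch pipeline path

def _classify_batch(
    seqs: Sequence[str],
    ids: Sequence[str],
    window: AmpliconWindow,
    wt_protein: str,
) -> list[VariantCall]:
    """Vectorized classification of same-length reads from one amplicon."""
    n_codons = window.length // 3
    wt_seg = wt_protein[window.start // 3 : window.start // 3 + n_codons]
    wt_idx = np.array([AA_INDEX[a] for a in wt_seg], dtype=np.int64)

    mat = np.vstack([encode(s) for s in seqs])
    codons = mat.reshape(len(seqs), n_codons, 3).astype(np.int64)
    bad = (codons >= 4).any(axis=2)
    codon_idx = 16 * codons[:, :, 0] + 4 * codons[:, :, 1] + codons[:, :, 2]
    codon_idx[bad] = 0
    aa_idx = CODON_AA_INDEX[codon_idx]

    untranslatable = bad.any(axis=1)
    diff = aa_idx != wt_idx[None, :]
    n_diff = diff.sum(axis=1)

    calls: list[VariantCall] = []
    offset = window.first_position - 1
    single = (~untranslatable) & (n_diff == 1)
    single_pos = np.where(single, diff.argmax(axis=1), 0)
    for k, read_id in enumerate(ids):
        if untranslatable[k]:
            calls.append(VariantCall(read_id, "UNTRANSLATABLE"))
        elif n_diff[k] == 0:
            calls.append(VariantCall(read_id, "WT"))
        elif n_diff[k] == 1:
            i = int(single_pos[k])
            calls.append(
                VariantCall(
                    read_id,
                    "SINGLE",
                    position=offset + i + 1,
                    mut_aa=MUTATION_COLUMNS[aa_idx[k, i]],
                )
            )
        else:
            calls.append(VariantCall(read_id, "MULTI"))
    return calls


def count_merged_reads(
    reads: Iterable[tuple[str, str]],
    wt_protein: str,
    windows: Sequence[AmpliconWindow],
    library_label: str = "",
) -> CountMatrix:
    """Classify merged reads against amplicon windows and count single mutants.

    ``reads`` yields (id, sequence). Each read is anchored to the unique
    window whose nucleotide length equals the read length; reads matching no
    window are INDEL_OR_LEN. Windows must therefore have distinct lengths.
    """
    lengths = [w.length for w in windows]
    if len(set(lengths)) != len(lengths):
        raise ValueError("amplicon windows must have distinct lengths")
    by_window: dict[int, tuple[list[str], list[str]]] = {
        w.length: ([], []) for w in windows
    }
    calls: list[VariantCall] = []
    for read_id, seq in reads:
        bucket = by_window.get(len(seq))
        if bucket is None:
            calls.append(VariantCall(read_id, "INDEL_OR_LEN"))
        else:
            bucket[0].append(read_id)
            bucket[1].append(seq)
    for window in windows:
        ids, seqs = by_window[window.length]
        if seqs:
            calls.extend(_classify_batch(seqs, ids, window, wt_protein))
    return count_mutations(calls, len(wt_protein), wt=wt_protein, library_label=library_label)
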
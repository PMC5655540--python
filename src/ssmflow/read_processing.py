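"""Paired-end read merging and Phred quality filtering.

Reads are merged by exhaustively scoring every ungapped overlap offset of
the forward read against the reverse-complemented reverse read, keeping the
offset with the most matching bases subject to a minimum overlap length and
a maximum mismatch fraction. Merged reads are then filtered on average and
minimum per-base Phred score.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._genetics import encode, revcomp

__all__ = [
    "ReadPair",
    "MergedRead",
    "MergeRejection",
    "QCParams",
    "merge_pair",
    "quality_filter",
    "read_fastq_pairs",
    "write_fastq",
    "merge_fastq",
]

PHRED_OFFSET = 33


@dataclass(frozen=True)
class QCParams:
    """Merging and quality-filter thresholds.

    Defaults follow the analysis protocol this package implements: average
    Phred >= 18, minimum per-position Phred >= 12, minimum pairwise overlap
    of 11 bases. Mismatch tolerance and the merged-quality cap are merger
    conventions, recorded in output metadata.
    """

    min_avg_phred: float = 18.0
    min_pos_phred: int = 12
    min_overlap: int = 11
    max_mismatch_frac: float = 0.1
    qual_cap: int = 41

    def __post_init__(self) -> None:
        if min(self.min_avg_phred, self.min_pos_phred, self.min_overlap) < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class ReadPair:
    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: np.ndarray  # per-base Phred integers
    rev_qual: np.ndarray

    def __post_init__(self) -> None:
        self.fwd_qual = np.asarray(self.fwd_qual, dtype=np.int64)
        self.rev_qual = np.asarray(self.rev_qual, dtype=np.int64)
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: np.ndarray
    overlap_len: int


@dataclass(frozen=True)
class MergeRejection:
    id: str
    reason: str  # no_overlap | ambiguous


def _overlap_matches(fwd: np.ndarray, rcr: np.ndarray) -> np.ndarray:
    """Matching-base counts for every non-negative shift of rcr along fwd.

    Entry ``s`` counts positions k with fwd[s+k] == rcr[k], for
    s = 0 .. len(fwd)-1. Computed by one-hot cross-correlation; code 4 (N)
    matches nothing.
    """
    lf, lr = len(fwd), len(rcr)
    total = np.zeros(lf + lr - 1)
    for base in range(4):
        total += np.correlate(
            (fwd == base).astype(np.float64),
            (rcr == base).astype(np.float64),
            mode="full",
        )
    # full correlation index (lr - 1 + s) corresponds to shift s
    return np.rint(total[lr - 1 :]).astype(np.int64)


def merge_pair(pair: ReadPair, params: QCParams = QCParams()) -> MergedRead | MergeRejection:
    """Merge one read pair, or reject with a reason code.

    The reverse read is reverse-complemented, every ungapped offset is
    scored, and the offset maximizing matched bases is kept if its overlap
    is at least ``params.min_overlap`` with mismatch fraction at most
    ``params.max_mismatch_frac``. An exact tie between distinct best offsets
    is rejected as ``ambiguous``; no qualifying offset is ``no_overlap``.
    In the overlap, agreeing bases take the capped sum of the two Phred
    scores and disagreeing bases take the higher-Phred call (forward read
    wins an exact quality tie).
    """
    rcr_seq = revcomp(pair.rev_seq)
    rcr_qual = pair.rev_qual[::-1]
    fwd = encode(pair.fwd_seq)
    rcr = encode(rcr_seq)
    lf, lr = len(fwd), len(rcr)

    matches = _overlap_matches(fwd, rcr)
    shifts = np.arange(lf)
    overlaps = np.minimum(lf - shifts, lr)
    mismatches = overlaps - matches
    valid = (overlaps >= params.min_overlap) & (
        mismatches <= params.max_mismatch_frac * overlaps
    )
    if not valid.any():
        return MergeRejection(pair.id, "no_overlap")
    best_score = matches[valid].max()
    candidates = shifts[valid & (matches == best_score)]
    if len(candidates) > 1:
        return MergeRejection(pair.id, "ambiguous")
    s = int(candidates[0])
    overlap = int(overlaps[s])

    out_len = max(lf, s + lr)
    seq = np.empty(out_len, dtype=np.uint8)
    qual = np.zeros(out_len, dtype=np.int64)
    seq[:lf] = fwd
    qual[:lf] = pair.fwd_qual
    if s + lr > lf:
        seq[lf:] = rcr[lf - s :]
        qual[lf:] = rcr_qual[lf - s :]
    # consensus inside the overlap [s, s+overlap)
    f_ov = fwd[s : s + overlap]
    r_ov = rcr[:overlap]
    fq_ov = pair.fwd_qual[s : s + overlap]
    rq_ov = rcr_qual[:overlap]
    agree = f_ov == r_ov
    cons_seq = np.where((~agree) & (rq_ov > fq_ov), r_ov, f_ov)
    cons_qual = np.where(
        agree,
        np.minimum(fq_ov + rq_ov, params.qual_cap),
        np.maximum(fq_ov, rq_ov),
    )
    seq[s : s + overlap] = cons_seq
    qual[s : s + overlap] = cons_qual

    from ._genetics import decode

    return MergedRead(id=pair.id, seq=decode(seq), qual=qual, overlap_len=overlap)


def quality_filter(read: MergedRead, params: QCParams = QCParams()) -> tuple[bool, str]:
    """Pass/fail a merged read on mean and minimum Phred thresholds.

    Returns ``(True, "pass")`` or ``(False, reason)`` with reason one of
    ``empty``, ``avg``, ``min_pos``.
    """
    if len(read.qual) == 0:
        return False, "empty"
    if float(np.mean(read.qual)) < params.min_avg_phred:
        return False, "avg"
    if int(np.min(read.qual)) < params.min_pos_phred:
        return False, "min_pos"
    return True, "pass"


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)

def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Iterate synchronized R1/R2 FASTQ files as ReadPair objects."""
    with open(r1_path) as h1, open(r2_path) as h2:
        for (id1, seq1, q1), (id2, seq2, q2) in zip(
            FastqGeneralIterator(h1), FastqGeneralIterator(h2), strict=True
        ):
            if id1.split()[0] != id2.split()[0]:
                raise ValueError(f"unsynchronized pair: {id1!r} vs {id2!r}")
            yield ReadPair(
                id=id1.split()[0],
                fwd_seq=seq1,
                rev_seq=seq2,
                fwd_qual=np.frombuffer(q1.encode(), np.uint8).astype(np.int64)
                - PHRED_OFFSET,
                rev_qual=np.frombuffer(q2.encode(), np.uint8).astype(np.int64)
                - PHRED_OFFSET,
            )


def write_fastq(reads, path) -> None:
    """Write merged reads (or any id/seq/qual records) as Phred+33 FASTQ."""
    with open(path, "w") as out:
        for read in reads:
            qual = (np.asarray(read.qual, dtype=np.int64) + PHRED_OFFSET).astype(
                np.uint8
            )
            out.write(f"@{read.id}\n{read.seq}\n+\n{qual.tobytes().decode('ascii')}\n")


def merge_fastq(
    r1_path,
    r2_path,
    out_path,
    reject_path=None,
    params: QCParams = QCParams(),
) -> dict[str, int]:
    """Merge an R1/R2 FASTQ pair of files; returns outcome tallies.

    Writes merged, quality-passing reads to ``out_path`` and, optionally, a
    TSV log of rejected read ids with reason codes.
    """
    tallies = {"pass": 0, "no_overlap": 0, "ambiguous": 0, "avg": 0, "min_pos": 0, "empty": 0}
    rejects: list[tuple[str, str]] = []
    with open(out_path, "w") as out:
        for pair in read_fastq_pairs(r1_path, r2_path):
            result = merge_pair(pair, params)
            if isinstance(result, MergeRejection):
                tallies[result.reason] += 1
                rejects.append((result.id, result.reason))
                continue
            ok, reason = quality_filter(result, params)
            if not ok:
                tallies[reason] += 1
                rejects.append((result.id, reason))
                continue
            tallies["pass"] += 1
            qual = (result.qual + PHRED_OFFSET).astype(np.uint8)
            out.write(
                f"@{result.id}\n{result.seq}\n+\n{qual.tobytes().decode('ascii')}\n"
            )
    if reject_path is not None:
        with open(reject_path, "w", newline="") as rh:
            writer = csv.writer(rh, delimiter="\t")
            writer.writerow(["read_id", "reason"])
            writer.writerows(rejects)
    return tallies
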
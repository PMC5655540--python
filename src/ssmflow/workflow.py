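"""End-to-end glue: simulate or load reads, merge, count, enrich.

Thin orchestration over the per-module APIs, shared by the CLI, the test
suite, and the acceptance report.
"""

from __future__ import annotations

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_design import CodingSequence
from .read_processing import QCParams, merge_fastq
from .variant_counting import AmpliconWindow, CountMatrix, count_merged_reads


def iter_merged_fastq(path):
    """Yield (id, sequence) from a merged FASTQ file."""
    with open(path) as handle:
        for read_id, seq, _qual in FastqGeneralIterator(handle):
            yield read_id.split()[0], seq


def merge_and_count(
    r1_path,
    r2_path,
    wt: CodingSequence,
    windows: tuple[AmpliconWindow, ...],
    merged_path,
    label: str,
    params: QCParams = QCParams(),
) -> tuple[CountMatrix, dict[str, int]]:
    """Merge an R1/R2 pair of FASTQ files and count single-mutant variants."""
    merge_tallies = merge_fastq(r1_path, r2_path, merged_path, params=params)
    matrix = count_merged_reads(
        iter_merged_fastq(merged_path), wt.protein, windows, library_label=label
    )
    return matrix, merge_tallies
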
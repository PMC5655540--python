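"""Synthetic SSM libraries, selection rounds, and paired-end read simulation.

Provides desk-scale stand-ins for a real deep-mutational-scanning
experiment: a random wild-type ORF, a variant pool with known per-variant
fitness (ground-truth log2 enrichment per round), deterministic selection
dynamics, and MiSeq-like paired FASTQ reads with a configurable
substitution-error and Phred model. All randomness flows from explicit
integer seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._genetics import AA_TO_CODON, CODON_TO_AA, MUTATION_COLUMNS, STOP, decode, encode
from .library_design import CodingSequence
from .variant_counting import AmpliconWindow

__all__ = [
    "SyntheticTruth",
    "ReadSimParams",
    "make_wt",
    "make_truth",
    "simulate_selection",
    "simulate_reads",
    "default_amplicon_layout",
]

#: key used for the wild-type fraction in pool-frequency dicts
WT_KEY = ("WT", "")

_SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != STOP)


def make_wt(length_aa: int, seed: int) -> CodingSequence:
    """Random ORF of ``length_aa`` residues: ATG start, no internal stops."""
    if length_aa < 2:
        raise ValueError("length_aa must be >= 2")
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + list(rng.choice(_SENSE_CODONS, size=length_aa - 1))
    return CodingSequence(id=f"synthetic_wt_L{length_aa}_s{seed}", nt="".join(codons))


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated SSM experiment.

    ``variant_freqs`` maps (position, mut_aa) to the naive-pool frequency;
    the remainder to 1 is the wild-type fraction. ``fitness`` maps the same
    keys to the true log2 enrichment per selection round (wild type fixed
    at 0).
    """

    wt: CodingSequence
    variant_freqs: dict[tuple[int, str], float]
    fitness: dict[tuple[int, str], float]
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.variant_freqs.values())
        if total > 1 + 1e-9:
            raise ValueError(f"variant frequencies sum to {total} > 1")

    @property
    def wt_fraction(self) -> float:
        return 1.0 - sum(self.variant_freqs.values())

    def pool(self) -> dict[tuple[int, str], float]:
        """Naive pool frequencies including the wild-type key."""
        return {WT_KEY: self.wt_fraction, **self.variant_freqs}

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("position\tmut_aa\tnaive_freq\tfitness\n")
            for key in sorted(self.variant_freqs):
                out.write(
                    f"{key[0]}\t{key[1]}\t{self.variant_freqs[key]!r}\t{self.fitness[key]!r}\n"
                )


def make_truth(
    wt: CodingSequence,
    seed: int,
    wt_fraction: float = 0.1,
    fitness_range: tuple[float, float] = (-2.0, 2.0),
    exclude_positions: frozenset[int] = frozenset({1}),
    neutral: bool = False,
) -> SyntheticTruth:
    """Uniform single-mutant pool over every non-wild-type mutation type.

    Each included position contributes 20 variants (the 19 other amino
    acids plus stop); fitness is drawn uniformly from ``fitness_range``
    unless ``neutral``, in which case it is identically zero.
    """
    rng = np.random.default_rng(seed)
    keys = [
        (pos, aa)
        for pos in range(1, len(wt.protein) + 1)
        if pos not in exclude_positions
        for aa in MUTATION_COLUMNS
        if aa != wt.protein[pos - 1]
    ]
    freq = (1.0 - wt_fraction) / len(keys)
    if neutral:
        fitness = dict.fromkeys(keys, 0.0)
    else:
        lo, hi = fitness_range
        fitness = dict(zip(keys, rng.uniform(lo, hi, size=len(keys))))
    return SyntheticTruth(
        wt=wt,
        variant_freqs=dict.fromkeys(keys, freq),
        fitness=fitness,
        seed=seed,
    )


def simulate_selection(
    truth: SyntheticTruth, rounds: int
) -> list[dict[tuple[int, str], float]]:
    """Deterministic selection: freq'(v) ∝ freq(v) * 2^fitness(v), renormalized.

    Returns one pool-frequency dict (wild type included, fitness 0) per
    round.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    pools = []
    pool = truth.pool()
    for _ in range(rounds):
        weighted = {
            key: f * 2.0 ** truth.fitness.get(key, 0.0) for key, f in pool.items()
        }
        total = sum(weighted.values())
        pool = {key: w / total for key, w in weighted.items()}
        pools.append(pool)
    return pools


@dataclass
class ReadSimParams:
    """Sequencing-simulation parameters (MiSeq-like defaults)."""

    depth: int = 200_000  # read pairs per library
    fwd_len: int = 305
    rev_len: int = 295
    error_rate: float = 0.001  # per-base substitution probability
    phred_mean: float = 32.0
    phred_sd: float = 4.0
    phred_floor: int = 2
    amplicons: tuple[AmpliconWindow, ...] | None = None  # None = auto layout
    inter_amplicon_overlap: int = 42
    indel_rate: float = 0.0  # per-read single-base deletion probability
    seed: int = 0

    def resolve_amplicons(self, orf_len: int) -> tuple[AmpliconWindow, ...]:
        if self.amplicons is not None:
            return tuple(self.amplicons)
        return default_amplicon_layout(
            orf_len, self.fwd_len, self.rev_len, self.inter_amplicon_overlap
        )

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["amplicons"] = [
            [w.start, w.end] for w in (self.amplicons or ())
        ] or None
        with open(path, "w") as out:
            json.dump(payload, out, indent=2)


def default_amplicon_layout(
    orf_len: int, fwd_len: int, rev_len: int, overlap: int = 42
) -> tuple[AmpliconWindow, ...]:
    """Codon-aligned amplicon windows covering the ORF.

    A single window when one read pair can span the whole ORF with a
    mergeable overlap; otherwise two windows sharing ``overlap`` nucleotides
    (rounded to codon boundaries), mirroring a two-amplicon MiSeq layout.
    """
    if fwd_len + rev_len - 11 >= orf_len:
        return (AmpliconWindow(0, orf_len),)
    end1 = 3 * round((orf_len + overlap) / 6)
    start2 = end1 - 3 * (overlap // 3)
    if end1 > min(fwd_len + rev_len - 11, orf_len) or orf_len - start2 > fwd_len + rev_len - 11:
        raise ValueError("ORF too long for a two-amplicon layout at these read lengths")
    if end1 == orf_len - start2:  # equal lengths break length-based anchoring
        end1 += 3
        start2 += 3
    return (AmpliconWindow(0, end1), AmpliconWindow(start2, orf_len))


def _variant_orf_matrix(truth: SyntheticTruth) -> tuple[list[tuple[int, str]], np.ndarray]:
    """Encoded ORF of each pool variant (wild type first), one row each.

    Mutant codons are the lexicographically first codon for the target
    amino acid, so DNA construction is deterministic.
    """
    keys = [WT_KEY] + sorted(truth.variant_freqs)
    wt_row = encode(truth.wt.nt)
    mat = np.tile(wt_row, (len(keys), 1))
    for row, (pos, aa) in enumerate(keys[1:], start=1):
        codon = encode(AA_TO_CODON[aa])
        mat[row, (pos - 1) * 3 : pos * 3] = codon
    return keys, mat


def simulate_reads(
    pool: dict[tuple[int, str], float],
    truth: SyntheticTruth,
    params: ReadSimParams,
    r1_path,
    r2_path,
    label: str = "lib",
) -> dict[str, int]:
    """Write paired FASTQ files sampled from a pool of variant frequencies.

    Read pairs are split evenly across the amplicon windows; per amplicon,
    variants are drawn multinomially, substitution errors are applied at
    ``params.error_rate``, and Phred scores come from a rounded truncated
    normal. Read ids carry the source variant (``pos=12 aa=K``) so that
    noiseless round-trips are verifiable. Returns sampled-pair tallies per
    amplicon.
    """
    rng = np.random.default_rng(params.seed)
    windows = params.resolve_amplicons(len(truth.wt.nt))
    keys, orfs = _variant_orf_matrix(truth)
    freqs = np.array([pool.get(k, 0.0) for k in keys], dtype=np.float64)
    freqs = freqs / freqs.sum()

    per_amp = [params.depth // len(windows)] * len(windows)
    per_amp[0] += params.depth - sum(per_amp)

    tallies: dict[str, int] = {}
    with open(r1_path, "w") as h1, open(r2_path, "w") as h2:
        for w_idx, (window, n_pairs) in enumerate(zip(windows, per_amp)):
            counts = rng.multinomial(n_pairs, freqs)
            variant_idx = np.repeat(np.arange(len(keys)), counts)
            rng.shuffle(variant_idx)
            amp = orfs[variant_idx][:, window.start : window.end]
            fl = min(params.fwd_len, window.length)
            rl = min(params.rev_len, window.length)
            fwd = amp[:, :fl].copy()
            rev = (3 - amp[:, window.length - rl :][:, ::-1]).copy()  # revcomp
            for mat in (fwd, rev):
                err = rng.random(mat.shape) < params.error_rate
                shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
                mat[err] = (mat[err] + shift[err]) % 4
            quals = []
            for mat in (fwd, rev):
                q = np.rint(rng.normal(params.phred_mean, params.phred_sd, mat.shape))
                quals.append(np.clip(q, params.phred_floor, 41).astype(np.uint8))
            drop = (
                rng.random(n_pairs) < params.indel_rate
                if params.indel_rate > 0
                else np.zeros(n_pairs, dtype=bool)
            )
            for i in range(n_pairs):
                pos, aa = keys[variant_idx[i]]
                rid = f"{label}:amp{w_idx}:{i} pos={pos} aa={aa}"
                f_seq, f_q = fwd[i], quals[0][i]
                r_seq, r_q = rev[i], quals[1][i]
                if drop[i]:  # single-base deletion in the forward read
                    cut = rng.integers(0, len(f_seq))
                    f_seq = np.delete(f_seq, cut)
                    f_q = np.delete(f_q, cut)
                h1.write(
                    f"@{rid}\n{decode(f_seq)}\n+\n{(f_q + 33).tobytes().decode('ascii')}\n"
                )
                h2.write(
                    f"@{rid}\n{decode(r_seq)}\n+\n{(r_q + 33).tobytes().decode('ascii')}\n"
                )
            tallies[f"amp{w_idx}"] = int(n_pairs)
    return tallies
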
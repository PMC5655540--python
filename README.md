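# ssmflow

Tools for engineering small-molecule binder proteins at the bench-analysis
level: site-saturation mutagenesis (SSM) library design, paired-end NGS read
processing, single-mutant variant counting, log2 enrichment analysis with
low-count masking, a ground-truth read simulator, and two
structural-preparation utilities (idealized ligand hydration and design-pose
filtering with Shrake–Rupley dSASA).

## Modules

| Module | What it does |
| --- | --- |
| `ssmflow.library_design` | Enumerate the position × amino-acid SSM space (e.g. 184 × 20 = 3680 for a 185-residue ORF without its start Met), expand degenerate codons (NNK = 32 codons → 20 aa + 1 stop), design NNK primer sets for two-step overlap PCR. |
| `ssmflow.read_processing` | Merge R1/R2 read pairs by exhaustive ungapped overlap scoring (min overlap 11, mismatch ≤ 10%, higher-Phred base wins disagreements), filter on average Phred ≥ 18 and minimum per-base Phred ≥ 12. |
| `ssmflow.variant_counting` | Translate merged reads, classify WT / single mutant / multi / indel / untranslatable, accumulate the position × mutation-type count matrix (20 aa + stop columns, wild-type identity cells flagged). |
| `ssmflow.enrichment` | Mutation probabilities (counts over the grand total across positions and the 21 mutation types), E = log2(p_selected / p_naive) with `> min_count` (default 15) masking on the naive library, masked-heat-map rendering (red = enrichment, green = depletion, grey = insufficient data). |
| `ssmflow.synthetic_data` | Deterministic wild-type ORFs, uniform single-mutant pools with known per-round fitness, frequency-proportional selection dynamics, and MiSeq-like paired FASTQ simulation (305/295 nt reads, substitution errors, truncated-normal Phred model). |
| `ssmflow.ligand_prep` | Tertiary-amine detection, water-oxygen placement at 3.0 Å / 109° (fourth tetrahedral vertex) and 3.0 Å / 120° in the carbonyl sp2 plane, rotatable-bond counting (acyclic single bonds between non-terminal heavy atoms, amide C–N excluded). |
| `ssmflow.pose_filter` | Top-k pose selection per scaffold, the design filter cascade (SC > 0.5, IFE < −10, dSASA ≥ 0.8, restraint ≤ 5, pocket RMSD < 1, ddG < −10, negative field signs) with per-filter attrition, and Shrake–Rupley SASA / buried-fraction computation. |

## CLI

Each stage is a subcommand of `ssmflow` and also a standalone script:

```bash
simulate --length 185 --depth 200000 --rounds 4 --seed 0 --out-dir sim/
merge-reads --r1 sim/naive_R1.fastq --r2 sim/naive_R2.fastq --out naive_merged.fastq
count-variants --merged naive_merged.fastq --wt sim/wt.fasta --label naive
enrich --naive naive.counts.tsv --selected round4.counts.tsv --wt sim/wt.fasta --min-count 15
design-library --orf sim/wt.fasta --flank 18
hydrate-ligand --in ligand.sdf --out ligand_hydrated.sdf
filter-poses --scores poses.tsv
dsasa --ligand lig.pdb --env complex.pdb
```

## Notes

- The merge step chooses the overlap offset maximizing matched bases over
  *all* offsets; exact ties are rejected as `ambiguous` rather than broken
  arbitrarily, and rejection reasons are logged.
- Enrichment cells are masked explicitly (`LOW_COUNT`, `WT_CELL`,
  `NO_DATA`) instead of being numerically faked; the low-count mask applies
  to the naive library by default and optionally to the selected one.
- All simulator randomness flows from explicit integer seeds; the same seed
  reproduces byte-identical FASTQ output.
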
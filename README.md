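# splitfuse

Detection of candidate fusion transcripts from single-end (or paired-end,
pooled as single-end) RNA-Seq reads by **pseudo paired-end read splitting**:

1. Full-length reads (>=50 nt) are aligned to a coding reference
   transcriptome; reads that align are discarded as normal transcripts.
2. Each unaligned read is split into a pseudo read pair — its first *n5* and
   last *n3* bases (fractions of read length, default 0.4, max 0.5) — with ids
   suffixed `/1` and `/2`. A per-position quality profile is also emitted.
3. The pseudo mates are aligned independently to the coding reference
   (built-in deterministic seed aligner: ungapped, end-to-end, either strand,
   <=2 mismatches in the first 28 bases and <=2 overall).
4. Mates are reunited by parent id and passed through a false-positive filter
   cascade: same-gene pairs (4A), pairs with an unaligned mate (4B), paralog
   pairs (4C, optional), antisense-overlapping gene pairs (4D, optional), an
   exact insert-geometry test requiring the distances to the fusion-abutting
   exon boundaries to sum to the unsequenced gap (4E), and an all-hits
   multi-mapping check against the coding and non-coding references that
   removes shared-exon artefacts (4F).
5. Surviving evidence is merged into genomic **alignment blocks** per gene;
   block combinations overlapping repeats of the same class are dropped
   (optional), the nearest canonical exon to each block's junction-side
   extremity is resolved, candidates below a minimum read count are removed,
   and each candidate is categorised (INTERCHROMOSOMAL / INTRACHROMOSOMAL /
   POTENTIAL_READTHROUGH / INVERSION).

The package also includes a read **simulator** (synthetic multi-exon
transcriptomes with optional high-identity gene families, planted
single-exon-to-single-exon fusion junction reads with a minimum overhang,
strand randomisation and random junk reads) and the matching
**sensitivity/PPV evaluation**, including synonymous-fusion accounting.

## Inputs

A *reference directory* containing:

| file | required | contents |
| --- | --- | --- |
| `coding.fa` | yes | coding transcript sequences, one record per transcript |
| `annotation.gtf` | yes | exon features with `gene_id`, `transcript_id`, `exon_id`, strand |
| `noncoding.fa` | no | non-coding transcripts (used by the step-4F check) |
| `paralogs.tsv` | no | two gene-id columns, unordered paralog pairs |
| `repeats.bed` | no | BED (0-based starts) with a repeat-class column |

FASTA record ids must match GTF `transcript_id`s. All reported coordinates
are 1-based inclusive.

## CLI

```sh
# end-to-end run (SE; add --fastq2 for PE pooled as SE)
splitfuse run --fastq reads.fastq --reference-dir ref/ --out results/ \
    --min-reads 4 --pseudo-frac-5 0.4 --pseudo-frac-3 0.4

# simulate a dataset with planted fusions
splitfuse simulate --out sim/ --seed 1 --genes 300 --fusions 55

# score a run against the simulation truth
splitfuse evaluate --summary results/summary.tsv --truth sim/truth.tsv \
    --families sim/reference/families.tsv --out eval.tsv

# regenerate the breakpoint alignment for one candidate, by gene names
splitfuse inspect GENE0001 GENE0002 --run-dir results/ --reference-dir ref/
```

Filters can be disabled with `--no-paralog-filter`, `--no-antisense-filter`,
`--no-repeat-filter`; `--multimap-drop-candidate` switches step 4F from
read-level to candidate-level removal. An external SAM-producing aligner can
replace the built-in one via `--aligner external --sam-full x.sam
--sam-pseudo y.sam`. All flags can also be given in a `key=value` file passed
with `--config`.

Outputs in the run directory: `summary.tsv` (ranked candidates),
`isoforms.tsv` (per-isoform blocks, nearest exons and boundary distances),
`evidence.fa` (pseudo mates + parent reads per isoform), `breakpoints.txt`
(reads laid across each junction window with a three-frame translation),
`filter_log.tsv` (one row per filtered read with its stage flag),
`stats.tsv` (per-stage read accounting; rows reconcile to the input count),
`quality_profile.tsv`, `pseudo_reads.fastq`, step-1/step-3 SAM files, and
`candidates.json` (machine-readable, used by `inspect`).

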
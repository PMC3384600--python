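"""Shared toy-reference fixtures.

Everything is generated programmatically: a small two-chromosome genome, two
plus/minus-strand multi-exon genes with hand-checkable coordinates, and a
helper for building stores directly from exon layouts.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from splitfuse.annotation import (
    AnnotationStore,
    Exon,
    Gene,
    Transcript,
    load_reference,
)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(42)
    return {"chrA": random_seq(rng, 20_000), "chrB": random_seq(rng, 20_000)}


# exon layouts: (exon_id, start, end) in genomic order
GA_EXONS = [("EA1", 1001, 1100), ("EA2", 1301, 1450)]  # + strand, chrA
GB_EXONS = [("EB2", 5001, 5120), ("EB1", 5401, 5500)]  # - strand, chrA
GC_EXONS = [("EC1", 2001, 2200)]  # + strand, chrB


def splice(genome: dict[str, str], chrom: str, exons, strand: int) -> str:
    """Independent hand-splice: concatenate exon chunks 5'->3'."""
    chunks = [genome[chrom][s - 1 : e] for _, s, e in exons]
    if strand > 0:
        return "".join(chunks)
    return "".join(reverse_complement(c) for c in reversed(chunks))


def build_gene(
    gene_id: str,
    transcript_id: str,
    chrom: str,
    strand: int,
    exon_coords,
    genome: dict[str, str],
    biotype: str = "coding",
) -> tuple[Gene, Transcript, dict[str, Exon]]:
    exons_genomic = [Exon(eid, chrom, s, e, strand) for eid, s, e in exon_coords]
    ordered = exons_genomic if strand > 0 else exons_genomic[::-1]
    seq = splice(genome, chrom, exon_coords, strand)
    tx = Transcript(transcript_id, gene_id, ordered, biotype, seq)
    gene = Gene(
        gene_id,
        gene_id,
        chrom,
        strand,
        min(e.genomic_start for e in ordered),
        max(e.genomic_end for e in ordered),
        [transcript_id],
    )
    return gene, tx, {e.exon_id: e for e in ordered}


def build_store(genome: dict[str, str], specs, **store_kwargs) -> AnnotationStore:
    """specs: iterable of (gene_id, transcript_id, chrom, strand, exon_coords[, biotype])."""
    genes, transcripts, exons = {}, {}, {}
    for spec in specs:
        gene, tx, ex = build_gene(*spec, genome=genome) if len(spec) == 5 else build_gene(
            *spec[:5], genome=genome, biotype=spec[5]
        )
        genes[gene.gene_id] = gene
        transcripts[tx.transcript_id] = tx
        exons.update(ex)
    return AnnotationStore(genes, transcripts, exons, **store_kwargs)


@pytest.fixture(scope="session")
def toy_store(toy_genome) -> AnnotationStore:
    return build_store(
        toy_genome,
        [
            ("GA", "TA", "chrA", 1, GA_EXONS),
            ("GB", "TB", "chrA", -1, GB_EXONS),
            ("GC", "TC", "chrB", 1, GC_EXONS),
        ],
    )


def write_toy_reference(tmp_path, toy_genome):
    """Write the toy annotation as GTF + FASTA flat files; returns their paths."""
    gtf_lines = []

    def emit(gene_id, tid, chrom, strand, exon_coords):
        ordered = exon_coords if strand > 0 else exon_coords[::-1]
        for number, (eid, s, e) in enumerate(ordered, start=1):
            attrs = (
                f'gene_id "{gene_id}"; transcript_id "{tid}"; '
                f'exon_number "{number}"; exon_id "{eid}"; '
                f'gene_name "{gene_id}"; gene_biotype "protein_coding";'
            )
            gtf_lines.append(
                f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{'+' if strand > 0 else '-'}\t.\t{attrs}"
            )

    emit("GA", "TA", "chrA", 1, GA_EXONS)
    emit("GB", "TB", "chrA", -1, GB_EXONS)
    emit("GC", "TC", "chrB", 1, GC_EXONS)
    gtf = tmp_path / "annotation.gtf"
    gtf.write_text("\n".join(gtf_lines) + "\n")

    fasta = tmp_path / "coding.fa"
    records = [
        ("TA", splice(toy_genome, "chrA", GA_EXONS, 1)),
        ("TB", splice(toy_genome, "chrA", GB_EXONS, -1)),
        ("TC", splice(toy_genome, "chrB", GC_EXONS, 1)),
    ]
    fasta.write_text("".join(f">{tid}\n{seq}\n" for tid, seq in records))
    return gtf, fasta


@pytest.fixture()
def toy_reference_files(tmp_path, toy_genome):
    return write_toy_reference(tmp_path, toy_genome)


@pytest.fixture()
def toy_loaded_store(toy_reference_files):
    gtf, fasta = toy_reference_files
    return load_reference(coding_fasta=fasta, annotation_gtf=gtf)
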
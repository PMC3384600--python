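"""Output files: summary/isoform tables, read evidence, filter log, statistics,
and the plain-text breakpoint alignment with three-frame translation."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Seq import Seq, reverse_complement

from .annotation import AnnotationStore
from .blocks import FusionCandidate, Isoform
from .filters import EvidencePair

SUMMARY_COLUMNS = [
    "Index Number",
    "G1_Ensembl_HGNC_ID",
    "G1_chromosome",
    "G2_Ensembl_HGNC_ID",
    "G2_chromosome",
    "totalreads",
    "G1_blocks",
    "G2_blocks",
    "isoforms",
    "category",
]

ISOFORM_COLUMNS = [
    "G1_Ensembl_HGNC_ID",
    "G1_chromosome",
    "G2_Ensembl_HGNC_ID",
    "G2_chromosome",
    "isoreads",
    "totalreads",
    "G1_block",
    "G1_exon",
    "G1_expos",
    "G1_str",
    "G2_block",
    "G2_exon",
    "G2_expos",
    "G2_str",
]

FILTER_LOG_COLUMNS = ["read_id", "stage", "g1", "g2", "hit1", "hit2"]

BREAKPOINT_FLANK = 30


def rank_candidates(candidates: Iterable[FusionCandidate]) -> list[FusionCandidate]:
    """Evidence-strength ranking: totalreads descending, then G1 id."""
    return sorted(candidates, key=lambda c: (-c.totalreads, c.g1, c.g2))


def write_summary(
    candidates: Iterable[FusionCandidate], store: AnnotationStore, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SUMMARY_COLUMNS)
        for index, cand in enumerate(rank_candidates(candidates), start=1):
            gene1, gene2 = store.gene(cand.g1), store.gene(cand.g2)
            writer.writerow(
                [
                    index,
                    gene1.label,
                    gene1.chromosome,
                    gene2.label,
                    gene2.chromosome,
                    cand.totalreads,
                    cand.g1_blocks,
                    cand.g2_blocks,
                    len(cand.isoforms),
                    ",".join(cand.categories),
                ]
            )


def write_isoforms(
    candidates: Iterable[FusionCandidate], store: AnnotationStore, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ISOFORM_COLUMNS)
        for cand in rank_candidates(candidates):
            gene1, gene2 = store.gene(cand.g1), store.gene(cand.g2)
            for iso in cand.isoforms:
                writer.writerow(
                    [
                        gene1.label,
                        gene1.chromosome,
                        gene2.label,
                        gene2.chromosome,
                        iso.isoreads,
                        cand.totalreads,
                        iso.g1_block.coords,
                        iso.g1_exon,
                        iso.g1_expos,
                        gene1.strand,
                        iso.g2_block.coords,
                        iso.g2_exon,
                        iso.g2_expos,
                        gene2.strand,
                    ]
                )


def write_read_evidence(
    candidates: Iterable[FusionCandidate],
    evidence_by_read: Mapping[str, EvidencePair],
    path: str | Path,
) -> None:
    """FASTA of pseudo mates and parent reads, grouped per candidate isoform."""
    with open(path, "w") as fh:
        for cand in rank_candidates(candidates):
            for iso_index, iso in enumerate(cand.isoforms, start=1):
                tag = f"fusion={cand.g1}:{cand.g2} isoform={iso_index}"
                for rid in iso.read_ids:
                    ev = evidence_by_read[rid]
                    pair = ev.pair
                    fh.write(f">{pair.mate1.read_id} {tag}\n{pair.mate1.sequence}\n")
                    fh.write(f">{pair.mate2.read_id} {tag}\n{pair.mate2.sequence}\n")
                    parent = (
                        pair.mate1.sequence
                        + "N" * pair.gap_bp
                        + pair.mate2.sequence
                    )
                    fh.write(f">{pair.parent_id} {tag} parent\n{parent}\n")


def write_filter_log(pairs: Iterable[EvidencePair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FILTER_LOG_COLUMNS)
        for ev in pairs:
            if ev.live:
                continue
            hit1 = (
                f"{ev.hit5.transcript_id}:{ev.hit5.t_start}" if ev.hit5 else "-"
            )
            hit2 = (
                f"{ev.hit3.transcript_id}:{ev.hit3.t_start}" if ev.hit3 else "-"
            )
            writer.writerow(
                [ev.parent_id, ev.stage.value, ev.g1 or "-", ev.g2 or "-", hit1, hit2]
            )


def write_stats(counters: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\treads\n")
        for key, value in counters.items():
            fh.write(f"{key}\t{value}\n")


def translate_three_frames(sequence: str) -> tuple[str, str, str]:
    """Forward three-frame translation; '*' for stops, 'X' for N-containing
    codons, trailing partial codons dropped."""
    sequence = sequence.upper()
    frames = []
    for offset in range(3):
        sub = sequence[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        frames.append(str(Seq(sub).translate()))
    return tuple(frames)


@dataclass
class BreakpointReport:
    """Fig-2-style alignment of parent reads across a fusion junction."""

    g1_label: str
    g2_label: str
    isoform_index: int
    g1_exon: str
    g2_exon: str
    window: str  # last 30 bases of the G1 exon + first 30 of the G2 exon
    junction_offset: int  # 0-based column of the first G2 base in the window
    reads: list[tuple[str, int, str]]  # (read_id, offset vs window start, sequence)
    frames: tuple[str, str, str] | None
    in_frame: str | None  # translation in the annotated CDS frame, if known

    def render(self) -> str:
        pad = max([0] + [-offset for _, offset, _ in self.reads])
        lines = [
            f"# {self.g1_label} : {self.g2_label}  isoform {self.isoform_index}",
            f"# G1 exon {self.g1_exon} | G2 exon {self.g2_exon}",
            " " * (pad + self.junction_offset) + "v junction",
            " " * pad + self.window,
        ]
        for read_id, offset, seq in self.reads:
            lines.append(" " * (pad + offset) + seq + "  " + read_id)
        if self.in_frame is not None:
            lines.append(" " * pad + _spread_peptide(self.in_frame) + "  (in-frame)")
        elif self.frames is not None:
            for i, frame in enumerate(self.frames):
                lines.append(
                    " " * (pad + i) + _spread_peptide(frame) + f"  (frame +{i})"
                )
        return "\n".join(lines) + "\n"


def _spread_peptide(peptide: str) -> str:
    """Lay one amino-acid letter under the middle base of each codon."""
    return "".join(f" {aa} " for aa in peptide)


def breakpoint_alignment(
    candidate: FusionCandidate,
    isoform: Isoform,
    store: AnnotationStore,
    evidence_by_read: Mapping[str, EvidencePair],
    isoform_index: int = 1,
    flank: int = BREAKPOINT_FLANK,
) -> BreakpointReport:
    """Lay the supporting parent reads against the fused exon junction window.

    The window is the last ``flank`` bases of the G1 exon followed by the first
    ``flank`` bases of the G2 exon, both in transcript orientation. Each parent
    read (reverse-complemented when it was sequenced from the opposite strand)
    is placed so its G1/G2 split sits on the junction column.
    """
    g1_part = _exon_sequence(store, candidate.g1, isoform.g1_exon)[-flank:]
    g2_part = _exon_sequence(store, candidate.g2, isoform.g2_exon)[:flank]
    window = g1_part + g2_part
    junction_offset = len(g1_part)

    reads = []
    for rid in isoform.read_ids:
        ev = evidence_by_read[rid]
        pair = ev.pair
        parent = pair.mate1.sequence + "N" * pair.gap_bp + pair.mate2.sequence
        if ev.flipped:
            parent = reverse_complement(parent)
        n5 = len(ev.mate5.sequence)
        bases_g1 = n5 + (ev.d1 or 0)
        offset = junction_offset - bases_g1
        if offset + len(parent) <= 0 or offset >= len(window):
            continue  # read does not overlap the display window
        reads.append((rid, offset, parent))

    in_frame = None
    frames = translate_three_frames(window)
    cds_frame = _cds_frame_at_window(store, candidate.g1, isoform.g1_exon, flank)
    if cds_frame is not None:
        in_frame = frames[cds_frame]
        sub = window[cds_frame:]
        in_frame = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
        frames = None

    gene1, gene2 = store.gene(candidate.g1), store.gene(candidate.g2)
    return BreakpointReport(
        g1_label=gene1.label,
        g2_label=gene2.label,
        isoform_index=isoform_index,
        g1_exon=isoform.g1_exon,
        g2_exon=isoform.g2_exon,
        window=window,
        junction_offset=junction_offset,
        reads=reads,
        frames=frames,
        in_frame=in_frame,
    )


def _exon_sequence(store: AnnotationStore, gene_id: str, exon_id: str) -> str:
    """Exon sequence in transcript orientation, sliced from a hosting transcript."""
    gene = store.gene(gene_id)
    for tid in gene.transcript_ids:
        tx = store.transcript(tid)
        for ex, lo, hi in tx.exon_spans():
            if ex.exon_id == exon_id:
                return tx.sequence[lo - 1 : hi]
    raise ValueError(f"exon {exon_id} not found in gene {gene_id}")


def _cds_frame_at_window(
    store: AnnotationStore, gene_id: str, exon_id: str, flank: int
) -> int | None:
    """Reading-frame offset of the window start within the G1 transcript's CDS."""
    gene = store.gene(gene_id)
    for tid in gene.transcript_ids:
        tx = store.transcript(tid)
        if tx.cds_t_start is None:
            continue
        for ex, lo, hi in tx.exon_spans():
            if ex.exon_id == exon_id:
                window_start = max(hi - flank + 1, lo)
                phase = (window_start - tx.cds_t_start) % 3
                return (3 - phase) % 3
    return None


def write_breakpoint_reports(
    candidates: Iterable[FusionCandidate],
    store: AnnotationStore,
    evidence_by_read: Mapping[str, EvidencePair],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for cand in rank_candidates(candidates):
            for index, iso in enumerate(cand.isoforms, start=1):
                report = breakpoint_alignment(
                    cand, iso, store, evidence_by_read, isoform_index=index
                )
                fh.write(report.render())
                fh.write("\n")
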
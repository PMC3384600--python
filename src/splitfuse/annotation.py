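"""Reference transcriptome annotation and transcript/genome coordinate arithmetic.

The reference is supplied as flat files: a coding-transcript FASTA (one record
per transcript), an optional non-coding FASTA, a GTF with exon features, and
optional side-car tables for paralog pairs (TSV) and repeat intervals (BED).
All public coordinates are 1-based inclusive; BED starts are converted on load.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from Bio import SeqIO
from Bio.Seq import reverse_complement
from gffutils.feature import feature_from_line

CODING = "coding"
NONCODING = "noncoding"

#: side arguments for :meth:`AnnotationStore.distance_to_exon_boundary`
EXON_3P_END = "3p_end"
EXON_5P_START = "5p_start"


class AnnotationError(Exception):
    """Raised for malformed or inconsistent reference inputs."""


@dataclass(frozen=True)
class Exon:
    exon_id: str
    chromosome: str
    genomic_start: int
    genomic_end: int
    strand: int  # +1 / -1

    def __post_init__(self) -> None:
        if self.genomic_start > self.genomic_end:
            raise AnnotationError(
                f"exon {self.exon_id}: start {self.genomic_start} > end {self.genomic_end}"
            )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1


@dataclass
class Transcript:
    """A spliced transcript; ``exons`` are ordered 5'->3' in transcript orientation."""

    transcript_id: str
    gene_id: str
    exons: list[Exon]
    biotype: str
    sequence: str
    cds_t_start: int | None = None  # 1-based transcript coordinate of CDS start, if annotated

    # cumulative transcript-coordinate span (t_lo, t_hi) per exon, filled in __post_init__
    _spans: list[tuple[int, int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        pos = 1
        self._spans = []
        for ex in self.exons:
            self._spans.append((pos, pos + ex.length - 1))
            pos += ex.length
        if self.sequence and len(self.sequence) != self.length:
            raise AnnotationError(
                f"transcript {self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= summed exon length {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(ex.length for ex in self.exons)

    @property
    def strand(self) -> int:
        return self.exons[0].strand

    @property
    def chromosome(self) -> str:
        return self.exons[0].chromosome

    def exon_spans(self) -> list[tuple[Exon, int, int]]:
        return [(ex, lo, hi) for ex, (lo, hi) in zip(self.exons, self._spans)]


@dataclass
class Gene:
    gene_id: str
    common_name: str
    chromosome: str
    strand: int
    span_start: int
    span_end: int
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.gene_id} ({self.common_name})"


@dataclass(frozen=True)
class RepeatAnnotation:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"repeat interval {self.start}>{self.end}")


class GenePairGeometry(NamedTuple):
    same_chromosome: bool
    same_strand: bool
    gap_bp: int | None  # None when chromosomes differ; 0 when spans overlap
    spans_overlap_opposite_strand: bool


class AnnotationStore:
    """Genes, transcripts and exons indexed by id, with coordinate maps."""

    def __init__(
        self,
        genes: dict[str, Gene],
        transcripts: dict[str, Transcript],
        exons: dict[str, Exon],
        paralog_pairs: set[frozenset[str]] | None = None,
        repeats: Iterable[RepeatAnnotation] | None = None,
    ):
        self.genes = genes
        self.transcripts = transcripts
        self.exons = exons
        self.paralog_pairs = paralog_pairs or set()
        self.repeats: dict[str, list[RepeatAnnotation]] = defaultdict(list)
        for rep in repeats or ():
            self.repeats[rep.chromosome].append(rep)
        for chrom in self.repeats:
            self.repeats[chrom].sort(key=lambda r: (r.start, r.end))
        self._validate()

    def _validate(self) -> None:
        for tx in self.transcripts.values():
            if tx.gene_id not in self.genes:
                raise AnnotationError(
                    f"transcript {tx.transcript_id} references unknown gene {tx.gene_id}"
                )
        claimed = {ex.exon_id for tx in self.transcripts.values() for ex in tx.exons}
        orphans = set(self.exons) - claimed
        if orphans:
            raise AnnotationError(f"exons belong to no transcript: {sorted(orphans)[:5]}")

    # -- lookups ---------------------------------------------------------

    def transcript(self, transcript_id: str) -> Transcript:
        try:
            return self.transcripts[transcript_id]
        except KeyError:
            raise AnnotationError(f"unknown transcript id {transcript_id!r}") from None

    def gene(self, gene_id: str) -> Gene:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene id {gene_id!r}") from None

    def gene_of_transcript(self, transcript_id: str) -> str:
        return self.transcript(transcript_id).gene_id

    def gene_by_name(self, name: str) -> Gene:
        for g in self.genes.values():
            if g.common_name == name or g.gene_id == name:
                return g
        raise AnnotationError(f"no gene with name or id {name!r}")

    def sequences(self, biotype: str) -> dict[str, str]:
        return {
            tid: tx.sequence
            for tid, tx in self.transcripts.items()
            if tx.biotype == biotype
        }

    def coding_sequences(self) -> dict[str, str]:
        return self.sequences(CODING)

    def noncoding_sequences(self) -> dict[str, str]:
        return self.sequences(NONCODING)

    def gene_exons(self, gene_id: str) -> list[Exon]:
        gene = self.gene(gene_id)
        seen: dict[str, Exon] = {}
        for tid in gene.transcript_ids:
            for ex in self.transcript(tid).exons:
                seen.setdefault(ex.exon_id, ex)
        return list(seen.values())

    # -- coordinate arithmetic ------------------------------------------

    def transcript_to_genomic(
        self, transcript_id: str, t_start: int, t_end: int
    ) -> list[tuple[str, int, int, int]]:
        """Map a transcript interval to maximal per-exon genomic segments.

        Returns segments in transcript order as ``(chromosome, genomic_start,
        genomic_end, strand)`` with ``genomic_start <= genomic_end``.
        """
        tx = self.transcript(transcript_id)
        if not (1 <= t_start <= t_end <= tx.length):
            raise AnnotationError(
                f"interval {t_start}-{t_end} out of range for transcript "
                f"{transcript_id} (length {tx.length})"
            )
        segments = []
        for ex, lo, hi in tx.exon_spans():
            if hi < t_start or lo > t_end:
                continue
            off_lo = max(t_start, lo) - lo
            off_hi = min(t_end, hi) - lo
            if ex.strand > 0:
                g_lo = ex.genomic_start + off_lo
                g_hi = ex.genomic_start + off_hi
            else:
                g_lo = ex.genomic_end - off_hi
                g_hi = ex.genomic_end - off_lo
            segments.append((ex.chromosome, g_lo, g_hi, ex.strand))
        return segments

    def genomic_to_transcript(self, transcript_id: str, genomic_pos: int) -> int:
        tx = self.transcript(transcript_id)
        for ex, lo, _hi in tx.exon_spans():
            if ex.genomic_start <= genomic_pos <= ex.genomic_end:
                if ex.strand > 0:
                    return lo + (genomic_pos - ex.genomic_start)
                return lo + (ex.genomic_end - genomic_pos)
        raise AnnotationError(
            f"genomic position {genomic_pos} not exonic in transcript {transcript_id}"
        )

    def exon_at(self, transcript_id: str, t_pos: int) -> tuple[Exon, int, int]:
        tx = self.transcript(transcript_id)
        for ex, lo, hi in tx.exon_spans():
            if lo <= t_pos <= hi:
                return ex, lo, hi
        raise AnnotationError(
            f"position {t_pos} out of range for transcript {transcript_id}"
        )

    def distance_to_exon_boundary(
        self, transcript_id: str, t_pos: int, side: str
    ) -> tuple[str, int]:
        """Distance (transcript bp) from ``t_pos`` to a boundary of its exon."""
        ex, lo, hi = self.exon_at(transcript_id, t_pos)
        if side == EXON_3P_END:
            return ex.exon_id, hi - t_pos
        if side == EXON_5P_START:
            return ex.exon_id, t_pos - lo
        raise ValueError(f"side must be {EXON_3P_END!r} or {EXON_5P_START!r}")

    def gene_pair_geometry(self, g1: str, g2: str) -> GenePairGeometry:
        a, b = self.gene(g1), self.gene(g2)
        same_chrom = a.chromosome == b.chromosome
        same_strand = a.strand == b.strand
        gap: int | None = None
        overlap_opposite = False
        if same_chrom:
            overlap = min(a.span_end, b.span_end) - max(a.span_start, b.span_start)
            gap = 0 if overlap >= 0 else -overlap - 1
            overlap_opposite = overlap >= 0 and not same_strand
        return GenePairGeometry(same_chrom, same_strand, gap, overlap_opposite)

    def is_paralog_pair(self, g1: str, g2: str) -> bool:
        return frozenset((g1, g2)) in self.paralog_pairs

    def repeat_classes_overlapping(self, chromosome: str, start: int, end: int) -> set[str]:
        reps = self.repeats.get(chromosome, [])
        starts = [r.start for r in reps]
        # repeats whose start is <= end are the only possible overlaps
        classes = set()
        for rep in reps[: bisect_right(starts, end)]:
            if rep.end >= start:
                classes.add(rep.repeat_class)
        return classes


# -- flat-file loading ----------------------------------------------------

_GTF_FIELDS = 9


def _parse_gtf(path: Path) -> list:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != _GTF_FIELDS - 1:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: expected {_GTF_FIELDS} "
                    f"tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils is permissive
                raise AnnotationError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feat.strand not in "+-":
                raise AnnotationError(
                    f"{path}: GTF line {lineno}: strand must be '+' or '-'"
                )
            features.append((lineno, feat))
    return features


def _attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def _read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AnnotationError(f"{path}: duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def load_reference(
    coding_fasta: str | Path,
    annotation_gtf: str | Path,
    noncoding_fasta: str | Path | None = None,
    paralog_tsv: str | Path | None = None,
    repeat_bed: str | Path | None = None,
) -> AnnotationStore:
    """Load an :class:`AnnotationStore` from flat reference files.

    FASTA record ids must match the GTF's ``transcript_id`` attributes; a FASTA
    record with no annotation, a missing sequence, or a duplicated transcript id
    is a load error naming the offending id.
    """
    coding_seqs = _read_fasta(Path(coding_fasta))
    noncoding_seqs = _read_fasta(Path(noncoding_fasta)) if noncoding_fasta else {}
    dup = set(coding_seqs) & set(noncoding_seqs)
    if dup:
        raise AnnotationError(f"transcript ids in both references: {sorted(dup)[:5]}")
    all_seqs = {**coding_seqs, **noncoding_seqs}

    features = _parse_gtf(Path(annotation_gtf))
    tx_exons: dict[str, list[tuple[int | None, Exon]]] = defaultdict(list)
    tx_meta: dict[str, dict] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    exon_index: dict[str, Exon] = {}

    for lineno, feat in features:
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gene_id = _attr(feat, "gene_id")
        tid = _attr(feat, "transcript_id")
        if not gene_id or not tid:
            raise AnnotationError(
                f"{annotation_gtf}: line {lineno}: {feat.featuretype} feature "
                f"missing gene_id/transcript_id"
            )
        if feat.featuretype == "CDS":
            tx_cds[tid].append((feat.start, feat.end))
            continue
        strand = 1 if feat.strand == "+" else -1
        exon_id = _attr(feat, "exon_id") or f"{tid}:exon{len(tx_exons[tid]) + 1}"
        exon = Exon(exon_id, feat.seqid, feat.start, feat.end, strand)
        prior = exon_index.get(exon_id)
        if prior is not None and prior != exon:
            raise AnnotationError(
                f"{annotation_gtf}: line {lineno}: exon id {exon_id!r} redefined "
                f"with different coordinates"
            )
        exon_index[exon_id] = exon
        number = _attr(feat, "exon_number")
        tx_exons[tid].append((int(number) if number else None, exon))
        meta = tx_meta.setdefault(
            tid,
            {
                "gene_id": gene_id,
                "gene_name": _attr(feat, "gene_name") or gene_id,
                "biotype": _attr(feat, "transcript_biotype")
                or _attr(feat, "gene_biotype"),
            },
        )
        if meta["gene_id"] != gene_id:
            raise AnnotationError(
                f"transcript {tid} assigned to multiple genes "
                f"({meta['gene_id']}, {gene_id})"
            )

    unannotated = set(all_seqs) - set(tx_meta)
    if unannotated:
        raise AnnotationError(
            f"FASTA records with no GTF annotation: {sorted(unannotated)[:5]}"
        )
    missing = set(tx_meta) - set(all_seqs)
    if missing:
        raise AnnotationError(
            f"annotated transcripts missing from FASTA: {sorted(missing)[:5]}"
        )

    transcripts: dict[str, Transcript] = {}
    genes: dict[str, Gene] = {}
    for tid, pairs in tx_exons.items():
        meta = tx_meta[tid]
        strand = pairs[0][1].strand
        if all(n is not None for n, _ in pairs):
            ordered = [ex for _, ex in sorted(pairs, key=lambda p: p[0])]
        else:
            ordered = [
                ex
                for _, ex in sorted(
                    pairs, key=lambda p: p[1].genomic_start, reverse=strand < 0
                )
            ]
        biotype = meta["biotype"]
        if biotype is None:
            biotype = NONCODING if tid in noncoding_seqs else CODING
            warnings.warn(
                f"transcript {tid} has no biotype attribute; defaulting to {biotype}",
                stacklevel=2,
            )
        else:
            biotype = CODING if biotype in ("protein_coding", CODING) else NONCODING
        tx = Transcript(tid, meta["gene_id"], ordered, biotype, all_seqs[tid])
        if tx_cds.get(tid):
            cds_left = min(lo for lo, _ in tx_cds[tid])
            cds_right = max(hi for _, hi in tx_cds[tid])
            g_start = cds_left if strand > 0 else cds_right
            try:
                tx.cds_t_start = _transcript_pos(tx, g_start)
            except AnnotationError:
                pass
        transcripts[tid] = tx
        gene = genes.get(meta["gene_id"])
        span_lo = min(ex.genomic_start for ex in ordered)
        span_hi = max(ex.genomic_end for ex in ordered)
        if gene is None:
            genes[meta["gene_id"]] = Gene(
                meta["gene_id"],
                meta["gene_name"],
                ordered[0].chromosome,
                strand,
                span_lo,
                span_hi,
                [tid],
            )
        else:
            gene.span_start = min(gene.span_start, span_lo)
            gene.span_end = max(gene.span_end, span_hi)
            gene.transcript_ids.append(tid)

    paralogs = _load_paralogs(Path(paralog_tsv)) if paralog_tsv else set()
    repeats = _load_repeats(Path(repeat_bed)) if repeat_bed else []
    return AnnotationStore(genes, transcripts, exon_index, paralogs, repeats)


def _transcript_pos(tx: Transcript, genomic_pos: int) -> int:
    for ex, (lo, _hi) in zip(tx.exons, tx._spans):
        if ex.genomic_start <= genomic_pos <= ex.genomic_end:
            if ex.strand > 0:
                return lo + (genomic_pos - ex.genomic_start)
            return lo + (ex.genomic_end - genomic_pos)
    raise AnnotationError(f"position {genomic_pos} not exonic in {tx.transcript_id}")


def _load_paralogs(path: Path) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}: line {lineno}: expected two gene ids")
            pairs.add(frozenset(fields[:2]))
    return pairs


def _load_repeats(path: Path) -> list[RepeatAnnotation]:
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected chrom/start/end/class"
                )
            chrom, start, end, rclass = fields[0], int(fields[1]), int(fields[2]), fields[3]
            repeats.append(RepeatAnnotation(chrom, start + 1, end, rclass))
    return repeats


def splice_from_genome(
    genome: Mapping[str, str], exons: Iterable[Exon]
) -> str:
    """Spliced transcript sequence (transcript orientation) from chromosome sequences."""
    parts = []
    for ex in exons:
        chunk = genome[ex.chromosome][ex.genomic_start - 1 : ex.genomic_end]
        parts.append(chunk if ex.strand > 0 else reverse_complement(chunk))
    return "".join(parts)
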
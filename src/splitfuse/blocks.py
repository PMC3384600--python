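"""Alignment-block construction, isoform resolution and fusion categorisation.

Evidence reads transposed to genomic coordinates are merged into "alignment
blocks" (connected components under >=1 bp interval overlap) per gene; each
supported (G1 block, G2 block) combination is one putative fusion isoform,
annotated with the nearest canonical exon boundary on the junction side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import AnnotationStore, Exon
from .filters import CandidatePair, EvidencePair, Stage

INTERCHROMOSOMAL = "INTERCHROMOSOMAL"
INTRACHROMOSOMAL = "INTRACHROMOSOMAL"
POTENTIAL_READTHROUGH = "POTENTIAL_READTHROUGH"
INVERSION = "INVERSION"

DEFAULT_READTHROUGH_DIST = 20_000


@dataclass
class AlignmentBlock:
    gene_id: str
    chromosome: str
    genomic_start: int
    genomic_end: int
    read_ids: list[str]
    junction_extremity: int = 0

    @property
    def coords(self) -> str:
        return f"{self.genomic_start}-{self.genomic_end}"


@dataclass
class Isoform:
    g1_block: AlignmentBlock
    g2_block: AlignmentBlock
    read_ids: list[str]
    g1_exon: str
    g1_expos: int
    g2_exon: str
    g2_expos: int

    @property
    def isoreads(self) -> int:
        return len(self.read_ids)


@dataclass
class FusionCandidate:
    pair: CandidatePair
    isoforms: list[Isoform] = field(default_factory=list)
    g1_blocks: int = 0
    g2_blocks: int = 0
    categories: list[str] = field(default_factory=list)

    @property
    def g1(self) -> str:
        return self.pair.g1

    @property
    def g2(self) -> str:
        return self.pair.g2

    @property
    def totalreads(self) -> int:
        return sum(iso.isoreads for iso in self.isoforms)


def _read_span(segments: list[tuple[str, int, int, int]]) -> tuple[str, int, int]:
    chroms = {seg[0] for seg in segments}
    if len(chroms) != 1:
        raise ValueError("evidence read spans multiple chromosomes")
    return (
        chroms.pop(),
        min(seg[1] for seg in segments),
        max(seg[2] for seg in segments),
    )


def _merge_blocks(
    gene_id: str, spans: list[tuple[str, str, int, int]]
) -> tuple[list[AlignmentBlock], dict[str, int]]:
    """Connected components of overlapping read intervals (>=1 shared base)."""
    blocks: list[AlignmentBlock] = []
    assignment: dict[str, int] = {}
    for chrom in sorted({s[1] for s in spans}):
        members = sorted(
            (s for s in spans if s[1] == chrom), key=lambda s: (s[2], s[3], s[0])
        )
        current: AlignmentBlock | None = None
        for read_id, _, lo, hi in members:
            if current is not None and lo <= current.genomic_end:
                current.genomic_end = max(current.genomic_end, hi)
                current.read_ids.append(read_id)
            else:
                current = AlignmentBlock(gene_id, chrom, lo, hi, [read_id])
                blocks.append(current)
            assignment[read_id] = len(blocks) - 1
    return blocks, assignment


def build_blocks(
    candidate: CandidatePair, store: AnnotationStore
) -> tuple[list[AlignmentBlock], list[AlignmentBlock], dict[tuple[int, int], list[str]]]:
    """Step 5A: merge genomic read footprints into per-gene alignment blocks.

    Returns the G1 blocks, the G2 blocks and a map from block-index combination
    to the ids of the parent reads supporting it.
    """
    g1_spans, g2_spans = [], []
    for ev in candidate.live_evidence:
        rid = ev.parent_id
        chrom1, lo1, hi1 = _read_span(ev.genomic1)
        chrom2, lo2, hi2 = _read_span(ev.genomic2)
        g1_spans.append((rid, chrom1, lo1, hi1))
        g2_spans.append((rid, chrom2, lo2, hi2))
    g1_blocks, assign1 = _merge_blocks(candidate.g1, g1_spans)
    g2_blocks, assign2 = _merge_blocks(candidate.g2, g2_spans)

    strand1 = store.gene(candidate.g1).strand
    strand2 = store.gene(candidate.g2).strand
    for blk in g1_blocks:  # junction side of G1 is its transcript-3' edge
        blk.junction_extremity = blk.genomic_end if strand1 > 0 else blk.genomic_start
    for blk in g2_blocks:  # junction side of G2 is its transcript-5' edge
        blk.junction_extremity = blk.genomic_start if strand2 > 0 else blk.genomic_end

    combinations: dict[tuple[int, int], list[str]] = {}
    for ev in candidate.live_evidence:
        key = (assign1[ev.parent_id], assign2[ev.parent_id])
        combinations.setdefault(key, []).append(ev.parent_id)
    return g1_blocks, g2_blocks, combinations


def filter_repeat_blocks(
    combinations: dict[tuple[int, int], list[str]],
    g1_blocks: list[AlignmentBlock],
    g2_blocks: list[AlignmentBlock],
    store: AnnotationStore,
    enabled: bool = True,
) -> tuple[dict[tuple[int, int], list[str]], list[str]]:
    """Step 5B: drop block combinations whose two blocks overlap repeats of an
    identical class. Returns surviving combinations and the filtered read ids."""
    if not enabled or not store.repeats:
        return dict(combinations), []
    kept: dict[tuple[int, int], list[str]] = {}
    removed_reads: list[str] = []
    for key, read_ids in combinations.items():
        b1, b2 = g1_blocks[key[0]], g2_blocks[key[1]]
        classes1 = store.repeat_classes_overlapping(
            b1.chromosome, b1.genomic_start, b1.genomic_end
        )
        classes2 = store.repeat_classes_overlapping(
            b2.chromosome, b2.genomic_start, b2.genomic_end
        )
        if classes1 & classes2:
            removed_reads.extend(read_ids)
        else:
            kept[key] = read_ids
    return kept, removed_reads


def _nearest_exon(store: AnnotationStore, gene_id: str, extremity: int, side: str) -> tuple[str, int]:
    """Nearest canonical exon boundary to a block extremity.

    ``side`` "3p" compares against each exon's transcript-3' genomic edge,
    "5p" against the transcript-5' edge. Ties break on smallest exon id.
    """
    gene = store.gene(gene_id)
    best: tuple[int, str] | None = None
    for ex in store.gene_exons(gene_id):
        boundary = _exon_boundary(ex, gene.strand, side)
        dist = abs(extremity - boundary)
        key = (dist, ex.exon_id)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"gene {gene_id} has no exons")
    return best[1], best[0]


def _exon_boundary(exon: Exon, strand: int, side: str) -> int:
    if side == "3p":
        return exon.genomic_end if strand > 0 else exon.genomic_start
    return exon.genomic_start if strand > 0 else exon.genomic_end


def assign_exons(
    combination: tuple[int, int],
    read_ids: list[str],
    g1_blocks: list[AlignmentBlock],
    g2_blocks: list[AlignmentBlock],
    store: AnnotationStore,
) -> Isoform:
    """Step 5C: resolve the exon nearest each block's junction-side extremity."""
    b1, b2 = g1_blocks[combination[0]], g2_blocks[combination[1]]
    g1_exon, g1_expos = _nearest_exon(store, b1.gene_id, b1.junction_extremity, "3p")
    g2_exon, g2_expos = _nearest_exon(store, b2.gene_id, b2.junction_extremity, "5p")
    return Isoform(b1, b2, sorted(read_ids), g1_exon, g1_expos, g2_exon, g2_expos)


def resolve_candidate(
    candidate: CandidatePair,
    store: AnnotationStore,
    repeat_filter: bool = True,
    readthrough_dist: int = DEFAULT_READTHROUGH_DIST,
) -> FusionCandidate | None:
    """Steps 5A-5C + 5E for one candidate; None when no combination survives."""
    g1_blocks, g2_blocks, combinations = build_blocks(candidate, store)
    combinations, removed = filter_repeat_blocks(
        combinations, g1_blocks, g2_blocks, store, enabled=repeat_filter
    )
    if removed:
        removed_set = set(removed)
        for ev in candidate.evidence:
            if ev.live and ev.parent_id in removed_set:
                ev.flag(Stage.STEP5B_REPEAT)
    if not combinations:
        return None
    isoforms = [
        assign_exons(key, read_ids, g1_blocks, g2_blocks, store)
        for key, read_ids in sorted(combinations.items())
    ]
    isoforms.sort(key=lambda iso: (-iso.isoreads, iso.g1_exon, iso.g2_exon))
    used_g1 = {key[0] for key in combinations}
    used_g2 = {key[1] for key in combinations}
    fusion = FusionCandidate(
        pair=candidate,
        isoforms=isoforms,
        g1_blocks=len(used_g1),
        g2_blocks=len(used_g2),
    )
    fusion.categories = categorize(fusion, store, readthrough_dist)
    return fusion


def apply_min_reads(
    candidates: list[FusionCandidate], min_reads: int
) -> list[FusionCandidate]:
    """Step 5D: drop candidates evidenced by fewer than ``min_reads`` reads."""
    kept = []
    for cand in candidates:
        if cand.totalreads >= min_reads:
            kept.append(cand)
        else:
            for ev in cand.pair.evidence:
                if ev.live:
                    ev.flag(Stage.STEP5D_MINREADS)
    return kept


def categorize(
    candidate: FusionCandidate,
    store: AnnotationStore,
    readthrough_dist: int = DEFAULT_READTHROUGH_DIST,
) -> list[str]:
    """Step 5E category labels for a candidate gene pair."""
    geom = store.gene_pair_geometry(candidate.g1, candidate.g2)
    if not geom.same_chromosome:
        return [INTERCHROMOSOMAL]
    categories = []
    if geom.same_strand and geom.gap_bp is not None and geom.gap_bp <= readthrough_dist:
        categories.append(POTENTIAL_READTHROUGH)
    if not geom.same_strand:
        categories.append(INVERSION)
    categories.append(INTRACHROMOSOMAL)
    return categories
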
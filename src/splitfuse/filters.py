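"""False-positive filter cascade over reunited pseudo-pair alignments.

Each pseudo pair becomes an :class:`EvidencePair` carrying the hits of its two
mates. Filters run in a fixed order (same-gene, unaligned, paralog, antisense,
insert geometry, multi-mapping); a filtered pair is flagged with exactly one
stage flag so every read entering the cascade is accounted for once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .align import (
    REVERSE_COMPLEMENT,
    AlignmentHit,
    AlignmentResult,
    SeedAligner,
    align_all,
)
from .annotation import EXON_3P_END, EXON_5P_START, AnnotationStore
from .pseudo import Mate, PseudoPair


class Stage(str, Enum):
    STEP4A_SAME_GENE = "STEP4A_SAME_GENE"
    STEP4B_UNALIGNED = "STEP4B_UNALIGNED"
    STEP4C_PARALOG = "STEP4C_PARALOG"
    STEP4D_ANTISENSE = "STEP4D_ANTISENSE"
    STEP4E_GEOMETRY = "STEP4E_GEOMETRY"
    STEP4F_MULTIMAP = "STEP4F_MULTIMAP"
    STEP5B_REPEAT = "STEP5B_REPEAT"
    STEP5D_MINREADS = "STEP5D_MINREADS"


class FilterError(Exception):
    pass


@dataclass
class EvidencePair:
    """One pseudo pair with its mate hits, oriented 5'-gene-first.

    When both mates align reverse-complement the parent read was sequenced from
    the opposite strand of the putative fusion transcript, so the mate roles
    are swapped (``flipped``) to keep ``hit5`` on the fusion's 5' gene.
    """

    pair: PseudoPair
    hit5: AlignmentHit | None
    hit3: AlignmentHit | None
    mate5: Mate
    mate3: Mate
    g1: str | None
    g2: str | None
    flipped: bool = False
    strand_consistent: bool = True
    stage: Stage | None = None
    d1: int | None = None
    d2: int | None = None
    genomic1: list[tuple[str, int, int, int]] = field(default_factory=list)
    genomic2: list[tuple[str, int, int, int]] = field(default_factory=list)

    @property
    def live(self) -> bool:
        return self.stage is None

    @property
    def parent_id(self) -> str:
        return self.pair.parent_id

    def flag(self, stage: Stage) -> None:
        if self.stage is None:
            self.stage = stage


@dataclass
class CandidatePair:
    g1: str
    g2: str
    evidence: list[EvidencePair]

    @property
    def live_evidence(self) -> list[EvidencePair]:
        return [ev for ev in self.evidence if ev.live]


def reunite_and_assign(
    pseudo_alignments: AlignmentResult,
    pairs: Sequence[PseudoPair],
    store: AnnotationStore,
) -> list[EvidencePair]:
    """Reunite mate hits by parent id and resolve the gene of each hit."""
    out = []
    for pair in pairs:
        for mate in (pair.mate1, pair.mate2):
            if mate.read_id not in pseudo_alignments:
                raise FilterError(
                    f"mate {mate.read_id} missing from pseudo alignment result"
                )
        h1 = pseudo_alignments.hit(pair.mate1.read_id)
        h2 = pseudo_alignments.hit(pair.mate2.read_id)
        flipped = False
        strand_consistent = True
        if h1 and h2:
            rc1 = h1.aligned_strand == REVERSE_COMPLEMENT
            rc2 = h2.aligned_strand == REVERSE_COMPLEMENT
            if rc1 and rc2:
                flipped = True
            elif rc1 != rc2:
                strand_consistent = False
        if flipped:
            hit5, hit3 = h2, h1
            mate5, mate3 = pair.mate2, pair.mate1
        else:
            hit5, hit3 = h1, h2
            mate5, mate3 = pair.mate1, pair.mate2
        out.append(
            EvidencePair(
                pair=pair,
                hit5=hit5,
                hit3=hit3,
                mate5=mate5,
                mate3=mate3,
                g1=store.gene_of_transcript(hit5.transcript_id) if hit5 else None,
                g2=store.gene_of_transcript(hit3.transcript_id) if hit3 else None,
                flipped=flipped,
                strand_consistent=strand_consistent,
            )
        )
    return out


def filter_same_gene(pairs: list[EvidencePair]) -> list[EvidencePair]:
    """Step 4A: both mates hit transcripts of one and the same gene."""
    for ev in pairs:
        if ev.live and ev.g1 is not None and ev.g1 == ev.g2:
            ev.flag(Stage.STEP4A_SAME_GENE)
    return pairs


def filter_unaligned(pairs: list[EvidencePair]) -> list[EvidencePair]:
    """Step 4B: either mate failed to align."""
    for ev in pairs:
        if ev.live and (ev.hit5 is None or ev.hit3 is None):
            ev.flag(Stage.STEP4B_UNALIGNED)
    return pairs


def filter_paralogs(
    pairs: list[EvidencePair], store: AnnotationStore, enabled: bool = True
) -> list[EvidencePair]:
    """Step 4C: the two genes are a known paralog pair. Inert without a table."""
    if not enabled or not store.paralog_pairs:
        return pairs
    for ev in pairs:
        if ev.live and store.is_paralog_pair(ev.g1, ev.g2):
            ev.flag(Stage.STEP4C_PARALOG)
    return pairs


def filter_antisense(
    pairs: list[EvidencePair], store: AnnotationStore, enabled: bool = True
) -> list[EvidencePair]:
    """Step 4D: gene spans overlap on opposite strands (antisense confusion)."""
    if not enabled:
        return pairs
    for ev in pairs:
        if not ev.live:
            continue
        geom = store.gene_pair_geometry(ev.g1, ev.g2)
        if geom.spans_overlap_opposite_strand:
            ev.flag(Stage.STEP4D_ANTISENSE)
    return pairs


def filter_insert_geometry(
    pairs: list[EvidencePair], store: AnnotationStore
) -> list[EvidencePair]:
    """Step 4E: the mapped positions must be realistic given the insert size.

    With the junction placed at the canonical boundary of the exon abutting it,
    the distance d1 from the 5'-mate's alignment end to its exon's 3' end plus
    the distance d2 from the 3'-mate's exon 5' start to its alignment start
    must equal the unsequenced gap of the parent read exactly.
    """
    for ev in pairs:
        if not ev.live:
            continue
        if not ev.strand_consistent:
            ev.flag(Stage.STEP4E_GEOMETRY)
            continue
        t_start5 = ev.hit5.t_start
        t_end5 = t_start5 + len(ev.mate5.sequence) - 1
        t_start3 = ev.hit3.t_start
        t_end3 = t_start3 + len(ev.mate3.sequence) - 1
        try:
            _, d1 = store.distance_to_exon_boundary(
                ev.hit5.transcript_id, t_end5, EXON_3P_END
            )
            _, d2 = store.distance_to_exon_boundary(
                ev.hit3.transcript_id, t_start3, EXON_5P_START
            )
        except Exception:
            ev.flag(Stage.STEP4E_GEOMETRY)
            continue
        ev.d1, ev.d2 = d1, d2
        if d1 < 0 or d2 < 0 or d1 + d2 != ev.pair.gap_bp:
            ev.flag(Stage.STEP4E_GEOMETRY)
            continue
        ev.genomic1 = store.transcript_to_genomic(ev.hit5.transcript_id, t_start5, t_end5)
        ev.genomic2 = store.transcript_to_genomic(ev.hit3.transcript_id, t_start3, t_end3)
    return pairs


def filter_multimap(
    pairs: list[EvidencePair],
    store: AnnotationStore,
    coding_aligner: SeedAligner | Mapping[str, str] | None = None,
    noncoding_aligner: SeedAligner | Mapping[str, str] | None = None,
    drop_candidate: bool = False,
) -> list[EvidencePair]:
    """Step 4F: realign surviving mates in all-hits mode against the coding and
    (when present) non-coding references; a pair whose two mates both map to
    transcripts of one common gene is flagged as a shared-exon false positive.

    With ``drop_candidate`` every pair of a (g1, g2) candidate is flagged as
    soon as any one of its pairs is ambiguous.
    """
    aligners = []
    for ref in (coding_aligner, noncoding_aligner):
        if ref is None:
            continue
        aligners.append(ref if isinstance(ref, SeedAligner) else SeedAligner(ref))
    if not aligners:
        aligners.append(SeedAligner(store.coding_sequences()))
        noncoding = store.noncoding_sequences()
        if noncoding:
            aligners.append(SeedAligner(noncoding))

    live = [ev for ev in pairs if ev.live]
    flagged_candidates: set[tuple[str, str]] = set()
    for ev in live:
        genes5: set[str] = set()
        genes3: set[str] = set()
        for aligner in aligners:
            result = align_all(
                [
                    (ev.mate5.read_id, ev.mate5.sequence, ev.mate5.qualities),
                    (ev.mate3.read_id, ev.mate3.sequence, ev.mate3.qualities),
                ],
                aligner,
            )
            genes5.update(
                store.gene_of_transcript(h.transcript_id)
                for h in result.hits[ev.mate5.read_id]
            )
            genes3.update(
                store.gene_of_transcript(h.transcript_id)
                for h in result.hits[ev.mate3.read_id]
            )
        if genes5 & genes3:
            ev.flag(Stage.STEP4F_MULTIMAP)
            flagged_candidates.add((ev.g1, ev.g2))
    if drop_candidate:
        for ev in live:
            if ev.live and (ev.g1, ev.g2) in flagged_candidates:
                ev.flag(Stage.STEP4F_MULTIMAP)
    return pairs


def collect_candidates(pairs: Iterable[EvidencePair]) -> list[CandidatePair]:
    """Group live evidence into one candidate per ordered (g1, g2) pair."""
    grouped: dict[tuple[str, str], CandidatePair] = {}
    for ev in pairs:
        if not ev.live:
            continue
        key = (ev.g1, ev.g2)
        if key not in grouped:
            grouped[key] = CandidatePair(ev.g1, ev.g2, [])
        grouped[key].evidence.append(ev)
    return list(grouped.values())


def stage_counts(pairs: Iterable[EvidencePair]) -> dict[str, int]:
    counts = {stage.value: 0 for stage in Stage}
    live = 0
    for ev in pairs:
        if ev.live:
            live += 1
        else:
            counts[ev.stage.value] += 1
    counts["live_evidence"] = live
    return counts
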
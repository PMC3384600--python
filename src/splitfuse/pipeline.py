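"""End-to-end orchestration of the five-step detection protocol.

Step 1: align full-length reads to the coding reference; keep the failures.
Step 2: split the failures into pseudo PE mates (+ quality profile).
Step 3: align the mates to the coding reference.
Step 4: reunite mates and run the false-positive filter cascade.
Step 5: build alignment blocks, resolve isoforms, threshold and categorise.
All report files are written into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import align, blocks, filters, pseudo, report
from .annotation import AnnotationStore, load_reference

logger = logging.getLogger(__name__)

REFERENCE_FILES = {
    "coding_fasta": ("coding.fa", "coding.fasta"),
    "annotation_gtf": ("annotation.gtf",),
    "noncoding_fasta": ("noncoding.fa", "noncoding.fasta"),
    "paralog_tsv": ("paralogs.tsv",),
    "repeat_bed": ("repeats.bed",),
}


class PipelineError(Exception):
    pass


@dataclass
class PipelineConfig:
    fastq: str | Path
    reference_dir: str | Path
    out_dir: str | Path
    fastq2: str | Path | None = None  # PE mode: second mate file, treated as SE
    min_reads: int = 1
    fraction5: float = pseudo.DEFAULT_FRACTION
    fraction3: float | None = None
    readthrough_dist: int = blocks.DEFAULT_READTHROUGH_DIST
    paralog_filter: bool = True
    antisense_filter: bool = True
    repeat_filter: bool = True
    multimap_drop_candidate: bool = False
    aligner: str = "builtin"  # or "external"
    sam_full: str | Path | None = None  # external step-1 SAM
    sam_pseudo: str | Path | None = None  # external step-3 SAM
    min_read_length: int = pseudo.MIN_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise PipelineError("min_reads must be >= 1")
        for frac in (self.fraction5, self.fraction3):
            if frac is not None and not (0.0 < frac <= 0.5):
                raise PipelineError(f"pseudo fraction {frac} outside (0, 0.5]")
        if self.aligner == "external" and not (self.sam_full and self.sam_pseudo):
            raise PipelineError(
                "external aligner backend requires --sam-full and --sam-pseudo"
            )


@dataclass
class PipelineResult:
    candidates: list[blocks.FusionCandidate]
    stats: dict[str, int]
    out_dir: Path
    evidence: list[filters.EvidencePair] = field(default_factory=list)


def load_reference_dir(reference_dir: str | Path) -> AnnotationStore:
    refdir = Path(reference_dir)
    found: dict[str, Path | None] = {}
    for key, names in REFERENCE_FILES.items():
        found[key] = next(
            (refdir / n for n in names if (refdir / n).exists()), None
        )
    if found["coding_fasta"] is None or found["annotation_gtf"] is None:
        raise PipelineError(
            f"reference dir {refdir} must contain coding.fa and annotation.gtf"
        )
    return load_reference(
        coding_fasta=found["coding_fasta"],
        annotation_gtf=found["annotation_gtf"],
        noncoding_fasta=found["noncoding_fasta"],
        paralog_tsv=found["paralog_tsv"],
        repeat_bed=found["repeat_bed"],
    )


def _load_reads(config: PipelineConfig) -> list[pseudo.FullRead]:
    reads = list(pseudo.iterate_fastq(config.fastq))
    if config.fastq2 is not None:
        # PE mode: pool both mate files as SE reads; original mate suffixes are
        # folded into the id so the later "/1"/"/2" pseudo suffixes stay unique
        def fold(read: pseudo.FullRead, tag: str) -> pseudo.FullRead:
            rid = read.read_id
            if rid.endswith(("/1", "/2")):
                rid = rid[:-2]
            return pseudo.FullRead(f"{rid}_{tag}", read.sequence, read.qualities)

        reads = [fold(r, "m1") for r in reads] + [
            fold(r, "m2") for r in pseudo.iterate_fastq(config.fastq2)
        ]
    return reads


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    store = load_reference_dir(config.reference_dir)
    coding = store.coding_sequences()
    noncoding = store.noncoding_sequences()
    if not coding:
        raise PipelineError("reference contains no coding transcripts")

    all_reads = _load_reads(config)
    stats: dict[str, int] = {"input_reads": len(all_reads)}
    reads, rejected = pseudo.reject_short_reads(all_reads, config.min_read_length)
    stats["too_short"] = rejected
    if rejected:
        logger.warning("rejected %d reads shorter than %d nt", rejected, config.min_read_length)

    coding_aligner = align.SeedAligner(coding)

    # Step 1: full-length reads vs the coding reference
    if config.aligner == "external":
        step1 = align.read_sam(config.sam_full, known_transcripts=coding)
    else:
        step1 = align.align_default(reads, coding_aligner)
        align.write_sam(step1, out_dir / "step1.sam", coding)
    unaligned = pseudo.select_unaligned(reads, step1)
    stats["step1_aligned"] = len(reads) - len(unaligned)
    stats["step1_unaligned"] = len(unaligned)
    logger.info("step 1: %d/%d reads unaligned", len(unaligned), len(reads))

    # Step 2: pseudo PE read creation + quality profile
    pairs = pseudo.split_reads(unaligned, config.fraction5, config.fraction3)
    pseudo.write_fastq(pseudo.pair_mates(pairs), out_dir / "pseudo_reads.fastq")
    pseudo.write_quality_profile(
        pseudo.quality_profile(reads), out_dir / "quality_profile.tsv"
    )

    # Step 3: pseudo mates vs the coding reference
    if config.aligner == "external":
        step3 = align.read_sam(config.sam_pseudo, known_transcripts=coding)
    else:
        step3 = align.align_default(pseudo.pair_mates(pairs), coding_aligner)
        align.write_sam(step3, out_dir / "step3.sam", coding)

    # Step 4: reunite and filter
    evidence = filters.reunite_and_assign(step3, pairs, store)
    filters.filter_same_gene(evidence)
    filters.filter_unaligned(evidence)
    filters.filter_paralogs(evidence, store, enabled=config.paralog_filter)
    filters.filter_antisense(evidence, store, enabled=config.antisense_filter)
    filters.filter_insert_geometry(evidence, store)
    filters.filter_multimap(
        evidence,
        store,
        coding_aligner=coding_aligner,
        noncoding_aligner=align.SeedAligner(noncoding) if noncoding else None,
        drop_candidate=config.multimap_drop_candidate,
    )
    candidates = filters.collect_candidates(evidence)
    logger.info("step 4: %d candidate gene pairs", len(candidates))

    # Step 5: blocks, isoforms, min-read threshold, categories
    fusion_candidates = []
    for cand in candidates:
        resolved = blocks.resolve_candidate(
            cand,
            store,
            repeat_filter=config.repeat_filter,
            readthrough_dist=config.readthrough_dist,
        )
        if resolved is not None:
            fusion_candidates.append(resolved)
    fusion_candidates = blocks.apply_min_reads(fusion_candidates, config.min_reads)
    fusion_candidates = report.rank_candidates(fusion_candidates)
    logger.info("step 5: %d fusion candidates", len(fusion_candidates))

    stats.update(filters.stage_counts(evidence))

    evidence_by_read = {ev.parent_id: ev for ev in evidence}
    report.write_summary(fusion_candidates, store, out_dir / "summary.tsv")
    report.write_isoforms(fusion_candidates, store, out_dir / "isoforms.tsv")
    report.write_read_evidence(
        fusion_candidates, evidence_by_read, out_dir / "evidence.fa"
    )
    report.write_breakpoint_reports(
        fusion_candidates, store, evidence_by_read, out_dir / "breakpoints.txt"
    )
    report.write_filter_log(evidence, out_dir / "filter_log.tsv")
    report.write_stats(stats, out_dir / "stats.tsv")
    _write_candidates_json(fusion_candidates, store, out_dir / "candidates.json")

    return PipelineResult(fusion_candidates, stats, out_dir, evidence)


def run_pe(config: PipelineConfig) -> PipelineResult:
    """PE mode: both mate files pooled as SE reads (see ``_load_reads``)."""
    if config.fastq2 is None:
        raise PipelineError("run_pe requires a second mate file")
    return run_pipeline(config)


def _write_candidates_json(
    candidates: list[blocks.FusionCandidate], store: AnnotationStore, path: Path
) -> None:
    payload = []
    for cand in candidates:
        evidence_by_read = {ev.parent_id: ev for ev in cand.pair.evidence}
        payload.append(
            {
                "g1": cand.g1,
                "g1_name": store.gene(cand.g1).common_name,
                "g2": cand.g2,
                "g2_name": store.gene(cand.g2).common_name,
                "totalreads": cand.totalreads,
                "categories": cand.categories,
                "isoforms": [
                    {
                        "isoreads": iso.isoreads,
                        "g1_block": iso.g1_block.coords,
                        "g2_block": iso.g2_block.coords,
                        "g1_exon": iso.g1_exon,
                        "g2_exon": iso.g2_exon,
                        "g1_expos": iso.g1_expos,
                        "g2_expos": iso.g2_expos,
                        "reads": [
                            _read_payload(evidence_by_read[rid])
                            for rid in iso.read_ids
                        ],
                    }
                    for iso in cand.isoforms
                ],
            }
        )
    path.write_text(json.dumps(payload, indent=1))


def _read_payload(ev: filters.EvidencePair) -> dict:
    return {
        "id": ev.parent_id,
        "mate1": ev.pair.mate1.sequence,
        "mate2": ev.pair.mate2.sequence,
        "gap_bp": ev.pair.gap_bp,
        "flipped": ev.flipped,
        "d1": ev.d1,
    }
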
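"""Read-to-transcriptome alignment.

The built-in backend performs ungapped end-to-end alignment on either strand,
accepting a placement when at most ``max_seed_mismatches`` (default 2)
mismatches fall within the seed — the first ``seed_length`` (default 28) bases
of the read as sequenced — and at most ``max_total_mismatches`` (default 2)
over the whole read. The latter mirrors the effective behaviour of short-read
aligners' default scoring on high-quality bases; without it a junction read
would align end-to-end to its 5' gene with an arbitrarily mismatched tail and
never reach the splitting stage. Candidate placements are found with a
pigeonhole 8-mer index over the reference: three disjoint 8-mer probes inside
the seed guarantee that any placement with <=2 seed mismatches is visited.

An external SAM-producing aligner can be substituted via :func:`read_sam`.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio.Seq import reverse_complement

FORWARD = "forward"
REVERSE_COMPLEMENT = "reverse_complement"

_PROBE_K = 8
_PROBE_OFFSETS = (0, 8, 16)
_MIN_INDEXED_SEED = _PROBE_OFFSETS[-1] + _PROBE_K  # 24


class AlignmentError(Exception):
    pass


class SamFormatError(AlignmentError):
    pass


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """Ungapped end-to-end placement of a read on a transcript.

    ``t_start`` is the 1-based transcript coordinate of the leftmost aligned
    base; ``mismatches`` is the whole-read mismatch count of the placement.
    """

    transcript_id: str
    t_start: int
    aligned_strand: str
    read_id: str
    mismatches: int


class AlignmentResult:
    """Per-read hit lists; an empty list marks an unaligned read."""

    def __init__(self, mode: str = "default"):
        self.mode = mode
        self.order: list[str] = []
        self.hits: dict[str, list[AlignmentHit]] = {}
        self.reads: dict[str, tuple[str, str]] = {}  # read_id -> (seq, qual)

    def add(self, read_id: str, seq: str, qual: str, hits: list[AlignmentHit]) -> None:
        if read_id in self.hits:
            raise AlignmentError(f"duplicate read id {read_id!r}")
        self.order.append(read_id)
        self.hits[read_id] = hits
        self.reads[read_id] = (seq, qual)

    def hit(self, read_id: str) -> AlignmentHit | None:
        hits = self.hits[read_id]
        return hits[0] if hits else None

    def is_aligned(self, read_id: str) -> bool:
        return bool(self.hits[read_id])

    def unaligned_ids(self) -> list[str]:
        return [rid for rid in self.order if not self.hits[rid]]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.hits

    def __len__(self) -> int:
        return len(self.order)


class SeedAligner:
    """Deterministic built-in aligner over an in-memory transcript set."""

    def __init__(
        self,
        reference: Mapping[str, str],
        seed_length: int = 28,
        max_seed_mismatches: int = 2,
        max_total_mismatches: int = 2,
    ):
        if not reference:
            raise AlignmentError("empty reference: no transcripts to index")
        self.reference = dict(reference)
        self.seed_length = seed_length
        self.max_seed_mismatches = max_seed_mismatches
        self.max_total_mismatches = max_total_mismatches
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid in sorted(self.reference):
            seq = self.reference[tid]
            for i in range(len(seq) - _PROBE_K + 1):
                self._index[seq[i : i + _PROBE_K]].append((tid, i))

    # -- candidate generation -------------------------------------------

    def _candidates(self, pattern: str, seed_lo: int, seed_len: int) -> set[tuple[str, int]]:
        """(transcript_id, 0-based offset) placements worth verifying."""
        out: set[tuple[str, int]] = set()
        if seed_len < _MIN_INDEXED_SEED:
            # three disjoint probes no longer fit inside the seed, so the
            # pigeonhole guarantee breaks; such short reads are rare enough
            # that scanning every placement is acceptable
            for tid, seq in self.reference.items():
                out.update((tid, i) for i in range(len(seq) - len(pattern) + 1))
            return out
        for off in _PROBE_OFFSETS:
            probe = pattern[seed_lo + off : seed_lo + off + _PROBE_K]
            for tid, pos in self._index.get(probe, ()):
                out.add((tid, pos - seed_lo - off))
        return out

    def _verify(
        self, pattern: str, tid: str, start: int, seed_lo: int, seed_len: int
    ) -> int | None:
        ref = self.reference[tid]
        if start < 0 or start + len(pattern) > len(ref):
            return None
        segment = ref[start : start + len(pattern)]
        if segment == pattern:
            return 0
        total = 0
        seed_mm = 0
        for i in range(len(pattern)):
            if pattern[i] != segment[i]:
                total += 1
                if total > self.max_total_mismatches:
                    return None
                if seed_lo <= i < seed_lo + seed_len:
                    seed_mm += 1
                    if seed_mm > self.max_seed_mismatches:
                        return None
        return total

    def query(self, read_id: str, sequence: str) -> list[AlignmentHit]:
        """All valid hits for one read, in deterministic sorted order."""
        sequence = sequence.upper()
        length = len(sequence)
        seed_len = min(self.seed_length, length)
        hits = []
        for pattern, strand in (
            (sequence, FORWARD),
            (reverse_complement(sequence), REVERSE_COMPLEMENT),
        ):
            # the seed is the first seed_len bases of the read as sequenced:
            # for a reverse-complement placement those are the pattern's last bases
            seed_lo = 0 if strand == FORWARD else length - seed_len
            for tid, start in self._candidates(pattern, seed_lo, seed_len):
                mm = self._verify(pattern, tid, start, seed_lo, seed_len)
                if mm is not None:
                    hits.append(AlignmentHit(tid, start + 1, strand, read_id, mm))
        return sorted(hits)


def _as_triples(reads: Iterable) -> Iterator[tuple[str, str, str]]:
    for read in reads:
        if isinstance(read, tuple):
            yield read
        else:  # FullRead / Mate duck-typing
            yield read.read_id, read.sequence, read.qualities


def align_default(reads: Iterable, reference: Mapping[str, str] | SeedAligner) -> AlignmentResult:
    """Align reads, reporting at most one hit per read.

    Among valid placements the hit with the fewest seed mismatches is chosen;
    remaining ties break on lexicographically smallest
    ``(transcript_id, t_start, strand)`` so output is reproducible.
    """
    aligner = reference if isinstance(reference, SeedAligner) else SeedAligner(reference)
    result = AlignmentResult(mode="default")
    for read_id, seq, qual in _as_triples(reads):
        hits = aligner.query(read_id, seq)
        if hits:
            best = min(hits, key=lambda h: (h.mismatches, h.transcript_id, h.t_start, h.aligned_strand))
            hits = [best]
        result.add(read_id, seq, qual, hits)
    return result


def align_all(reads: Iterable, reference: Mapping[str, str] | SeedAligner) -> AlignmentResult:
    """Align reads reporting every valid hit (all-hits mode)."""
    aligner = reference if isinstance(reference, SeedAligner) else SeedAligner(reference)
    result = AlignmentResult(mode="all")
    for read_id, seq, qual in _as_triples(reads):
        result.add(read_id, seq, qual, aligner.query(read_id, seq))
    return result


# -- SAM interchange ------------------------------------------------------


def write_sam(result: AlignmentResult, path: str | Path, reference: Mapping[str, str]) -> None:
    names = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(reference[n])} for n in names],
    }
    ref_index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read_id in result.order:
            seq, qual = result.reads[read_id]
            hits = result.hits[read_id]
            if not hits:
                seg = pysam.AlignedSegment()
                seg.query_name = read_id
                seg.flag = 4
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array(qual)
                out.write(seg)
                continue
            for hit in hits:
                seg = pysam.AlignedSegment()
                seg.query_name = read_id
                rc = hit.aligned_strand == REVERSE_COMPLEMENT
                seg.flag = 16 if rc else 0
                seg.reference_id = ref_index[hit.transcript_id]
                seg.reference_start = hit.t_start - 1
                seg.mapping_quality = 255
                seg.cigarstring = f"{len(seq)}M"
                seg.query_sequence = reverse_complement(seq) if rc else seq
                q = qual[::-1] if rc else qual
                seg.query_qualities = pysam.qualitystring_to_array(q)
                seg.set_tag("NM", hit.mismatches)
                out.write(seg)


def _prevalidate_sam(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SamFormatError(
                    f"{path}: malformed SAM line {lineno}: expected >=11 fields"
                )
            try:
                int(fields[1]), int(fields[3])
            except ValueError:
                raise SamFormatError(
                    f"{path}: malformed SAM line {lineno}: non-numeric FLAG/POS"
                ) from None


def read_sam(path: str | Path, known_transcripts: Iterable[str] | None = None) -> AlignmentResult:
    """Read alignments from a (text) SAM file produced here or by an external aligner."""
    path = Path(path)
    _prevalidate_sam(path)
    known = set(known_transcripts) if known_transcripts is not None else None
    result = AlignmentResult(mode="sam")
    pending: dict[str, tuple[str, str, list[AlignmentHit]]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            rid = seg.query_name
            rc = bool(seg.flag & 16)
            seq = seg.query_sequence or ""
            qual = (
                pysam.qualities_to_qualitystring(seg.query_qualities)
                if seg.query_qualities is not None
                else "I" * len(seq)
            )
            if rc:
                seq, qual = reverse_complement(seq), qual[::-1]
            if rid not in pending:
                pending[rid] = (seq, qual, [])
                order.append(rid)
            if seg.is_unmapped:
                continue
            tid = seg.reference_name
            if known is not None and tid not in known:
                raise SamFormatError(f"{path}: SAM record for unknown transcript {tid!r}")
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            pending[rid][2].append(
                AlignmentHit(
                    tid,
                    seg.reference_start + 1,
                    REVERSE_COMPLEMENT if rc else FORWARD,
                    rid,
                    int(nm),
                )
            )
    for rid in order:
        seq, qual, hits = pending[rid]
        result.add(rid, seq, qual, sorted(hits))
    return result
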
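"""Pseudo paired-end read derivation.

Full-length reads that fail to align to the coding reference are split into a
pair of "pseudo PE" reads: the first n5 and last n3 bases of the parent, with
ids suffixed "/1" and "/2" so the mates can later be reunited.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import AlignmentResult

MIN_READ_LENGTH = 50
DEFAULT_FRACTION = 0.4


class PseudoPairError(Exception):
    pass


@dataclass(frozen=True)
class FullRead:
    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise PseudoPairError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Mate:
    read_id: str
    sequence: str
    qualities: str


@dataclass(frozen=True)
class PseudoPair:
    parent_id: str
    mate1: Mate  # first n5 bases, id = parent_id + "/1"
    mate2: Mate  # last n3 bases, id = parent_id + "/2"
    gap_bp: int  # parent length - n5 - n3


def iterate_fastq(path: str | Path) -> Iterator[FullRead]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield FullRead(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[FullRead | Mate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.qualities}\n")


def reject_short_reads(
    reads: Iterable[FullRead], min_length: int = MIN_READ_LENGTH
) -> tuple[list[FullRead], int]:
    """Drop reads below the minimum length; returns (kept, rejected count)."""
    kept, rejected = [], 0
    for read in reads:
        if len(read) < min_length:
            rejected += 1
        else:
            kept.append(read)
    return kept, rejected


def select_unaligned(
    reads: Iterable[FullRead], step1_result: AlignmentResult
) -> list[FullRead]:
    """Exactly the reads flagged unaligned in the step-1 result, input order kept."""
    out = []
    for read in reads:
        if read.read_id not in step1_result:
            raise PseudoPairError(
                f"read {read.read_id} missing from step-1 alignment result"
            )
        if not step1_result.is_aligned(read.read_id):
            out.append(read)
    return out


def split_read(
    read: FullRead,
    fraction5: float = DEFAULT_FRACTION,
    fraction3: float | None = None,
) -> PseudoPair:
    """Split a full-length read into its two pseudo PE mates.

    Mate lengths are ``floor(len * fraction)``; fractions above 0.5 are a
    parameter error since the mates would overlap.
    """
    if fraction3 is None:
        fraction3 = fraction5
    for frac in (fraction5, fraction3):
        if not (0.0 < frac <= 0.5):
            raise PseudoPairError(f"pseudo fraction {frac} outside (0, 0.5]")
    length = len(read)
    n5 = int(length * fraction5)
    n3 = int(length * fraction3)
    if n5 < 1 or n3 < 1:
        raise PseudoPairError(f"read {read.read_id}: too short to split at given fractions")
    mate1 = Mate(read.read_id + "/1", read.sequence[:n5], read.qualities[:n5])
    mate2 = Mate(read.read_id + "/2", read.sequence[length - n3 :], read.qualities[length - n3 :])
    return PseudoPair(read.read_id, mate1, mate2, length - n5 - n3)


def split_reads(
    reads: Iterable[FullRead],
    fraction5: float = DEFAULT_FRACTION,
    fraction3: float | None = None,
) -> list[PseudoPair]:
    return [split_read(r, fraction5, fraction3) for r in reads]


def parent_id_of(mate_id: str) -> str:
    if not mate_id.endswith(("/1", "/2")):
        raise PseudoPairError(f"mate id {mate_id!r} lacks a /1 or /2 suffix")
    return mate_id[:-2]


def pair_mates(pairs: Iterable[PseudoPair]) -> Iterator[Mate]:
    for pair in pairs:
        yield pair.mate1
        yield pair.mate2


def quality_profile(reads: Iterable[FullRead]) -> list[tuple[int, float, int]]:
    """Per-position mean phred score over all reads covering that position.

    Returns rows ``(position 1-based, mean_phred, n_reads)``.
    """
    totals = np.zeros(0, dtype=np.int64)
    counts = np.zeros(0, dtype=np.int64)
    for read in reads:
        scores = np.frombuffer(read.qualities.encode(), dtype=np.uint8).astype(np.int64) - 33
        if len(scores) > len(totals):
            totals = np.pad(totals, (0, len(scores) - len(totals)))
            counts = np.pad(counts, (0, len(scores) - len(counts)))
        totals[: len(scores)] += scores
        counts[: len(scores)] += 1
    return [
        (i + 1, totals[i] / counts[i], int(counts[i])) for i in range(len(totals))
    ]


def write_quality_profile(profile: Sequence[tuple[int, float, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tmean_phred\tn_reads\n")
        for pos, mean, n in profile:
            fh.write(f"{pos}\t{mean:.4f}\t{n}\n")
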
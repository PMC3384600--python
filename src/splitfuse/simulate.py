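"""Synthetic transcriptome / RNA-Seq simulation with planted fusions, plus
sensitivity and positive-predictive-value scoring of predictions.

The simulator builds random multi-exon genes on synthetic chromosomes
(optionally grouped into high-identity families), writes a mutually consistent
GTF + transcript FASTA, plants single-exon-to-single-exon fusion transcripts,
and emits reads: background reads over expressed transcripts (log-normal
per-transcript depth), junction reads spanning each fusion breakpoint with a
minimum overhang on each side, and uniformly random junk reads. A manifest
records every read's origin, and a truth table records the planted fusions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 100
    n_families: int = 0
    family_size: int = 2
    family_identity: float = 0.95
    n_chromosomes: int = 4
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (200, 2000)
    intergenic_gap: tuple[int, int] = (25_000, 40_000)
    read_length: int = 75
    n_fusions: int = 55
    junction_reads: tuple[int, int] = (1, 295)
    n_junk_reads: int = 10_000
    min_overhang: int = 30
    revcomp_prob: float = 0.5
    expressed_fraction: float = 0.8
    background_reads: int = 20_000
    lognormal_sigma: float = 1.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_overhang < 1:
            raise SimulationError("min_overhang must be >= 1")
        if 2 * self.min_overhang > self.read_length:
            raise SimulationError("2*min_overhang exceeds the read length")
        if self.n_families * self.family_size > self.n_genes:
            raise SimulationError("more family members than genes")


@dataclass
class SimGene:
    gene_id: str
    name: str
    transcript_id: str
    chromosome: str
    strand: int
    exons: list[tuple[str, int, int]]  # (exon_id, genomic start, genomic end), genomic order
    sequence: str  # spliced transcript sequence, transcript orientation
    family: str | None = None

    @property
    def exon_ids(self) -> list[str]:
        ids = [e[0] for e in self.exons]
        return ids if self.strand > 0 else ids[::-1]

    def exon_sequence(self, exon_id: str) -> str:
        order = self.exon_ids
        pos = 0
        for eid in order:
            length = next(e[2] - e[1] + 1 for e in self.exons if e[0] == eid)
            if eid == exon_id:
                return self.sequence[pos : pos + length]
            pos += length
        raise KeyError(exon_id)


@dataclass
class SimulatedTranscriptome:
    config: SimulationConfig
    genes: list[SimGene]
    chromosomes: dict[str, str]
    family_map: dict[str, str] = field(default_factory=dict)  # gene_id -> family id

    def gene(self, gene_id: str) -> SimGene:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def gtf_text(self) -> str:
        lines = []
        for gene in self.genes:
            strand = "+" if gene.strand > 0 else "-"
            exon_order = gene.exon_ids
            for number, eid in enumerate(exon_order, start=1):
                start, end = next((s, e) for x, s, e in gene.exons if x == eid)
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{gene.transcript_id}"; '
                    f'exon_number "{number}"; exon_id "{eid}"; '
                    f'gene_name "{gene.name}"; gene_biotype "protein_coding";'
                )
                lines.append(
                    f"{gene.chromosome}\tsim\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
                )
        return "\n".join(lines) + "\n"

    def fasta_text(self) -> str:
        return "".join(
            f">{g.transcript_id}\n{g.sequence}\n" for g in self.genes
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "coding_fasta": outdir / "coding.fa",
            "gtf": outdir / "annotation.gtf",
            "families": outdir / "families.tsv",
        }
        paths["coding_fasta"].write_text(self.fasta_text())
        paths["gtf"].write_text(self.gtf_text())
        with open(paths["families"], "w") as fh:
            fh.write("gene_id\tfamily\n")
            for gene in self.genes:
                fh.write(f"{gene.gene_id}\t{self.family_map.get(gene.gene_id, gene.gene_id)}\n")
        return paths


@dataclass(frozen=True)
class FusionTruth:
    fusion_id: str
    g1: str
    g2: str
    g1_exon: str
    g2_exon: str
    junction_reads: int


@dataclass
class EvaluationResult:
    threshold: int
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    ppv: float | None
    labels: dict[tuple[str, str], str]  # prediction pair -> label

    @property
    def n_synonymous(self) -> int:
        return sum(1 for v in self.labels.values() if v == "synonymous_fusion")


# -- transcriptome generation ---------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def generate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedTranscriptome:
    """Place random multi-exon genes on synthetic chromosomes.

    The first ``n_families * family_size`` genes form families: members share
    exon structure and ``family_identity`` expected sequence identity (mutated
    copies placed at independent loci). Deterministic for a given config+rng.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom_parts: dict[str, list[str]] = {
        f"chromosome_{i + 1}": [] for i in range(config.n_chromosomes)
    }
    chrom_pos = {c: 0 for c in chrom_parts}
    chrom_names = sorted(chrom_parts)

    # plan gene templates; family copies reuse their template's exon sequences
    templates: list[tuple[str | None, list[str] | None]] = []
    fam = 0
    while len(templates) < config.n_genes:
        if fam < config.n_families:
            family_id = f"FAM{fam + 1:03d}"
            base: list[str] | None = None
            for _ in range(config.family_size):
                templates.append((family_id, base))
                base = []  # sentinel replaced below; members after the first mutate
            fam += 1
        else:
            templates.append((None, None))
    templates = templates[: config.n_genes]

    genes: list[SimGene] = []
    family_map: dict[str, str] = {}
    family_exon_seqs: dict[str, list[str]] = {}
    for index, (family_id, marker) in enumerate(templates):
        gene_id = f"SFG{index + 1:04d}"
        name = f"GENE{index + 1:04d}"
        tid = f"SFT{index + 1:04d}"
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        strand = 1 if rng.random() < 0.5 else -1
        if family_id is not None and family_id in family_exon_seqs:
            exon_seqs = [
                _mutate(rng, s, 1.0 - config.family_identity)
                for s in family_exon_seqs[family_id]
            ]
        else:
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_seqs = [
                _random_seq(rng, int(rng.integers(config.exon_length[0], config.exon_length[1] + 1)))
                for _ in range(n_exons)
            ]
            if family_id is not None:
                family_exon_seqs[family_id] = exon_seqs
        if family_id is not None:
            family_map[gene_id] = family_id

        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        chrom_parts[chrom].append(_random_seq(rng, gap))
        pos = chrom_pos[chrom] + gap

        # genomic layout: exon sequences appear 5'->3' along the genome in
        # transcript order for +, reversed and complemented for -
        genomic_exon_seqs = (
            exon_seqs if strand > 0 else [reverse_complement(s) for s in exon_seqs[::-1]]
        )
        exon_coords: list[tuple[str, int, int]] = []
        n_exons = len(exon_seqs)
        for k, gseq in enumerate(genomic_exon_seqs):
            start = pos + 1
            end = pos + len(gseq)
            # exon ids follow transcript order regardless of strand
            t_index = k + 1 if strand > 0 else n_exons - k
            exon_coords.append((f"SFE{index + 1:04d}_{t_index}", start, end))
            chrom_parts[chrom].append(gseq)
            pos = end
            if k < n_exons - 1:
                intron = int(
                    rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                )
                chrom_parts[chrom].append(_random_seq(rng, intron))
                pos += intron
        chrom_pos[chrom] = pos
        genes.append(
            SimGene(
                gene_id,
                name,
                tid,
                chrom,
                strand,
                exon_coords,
                "".join(exon_seqs),
                family_id,
            )
        )
    chromosomes = {c: "".join(parts) for c, parts in chrom_parts.items()}
    return SimulatedTranscriptome(config, genes, chromosomes, family_map)


# -- fusion planting and read simulation ----------------------------------


def plant_fusions(
    config: SimulationConfig,
    transcriptome: SimulatedTranscriptome,
    rng: np.random.Generator | None = None,
) -> list[FusionTruth]:
    """Select random distinct gene pairs and one exon from each as fusions."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if 2 * config.n_fusions > len(transcriptome.genes):
        raise SimulationError("not enough genes to plant the requested fusions")
    order = rng.permutation(len(transcriptome.genes))
    truths: list[FusionTruth] = []
    cursor = 0
    for k in range(config.n_fusions):
        while True:
            if cursor + 1 >= len(order):
                raise SimulationError("could not find a feasible fusion exon pair")
            ga = transcriptome.genes[order[cursor]]
            gb = transcriptome.genes[order[cursor + 1]]
            cursor += 2
            pair = _pick_fusion_exons(config, ga, gb, rng)
            if pair is not None:
                break
        exon_a, exon_b = pair
        count = int(rng.integers(config.junction_reads[0], config.junction_reads[1] + 1))
        truths.append(
            FusionTruth(f"FUS{k + 1:03d}", ga.gene_id, gb.gene_id, exon_a, exon_b, count)
        )
    return truths


def _pick_fusion_exons(
    config: SimulationConfig, ga: SimGene, gb: SimGene, rng: np.random.Generator
) -> tuple[str, str] | None:
    length = config.read_length
    over = config.min_overhang
    exons_a = [e for e in ga.exon_ids if len(ga.exon_sequence(e)) >= over]
    exons_b = [e for e in gb.exon_ids if len(gb.exon_sequence(e)) >= over]
    rng.shuffle(exons_a)
    rng.shuffle(exons_b)
    for ea in exons_a:
        la = len(ga.exon_sequence(ea))
        for eb in exons_b:
            lb = len(gb.exon_sequence(eb))
            if max(over, length - lb) <= min(length - over, la):
                return ea, eb
    return None


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    return _mutate(rng, seq, rate)


def simulate_reads(
    config: SimulationConfig,
    transcriptome: SimulatedTranscriptome,
    truth: Sequence[FusionTruth],
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], list[dict]]:
    """Generate (read_id, sequence, qualities) triples plus a per-read manifest.

    Background reads cover expressed transcripts uniformly with per-transcript
    counts drawn log-normally; junction reads span each planted breakpoint with
    at least ``min_overhang`` bases of either exon; junk reads are uniform
    random sequence. Each read is reverse-complemented with ``revcomp_prob``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    length = config.read_length
    qual = "I" * length
    reads: list[tuple[str, str, str]] = []
    manifest: list[dict] = []

    def emit(read_id: str, seq: str, origin: str, source: str, pos: int) -> None:
        seq = _apply_errors(rng, seq, config.error_rate)
        rc = rng.random() < config.revcomp_prob
        if rc:
            seq = reverse_complement(seq)
        reads.append((read_id, seq, qual))
        manifest.append(
            {
                "read_id": read_id,
                "origin": origin,
                "source": source,
                "position": pos,
                "strand": "-" if rc else "+",
            }
        )

    # background
    eligible = [g for g in transcriptome.genes if len(g.sequence) >= length]
    n_expressed = max(1, int(round(config.expressed_fraction * len(eligible))))
    chosen = rng.permutation(len(eligible))[:n_expressed]
    weights = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n_expressed)
    counts = np.floor(weights / weights.sum() * config.background_reads).astype(int)
    serial = 0
    for idx, count in zip(chosen, counts):
        gene = eligible[idx]
        for _ in range(int(count)):
            start = int(rng.integers(0, len(gene.sequence) - length + 1))
            serial += 1
            emit(
                f"bg_{serial:07d}",
                gene.sequence[start : start + length],
                "background",
                gene.transcript_id,
                start + 1,
            )

    # fusion junction reads
    for fus in truth:
        ga = transcriptome.gene(fus.g1)
        gb = transcriptome.gene(fus.g2)
        seq_a = ga.exon_sequence(fus.g1_exon)
        seq_b = gb.exon_sequence(fus.g2_exon)
        fused = seq_a + seq_b
        lo = max(0, len(seq_a) - (length - config.min_overhang))
        # 0-based inclusive start range keeping >=min_overhang bases of each
        # exon in the read while staying inside the fused sequence
        hi = min(len(seq_a) - config.min_overhang, len(fused) - length)
        if lo > hi:
            raise SimulationError(f"infeasible junction window for {fus.fusion_id}")
        for j in range(fus.junction_reads):
            start = int(rng.integers(lo, hi + 1))
            emit(
                f"{fus.fusion_id}_{j + 1:04d}",
                fused[start : start + length],
                "fusion",
                fus.fusion_id,
                start + 1,
            )

    # junk
    for j in range(config.n_junk_reads):
        emit(f"junk_{j + 1:06d}", _random_seq(rng, length), "junk", "-", 0)
    return reads, manifest


def write_reads_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_truth(truth: Iterable[FusionTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["fusion_id", "g1", "g2", "g1_exon", "g2_exon", "junction_reads"])
        for fus in truth:
            writer.writerow(
                [fus.fusion_id, fus.g1, fus.g2, fus.g1_exon, fus.g2_exon, fus.junction_reads]
            )


def read_truth(path: str | Path) -> list[FusionTruth]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                FusionTruth(
                    row["fusion_id"],
                    row["g1"],
                    row["g2"],
                    row["g1_exon"],
                    row["g2_exon"],
                    int(row["junction_reads"]),
                )
            )
    return out


def write_manifest(manifest: Iterable[dict], path: str | Path) -> None:
    fields = ["read_id", "origin", "source", "position", "strand"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(manifest)


def read_family_map(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["gene_id"]] = row["family"]
    return out


# -- performance measures --------------------------------------------------


def sensitivity(tp: int, fn: int) -> float | None:
    """TP / (TP + FN); None when no condition positives exist."""
    return tp / (tp + fn) if tp + fn else None


def ppv(tp: int, fp: int) -> float | None:
    """TP / (TP + FP); None when nothing was predicted."""
    return tp / (tp + fp) if tp + fp else None


def load_summary_pairs(path: str | Path) -> list[tuple[str, str, int]]:
    """(g1, g2, totalreads) rows from a pipeline summary TSV."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            g1 = row["G1_Ensembl_HGNC_ID"].split()[0]
            g2 = row["G2_Ensembl_HGNC_ID"].split()[0]
            out.append((g1, g2, int(row["totalreads"])))
    return out


def evaluate(
    predictions: Sequence[tuple[str, str, int]],
    truth: Sequence[FusionTruth],
    family_map: Mapping[str, str] | None = None,
    threshold: int = 1,
) -> EvaluationResult:
    """Score predicted gene pairs against the simulation truth.

    Predictions evidenced by fewer than ``threshold`` reads are ignored.
    A prediction matching a truth pair (unordered) is a true positive; one that
    matches only after substituting a gene for a same-family member is a
    "synonymous fusion" and counts as a false positive, as does anything else.
    """
    family_map = family_map or {}

    def fam(gene: str) -> str:
        return family_map.get(gene, gene)

    truth_pairs = {frozenset((f.g1, f.g2)) for f in truth}
    truth_family_pairs = {frozenset((fam(f.g1), fam(f.g2))) for f in truth}

    labels: dict[tuple[str, str], str] = {}
    matched: set[frozenset] = set()
    fp = 0
    for g1, g2, count in predictions:
        if count < threshold:
            continue
        key = (g1, g2)
        pair = frozenset((g1, g2))
        if pair in truth_pairs:
            labels[key] = "true_positive"
            matched.add(pair)
        elif frozenset((fam(g1), fam(g2))) in truth_family_pairs:
            labels[key] = "synonymous_fusion"
            fp += 1
        else:
            labels[key] = "false_positive"
            fp += 1
    tp = len(matched)
    fn = len(truth_pairs) - tp
    return EvaluationResult(
        threshold, tp, fp, fn, sensitivity(tp, fn), ppv(tp, fp), labels
    )


def write_evaluation(results: Sequence[EvaluationResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["threshold", "TP", "FP", "FN", "Sensitivity", "PPV", "synonymous_fusions"]
        )
        for res in results:
            writer.writerow(
                [
                    res.threshold,
                    res.tp,
                    res.fp,
                    res.fn,
                    "" if res.sensitivity is None else f"{res.sensitivity:.4f}",
                    "" if res.ppv is None else f"{res.ppv:.4f}",
                    res.n_synonymous,
                ]
            )


# -- end-to-end study ------------------------------------------------------


def run_simulation_study(
    seed: int,
    workdir: str | Path,
    config: SimulationConfig | None = None,
    min_reads: int = 1,
    **overrides,
) -> dict:
    """Simulate a dataset, run the full pipeline on it, and score the result.

    Returns a dict with the evaluation at the requested ``min_reads`` threshold
    plus the paths of the generated artefacts. All randomness flows from
    ``seed``.
    """
    from .pipeline import PipelineConfig, run_pipeline  # local import; avoids cycle

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimulationConfig(seed=seed, **overrides)
    elif overrides:
        config = replace(config, **overrides)
    config = replace(config, seed=seed)

    rng = np.random.default_rng(seed)
    transcriptome = generate_transcriptome(config, rng)
    truth = plant_fusions(config, transcriptome, rng)
    reads, manifest = simulate_reads(config, transcriptome, truth, rng)

    refdir = workdir / "reference"
    paths = transcriptome.write(refdir)
    fastq = workdir / "reads.fastq"
    write_reads_fastq(reads, fastq)
    write_truth(truth, workdir / "truth.tsv")
    write_manifest(manifest, workdir / "manifest.tsv")

    outdir = workdir / "run"
    pipe_config = PipelineConfig(
        fastq=fastq,
        reference_dir=refdir,
        out_dir=outdir,
        min_reads=min_reads,
        seed=seed,
    )
    run_pipeline(pipe_config)

    predictions = load_summary_pairs(outdir / "summary.tsv")
    family_map = read_family_map(paths["families"])
    result = evaluate(predictions, truth, family_map, threshold=min_reads)
    return {
        "config": config,
        "truth": truth,
        "predictions": predictions,
        "evaluation": result,
        "workdir": workdir,
        "outdir": outdir,
    }
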
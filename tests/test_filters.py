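"""Step-4 filter cascade: reuniting, per-stage flags, idempotence, conservation."""

import numpy as np
import pytest

from splitfuse.align import FORWARD, REVERSE_COMPLEMENT, AlignmentHit, AlignmentResult
from splitfuse.annotation import AnnotationStore, Exon, Gene, Transcript
from splitfuse.filters import (
    FilterError,
    Stage,
    collect_candidates,
    filter_antisense,
    filter_insert_geometry,
    filter_multimap,
    filter_paralogs,
    filter_same_gene,
    filter_unaligned,
    reunite_and_assign,
    stage_counts,
)
from splitfuse.pseudo import Mate, PseudoPair

from .conftest import build_store, random_seq


@pytest.fixture(scope="module")
def filter_store(toy_genome):
    # GA + GB: far apart, same chromosome/strand; GD/GE overlap on opposite strands
    return build_store(
        toy_genome,
        [
            ("GA", "TA", "chrA", 1, [("XA", 1001, 1100)]),
            ("GB", "TB", "chrA", 1, [("XB", 9001, 9100)]),
            ("GC", "TC", "chrB", 1, [("XC", 2001, 2100)]),
            ("GD", "TD", "chrA", 1, [("XD", 3001, 3200)]),
            ("GE", "TE", "chrA", -1, [("XE", 3101, 3300)]),
        ],
        paralog_pairs={frozenset(("GA", "GC"))},
    )


def make_pair(parent_id="p1", n5=30, n3=30, gap=16, seq5=None, seq3=None):
    seq5 = seq5 or "A" * n5
    seq3 = seq3 or "C" * n3
    return PseudoPair(
        parent_id,
        Mate(parent_id + "/1", seq5, "I" * len(seq5)),
        Mate(parent_id + "/2", seq3, "I" * len(seq3)),
        gap,
    )


def make_evidence(store, pair, hit1, hit2):
    """Run the real reuniting path for a single pseudo pair."""
    result = AlignmentResult()
    result.add(pair.mate1.read_id, pair.mate1.sequence, pair.mate1.qualities,
               [hit1] if hit1 else [])
    result.add(pair.mate2.read_id, pair.mate2.sequence, pair.mate2.qualities,
               [hit2] if hit2 else [])
    return reunite_and_assign(result, [pair], store)[0]


def hit(tid, t_start, mate_id, strand=FORWARD):
    return AlignmentHit(tid, t_start, strand, mate_id, 0)


class TestReunite:
    def test_both_mates_distinct_genes(self, filter_store):
        pair = make_pair()
        ev = make_evidence(filter_store, pair, hit("TA", 69, "p1/1"), hit("TB", 15, "p1/2"))
        assert ev.live and (ev.g1, ev.g2) == ("GA", "GB")

    def test_missing_mate_raises(self, filter_store):
        pair = make_pair()
        result = AlignmentResult()
        result.add("p1/1", pair.mate1.sequence, pair.mate1.qualities, [])
        with pytest.raises(FilterError, match="p1/2"):
            reunite_and_assign(result, [pair], filter_store)

    def test_conservation_three_in_three_out(self, filter_store):
        pairs = [make_pair(f"p{i}") for i in range(3)]
        result = AlignmentResult()
        for pair in pairs:
            result.add(pair.mate1.read_id, pair.mate1.sequence, pair.mate1.qualities, [])
            result.add(pair.mate2.read_id, pair.mate2.sequence, pair.mate2.qualities, [])
        assert len(reunite_and_assign(result, pairs, filter_store)) == 3

    def test_double_reverse_complement_flips_roles(self, filter_store):
        pair = make_pair()
        ev = make_evidence(
            filter_store,
            pair,
            hit("TB", 15, "p1/1", REVERSE_COMPLEMENT),
            hit("TA", 69, "p1/2", REVERSE_COMPLEMENT),
        )
        assert ev.flipped
        assert (ev.g1, ev.g2) == ("GA", "GB")  # 5' gene recovered despite RC


class TestSimpleFilters:
    def test_same_gene_flagged(self, filter_store):
        ev = make_evidence(filter_store, make_pair(), hit("TA", 1, "p1/1"), hit("TA", 40, "p1/2"))
        filter_same_gene([ev])
        assert ev.stage == Stage.STEP4A_SAME_GENE

    def test_cross_gene_live(self, filter_store):
        ev = make_evidence(filter_store, make_pair(), hit("TA", 1, "p1/1"), hit("TB", 1, "p1/2"))
        filter_same_gene([ev])
        assert ev.live

    def test_mixed_set_partition(self, filter_store):
        same = make_evidence(filter_store, make_pair("s"), hit("TB", 1, "s/1"), hit("TB", 40, "s/2"))
        cross = make_evidence(filter_store, make_pair("c"), hit("TA", 1, "c/1"), hit("TB", 1, "c/2"))
        filter_same_gene([same, cross])
        assert same.stage == Stage.STEP4A_SAME_GENE and cross.live

    @pytest.mark.parametrize("h1,h2", [(None, True), (True, None), (None, None)])
    def test_unaligned_flagged(self, filter_store, h1, h2):
        ev = make_evidence(
            filter_store,
            make_pair(),
            hit("TA", 1, "p1/1") if h1 else None,
            hit("TB", 1, "p1/2") if h2 else None,
        )
        filter_unaligned([ev])
        assert ev.stage == Stage.STEP4B_UNALIGNED

    def test_paralog_pair_flagged_and_disable(self, filter_store):
        for enabled, expect in ((True, Stage.STEP4C_PARALOG), (False, None)):
            ev = make_evidence(
                filter_store, make_pair(), hit("TA", 1, "p1/1"), hit("TC", 1, "p1/2")
            )
            filter_paralogs([ev], filter_store, enabled=enabled)
            assert ev.stage == expect

    def test_unlisted_pair_live(self, filter_store):
        ev = make_evidence(filter_store, make_pair(), hit("TA", 1, "p1/1"), hit("TB", 1, "p1/2"))
        filter_paralogs([ev], filter_store)
        assert ev.live

    def test_antisense_overlap_flagged_and_disable(self, filter_store):
        for enabled, expect in ((True, Stage.STEP4D_ANTISENSE), (False, None)):
            ev = make_evidence(
                filter_store, make_pair(), hit("TD", 1, "p1/1"), hit("TE", 1, "p1/2")
            )
            filter_antisense([ev], filter_store, enabled=enabled)
            assert ev.stage == expect

    def test_nonoverlapping_opposite_strand_live(self, toy_genome):
        store = build_store(
            toy_genome,
            [
                ("GP", "TP", "chrA", 1, [("XP", 1001, 1100)]),
                ("GQ", "TQ", "chrA", -1, [("XQ", 8001, 8100)]),
            ],
        )
        ev = make_evidence(store, make_pair(), hit("TP", 1, "p1/1"), hit("TQ", 1, "p1/2"))
        filter_antisense([ev], store)
        assert ev.live


class TestInsertGeometry:
    """Worked arithmetic: 76-mer parent, 30-mer mates => 16-base gap; the pair
    survives iff d1 + d2 equals that gap exactly."""

    def _geometry_ev(self, store, t_start1, t_start2, gap=16):
        pair = make_pair(gap=gap)
        return make_evidence(
            store, pair, hit("TA", t_start1, "p1/1"), hit("TB", t_start2, "p1/2")
        )

    def test_d1_2_d2_14_live(self, filter_store):
        # mate1 ends at t=98 of the 100-bp exon (d1=2); mate2 starts at t=15 (d2=14)
        ev = self._geometry_ev(filter_store, 69, 15)
        filter_insert_geometry([ev], filter_store)
        assert ev.live and (ev.d1, ev.d2) == (2, 14)

    def test_d1_0_d2_16_live(self, filter_store):
        ev = self._geometry_ev(filter_store, 71, 17)
        filter_insert_geometry([ev], filter_store)
        assert ev.live and (ev.d1, ev.d2) == (0, 16)

    def test_sum_mismatch_filtered(self, filter_store):
        # d1=10, d2=10: sum 20 != 16
        ev = self._geometry_ev(filter_store, 61, 11)
        filter_insert_geometry([ev], filter_store)
        assert ev.stage == Stage.STEP4E_GEOMETRY
        assert (ev.d1, ev.d2) == (10, 10)

    def test_mixed_strand_pair_filtered(self, filter_store):
        pair = make_pair()
        ev = make_evidence(
            filter_store,
            pair,
            hit("TA", 69, "p1/1", FORWARD),
            hit("TB", 15, "p1/2", REVERSE_COMPLEMENT),
        )
        filter_insert_geometry([ev], filter_store)
        assert ev.stage == Stage.STEP4E_GEOMETRY

    def test_genomic_segments_filled_for_live_pairs(self, filter_store):
        ev = self._geometry_ev(filter_store, 69, 15)
        filter_insert_geometry([ev], filter_store)
        assert ev.genomic1 == [("chrA", 1069, 1098, 1)]
        assert ev.genomic2 == [("chrA", 9015, 9044, 1)]


@pytest.fixture(scope="module")
def shared_exon_store():
    """GX and GY each own one exon; GZ (noncoding) is built from both sequences."""
    rng = np.random.default_rng(31)
    s1, s2 = random_seq(rng, 80), random_seq(rng, 90)
    exons = {
        "X1": Exon("X1", "chr1", 101, 180, 1),
        "Y1": Exon("Y1", "chr1", 1001, 1090, 1),
        "Z1": Exon("Z1", "chr2", 201, 280, 1),
        "Z2": Exon("Z2", "chr2", 501, 590, 1),
    }
    transcripts = {
        "TX": Transcript("TX", "GX", [exons["X1"]], "coding", s1),
        "TY": Transcript("TY", "GY", [exons["Y1"]], "coding", s2),
        "TZ": Transcript("TZ", "GZ", [exons["Z1"], exons["Z2"]], "noncoding", s1 + s2),
    }
    genes = {
        "GX": Gene("GX", "GX", "chr1", 1, 101, 180, ["TX"]),
        "GY": Gene("GY", "GY", "chr1", 1, 1001, 1090, ["TY"]),
        "GZ": Gene("GZ", "GZ", "chr2", 1, 201, 590, ["TZ"]),
    }
    return AnnotationStore(genes, transcripts, exons), s1, s2


class TestMultimap:
    def test_shared_exon_gene_flagged(self, shared_exon_store):
        store, s1, s2 = shared_exon_store
        pair = make_pair(seq5=s1[10:40], seq3=s2[20:50], gap=16)
        ev = make_evidence(store, pair, hit("TX", 11, "p1/1"), hit("TY", 21, "p1/2"))
        filter_multimap([ev], store)
        assert ev.stage == Stage.STEP4F_MULTIMAP

    def test_unique_mates_live(self, filter_store, toy_genome):
        seq5 = filter_store.transcript("TA").sequence[:30]
        seq3 = filter_store.transcript("TB").sequence[:30]
        pair = make_pair(seq5=seq5, seq3=seq3)
        ev = make_evidence(filter_store, pair, hit("TA", 1, "p1/1"), hit("TB", 1, "p1/2"))
        filter_multimap([ev], filter_store)
        assert ev.live

    def test_noncoding_reference_absent_only_coding_checked(self, shared_exon_store):
        store, s1, s2 = shared_exon_store
        pair = make_pair(seq5=s1[10:40], seq3=s2[20:50], gap=16)
        ev = make_evidence(store, pair, hit("TX", 11, "p1/1"), hit("TY", 21, "p1/2"))
        # GZ lives in the noncoding reference only; skipping it keeps the pair
        filter_multimap([ev], store, coding_aligner=store.coding_sequences())
        assert ev.live

    def test_drop_candidate_mode(self, shared_exon_store):
        store, s1, s2 = shared_exon_store
        ambiguous = make_pair("amb", seq5=s1[10:40], seq3=s2[20:50], gap=16)
        rng = np.random.default_rng(77)
        unique = make_pair("uni", seq5="".join(s1[:15]) + random_seq(rng, 15),
                           seq3=random_seq(rng, 30), gap=16)
        ev1 = make_evidence(store, ambiguous, hit("TX", 11, "amb/1"), hit("TY", 21, "amb/2"))
        ev2 = make_evidence(store, unique, hit("TX", 1, "uni/1"), hit("TY", 31, "uni/2"))
        filter_multimap([ev1, ev2], store, drop_candidate=True)
        assert ev1.stage == Stage.STEP4F_MULTIMAP
        assert ev2.stage == Stage.STEP4F_MULTIMAP  # whole candidate dropped


class TestCollectAndInvariants:
    def test_grouping_counts(self, filter_store):
        evs = []
        for i in range(3):
            evs.append(make_evidence(filter_store, make_pair(f"a{i}"),
                                     hit("TA", 1, f"a{i}/1"), hit("TB", 1, f"a{i}/2")))
        for i in range(2):
            evs.append(make_evidence(filter_store, make_pair(f"b{i}"),
                                     hit("TA", 1, f"b{i}/1"), hit("TC", 1, f"b{i}/2")))
        candidates = collect_candidates(evs)
        assert [(c.g1, c.g2, len(c.evidence)) for c in candidates] == [
            ("GA", "GB", 3),
            ("GA", "GC", 2),
        ]

    def test_empty_and_single(self, filter_store):
        assert collect_candidates([]) == []
        ev = make_evidence(filter_store, make_pair(), hit("TA", 1, "p1/1"), hit("TB", 1, "p1/2"))
        assert len(collect_candidates([ev])) == 1

    def test_filter_idempotence(self, filter_store):
        evs = [
            make_evidence(filter_store, make_pair("x"), hit("TA", 1, "x/1"), hit("TA", 2, "x/2")),
            make_evidence(filter_store, make_pair("y"), hit("TA", 69, "y/1"), hit("TB", 15, "y/2")),
            make_evidence(filter_store, make_pair("z"), hit("TA", 1, "z/1"), None),
        ]
        for filt in (
            filter_same_gene,
            filter_unaligned,
            lambda p: filter_paralogs(p, filter_store),
            lambda p: filter_antisense(p, filter_store),
            lambda p: filter_insert_geometry(p, filter_store),
        ):
            filt(evs)
            snapshot = [(ev.stage, ev.d1, ev.d2) for ev in evs]
            filt(evs)
            assert [(ev.stage, ev.d1, ev.d2) for ev in evs] == snapshot

    def test_stage_counts_reconcile(self, filter_store):
        evs = [
            make_evidence(filter_store, make_pair("x"), hit("TA", 1, "x/1"), hit("TA", 2, "x/2")),
            make_evidence(filter_store, make_pair("y"), hit("TA", 69, "y/1"), hit("TB", 15, "y/2")),
            make_evidence(filter_store, make_pair("z"), None, None),
        ]
        filter_same_gene(evs)
        filter_unaligned(evs)
        filter_insert_geometry(evs, filter_store)
        counts = stage_counts(evs)
        assert counts["STEP4A_SAME_GENE"] == 1
        assert counts["STEP4B_UNALIGNED"] == 1
        assert counts["live_evidence"] == 1
        total = sum(counts[s.value] for s in Stage) + counts["live_evidence"]
        assert total == len(evs)
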
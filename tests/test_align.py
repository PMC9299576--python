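import numpy as np
import pytest

from cfrna.align import (
    AlignmentRecord,
    AssignedRead,
    TierAligner,
    TieredAligner,
    align_v1,
    assign_tiers,
    mirna_positional_filter,
    sense_antisense_ratio,
)
from cfrna.preprocess import ReadRecord
from cfrna.references import MatureMiRNA, ReferenceSet, TranscriptRecord
from cfrna.simulate import revcomp

from conftest import brute_force_align, random_seq


def rr(read_id, bases):
    return ReadRecord(read_id, bases, "I" * len(bases))


class TestAlignV1:
    def test_planted_read_found_once(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 300)
        read = seq[50:70]
        t = TranscriptRecord("t", "g", "mRNA", seq)
        hits = align_v1("r", read, [t])
        # brute force confirms uniqueness at this seed
        assert brute_force_align(read, [t]) == [("t", 50, 0)]
        assert [(h.transcript_id, h.start, h.mismatches) for h in hits] == [
            ("t", 50, 0)
        ]

    def test_best_stratum_suppresses_one_mismatch_hits(self):
        rng = np.random.default_rng(2)
        seq_a = random_seq(rng, 100)
        read = seq_a[10:40]
        mutated = read[:5] + ("A" if read[5] != "A" else "C") + read[6:]
        t_a = TranscriptRecord("A", "A", "mRNA", seq_a)
        t_b = TranscriptRecord("B", "B", "mRNA", random_seq(rng, 30) + mutated)
        hits = align_v1("r", read, [t_a, t_b])
        assert {h.transcript_id for h in hits} == {"A"}
        assert all(h.mismatches == 0 for h in hits)

    def test_forward_only_misses_reverse_complement(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 200)
        t = TranscriptRecord("t", "g", "mRNA", seq)
        assert align_v1("r", revcomp(seq[20:60]), [t]) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        """Pigeonhole seed search equals the all-offset oracle, including
        reads with a planted mismatch and multi-mapping reads."""
        rng = np.random.default_rng(seed)
        ts = [
            TranscriptRecord(f"t{i}", f"g{i}", "mRNA", random_seq(rng, 300))
            for i in range(5)
        ]
        aligner = TierAligner(ts)
        for _ in range(50):
            src = ts[rng.integers(5)]
            s = int(rng.integers(0, src.length - 20))
            read = src.sequence[s : s + 20]
            if rng.random() < 0.5:  # plant a mismatch
                i = int(rng.integers(20))
                read = read[:i] + "ACGT"[rng.integers(4)] + read[i + 1 :]
            got = [
                (h.transcript_id, h.start, h.mismatches)
                for h in aligner.align("r", read)
            ]
            assert got == brute_force_align(read, ts)


class TestMirnaFilter:
    MATURE = [MatureMiRNA("miR-9", "hp", 10, 32)]

    def aln(self, start, end):
        return AlignmentRecord("r", "hp", start, end - start, 0)

    @pytest.mark.parametrize(
        "start,end,status",
        [
            (12, 33, "kept"),     # offsets (2, 1)
            (13, 37, "kept"),     # boundary offsets (3, 5)
            (14, 33, "rejected"), # start offset 4 > 3
            (10, 38, "rejected"), # end offset 6 > 5
            (7, 27, "kept"),      # offsets (3, 5) on the low side
            (6, 32, "rejected"),  # start offset 4
        ],
    )
    def test_positional_thresholds(self, start, end, status):
        got, name, _ = mirna_positional_filter(self.aln(start, end), self.MATURE)
        assert got == status
        if status == "kept":
            assert name == "miR-9"

    def test_hairpin_without_mature_distinct_status(self):
        got, _, _ = mirna_positional_filter(self.aln(10, 32), [])
        assert got == "no_mature"

    def test_closest_mature_wins(self):
        matures = [
            MatureMiRNA("miR-5p", "hp", 10, 32),
            MatureMiRNA("miR-3p", "hp", 12, 34),
        ]
        got, name, offsets = mirna_positional_filter(self.aln(12, 33), matures)
        assert (got, name, offsets) == ("kept", "miR-3p", (0, 1))


class TestAssignTiers:
    def test_rrna_read_depleted_before_mirna(self, toy_refset):
        read = toy_refset.sequence("rRNA1")[100:130]
        assigned, stats = assign_tiers([rr("r1", read)], toy_refset)
        assert stats["n_depleted"] == 1
        assert assigned == []

    def test_trna_outranks_pirna_on_equal_stratum(self, toy_refset):
        # the toy piRNA1 sequence is embedded verbatim in tRNA1
        read = toy_refset.sequence("piRNA1")[:24]
        assigned, _ = assign_tiers([rr("r1", read)], toy_refset)
        [a] = assigned
        assert a.biotype == "tRNA"
        assert a.target_ids == ("tRNA1",)
        assert a.weight_per_target == 1.0

    def test_two_pirna_hits_split_weight(self, toy_refset):
        # plant a read present in both piRNA-only transcripts
        seq = toy_refset.sequence("piRNA2")
        extra = TranscriptRecord("piRNA3", "piRNA3", "piRNA", seq)
        rs = ReferenceSet(
            list(toy_refset.transcripts.values()) + [extra],
            toy_refset.matures,
        )
        assigned, _ = assign_tiers([rr("r1", seq[:20])], rs)
        [a] = assigned
        assert a.target_ids == ("piRNA2", "piRNA3")
        assert a.weight_per_target == 0.5

    def test_mature_mirna_read_assigned(self, toy_refset):
        m = toy_refset.matures[0]
        read = toy_refset.sequence("hp1")[m.start : m.end]
        assigned, _ = assign_tiers([rr("r1", read)], toy_refset)
        [a] = assigned
        assert (a.tier, a.target_ids) == ("miRNA", ("miR-1",))

    def test_hairpin_read_off_mature_falls_through_to_unmapped(self, toy_refset):
        read = toy_refset.sequence("hp1")[40:60]  # far from mature at [10,32)
        assigned, stats = assign_tiers([rr("r1", read)], toy_refset)
        assert assigned == [] and stats["n_unmapped"] == 1

    def test_conservation_over_random_reads(self, sim_refset):
        rng = np.random.default_rng(5)
        tids = sorted(sim_refset.transcripts)
        reads = []
        for i in range(200):
            t = sim_refset.transcripts[tids[rng.integers(len(tids))]]
            s = int(rng.integers(0, t.length - 20))
            reads.append(rr(f"r{i}", t.sequence[s : s + 20]))
        reads.append(rr("junk", "ACGT" * 5))
        assigned, stats = assign_tiers(reads, sim_refset)
        assert stats["n_input"] == 201
        assert (
            stats["n_depleted"]
            + sum(stats["per_tier"].values())
            + stats["n_unmapped"]
            == stats["n_input"]
        )

    def test_later_tier_additions_do_not_steal_earlier_reads(self, toy_refset):
        read = toy_refset.sequence("tRNA1")[30:55]
        a1, _ = assign_tiers([rr("r1", read)], toy_refset)
        # add an mRNA (later tier) containing the same sequence
        extra = TranscriptRecord(
            "mRNA9", "mRNA9", "mRNA", read + toy_refset.sequence("mRNA1")[:100]
        )
        rs = ReferenceSet(
            list(toy_refset.transcripts.values()) + [extra], toy_refset.matures
        )
        a2, _ = assign_tiers([rr("r1", read)], rs)
        assert a1[0].target_ids == a2[0].target_ids == ("tRNA1",)


class TestSenseAntisense:
    def test_pure_sense_and_pure_antisense(self, toy_refset):
        seq = toy_refset.sequence("mRNA1")
        sense = [rr(f"s{i}", seq[i : i + 25]) for i in range(0, 100, 10)]
        anti = [rr(f"a{i}", revcomp(seq[i : i + 25])) for i in range(0, 100, 10)]
        fs = sense_antisense_ratio(sense, toy_refset)
        fa = sense_antisense_ratio(anti, toy_refset)
        assert fs["mRNA"]["sense"] == 1.0
        assert fa["mRNA"]["antisense"] == 1.0

    def test_mixture_fraction_recovered(self, toy_refset):
        rng = np.random.default_rng(6)
        seq = toy_refset.sequence("mRNA2")
        reads = []
        n, p_sense = 2000, 0.8
        for i in range(n):
            s = int(rng.integers(0, len(seq) - 25))
            piece = seq[s : s + 25]
            if rng.random() >= p_sense:
                piece = revcomp(piece)
            reads.append(rr(f"r{i}", piece))
        frac = sense_antisense_ratio(reads, toy_refset)["mRNA"]["sense"]
        assert abs(frac - p_sense) < 3 * np.sqrt(p_sense * (1 - p_sense) / n)
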
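"""Segment maps, read classification, profiles and Venn partitions."""

import itertools
import random

import pytest

from spliceomir.annotation_io import MiRNALocus, ReadAlignment
from spliceomir.segmental_profiler import (
    SegmentClass, build_segment_map, classify_read, profile, venn_partition,
    venn_set_totals,
)


@pytest.fixture
def locus():
    return MiRNALocus("hsa-mir-x", "c1", "+", (5000, 5085),
                      {"5p": (5006, 5028), "3p": (5058, 5080)})


@pytest.fixture
def smap(locus):
    return build_segment_map(locus, margin_nt=25)


class TestSegmentMap:
    def test_tiling_matches_definition(self, smap):
        assert smap.leader == (5000, 5006)
        assert smap.mature5p == (5006, 5028)
        assert smap.loop == (5028, 5058)
        assert smap.mature3p == (5058, 5080)
        assert smap.trailer == (5080, 5085)
        assert smap.left_margin == (4975, 5000)
        assert smap.right_margin == (5085, 5110)

    def test_tiling_has_no_gaps(self, smap):
        segs = sorted([smap.leader, smap.mature5p, smap.loop,
                       smap.mature3p, smap.trailer])
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            assert e1 == s2
        assert (segs[0][0], segs[-1][1]) == smap.hairpin

    def test_margin_clipped_at_contig_start(self):
        loc = MiRNALocus("m", "c1", "+", (10, 90), {"5p": (16, 38), "3p": (60, 82)})
        sm = build_segment_map(loc, margin_nt=25, contig_length=100)
        assert sm.left_margin == (0, 10)
        assert sm.right_margin == (90, 100)

    def test_minus_strand_same_genomic_intervals(self):
        loc = MiRNALocus("m", "c1", "-", (5000, 5085),
                         {"3p": (5006, 5028), "5p": (5058, 5080)})
        sm = build_segment_map(loc, 25)
        assert sm.mature5p == (5058, 5080)
        assert sm.mature3p == (5006, 5028)
        # leader is the transcription-order upstream side: high coords on minus
        assert sm.leader == (5080, 5085)
        assert sm.trailer == (5000, 5006)

    def test_single_arm_locus_gets_empty_segments(self):
        loc = MiRNALocus("m", "c1", "+", (100, 180), {"5p": (106, 128)})
        sm = build_segment_map(loc, 25)
        assert sm.mature5p == (106, 128)
        assert sm.mature3p[0] == sm.mature3p[1]  # zero-length


class TestClassifyRead:
    def r(self, start, end, strand="+"):
        return ReadAlignment("r", "c1", strand, start, end)

    def test_exact_arm_match_is_mature(self, smap):
        assert classify_read(self.r(5006, 5028), smap) is SegmentClass.MATURE

    def test_border_crossing_read_is_overlap(self, smap):
        # 8 nt left of the arm/loop border at 5028, 12 nt right
        assert classify_read(self.r(5020, 5040), smap) is SegmentClass.OVERLAP

    def test_antisense_read_is_complement(self, smap):
        assert classify_read(self.r(5030, 5050, "-"), smap) is SegmentClass.COMPLEMENT

    def test_margin_crossing_read_is_extension(self, smap):
        assert classify_read(self.r(4995, 5015), smap) is SegmentClass.EXTENSION

    def test_loop_contained_read_is_loop(self, smap):
        assert classify_read(self.r(5030, 5050), smap) is SegmentClass.LOOP

    def test_arm_with_small_slop_is_still_mature(self, smap):
        # 2 nt beyond each arm end: below the 3-nt border threshold
        assert classify_read(self.r(5004, 5028), smap) is SegmentClass.MATURE
        assert classify_read(self.r(5006, 5030), smap) is SegmentClass.MATURE

    def test_non_overlapping_read_rejected(self, smap):
        with pytest.raises(ValueError):
            classify_read(self.r(8000, 8020), smap)

    def test_agrees_with_brute_force_on_adversarial_border_reads(self, smap):
        """Independent oracle: re-derive the class from first principles by
        interval arithmetic over every border and segment."""
        rng = random.Random(0)
        borders = [5006, 5028, 5058, 5080]
        for _ in range(500):
            b = rng.choice(borders + [5000, 5085])
            start = b + rng.randint(-25, 3)
            length = rng.randint(17, 30)
            read = self.r(start, start + length)
            got = classify_read(read, smap, border_overhang=3)
            assert got is _oracle_classify(read, smap, 3)

    def test_strand_symmetry_under_mirror(self, locus):
        """Classifying mirrored reads on the mirrored locus gives the same
        class multiset."""
        N = 10_000
        mirrored = MiRNALocus(
            locus.mirna_id, "c1m", "-", (N - locus.hairpin[1], N - locus.hairpin[0]),
            {"5p": (N - locus.mature_arms["5p"][1], N - locus.mature_arms["5p"][0]),
             "3p": (N - locus.mature_arms["3p"][1], N - locus.mature_arms["3p"][0])},
        )
        sm = build_segment_map(locus, 25)
        smm = build_segment_map(mirrored, 25)
        rng = random.Random(1)
        fwd, rev = [], []
        for i in range(300):
            start = rng.randint(4975, 5090)
            length = rng.randint(17, 30)
            strand = rng.choice("+-")
            fwd.append(classify_read(self.r(start, start + length, strand), sm))
            flipped = "-" if strand == "+" else "+"
            rev.append(classify_read(
                ReadAlignment("r", "c1m", flipped, N - start - length, N - start), smm))
        assert sorted(c.value for c in fwd) == sorted(c.value for c in rev)


def _oracle_classify(read, smap, k):
    """Brute-force reimplementation of the decision rule via raw interval
    arithmetic (kept independent of the production code paths)."""
    hs, he = smap.hairpin
    if read.strand != smap.locus.strand:
        return SegmentClass.COMPLEMENT
    covered = set(range(read.start, read.end))
    if (hs in covered and len([p for p in covered if p < hs]) >= k) or \
       (he in covered and read.start < he and len([p for p in covered if p >= he]) >= k):
        return SegmentClass.EXTENSION
    for b in smap.internal_borders:
        left = len([p for p in covered if p < b])
        right = len([p for p in covered if p >= b])
        if covered and min(left, right) >= k and read.start <= b - k and read.end >= b + k:
            return SegmentClass.OVERLAP
    for iv in (smap.mature5p, smap.mature3p):
        if iv[1] > iv[0]:
            outside = [p for p in covered if not iv[0] <= p < iv[1]]
            before = len([p for p in outside if p < iv[0]])
            after = len([p for p in outside if p >= iv[1]])
            if before < k and after < k and covered & set(range(*iv)):
                return SegmentClass.MATURE
    for iv in (smap.leader, smap.loop, smap.trailer):
        if iv[1] > iv[0]:
            outside = [p for p in covered if not iv[0] <= p < iv[1]]
            before = len([p for p in outside if p < iv[0]])
            after = len([p for p in outside if p >= iv[1]])
            if before < k and after < k and covered & set(range(*iv)):
                return SegmentClass.LOOP
    return SegmentClass.UNASSIGNED


class TestProfile:
    def test_references_vs_unique_items(self, locus):
        reads = {
            "hsa-mir-x": [
                ReadAlignment("a", "c1", "+", 5006, 5028),  # mature
                ReadAlignment("b", "c1", "+", 5020, 5040),  # overlap
            ]
        }
        prof = profile(reads, [locus])
        assert prof.references == 2
        assert prof.unique_items == 1
        assert prof.class_read_totals["mature"] == 1
        assert prof.class_read_totals["overlap"] == 1

    def test_empty_read_set_gives_zero_profile(self, locus):
        prof = profile({}, [locus])
        assert prof.references == 0 and prof.unique_items == 0
        assert sum(prof.class_read_totals.values()) == 0

    def test_class_counts_conserve_reads(self, locus):
        rng = random.Random(3)
        reads = [ReadAlignment(f"r{i}", "c1", rng.choice("+-"),
                               s := rng.randint(4980, 5085), s + rng.randint(17, 25))
                 for i in range(200)]
        prof = profile({"hsa-mir-x": reads}, [locus])
        assert sum(prof.class_read_totals.values()) == prof.n_reads == 200


class TestVennPartition:
    def test_k5_enumerates_32_sections(self):
        sets = {f"S{i}": {i, 99} for i in range(5)}
        sections = venn_partition(sets)
        assert len(sections) == 32
        assert sections[frozenset(sets)] == 1  # 99 is in all five

    def test_small_example(self):
        sections = venn_partition({"A": {"x", "y"}, "B": {"y"}, "C": set()})
        assert sections[frozenset({"A"})] == 1
        assert sections[frozenset({"A", "B"})] == 1
        assert sum(sections.values()) == 2

    def test_matches_bitmask_oracle_k4(self):
        rng = random.Random(7)
        universe = list(range(60))
        sets = {n: set(rng.sample(universe, rng.randint(0, 40))) for n in "ABCD"}
        sections = venn_partition(sets, universe=universe)
        # independent per-id membership bitmask count
        from collections import Counter
        oracle = Counter(
            frozenset(n for n in sets if i in sets[n]) for i in universe
        )
        for sec, count in sections.items():
            assert count == oracle.get(sec, 0)
        assert sum(sections.values()) == len(universe)

    def test_per_set_totals_recovered_from_sections(self):
        sets = {"A": {1, 2, 3}, "B": {2, 3, 4, 5}, "C": {5}}
        totals = venn_set_totals(venn_partition(sets))
        assert totals == {"A": 3, "B": 4, "C": 1}

    @pytest.mark.parametrize("k", [1, 7])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            venn_partition({f"S{i}": set() for i in range(k)})
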
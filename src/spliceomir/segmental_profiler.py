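"""Hairpin segmentation and five-group read classification.

Each pre-miRNA hairpin is tiled (in transcription order) into leader,
5p mature arm, loop, 3p mature arm and trailer segments, flanked by two
extension margins of genomic sequence outside the annotated precursor.
Every aligned read gets exactly one class:

mature     contained in a mature arm (small end-wobble slop allowed)
loop       contained in within-precursor non-mature sequence
overlap    crosses an internal segment border with enough nt on both sides
extension  crosses a hairpin end into the flanking margin
complement antisense to the locus strand
unassigned none of the above

Precedence is complement, then extension, then overlap, then containment;
a read that both leaves the precursor and crosses an internal border is an
extension read.
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import MiRNALocus, ReadAlignment


class SegmentClass(enum.Enum):
    MATURE = "mature"
    LOOP = "loop"
    OVERLAP = "overlap"
    EXTENSION = "extension"
    COMPLEMENT = "complement"
    UNASSIGNED = "unassigned"

    def __str__(self):
        return self.value


#: the five named read groups (everything but unassigned)
NAMED_CLASSES = (
    SegmentClass.MATURE, SegmentClass.LOOP, SegmentClass.OVERLAP,
    SegmentClass.EXTENSION, SegmentClass.COMPLEMENT,
)


@dataclass(frozen=True)
class SegmentMap:
    """Genomic tiling of one hairpin plus its extension margins.

    Intervals are half-open genomic; empty (zero-length) segments are kept
    so that the tiling is gap-free.  ``internal_borders`` are the positions
    strictly inside the hairpin where two segments meet.
    """

    locus: MiRNALocus
    leader: tuple
    mature5p: tuple
    loop: tuple
    mature3p: tuple
    trailer: tuple
    left_margin: tuple
    right_margin: tuple
    internal_borders: tuple = field(default=())

    @property
    def hairpin(self) -> tuple:
        return self.locus.hairpin

    def arms(self) -> list:
        return [iv for iv in (self.mature5p, self.mature3p) if iv[1] > iv[0]]

    def within_precursor_nonmature(self) -> list:
        return [iv for iv in (self.leader, self.loop, self.trailer) if iv[1] > iv[0]]


def build_segment_map(locus: MiRNALocus, margin_nt: int = 25,
                      contig_length: int = None) -> SegmentMap:
    """Tile a hairpin into segments and attach flanking extension margins.

    Single-arm loci get zero-length segments on the missing side; margins
    are clipped at contig bounds when ``contig_length`` is given.
    """
    if not locus.mature_arms:
        raise ValueError(f"{locus.mirna_id}: no mature arms")
    hs, he = locus.hairpin
    arms_by_pos = sorted(locus.mature_arms.values())
    if len(arms_by_pos) == 2:
        left_arm, right_arm = arms_by_pos
    else:
        left_arm = right_arm = arms_by_pos[0]
    leader_g = (hs, left_arm[0])
    loop_g = (left_arm[1], right_arm[0]) if left_arm != right_arm else (left_arm[1], left_arm[1])
    trailer_g = (right_arm[1], he)
    left_margin = (max(0, hs - margin_nt), hs)
    right_margin = (he, he + margin_nt if contig_length is None else min(contig_length, he + margin_nt))
    # genomic -> transcription-order naming
    if locus.strand == "+":
        m5, m3 = ((left_arm, right_arm) if len(arms_by_pos) == 2 else
                  ((left_arm, (left_arm[1], left_arm[1])) if "5p" in locus.mature_arms
                   else ((left_arm[0], left_arm[0]), left_arm)))
        leader, trailer = leader_g, trailer_g
    else:
        if len(arms_by_pos) == 2:
            m5, m3 = right_arm, left_arm
        elif "5p" in locus.mature_arms:
            m5, m3 = left_arm, (left_arm[0], left_arm[0])
        else:
            m5, m3 = (left_arm[1], left_arm[1]), left_arm
        leader, trailer = trailer_g, leader_g
    borders = sorted(
        {p for iv in (leader_g, left_arm, loop_g, right_arm, trailer_g) for p in iv}
        - {hs, he}
    )
    return SegmentMap(
        locus=locus, leader=leader, mature5p=tuple(m5), loop=loop_g,
        mature3p=tuple(m3), trailer=trailer,
        left_margin=left_margin, right_margin=right_margin,
        internal_borders=tuple(borders),
    )


def _contained_with_slop(read, iv, slop):
    return (max(0, iv[0] - read.start) < slop and max(0, read.end - iv[1]) < slop
            and read.start < iv[1] and read.end > iv[0])


def classify_read(read: ReadAlignment, smap: SegmentMap,
                  border_overhang: int = 3) -> SegmentClass:
    """Assign one segment class to a read overlapping the locus window."""
    hs, he = smap.hairpin
    window = (smap.left_margin[0], smap.right_margin[1])
    if read.end <= window[0] or read.start >= window[1]:
        raise ValueError(
            f"read {read.read_id} does not overlap locus window of {smap.locus.mirna_id}"
        )
    if read.strand != smap.locus.strand:
        return SegmentClass.COMPLEMENT
    # extension: crosses a hairpin end with >= border_overhang nt outside
    if read.start < hs <= read.end - 1 and hs - read.start >= border_overhang:
        return SegmentClass.EXTENSION
    if read.start < he < read.end and read.end - he >= border_overhang:
        return SegmentClass.EXTENSION
    # overlap: crosses an internal border with >= border_overhang nt both sides
    for b in smap.internal_borders:
        if read.start <= b - border_overhang and read.end >= b + border_overhang:
            return SegmentClass.OVERLAP
    for arm in smap.arms():
        if _contained_with_slop(read, arm, border_overhang):
            return SegmentClass.MATURE
    for iv in smap.within_precursor_nonmature():
        if _contained_with_slop(read, iv, border_overhang):
            return SegmentClass.LOOP
    return SegmentClass.UNASSIGNED


def assign_reads_to_loci(reads, loci, margin_nt: int = 25,
                         contig_lengths: dict = None) -> dict:
    """Assign each read to the locus window it overlaps most.

    Returns ``{mirna_id: [reads]}``; reads overlapping no locus window are
    dropped.  Ties go to the lexicographically smallest mirna_id.
    """
    maps = {
        loc.mirna_id: build_segment_map(
            loc, margin_nt,
            None if contig_lengths is None else contig_lengths.get(loc.contig_id),
        )
        for loc in loci
    }
    trees = defaultdict(IntervalTree)
    for mid, sm in maps.items():
        trees[sm.locus.contig_id].addi(sm.left_margin[0], sm.right_margin[1], mid)
    assigned = defaultdict(list)
    for read in reads:
        hits = trees[read.contig_id].overlap(read.start, read.end)
        if not hits:
            continue
        best = max(
            hits,
            key=lambda h: (min(read.end, h.end) - max(read.start, h.begin), h.data),
        )
        # max() prefers larger mirna_id on ties; re-pick smallest among max-overlap
        best_ov = min(read.end, best.end) - max(read.start, best.begin)
        cands = sorted(
            h.data for h in hits
            if min(read.end, h.end) - max(read.start, h.begin) == best_ov
        )
        assigned[cands[0]].append(read)
    return {mid: assigned[mid] for mid in sorted(assigned)}


@dataclass
class SegmentalProfile:
    """Read- and miRNA-level tallies of segment classes.

    ``references`` counts (miRNA, class) pairs with nonzero reads over the
    five named groups; ``unique_items`` counts distinct miRNAs among them.
    """

    per_mirna_class: pd.DataFrame  # index mirna_id, columns class names
    class_read_totals: dict  # class name -> reads
    references: int
    unique_items: int
    class_sets: dict  # class name -> set of mirna ids (named classes only)
    n_reads: int = 0

    def class_fractions(self) -> dict:
        total = sum(self.class_read_totals.values())
        return {k: (v / total if total else 0.0) for k, v in self.class_read_totals.items()}


def profile(reads_by_locus: dict, loci, margin_nt: int = 25,
            border_overhang: int = 3, contig_lengths: dict = None) -> SegmentalProfile:
    """Classify pre-assigned reads per locus and tally the segment classes."""
    loci_by_id = {loc.mirna_id: loc for loc in loci}
    counts = Counter()
    n_reads = 0
    for mid, reads in reads_by_locus.items():
        loc = loci_by_id[mid]
        smap = build_segment_map(
            loc, margin_nt,
            None if contig_lengths is None else contig_lengths.get(loc.contig_id),
        )
        for read in reads:
            cls = classify_read(read, smap, border_overhang)
            counts[(mid, cls.value)] += 1
            n_reads += 1
    class_names = [c.value for c in SegmentClass]
    mirna_ids = sorted(loci_by_id)
    table = pd.DataFrame(0, index=mirna_ids, columns=class_names, dtype=int)
    for (mid, cname), n in counts.items():
        table.loc[mid, cname] = n
    class_read_totals = {c.value: int(table[c.value].sum()) for c in SegmentClass}
    class_sets = {
        c.value: set(table.index[table[c.value] > 0]) for c in NAMED_CLASSES
    }
    named = table[[c.value for c in NAMED_CLASSES]]
    references = int((named > 0).sum().sum())
    unique_items = int((named.sum(axis=1) > 0).sum())
    return SegmentalProfile(
        per_mirna_class=table, class_read_totals=class_read_totals,
        references=references, unique_items=unique_items,
        class_sets=class_sets, n_reads=n_reads,
    )


def venn_partition(named_sets: dict, universe=None) -> dict:
    """Exact membership-section counts for k named sets (2 <= k <= 6).

    Returns ``{frozenset(of set names): count}`` over all 2^k sections; the
    empty frozenset counts ids in ``universe`` outside the union (0 when no
    universe is given).  Every id lands in exactly one section, so the
    section counts sum to |union| (+ outside-union).
    """
    k = len(named_sets)
    if not (2 <= k <= 6):
        raise ValueError(f"venn_partition needs 2..6 sets, got {k}")
    names = sorted(named_sets)
    sections = {
        frozenset(combo): 0
        for r in range(k + 1)
        for combo in itertools.combinations(names, r)
    }
    union = set().union(*named_sets.values())
    for item in union:
        member = frozenset(n for n in names if item in named_sets[n])
        sections[member] += 1
    if universe is not None:
        sections[frozenset()] = len(set(universe) - union)
    return sections


def venn_set_totals(sections: dict) -> dict:
    """Recover each set's total from a section table (sum of its sections)."""
    names = set().union(*sections.keys())
    return {
        n: sum(count for sec, count in sections.items() if n in sec)
        for n in names
    }


def venn_table(sections: dict) -> pd.DataFrame:
    rows = [
        ("+".join(sorted(sec)) if sec else "(outside)", n)
        for sec, n in sorted(sections.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["section", "count"])
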
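"""Antisense splice-junction complementarity scanning.

A mature miRNA expressed antisense to a spliced transcript can base-pair
across one of the transcript's splice junctions (the miR-99b / SPACA6-AS1
configuration).  The scan extracts, for each junction, a window covering
the last ``upstream`` exonic and first ``downstream`` intronic nucleotides
in transcription order (default -6..+16, i.e. a 22-nt window) and scores
ungapped antiparallel Watson-Crick complementarity of antisense mature
arms against it.  No thermodynamic model is used: the scores are the
number of paired positions and the longest paired run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import (
    GenomeSequence, MiRNALocus, SpliceJunction, TranscriptModel, revcomp,
)

# Watson-Crick pairs over DNA letters (miRNA U is mapped to T at input)
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class JunctionWindow:
    """A junction-centered window on the transcript strand.

    Positions -upstream..-1 are on the exonic side of the boundary and
    +1..+downstream on the other side (there is no position 0); length is
    ``upstream + downstream``.
    """

    junction: SpliceJunction
    upstream: int
    downstream: int
    genomic_interval: tuple  # forward-genome half-open
    sequence: str  # transcript strand, transcription order

    def __post_init__(self):
        if len(self.sequence) != self.upstream + self.downstream:
            raise ValueError("window sequence length != upstream + downstream")


@dataclass(frozen=True)
class DuplexResult:
    """Ungapped antiparallel pairing of a miRNA against a junction window."""

    mirna_id: str
    transcript_id: str
    junction: SpliceJunction
    n_paired: int
    n_total: int
    longest_paired_run: int
    full_complement: bool
    wobble_allowed: bool
    length_mismatch: bool = False
    arm: str = ""
    window: JunctionWindow = None


def junction_window(junction: SpliceJunction, transcript: TranscriptModel,
                    genome: GenomeSequence, upstream: int = 6,
                    downstream: int = 16) -> JunctionWindow:
    """Extract the -upstream..+downstream window around one splice site.

    For a five_prime site the upstream side is exonic and the downstream
    side intronic; for a three_prime site the roles are mirrored (upstream
    intronic, downstream exonic).  The sequence is returned on the
    transcript strand in transcription order.
    """
    if junction.transcript_id and junction.transcript_id != transcript.transcript_id:
        raise ValueError("junction does not belong to transcript")
    if junction.kind == "five_prime":
        boundary_first_after = junction.donor_pos  # first intronic base
    else:
        boundary_first_after = junction.acceptor_pos + 1 if transcript.strand == "+" \
            else junction.acceptor_pos  # first exonic base after the intron
    if transcript.strand == "+":
        start = boundary_first_after - upstream
        end = boundary_first_after + downstream
        seq = genome.slice(start, end)  # raises off-contig
    else:
        # transcription order runs toward lower genomic coordinates
        if junction.kind == "five_prime":
            first_after_g = junction.donor_pos  # highest intronic base
        else:
            first_after_g = junction.acceptor_pos - 1  # first exonic base (genomic)
        start = first_after_g - downstream + 1
        end = first_after_g + upstream + 1
        seq = revcomp(genome.slice(start, end))
    return JunctionWindow(junction, upstream, downstream, (start, end), seq)


def duplex_complementarity(mirna_seq: str, window_seq: str,
                           allow_gu: bool = False, mirna_id: str = "",
                           transcript_id: str = "", junction: SpliceJunction = None,
                           arm: str = "", window: JunctionWindow = None) -> DuplexResult:
    """Score ungapped antiparallel pairing of a miRNA against a window.

    The miRNA 5'->3' is laid against the window 3'->5', so position i of the
    miRNA pairs with position L-1-i of the window.  With unequal lengths the
    overlap of length min(len) is scored and ``length_mismatch`` is set;
    ``full_complement`` additionally requires equal lengths.
    """
    if not mirna_seq or not window_seq:
        raise ValueError("empty sequence")
    q = mirna_seq.upper().replace("U", "T")
    w = window_seq.upper().replace("U", "T")
    n = min(len(q), len(w))
    pairs = _WC | _GU if allow_gu else _WC
    n_paired = longest = run = 0
    for i in range(n):
        if (q[i], w[len(w) - 1 - i]) in pairs:
            n_paired += 1
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    mismatch = len(q) != len(w)
    full = (not mismatch) and n_paired == n
    return DuplexResult(
        mirna_id=mirna_id, transcript_id=transcript_id, junction=junction,
        n_paired=n_paired, n_total=n, longest_paired_run=longest,
        full_complement=full, wobble_allowed=allow_gu,
        length_mismatch=mismatch, arm=arm, window=window,
    )


@dataclass(frozen=True)
class ExonOverlapHit:
    """An antisense miRNA locus overlapping a transcript exon body."""

    mirna_id: str
    transcript_id: str
    exon_index: int  # 1-based, transcription order
    overlap_nt: int


@dataclass
class ScanResult:
    junction_hits: list  # DuplexResult, sorted n_paired desc then ids
    exon_hits: list  # ExonOverlapHit (only in exon mode)


def _overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def scan(loci, transcripts, genomes: dict, upstream: int = 6, downstream: int = 16,
         allow_gu: bool = False, region: str = "hairpin",
         sites=("five_prime",), exon_mode: bool = False) -> ScanResult:
    """Scan all antisense (miRNA locus, transcript) pairs for junction duplexes.

    For every pair on opposite strands with genomic overlap, each junction
    window (of the configured site kinds) that overlaps the miRNA locus
    (hairpin, or mature arms when ``region='arm'``) is scored against every
    mature arm of the locus.  ``exon_mode`` additionally reports antisense
    loci overlapping exon bodies, which never become junction hits.
    """
    from .annotation_io import derive_junctions

    hits, exon_hits = [], []
    for t in transcripts:
        junctions = [j for j in derive_junctions(t) if j.kind in sites]
        for loc in loci:
            if loc.contig_id != t.contig_id or loc.strand == t.strand:
                continue
            if _overlap(loc.hairpin, t.span) == 0:
                continue
            genome = genomes[t.contig_id]
            gate_ivs = [loc.hairpin] if region == "hairpin" else list(loc.mature_arms.values())
            for j in junctions:
                win = junction_window(j, t, genome, upstream, downstream)
                if not any(_overlap(win.genomic_interval, iv) for iv in gate_ivs):
                    continue
                for arm in sorted(loc.mature_arms):
                    res = duplex_complementarity(
                        loc.arm_sequence(genome, arm), win.sequence,
                        allow_gu=allow_gu, mirna_id=loc.mirna_id,
                        transcript_id=t.transcript_id, junction=j, arm=arm,
                        window=win,
                    )
                    hits.append(res)
            if exon_mode:
                order = t.exons_in_transcription_order()
                for idx, exon in enumerate(order, 1):
                    ov = _overlap(loc.hairpin, exon)
                    if ov:
                        exon_hits.append(
                            ExonOverlapHit(loc.mirna_id, t.transcript_id, idx, ov)
                        )
    hits.sort(key=lambda r: (-r.n_paired, r.mirna_id, r.arm, r.transcript_id,
                             r.junction.intron_index))
    exon_hits.sort(key=lambda h: (h.mirna_id, h.transcript_id, h.exon_index))
    return ScanResult(junction_hits=hits, exon_hits=exon_hits)


def scan_report(result: ScanResult):
    """Flat table of junction hits (for the TSV report)."""
    import pandas as pd

    rows = [
        dict(
            mirna_id=r.mirna_id, arm=r.arm, transcript_id=r.transcript_id,
            intron_index=r.junction.intron_index, site=r.junction.kind,
            window_start=r.window.genomic_interval[0],
            window_end=r.window.genomic_interval[1],
            n_paired=r.n_paired, n_total=r.n_total,
            longest_run=r.longest_paired_run, full_complement=r.full_complement,
        )
        for r in result.junction_hits
    ]
    cols = ["mirna_id", "arm", "transcript_id", "intron_index", "site",
            "window_start", "window_end", "n_paired", "n_total",
            "longest_run", "full_complement"]
    return pd.DataFrame(rows, columns=cols)
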
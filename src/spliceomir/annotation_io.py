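"""Readers, writers and coordinate conventions for all pipeline inputs.

All internal coordinates are 0-based half-open ``[start, end)`` on the
forward genomic strand; GFF3 (1-based inclusive) and SAM (1-based) are
converted at the boundary.  Strand is ``'+'`` or ``'-'``; positions on the
minus strand are still stored in forward-genome coordinates, with
transcription order derived from the strand where needed.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_DNA = re.compile(r"[^ACGTN]")
_FAMILY_RE = re.compile(r"^(?:[a-z]{2,4}-)?((?:mir|let)-\d+)", re.IGNORECASE)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: uppercase DNA over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.contig_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Forward-strand subsequence; rejects out-of-bounds lookups."""
        if not (0 <= start <= end <= len(self.sequence)):
            raise IndexError(
                f"slice [{start}, {end}) outside contig {self.contig_id!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: ordered, non-overlapping exons on one strand."""

    transcript_id: str
    gene_id: str
    contig_id: str
    strand: str
    exons: tuple  # of (start, end), 0-based half-open, sorted by start
    biotype: str = "misc_RNA"

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        object.__setattr__(self, "exons", tuple(map(tuple, self.exons)))
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty/inverted exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exons_in_transcription_order(self) -> list:
        return list(self.exons) if self.strand == "+" else list(reversed(self.exons))


@dataclass(frozen=True)
class SpliceJunction:
    """One splice site handle of one intron, in transcription order.

    ``donor_pos`` is the first intronic base in transcription order and
    ``acceptor_pos`` the last; both are 0-based forward-genome positions.
    ``kind`` selects which side of the intron this handle refers to.
    """

    contig_id: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    intron_index: int  # 1-based, transcription order
    kind: str  # "five_prime" | "three_prime"
    transcript_id: str = ""

    def __post_init__(self):
        if self.kind not in ("five_prime", "three_prime"):
            raise ValueError(f"bad junction kind {self.kind!r}")


@dataclass(frozen=True)
class MiRNALocus:
    """A pre-miRNA hairpin with up to two annotated mature arms."""

    mirna_id: str
    contig_id: str
    strand: str
    hairpin: tuple  # (start, end)
    mature_arms: dict = field(default_factory=dict)  # {"5p"|"3p": (start, end)}
    family: str = ""

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        hs, he = self.hairpin
        if he <= hs:
            raise ValueError(f"{self.mirna_id}: empty hairpin")
        arms = {k: tuple(v) for k, v in self.mature_arms.items()}
        object.__setattr__(self, "mature_arms", arms)
        for name, (s, e) in arms.items():
            if name not in ("5p", "3p"):
                raise ValueError(f"{self.mirna_id}: bad arm name {name!r}")
            if not (hs <= s < e <= he):
                raise ValueError(f"{self.mirna_id}: arm {name} [{s},{e}) outside hairpin [{hs},{he})")
        if "5p" in arms and "3p" in arms:
            a5, a3 = arms["5p"], arms["3p"]
            if a5[1] > a3[0] and a3[1] > a5[0]:
                raise ValueError(f"{self.mirna_id}: arms overlap")
            upstream_first = a5[0] < a3[0] if self.strand == "+" else a5[0] > a3[0]
            if not upstream_first:
                raise ValueError(f"{self.mirna_id}: 5p arm not upstream of 3p in transcription order")
        if not self.family:
            object.__setattr__(self, "family", mirna_family(self.mirna_id))

    def arm_sequence(self, genome: GenomeSequence, arm: str) -> str:
        """Mature-arm sequence 5'->3' (reverse-complemented on minus strand)."""
        s, e = self.mature_arms[arm]
        raw = genome.slice(s, e)
        return raw if self.strand == "+" else revcomp(raw)


@dataclass(frozen=True)
class ReadAlignment:
    """A gapless small-RNA read alignment interval."""

    read_id: str
    contig_id: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: empty interval")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.read_id}: bad strand")

    @property
    def length(self) -> int:
        return self.end - self.start


class AlignmentCollection(list):
    """A list of ReadAlignment plus the count of rejected (gapped) records."""

    def __init__(self, reads=(), n_rejected: int = 0):
        super().__init__(reads)
        self.n_rejected = n_rejected


@dataclass
class CountMatrix:
    """miRNA x sample count table with cell-line grouping of the columns."""

    counts: pd.DataFrame  # index mirna_id, columns sample_id
    groups: dict  # sample_id -> cell-line label
    normalization_state: str = "raw"  # raw | cpm | size_factor

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative entries in count matrix")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate row or column labels")
        missing = [c for c in self.counts.columns if c not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def cell_lines(self) -> list:
        seen = []
        for c in self.counts.columns:
            g = self.groups[c]
            if g not in seen:
                seen.append(g)
        return seen

    def pooled(self) -> pd.DataFrame:
        """Sum replicate columns within each cell line."""
        pooled = {}
        for line in self.cell_lines:
            cols = [c for c in self.counts.columns if self.groups[c] == line]
            pooled[line] = self.counts[cols].sum(axis=1)
        return pd.DataFrame(pooled)


@dataclass(frozen=True)
class TrendRecord:
    """Per-disease literature report tally for one miRNA."""

    mirna_id: str
    disease: str
    n_up: int
    n_down: int

    def __post_init__(self):
        if self.n_up < 0 or self.n_down < 0 or self.n_up + self.n_down < 1:
            raise ValueError(f"{self.mirna_id}/{self.disease}: need >=1 report")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path) -> dict:
    """Read a FASTA file into ``{contig_id: GenomeSequence}``.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a warning.  Duplicate contig ids and empty files are hard errors.
    """
    genomes = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genomes:
            raise ValueError(f"duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        n_bad = len(_VALID_DNA.findall(seq))
        if n_bad:
            warnings.warn(f"contig {rec.id}: {n_bad} non-ACGTN characters mapped to N")
            seq = _VALID_DNA.sub("N", seq)
        genomes[rec.id] = GenomeSequence(rec.id, seq)
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_genome(genomes: dict, path) -> None:
    recs = [SeqRecord(Seq(g.sequence), id=cid, description="") for cid, g in sorted(genomes.items())]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 transcripts
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("transcript", "mRNA", "lnc_RNA", "primary_transcript")


def _gff_db(path):
    return gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)


def read_transcripts(path) -> list:
    """Read gene/transcript/exon GFF3 into TranscriptModel objects.

    GFF3 1-based inclusive coordinates become 0-based half-open; exons are
    stored sorted in genomic order.  An exon without a parent transcript, or
    overlapping exons within one transcript, are errors.
    """
    db = _gff_db(path)
    known = {t.id for t in db.features_of_type(_TRANSCRIPT_TYPES)}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in known for p in parents):
            raise ValueError(f"exon at {exon.seqid}:{exon.start}-{exon.end} has no parent transcript")
    out = []
    for t in db.features_of_type(_TRANSCRIPT_TYPES):
        exons = sorted(
            ((e.start - 1, e.end) for e in db.children(t, featuretype="exon")),
            key=lambda iv: iv[0],
        )
        if not exons:
            raise ValueError(f"transcript {t.id} has no exons")
        gene = t.attributes.get("Parent", [t.attributes.get("gene_id", [t.id])[0]])[0]
        biotype = t.attributes.get("biotype", t.attributes.get("gene_biotype", ["misc_RNA"]))[0]
        out.append(
            TranscriptModel(
                transcript_id=t.id, gene_id=gene, contig_id=t.seqid,
                strand=t.strand, exons=tuple(exons), biotype=biotype,
            )
        )
    out.sort(key=lambda t: t.transcript_id)
    return out


def write_transcripts(transcripts, path) -> None:
    """Write TranscriptModels as GFF3 (gene/transcript/exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            s, e = t.span
            fh.write(
                f"{t.contig_id}\tspliceomir\tgene\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                f"ID=gene:{t.gene_id}\n"
            )
            fh.write(
                f"{t.contig_id}\tspliceomir\ttranscript\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent=gene:{t.gene_id};biotype={t.biotype}\n"
            )
            for i, (xs, xe) in enumerate(t.exons, 1):
                fh.write(
                    f"{t.contig_id}\tspliceomir\texon\t{xs + 1}\t{xe}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                )


def derive_junctions(transcript: TranscriptModel) -> list:
    """Splice junctions of a transcript, one five_prime/three_prime pair per intron.

    ``donor_pos`` is the first intronic base in transcription order, so on
    the minus strand it sits at the *higher* genomic coordinate of the
    intron.  A single-exon transcript yields an empty list.
    """
    exons = list(transcript.exons)
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    if transcript.strand == "-":
        introns = list(reversed(introns))
    out = []
    for idx, (gs, ge) in enumerate(introns, 1):
        if transcript.strand == "+":
            donor, acceptor = gs, ge - 1
        else:
            donor, acceptor = ge - 1, gs
        for kind in ("five_prime", "three_prime"):
            out.append(
                SpliceJunction(
                    contig_id=transcript.contig_id, strand=transcript.strand,
                    donor_pos=donor, acceptor_pos=acceptor,
                    intron_index=idx, kind=kind, transcript_id=transcript.transcript_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# miRNA loci (miRBase-dialect GFF3)
# ---------------------------------------------------------------------------

def mirna_family(mirna_id: str) -> str:
    """Family stem of a miRNA id: strip species prefix, arm suffix and
    locus-copy numbering, then collapse lettered variants on the numeric stem
    (``hsa-let-7a-1 -> let-7``, ``hsa-mir-99b -> mir-99``)."""
    m = _FAMILY_RE.match(mirna_id.strip())
    return m.group(1).lower() if m else mirna_id.lower()


def read_mirna_loci(path) -> list:
    """Read a miRBase-dialect GFF3 of hairpins and mature arms.

    ``miRNA_primary_transcript`` features are hairpins; ``miRNA`` features
    reference their hairpin via ``Derives_from``.  Arm side comes from a
    ``-5p``/``-3p`` name suffix, else from genomic position and strand.
    """
    db = _gff_db(path)
    hairpins = {}
    for h in db.features_of_type("miRNA_primary_transcript"):
        name = h.attributes.get("Name", [h.id])[0]
        hairpins[h.id] = dict(name=name, contig=h.seqid, strand=h.strand,
                              interval=(h.start - 1, h.end), arms={})
    for m in db.features_of_type("miRNA"):
        parents = m.attributes.get("Derives_from", m.attributes.get("Parent", []))
        if not parents or parents[0] not in hairpins:
            raise ValueError(f"mature miRNA {m.id} does not reference a known hairpin")
        h = hairpins[parents[0]]
        name = m.attributes.get("Name", [m.id])[0]
        iv = (m.start - 1, m.end)
        if name.endswith("-5p"):
            side = "5p"
        elif name.endswith("-3p"):
            side = "3p"
        else:
            side = None
        h["arms"][m.id] = (side, iv)
    out = []
    for h in hairpins.values():
        arms = {}
        unnamed = sorted((iv for side, iv in h["arms"].values() if side is None), key=lambda iv: iv[0])
        for side, iv in h["arms"].values():
            if side is not None:
                arms[side] = iv
        if unnamed:
            # positional fallback: upstream arm in transcription order is 5p
            order = unnamed if h["strand"] == "+" else list(reversed(unnamed))
            for side, iv in zip(("5p", "3p"), order):
                if side in arms:
                    raise ValueError(f"{h['name']}: ambiguous arm naming")
                arms[side] = iv
        out.append(
            MiRNALocus(mirna_id=h["name"], contig_id=h["contig"], strand=h["strand"],
                       hairpin=h["interval"], mature_arms=arms)
        )
    out.sort(key=lambda l: l.mirna_id)
    return out


def write_mirna_loci(loci, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in sorted(loci, key=lambda l: l.mirna_id):
            hs, he = loc.hairpin
            hid = f"{loc.mirna_id}.hp"
            fh.write(
                f"{loc.contig_id}\tspliceomir\tmiRNA_primary_transcript\t{hs + 1}\t{he}\t.\t"
                f"{loc.strand}\t.\tID={hid};Name={loc.mirna_id}\n"
            )
            for side in ("5p", "3p"):
                if side in loc.mature_arms:
                    s, e = loc.mature_arms[side]
                    fh.write(
                        f"{loc.contig_id}\tspliceomir\tmiRNA\t{s + 1}\t{e}\t.\t{loc.strand}\t.\t"
                        f"ID={loc.mirna_id}-{side};Name={loc.mirna_id}-{side};Derives_from={hid}\n"
                    )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignments(path, dialect: str = "bed") -> AlignmentCollection:
    """Read BED6 or SAM alignments into 0-based half-open intervals.

    The read model is gapless: SAM records whose CIGAR contains anything
    other than aligned-match operations (M/=/X) are rejected and counted in
    ``result.n_rejected``.
    """
    if dialect == "bed":
        reads = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
                chrom, start, end, name, _score, strand = parts[:6]
                reads.append(ReadAlignment(name, chrom, strand, int(start), int(end)))
        return AlignmentCollection(reads)
    if dialect == "sam":
        reads, n_rejected = [], 0
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                if any(op not in (0, 7, 8) for op, _ in (rec.cigartuples or [])):
                    n_rejected += 1
                    continue
                reads.append(
                    ReadAlignment(
                        rec.query_name, rec.reference_name,
                        "-" if rec.is_reverse else "+",
                        rec.reference_start, rec.reference_end,
                    )
                )
        if n_rejected:
            log.info("rejected %d gapped/clipped SAM records", n_rejected)
        return AlignmentCollection(reads, n_rejected)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignments_bed(reads, path) -> None:
    with open(path, "w") as fh:
        for r in sorted(reads, key=lambda r: (r.contig_id, r.start, r.read_id)):
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_counts_tsv(path, groups: dict = None, normalization_state: str = "raw") -> CountMatrix:
    """Read a counts TSV (first column mirna_id, remaining columns samples).

    ``groups`` maps sample to cell line; if omitted, the prefix of the sample
    id before the last ``_`` is used (``HCN_rep1 -> HCN``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if groups is None:
        groups = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return CountMatrix(df, groups, normalization_state)


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    df = matrix.counts.sort_index()
    df.index.name = "mirna_id"
    df.to_csv(path, sep="\t")


def read_trend_table(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        TrendRecord(row.mirna_id, row.disease, int(row.n_up), int(row.n_down))
        for row in df.itertuples()
    ]


def write_trend_table(records, path) -> None:
    rows = sorted(records, key=lambda r: (r.mirna_id, r.disease))
    df = pd.DataFrame(
        [(r.mirna_id, r.disease, r.n_up, r.n_down) for r in rows],
        columns=["mirna_id", "disease", "n_up", "n_down"],
    )
    df.to_csv(path, sep="\t", index=False)
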
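"""Synthetic locus, read, count and trend-table generator with ground truth.

The generator emulates the study design this package analyzes: a sense
gene whose intron hosts a three-hairpin miRNA cluster (a miR-99b /
let-7e / miR-125a analog), an antisense two-exon lncRNA whose intron-1
five-prime junction window (-6..+16) is, by construction, the exact
reverse complement of the planted miRNA's 22-nt 5p arm; segment-labelled
small-RNA reads drawn from the hairpins; negative-binomial replicate
counts for three cell lines in biological triplicate; and a
miRCancer-style trend table with a controllable fraction of conflicting
reports.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import (
    GenomeSequence, MiRNALocus, ReadAlignment, TranscriptModel, CountMatrix,
    TrendRecord, revcomp,
)
from .segmental_profiler import SegmentClass, build_segment_map

CONTIG = "chrS"
CONTIG_LEN = 20_000

#: default per-class read proportions: mature-dominated, as in a normal
#: cortical-neuron spliceosome fraction where ~98% of hairpin reads are
#: mature-arm derived.
DEFAULT_PROPORTIONS = {
    "mature5p": 0.68,
    "mature3p": 0.30,
    "loop": 0.004,
    "overlap": 0.010,
    "extension": 0.003,
    "complement": 0.003,
}

READ_CLASSES = tuple(DEFAULT_PROPORTIONS)

CELL_LINES = ("HCN", "U87MG", "SH-SY5Y")
DISEASES = ("glioma", "glioblastoma")


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions."""

    seed: int
    n_reads: int = 100_000  # reads per sample
    n_mirnas: int = 30
    n_samples_per_line: int = 3  # biological triplicates
    cell_lines: tuple = CELL_LINES
    read_len_range: tuple = (17, 30)
    dispersion: float = 0.1  # NB alpha: var = mu + alpha mu^2
    conflict_fraction: float = 0.1
    n_reports: int = 10
    dem_fraction: float = 0.2  # share of miRNAs given a planted fold change
    dem_fold: float = 8.0
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    margin_nt: int = 25
    border_overhang: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_reads", "n_mirnas", "n_samples_per_line", "n_reports"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.conflict_fraction <= 0.5:
            raise ValueError("conflict_fraction must be in [0, 0.5]")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        if self.n_mirnas < 3:
            raise ValueError("need at least the 3 cluster miRNAs")


@dataclass
class PlantedLocusTruth:
    """Ground truth for every downstream stage."""

    loci: list  # MiRNALocus, cluster first
    transcripts: list
    antisense_transcript_id: str
    planted_mirna_id: str
    planted_arm: str
    planted_intron_index: int
    window_interval: tuple  # genomic, equals the planted 5p arm interval
    proportions: dict
    baseline_weights: dict  # mirna_id -> relative abundance
    multipliers: dict  # cell line -> {mirna_id: multiplier}
    true_dem: dict  # (line_a, line_b) -> {mirna_id: "up"|"down"}
    config: SimulationConfig = None


def _hairpin(mirna_id, start, strand="+"):
    """A 76-nt hairpin: 6 leader, 22 5p, 20 loop, 22 3p, 6 trailer."""
    arms = {"5p": (start + 6, start + 28), "3p": (start + 48, start + 70)}
    if strand == "-":
        arms = {"5p": (start + 48, start + 70), "3p": (start + 6, start + 28)}
    return MiRNALocus(mirna_id=mirna_id, contig_id=CONTIG, strand=strand,
                      hairpin=(start, start + 76), mature_arms=arms)


def make_planted_locus(config: SimulationConfig, seed: int = None):
    """Build the planted antisense-junction locus.

    Returns ``(genome_dict, transcripts, loci, truth)``.  The contig is
    random under the seed except for planted splice-site dinucleotides; the
    full-complement identity between the planted arm and the lncRNA
    junction window holds because the arm interval *is* the window
    interval, read on opposite strands.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=CONTIG_LEN)
    seq = b"".join(seq).decode()

    # antisense lncRNA (minus strand): exon1 [9000,9400), intron [5600,9000),
    # exon2 [5000,5600); its 5' junction of intron 1 sits at genomic 9000.
    b0 = 9000
    up, down = 6, 16
    # plant canonical GT..AG on the minus strand: transcript base at genomic p
    # is complement(genome[p])
    seq = seq[:8998] + "AC" + seq[9000:]          # donor GT (transcript) at 8999,8998
    seq = seq[:5600] + "CT" + seq[5602:]          # acceptor AG (transcript) at 5601,5600
    genome = {CONTIG: GenomeSequence(CONTIG, seq)}

    sense_gene = TranscriptModel(
        transcript_id="SENSE-1", gene_id="SENSE", contig_id=CONTIG, strand="+",
        exons=((2000, 2300), (16000, 16500)), biotype="protein_coding",
    )
    lnc = TranscriptModel(
        transcript_id="AS-LNC-1", gene_id="AS-LNC", contig_id=CONTIG, strand="-",
        exons=((5000, 5600), (b0, 9400)), biotype="lncRNA",
    )

    # planted hairpin: 5p arm is exactly the window interval [b0-16, b0+6)
    planted = _hairpin("syn-mir-99b", b0 - down - 6)  # arm = [b0-16, b0+6)
    assert planted.mature_arms["5p"] == (b0 - down, b0 + up)
    neighbors = [_hairpin("syn-let-7e", 9100), _hairpin("syn-mir-125a", 9250)]
    background_ids = ["syn-let-7a", "syn-let-7b", "syn-let-7c"]
    background_ids += [f"syn-mir-{200 + k}" for k in range(len(background_ids), config.n_mirnas - 3)]
    background_ids = background_ids[: config.n_mirnas - 3]
    starts = [11000 + 150 * k for k in range(len(background_ids))]
    if starts and starts[-1] + 76 + config.margin_nt > CONTIG_LEN:
        raise ValueError("too many miRNAs for the contig layout")
    background = [_hairpin(mid, s) for mid, s in zip(background_ids, starts)]
    loci = [planted] + neighbors + background

    weights = {loc.mirna_id: float(w) for loc, w in
               zip(loci, np.exp(rng.uniform(np.log(1.0), np.log(100.0), size=len(loci))))}

    # planted fold changes: each DEM miRNA is perturbed in one non-reference
    # cell line, up or down by config.dem_fold
    mult = {line: {loc.mirna_id: 1.0 for loc in loci} for line in config.cell_lines}
    n_dem = int(round(config.dem_fraction * len(loci)))
    dem_ids = list(rng.choice([l.mirna_id for l in loci], size=n_dem, replace=False))
    for mid in dem_ids:
        line = config.cell_lines[1 + rng.integers(len(config.cell_lines) - 1)]
        direction = config.dem_fold if rng.random() < 0.5 else 1.0 / config.dem_fold
        mult[line][mid] = direction
    true_dem = {}
    for i, a in enumerate(config.cell_lines):
        for b in config.cell_lines[i + 1:]:
            calls = {}
            for loc in loci:
                ratio = mult[a][loc.mirna_id] / mult[b][loc.mirna_id]
                if ratio >= 5:
                    calls[loc.mirna_id] = "up"
                elif ratio <= 0.2:
                    calls[loc.mirna_id] = "down"
            true_dem[(a, b)] = calls

    truth = PlantedLocusTruth(
        loci=loci, transcripts=[sense_gene, lnc],
        antisense_transcript_id=lnc.transcript_id,
        planted_mirna_id=planted.mirna_id, planted_arm="5p",
        planted_intron_index=1, window_interval=(b0 - down, b0 + up),
        proportions=dict(config.proportions), baseline_weights=weights,
        multipliers=mult, true_dem=true_dem, config=config,
    )
    # construction invariant: revcomp(mature arm) == junction window sequence
    arm_seq = planted.arm_sequence(genome[CONTIG], "5p")
    window_seq = revcomp(genome[CONTIG].slice(b0 - down, b0 + up))
    assert revcomp(arm_seq) == window_seq
    return genome, [sense_gene, lnc], loci, truth


def _sample_read(rng, cls, smap, lmin, lmax, overhang, margin_nt):
    """Uniformly sample one read of the given class within its geometric
    constraints; returns (start, end, strand)."""
    loc = smap.locus
    hs, he = loc.hairpin
    if cls in ("mature5p", "mature3p"):
        arm = smap.mature5p if cls == "mature5p" else smap.mature3p
        alen = arm[1] - arm[0]
        if alen < lmin:
            raise ValueError(f"{loc.mirna_id}: arm shorter than min read length")
        L = int(rng.integers(lmin, min(lmax, alen) + 1))
        s = int(rng.integers(arm[0], arm[1] - L + 1))
        return s, s + L, loc.strand
    if cls == "loop":
        loop = smap.loop
        llen = loop[1] - loop[0]
        if llen < lmin:
            raise ValueError(f"{loc.mirna_id}: loop shorter than min read length")
        L = int(rng.integers(lmin, min(lmax, llen) + 1))
        s = int(rng.integers(loop[0], loop[1] - L + 1))
        return s, s + L, loc.strand
    if cls == "overlap":
        borders = smap.internal_borders
        if not borders:
            raise ValueError(f"{loc.mirna_id}: no internal borders")
        b = int(borders[rng.integers(len(borders))])
        L = int(rng.integers(max(lmin, 2 * overhang), lmax + 1))
        lo = max(hs, b - L + overhang)
        hi = min(b - overhang, he - L)
        if lo > hi:
            raise ValueError(f"{loc.mirna_id}: overlap read infeasible at border {b}")
        s = int(rng.integers(lo, hi + 1))
        return s, s + L, loc.strand
    if cls == "extension":
        L = int(rng.integers(max(lmin, overhang + 1), lmax + 1))
        side = "left" if rng.random() < 0.5 else "right"
        out_max = min(margin_nt, L - 1)
        o = int(rng.integers(overhang, out_max + 1))
        if side == "left":
            s = hs - o
        else:
            s = he + o - L
        return s, s + L, loc.strand
    if cls == "complement":
        L = int(rng.integers(lmin, min(lmax, he - hs) + 1))
        s = int(rng.integers(hs, he - L + 1))
        return s, s + L, ("-" if loc.strand == "+" else "+")
    raise ValueError(f"unknown read class {cls!r}")


def simulate_reads(truth: PlantedLocusTruth, n_reads: int, seed: int):
    """Draw segment-labelled reads from the planted loci.

    Loci are chosen proportionally to the truth's baseline weights, classes
    multinomially from the truth proportions, and positions uniformly
    within each class's geometric constraints, so the classifier label of
    every read is unambiguous.  Returns ``(AlignmentCollection-like list,
    {read_id: SegmentClass})``.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    lmin, lmax = cfg.read_len_range
    probs = np.array([truth.proportions.get(c, 0.0) for c in READ_CLASSES])
    ids = [loc.mirna_id for loc in truth.loci]
    w = np.array([truth.baseline_weights[m] for m in ids])
    w = w / w.sum()
    smaps = {
        loc.mirna_id: build_segment_map(loc, cfg.margin_nt, CONTIG_LEN)
        for loc in truth.loci
    }
    label_of = {
        "mature5p": SegmentClass.MATURE, "mature3p": SegmentClass.MATURE,
        "loop": SegmentClass.LOOP, "overlap": SegmentClass.OVERLAP,
        "extension": SegmentClass.EXTENSION, "complement": SegmentClass.COMPLEMENT,
    }
    reads, labels = [], {}
    if n_reads == 0:
        return reads, labels
    locus_idx = rng.choice(len(ids), size=n_reads, p=w)
    class_idx = rng.choice(len(READ_CLASSES), size=n_reads, p=probs)
    for i in range(n_reads):
        cls = READ_CLASSES[class_idx[i]]
        smap = smaps[ids[locus_idx[i]]]
        s, e, strand = _sample_read(
            rng, cls, smap, lmin, lmax, cfg.border_overhang, cfg.margin_nt,
        )
        rid = f"r{i:07d}"
        reads.append(ReadAlignment(rid, CONTIG, strand, s, e))
        labels[rid] = label_of[cls]
    return reads, labels


def simulate_counts(truth: PlantedLocusTruth, config: SimulationConfig = None,
                    seed: int = None):
    """Negative-binomial replicate counts for all cell lines.

    Per-entry mean is ``n_reads * lib_factor * abundance * multiplier``;
    variance follows var = mu + alpha mu^2 with alpha = config.dispersion.
    Returns ``(CountMatrix raw, true_dem)`` where true_dem maps each
    cell-line pair to the planted >=5-fold miRNAs with direction.
    """
    import pandas as pd

    cfg = config or truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = [loc.mirna_id for loc in truth.loci]
    w = np.array([truth.baseline_weights[m] for m in ids])
    p_base = w / w.sum()
    size = 1.0 / cfg.dispersion
    cols, groups = {}, {}
    for line in cfg.cell_lines:
        m = np.array([truth.multipliers[line][mid] for mid in ids])
        for rep in range(1, cfg.n_samples_per_line + 1):
            sample = f"{line}_rep{rep}"
            lib = rng.uniform(0.8, 1.2)
            mu = cfg.n_reads * lib * p_base * m
            counts = rng.negative_binomial(size, size / (size + mu))
            cols[sample] = counts
            groups[sample] = line
    df = pd.DataFrame(cols, index=ids)
    return CountMatrix(df, groups, "raw"), truth.true_dem


def true_trends(truth: PlantedLocusTruth, contrast: tuple = None,
                diseases: tuple = DISEASES) -> dict:
    """Per-(miRNA, disease) literature-truth directions from the planted DEMs.

    The default contrast is the second cell line versus the first
    (cancer-analog vs normal-analog); every planted DEM of that contrast
    gets the same true direction in each disease.
    """
    cfg = truth.config
    contrast = contrast or (cfg.cell_lines[1], cfg.cell_lines[0])
    a, b = contrast
    key = (a, b) if (a, b) in truth.true_dem else (b, a)
    calls = truth.true_dem[key]
    flip = key != (a, b)
    out = {}
    for mid, direction in calls.items():
        if flip:
            direction = "down" if direction == "up" else "up"
        for dis in diseases:
            out[(mid, dis)] = direction
    return out


def simulate_trend_table(trends: dict, conflict_fraction: float, seed: int,
                         n_reports: int = 10) -> list:
    """miRCancer-style report tallies with a planted conflict share.

    Each (miRNA, disease) gets ``n_reports`` reports of which exactly
    ``round(conflict_fraction * n_reports)`` contradict the true trend (so
    conflict_fraction 0.2 at 10 reports plants 2 opposite reports, which
    the strict >10% rule flags as conflicted, while 0.1 plants exactly the
    non-conflicted boundary).  The seed only fixes output order.
    """
    if not 0 <= conflict_fraction <= 0.5:
        raise ValueError("conflict_fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    n_opp = int(round(conflict_fraction * n_reports))
    records = []
    for (mid, disease), direction in sorted(trends.items()):
        up = n_reports - n_opp if direction == "up" else n_opp
        records.append(TrendRecord(mid, disease, up, n_reports - up))
    perm = rng.permutation(len(records))
    return [records[i] for i in perm]


def write_synthetic_dataset(outdir, config: SimulationConfig):
    """Generate and write a full dataset (FASTA/GFF3/BED/TSV + truth/config).

    Returns the truth object and a dict of written paths.
    """
    import pathlib

    import pandas as pd
    import yaml

    from . import annotation_io as aio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, loci, truth = make_planted_locus(config)
    reads, labels = simulate_reads(truth, config.n_reads, config.seed + 1)
    matrix, true_dem = simulate_counts(truth, config, config.seed + 2)
    trends = true_trends(truth)
    trend_records = simulate_trend_table(
        trends, config.conflict_fraction, config.seed + 3, config.n_reports,
    )
    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.gff3",
        "mirnas": outdir / "mirnas.gff3",
        "reads": outdir / "reads.bed",
        "counts": outdir / "counts.tsv",
        "trends": outdir / "trends.tsv",
        "read_labels": outdir / "read_labels.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    aio.write_genome(genome, paths["genome"])
    aio.write_transcripts(transcripts, paths["transcripts"])
    aio.write_mirna_loci(loci, paths["mirnas"])
    aio.write_alignments_bed(reads, paths["reads"])
    aio.write_counts_tsv(matrix, paths["counts"])
    aio.write_trend_table(trend_records, paths["trends"])
    pd.DataFrame(
        sorted(labels.items()), columns=["read_id", "true_class"]
    ).assign(true_class=lambda d: d.true_class.map(lambda c: c.value)).to_csv(
        paths["read_labels"], sep="\t", index=False)
    truth_rows = []
    for loc in truth.loci:
        row = dict(mirna_id=loc.mirna_id, family=loc.family,
                   baseline_weight=truth.baseline_weights[loc.mirna_id])
        for line in config.cell_lines:
            row[f"multiplier_{line}"] = truth.multipliers[line][loc.mirna_id]
        truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return truth, {k: str(v) for k, v in paths.items()}
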
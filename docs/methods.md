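# Methods

## Scope and model

`spliceomir` analyzes small-RNA reads attributed to pre-miRNA hairpin loci
in a nuclear (spliceosome-associated) RNA fraction. It implements four
analysis stages and a ground-truthed generator:

1. **Segmental classification** of reads on hairpin loci,
2. **Antisense splice-junction scanning** for miRNA/lncRNA duplexes,
3. **Expression statistics** (filters, normalization, detection, fold-change
   DEM calls, ddCt),
4. **Trend concordance** against a literature report table.

Read alignment itself is out of scope: alignments are consumed as BED6/SAM
intervals under a gapless model (records with indels or splices are
rejected and counted), which is appropriate for <= ~50 nt small RNAs mapped
within hairpin loci.

All internal coordinates are 0-based half-open on the forward genome
strand; GFF3 (1-based inclusive) and SAM (1-based) are converted at the I/O
boundary only. "5' splice junction", "upstream" and segment order are
always defined in transcription order, so minus-strand loci are handled by
coordinate reflection, never by special-cased logic. Two mirror-image
property tests (segment classification and junction-window extraction under
genome reverse complement) pin this down.

## Hairpin segmentation and read classes

Each hairpin is tiled, in transcription order, into leader, 5p mature arm,
loop, 3p mature arm and trailer segments (zero-length segments are kept so
the tiling is gap-free), flanked by two `margin_nt` (default 25 nt)
extension margins of genomic sequence. Reads get exactly one of six
classes with precedence:

1. **complement** — antisense to the locus strand;
2. **extension** — crosses a hairpin end with >= `border_overhang` nt
   outside the precursor;
3. **overlap** — crosses an internal segment border with >=
   `border_overhang` nt on both sides;
4. **mature** — contained in a mature arm, allowing < `border_overhang` nt
   of end slop;
5. **loop** — contained in leader/loop/trailer (same slop rule); leader and
   trailer are binned with the loop as within-precursor non-mature
   sequence;
6. **unassigned** otherwise.

`border_overhang` defaults to 3 nt. The threshold separates isomiR-style
end wobble (1-2 nt templated/non-templated end variation, which should not
promote an arm read to "overlap") from genuinely border-spanning reads; it
is a configuration knob, not a fitted constant. Putting extension above
overlap resolves the reads that cross both a hairpin end and an internal
border: leaving the annotated precursor is the rarer, more informative
event.

Profiles report *references* ((miRNA, class) pairs with nonzero reads over
the five named classes) and *unique items* (distinct miRNAs among them),
plus per-class miRNA sets for k-set Venn partitions. `venn_partition`
enumerates all 2^k membership sections exactly (k = 2..6) by per-id
membership, so section counts always sum to the union size.

## Junction windows and duplex scoring

For a transcript intron, the five-prime window covers the last `upstream`
exonic and first `downstream` intronic nucleotides in transcription order
(defaults 6 and 16: positions -6..-1 and +1..+16, no position 0, 22 nt
total — the geometry of the motivating miR-99b/SPACA6-AS1 case). The
three-prime window is defined mirror-symmetrically (upstream intronic,
downstream exonic); only five-prime sites are scanned by default.

Duplex scoring lays the mature arm 5'->3' against the window 3'->5'
(antiparallel, ungapped) and counts Watson-Crick pairs (A:U/T, G:C), with
optional G:U wobble. Scores are the number of paired positions and the
longest paired run; `full_complement` requires equal lengths and pairing at
every position. No thermodynamic (free-energy) model is used: the biology
of interest is complete or near-complete complementarity, for which a
pairing count is the direct readout. U is mapped to T at input; DNA
alphabet throughout.

The scan gates candidates on (i) opposite strands, (ii) genomic overlap of
locus and transcript, and (iii) the junction window overlapping the hairpin
(or the arms, per config). An optional exon mode additionally reports
antisense loci overlapping exon bodies (the let-7e / miR-125a-style
configuration), which never appear as junction hits.

## Expression statistics

- **Read filter**: reads < 17 nt are dropped before profiling.
- **Exclusion**: blacklisted entries (default `hsa-miR-6087`, a withdrawn
  catalog entry) are removed from the *raw* matrix before any
  normalization, so library totals are computed without them. The order is
  observable and tested by a two-order comparison.
- **CPM**: value x 1e6 / column total; used for detection thresholds and
  reporting shares.
- **Median-of-ratios size factors**: factor_j = median over rows with
  all-positive counts of count_ij / row geometric mean. On a
  duplicated-then-doubled column pair this gives (1, 2)/sqrt(2).
- **Pooling**: replicates are summed per cell line before detection and
  fold-change calls; size factors are also computed replicate-wise for the
  per-sample normalization path.
- **Detection**: pooled CPM >= `detect_threshold` (default 30) per line;
  the per-line sets feed a 3-set Venn partition.
- **DEM calls**: fold = (a + pseudo)/(b + pseudo) with pseudo = 1 on pooled
  **median-of-ratios-normalized** counts; DEM iff fold >= 5 or <= 0.2.
  CPM is deliberately not used here: with tens of miRNAs, a strong change
  in one high-abundance miRNA shifts the library total and compresses
  every CPM ratio (compositional bias), which median-of-ratios
  normalization absorbs. The pseudo-count handles zeros; the paper-style
  rule gives no zero-handling prescription, and 1.0 in normalized units is
  the smallest count-scale regularizer.
- **Top lists / families**: rows with total normalized reads >= `min_reads`
  ranked by total, with per-line percentage shares; family aggregation
  derives the family stem from the id (strip species prefix, arm suffix and
  locus-copy number; lettered variants collapse, e.g. `hsa-let-7a-1` ->
  `let-7`).
- **ddCt**: per replicate dCt = Ct_target - Ct_reference; ddCt =
  mean dCt(treated) - mean dCt(control); fold = 2^-ddCt, with SD over
  per-replicate treated folds against the control mean.

Dispersion estimation, likelihood-ratio tests and FDR control are
deliberately not implemented; the DEM contract here is the fold-change
rule only.

## Trend concordance

A database record (miRNA, disease, n_up, n_down) is *conflicted* when the
minority share is strictly greater than 10% of reports; a 50/50 tie is
maximal conflict. Exactly 10% is a clean majority call (tested at 10, 20
and 100 reports). Each DEM is classified against the queried diseases into
one of six verdicts — absent, db_conflicted, opposite_all, opposite_one,
concordant_all, concordant_one_absent_other — by the precedence documented
in `trend_concordance._verdict`. The taxonomy is a total function, and
flipping every DEM direction swaps concordant_all with opposite_all while
fixing db_conflicted and absent counts (property-tested).

## The synthetic generator

`make_planted_locus` builds a 20 kb contig containing a plus-strand
two-exon sense gene whose intron hosts a three-hairpin cluster, and a
minus-strand two-exon lncRNA whose intron-1 five-prime junction sits at the
cluster. The planted hairpin's 22-nt 5p arm occupies exactly the window
interval [junction-16, junction+6), so the arm (read on +) is the reverse
complement of the window (read on -) by construction, for every seed.
Canonical GT/AG splice-site dinucleotides are planted on the lncRNA
transcript strand; all other sequence is uniform random under the seed.
The two cluster neighbors overlap the lncRNA's exon 1 only — they exercise
the exon-overlap reporting mode and can never be junction hits. Background
hairpins (76 nt: 6 leader / 22 arm / 20 loop / 22 arm / 6 trailer) are laid
out with >= 150 nt spacing so locus windows are effectively disjoint.

Reads are drawn per locus (abundance-weighted) and per class
(multinomially), uniformly within each class's geometric constraints, so
every read's class label is unambiguous and must be reproduced by the
classifier — an exact, not statistical, oracle. Default proportions are
mature-dominated (98% mature, split 68/30 between arms), emulating a
normal cortical-neuron fraction; lengths are uniform on 17-30 nt so the
>= 17 nt filter is exercised at its boundary. A class that is geometrically
impossible for a locus (e.g. loop reads on a short loop) raises rather than
silently re-sampling.

Counts are negative binomial with mean = depth x library factor x
abundance x cell-line multiplier and variance mu + alpha mu^2. The
`dispersion` knob is this alpha (default 0.1, a typical bulk RNA-seq
biological-replicate value); the NB size parameter used for sampling is
1/alpha. Defaults are three cell lines x three biological replicates at
100,000 reads per sample with 30 miRNAs; 20% of miRNAs get an 8-fold
perturbation in one randomly chosen non-reference line. Abundances are
log-uniform over [1, 100] relative weight, spanning the 2 orders of
magnitude where both detection and fold-change calling remain
well-powered at this depth.

Trend tables give each (miRNA, disease) exactly `n_reports` reports with
`round(conflict_fraction * n_reports)` planted opposite reports, so the
>10% conflict rule's boundary is constructible exactly (0.1 x 10 -> the
non-conflicted boundary; 0.2 x 10 -> conflicted).

What the generator does **not** model: sequencing error, quality scores,
multi-mapping, isomiR end heterogeneity beyond uniform placement, GC or
length bias, and correlated dispersion across miRNAs. Passing tests
therefore demonstrate correctness of the analysis arithmetic and geometry
under the stated statistical model, not robustness to real-library
artifacts.

## Determinism and numerical choices

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds below 2^31 by hashing the stage name with the master seed,
so identical configs give byte-identical outputs (tested by file digests)
and stages can be rerun independently. Ties in read-to-locus assignment go
to the lexicographically smallest miRNA id; writers emit lexicographically
sorted rows. CPM conservation is exact to floating point (columns sum to
1e6); size-factor checks use machine-precision tolerances; statistical
recovery checks (DEM sensitivity >= 0.9, FPR <= 0.05 at fold 8) run over
50 generator seeds, and planted-junction recovery over 20.

Problem sizes in the test suite (1,000-10,000 reads per simulated library,
10-50 seeds per Monte-Carlo check) were chosen so the whole suite settles
in a few seconds while keeping binomial standard errors well below the
margins being asserted.

## Known limitations

- The "complement" class is implemented as antisense alignment; if
  unannotated star-strand species were intended instead, they would
  require an isomiR-level model this package deliberately omits.
- Detection thresholds can be interpreted in CPM or raw-read units
  (`detect_units` semantics differ between protocol descriptions); we
  apply the threshold to pooled per-line CPM.
- The junction-window offsets generalize a single well-characterized
  example; scanning other geometries requires changing `upstream` /
  `downstream`.
- No p-values or FDR accompany DEM calls; the fold-change rule is the
  entire contract.
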
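"""Expression filters, normalization, detection sets, DEM calls and ddCt.

Implements the count-level arithmetic of the pipeline: the >=17 nt read
retention filter, exclusion of withdrawn catalog entries before
normalization, counts-per-million (CPM) and median-of-ratios size
factors, pooled per-cell-line detection sets with Venn partitions,
pseudo-counted fold-change DEM calls at the >=5-fold rule, ranked
top-lists, family aggregation, and 2^-ddCt qPCR quantitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import CountMatrix, mirna_family
from .segmental_profiler import venn_partition

log = logging.getLogger(__name__)

DEFAULT_BLACKLIST = ("hsa-miR-6087",)


def filter_reads(reads, min_len: int = 17):
    """Retain only reads of at least ``min_len`` nt; log the removal count."""
    kept = [r for r in reads if r.length >= min_len]
    removed = len(reads) - len(kept)
    if removed:
        log.info("filter_reads: removed %d reads shorter than %d nt", removed, min_len)
    return kept


def exclude_mirnas(matrix: CountMatrix, blacklist=DEFAULT_BLACKLIST) -> CountMatrix:
    """Drop blacklisted rows from a *raw* matrix, before any normalization.

    Exclusion order is observable: removing a nonzero row changes every CPM
    in its columns.  Absent blacklist entries are ignored with a log note.
    """
    if matrix.normalization_state != "raw":
        raise ValueError("exclude_mirnas must run on raw counts, before normalization")
    present = [m for m in blacklist if m in matrix.counts.index]
    absent = [m for m in blacklist if m not in matrix.counts.index]
    if absent:
        log.info("exclude_mirnas: not present, ignored: %s", absent)
    return CountMatrix(matrix.counts.drop(index=present), dict(matrix.groups), "raw")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: value * 1e6 / column sum."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero total counts in sample(s) {zero}")
    return counts * 1e6 / totals


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (DESeq-style) per-sample size factors.

    factor_j = median over all-positive rows of count_ij / geomean_i.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >=2 samples")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no row with all-positive counts; filter low-count miRNAs first"
        )
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0))


def median_of_ratios_norm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors.

    This is the normalization used for fold-change comparisons: unlike CPM
    it is robust to compositional shifts, where a strongly changed
    high-abundance miRNA would otherwise drag every other ratio with it.
    """
    return counts / size_factors(counts)


@dataclass
class ExpressionSummary:
    """Normalized expression with detection and DEM annotations."""

    cpm: CountMatrix
    pooled_cpm: pd.DataFrame  # one column per cell line (detection scale)
    pooled_norm: pd.DataFrame  # median-of-ratios normalized (fold-change scale)
    size_factors: pd.Series
    detection: dict = field(default_factory=dict)  # line -> set of mirna ids
    venn_sections: dict = field(default_factory=dict)
    dem_tables: dict = field(default_factory=dict)  # (line_a, line_b) -> DataFrame


def detection_sets(pooled_cpm: pd.DataFrame, detect_threshold: float = 30.0):
    """Detected-miRNA sets per cell line and their Venn partition.

    A miRNA is detected in a line when its pooled normalized value meets
    the threshold.
    """
    sets = {
        line: set(pooled_cpm.index[pooled_cpm[line] >= detect_threshold])
        for line in pooled_cpm.columns
    }
    sections = venn_partition(sets, universe=set(pooled_cpm.index))
    return sets, sections


def fold_change_dem(pooled_norm: pd.DataFrame, pair: tuple,
                    fc_threshold: float = 5.0, pseudo: float = 1.0) -> pd.DataFrame:
    """Pseudo-counted fold changes and >=5-fold DEM flags between two lines.

    fold = (a + pseudo) / (b + pseudo); DEM iff fold >= fc_threshold or
    fold <= 1/fc_threshold, with direction up/down accordingly.
    """
    a, b = pair
    fold = (pooled_norm[a] + pseudo) / (pooled_norm[b] + pseudo)
    dem = (fold >= fc_threshold) | (fold <= 1.0 / fc_threshold)
    direction = np.where(fold >= 1.0, "up", "down")
    return pd.DataFrame(
        {"fold": fold, "direction": direction, "dem": dem},
        index=pooled_norm.index,
    )


def top_lists(pooled_norm: pd.DataFrame, min_reads: float) -> pd.DataFrame:
    """Rows with total normalized reads >= min_reads, ranked by total.

    Adds per-line percentage shares (each emitted row's shares sum to 100).
    """
    total = pooled_norm.sum(axis=1)
    kept = pooled_norm[total >= min_reads]
    out = kept.div(kept.sum(axis=1), axis=0) * 100.0
    out.columns = [f"{c}_pct" for c in kept.columns]
    out["total"] = kept.sum(axis=1)
    return out.sort_values("total", ascending=False)


def family_aggregate(pooled_norm: pd.DataFrame, family: str,
                     families: dict = None) -> dict:
    """Per-line totals, within-line share and dominant member of a family.

    ``families`` maps mirna_id -> family; by default the family is derived
    from the id.  Unknown families give an empty result with a warning.
    """
    if families is None:
        families = {m: mirna_family(m) for m in pooled_norm.index}
    members = [m for m in pooled_norm.index if families.get(m) == family]
    if not members:
        log.warning("family_aggregate: no members of family %r", family)
        return {"family": family, "members": [], "totals": {}, "share_pct": {},
                "dominant_member": {}}
    sub = pooled_norm.loc[members]
    line_totals = pooled_norm.sum(axis=0)
    totals = sub.sum(axis=0)
    share = (totals / line_totals * 100.0).where(line_totals > 0, 0.0)
    dominant = {line: sub[line].idxmax() for line in pooled_norm.columns}
    return {
        "family": family, "members": members,
        "totals": totals.to_dict(), "share_pct": share.to_dict(),
        "dominant_member": dominant,
    }


def summarize_expression(matrix: CountMatrix, detect_threshold: float = 30.0,
                         fc_threshold: float = 5.0, pseudo: float = 1.0,
                         blacklist=DEFAULT_BLACKLIST) -> ExpressionSummary:
    """Full expression pass: exclude, normalize, detect, call DEMs.

    Replicates are pooled (summed) per cell line; detection uses pooled
    CPM against the CPM threshold, while fold-change DEM calls use pooled
    median-of-ratios-normalized counts (robust to compositional shifts).
    Size factors are also computed replicate-wise on the filtered raw
    matrix for the per-sample normalization path.
    """
    raw = exclude_mirnas(matrix, blacklist)
    factors = size_factors(raw.counts)
    cpm_df = cpm(raw.counts)
    cpm_matrix = CountMatrix(cpm_df, dict(raw.groups), "cpm")
    pooled = raw.pooled()
    pooled_cpm = cpm(pooled)
    pooled_norm = median_of_ratios_norm(pooled)
    detection, sections = detection_sets(pooled_cpm, detect_threshold)
    lines = raw.cell_lines
    dem_tables = {}
    for i, a in enumerate(lines):
        for b in lines[i + 1:]:
            dem_tables[(a, b)] = fold_change_dem(pooled_norm, (a, b), fc_threshold, pseudo)
    return ExpressionSummary(
        cpm=cpm_matrix, pooled_cpm=pooled_cpm, pooled_norm=pooled_norm,
        size_factors=factors, detection=detection, venn_sections=sections,
        dem_tables=dem_tables,
    )


@dataclass(frozen=True)
class DdCtRecord:
    """Replicate Ct values for one target in treated vs control conditions."""

    name: str
    treated_target_ct: tuple
    treated_ref_ct: tuple
    control_target_ct: tuple
    control_ref_ct: tuple

    def __post_init__(self):
        for f in ("treated_target_ct", "treated_ref_ct",
                  "control_target_ct", "control_ref_ct"):
            vals = getattr(self, f)
            if not vals:
                raise ValueError(f"{self.name}: missing {f}")
            object.__setattr__(self, f, tuple(float(v) for v in vals))
        if len(self.treated_target_ct) != len(self.treated_ref_ct) or \
           len(self.control_target_ct) != len(self.control_ref_ct):
            raise ValueError(f"{self.name}: target/reference replicate mismatch")


def delta_delta_ct(records) -> pd.DataFrame:
    """Relative 2^-ddCt quantitation with replicate SD.

    Per replicate dCt = Ct_target - Ct_ref; ddCt = mean dCt(treated) -
    mean dCt(control); fold = 2^-ddCt.  The SD is taken over per-replicate
    treated folds 2^-(dCt_r - mean dCt(control)).
    """
    rows = []
    for rec in records:
        d_treat = np.array(rec.treated_target_ct) - np.array(rec.treated_ref_ct)
        d_ctl = np.array(rec.control_target_ct) - np.array(rec.control_ref_ct)
        ddct = d_treat.mean() - d_ctl.mean()
        fold = 2.0 ** (-ddct)
        rep_folds = 2.0 ** (-(d_treat - d_ctl.mean()))
        sd = float(rep_folds.std(ddof=1)) if len(rep_folds) > 1 else 0.0
        rows.append(dict(name=rec.name, delta_ct_treated=d_treat.mean(),
                         delta_ct_control=d_ctl.mean(), ddct=ddct,
                         fold=fold, fold_sd=sd))
    return pd.DataFrame(rows).set_index("name")


def read_ddct_tsv(path) -> list:
    """Read ddCt input TSV: columns name, condition, replicate, target_ct, ref_ct."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for name, grp in df.groupby("name", sort=True):
        t = grp[grp.condition == "treated"].sort_values("replicate")
        c = grp[grp.condition == "control"].sort_values("replicate")
        records.append(DdCtRecord(
            name, tuple(t.target_ct), tuple(t.ref_ct),
            tuple(c.target_ct), tuple(c.ref_ct),
        ))
    return records
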
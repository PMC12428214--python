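"""Concordance of cell-line DEM directions with a per-disease report table.

Literature-mined databases tally, per miRNA and disease, how many reports
call the miRNA up- or down-regulated.  A database entry is *conflicted*
when strictly more than 10% of its reports oppose the majority (a 50/50
tie is maximal conflict).  Each DEM is then classified against the
queried diseases into a single verdict.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .annotation_io import TrendRecord

CONFLICT_SHARE = 0.10

VERDICTS = (
    "concordant_all", "opposite_all", "opposite_one",
    "concordant_one_absent_other", "db_conflicted", "absent",
)


def db_direction(record: TrendRecord, conflict_share: float = CONFLICT_SHARE) -> str:
    """Majority direction of a report tally, or ``conflicted``.

    Conflicted iff minority/(n_up + n_down) > conflict_share, strictly:
    exactly 10% opposite reports is still a clean call.
    """
    total = record.n_up + record.n_down
    minority = min(record.n_up, record.n_down)
    if minority / total > conflict_share:
        return "conflicted"
    return "up" if record.n_up >= record.n_down else "down"


@dataclass(frozen=True)
class ConcordanceCall:
    mirna_id: str
    cell_direction: str  # up | down
    db_directions: dict  # disease -> up | down | conflicted | absent
    verdict: str

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"bad verdict {self.verdict!r}")


def _verdict(cell_direction: str, db_dirs: dict) -> str:
    """Total verdict function over the queried diseases.

    Precedence: absent everywhere -> absent; every present record
    conflicted -> db_conflicted; opposite in every disease -> opposite_all;
    any opposite -> opposite_one; concordant in every disease ->
    concordant_all; else (some concordant, rest absent/conflicted) ->
    concordant_one_absent_other.
    """
    states = list(db_dirs.values())
    if all(s == "absent" for s in states):
        return "absent"
    present = [s for s in states if s != "absent"]
    if all(s == "conflicted" for s in present):
        return "db_conflicted"
    n_opp = sum(1 for s in states if s in ("up", "down") and s != cell_direction)
    n_conc = sum(1 for s in states if s == cell_direction)
    if n_opp == len(states):
        return "opposite_all"
    if n_opp >= 1:
        return "opposite_one"
    if n_conc == len(states):
        return "concordant_all"
    return "concordant_one_absent_other"


def classify(dem_table: pd.DataFrame, trend_db, diseases,
             conflict_share: float = CONFLICT_SHARE):
    """Classify every DEM against the trend database.

    ``dem_table`` needs a ``direction`` column (index mirna_id) and is
    restricted to rows flagged ``dem`` when that column exists;
    ``trend_db`` is an iterable of TrendRecord.  Returns
    ``(calls, summary)`` where summary counts verdicts overall and per
    disease counts the per-disease states.
    """
    db = {}
    for rec in trend_db:
        key = (rec.mirna_id, rec.disease)
        if key in db:
            raise ValueError(f"duplicate trend record for {key}")
        db[key] = db_direction(rec, conflict_share)
    rows = dem_table[dem_table["dem"]] if "dem" in dem_table.columns else dem_table
    calls = []
    for mid in sorted(rows.index):
        cell_dir = rows.loc[mid, "direction"]
        db_dirs = {d: db.get((mid, d), "absent") for d in diseases}
        calls.append(ConcordanceCall(
            mirna_id=mid, cell_direction=cell_dir, db_directions=db_dirs,
            verdict=_verdict(cell_dir, db_dirs),
        ))
    summary = {
        "verdicts": dict(Counter(c.verdict for c in calls)),
        "per_disease": {
            d: dict(Counter(c.db_directions[d] for c in calls)) for d in diseases
        },
        "n_dem": len(calls),
    }
    return calls, summary


def calls_table(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = dict(mirna_id=c.mirna_id, cell_direction=c.cell_direction,
                   verdict=c.verdict)
        for d, s in c.db_directions.items():
            row[f"db_{d}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
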
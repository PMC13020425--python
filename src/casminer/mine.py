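"""Genome-mining filter cascade for Cas9 candidates.

Stages: length window (800-1600 aa) -> 100-aa length bins -> selection of
the bin richest in multi-domain Cas9 Pfam annotations -> classifier score
thresholds (report at >0.5, keep at >=0.9) -> ranking of survivors with
more than ``min_repeats`` CRISPR repeats near the locus, ordered by score.

Domain annotation (HMMER vs Pfam) and CRISPR-repeat detection are external
tools; their outputs enter as a tab-separated table with columns
``id``, ``length``, ``pfam_hits`` (comma-separated), ``repeat_count`` and
optionally ``score``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .net import CasMinerClassifier, predict
from .seqio import ProteinSequence

logger = logging.getLogger("casminer")

#: Cas9-related Pfam domains used for bin selection.
CAS9_PFAMS = frozenset(
    {"RuvC_III", "Cas9_BH", "Cas9_REC", "HNH_4", "Cas9_PI"})
DEFAULT_WINDOW = (800, 1600)
DEFAULT_BIN_WIDTH = 100


@dataclass(frozen=True)
class AnnotationRecord:
    """External annotation for one candidate locus.

    ``repeat_count`` is None when no repeat search result is available for
    the genome; ``score`` is an optional precomputed classifier score.
    """

    seq_id: str
    length: int
    pfam_hits: frozenset[str] = frozenset()
    repeat_count: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.seq_id}: length must be >= 1")
        if self.repeat_count is not None and self.repeat_count < 0:
            raise ValueError(f"{self.seq_id}: repeat_count must be >= 0")


@dataclass
class MiningCandidate:
    """A candidate's record through the cascade."""

    seq_id: str
    length: int
    bin_label: str = ""
    pfam_count: int = 0
    score: float | None = None
    repeat_count: int | None = None
    final_rank: int | None = None


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read the annotation TSV (columns id, length, pfam_hits, repeat_count
    and optionally score; header row mandatory)."""
    df = pd.read_csv(path, sep="\t", dtype={"pfam_hits": str})
    required = {"id", "length", "pfam_hits", "repeat_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        hits = getattr(row, "pfam_hits")
        pfams = frozenset(
            h.strip() for h in str(hits).split(",") if h.strip()
        ) if pd.notna(hits) else frozenset()
        rep = getattr(row, "repeat_count")
        score = getattr(row, "score", None)
        out.append(AnnotationRecord(
            seq_id=str(row.id),
            length=int(row.length),
            pfam_hits=pfams,
            repeat_count=None if pd.isna(rep) else int(rep),
            score=None if score is None or pd.isna(score) else float(score),
        ))
    return out


def bin_label(lo: int, width: int) -> str:
    """Inclusive label for the half-open bin [lo, lo+width), e.g. 1301-1400."""
    return f"{lo + 1}-{lo + width}"


def bin_by_length(
    records: list[AnnotationRecord],
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> dict[str, list[AnnotationRecord]]:
    """Partition in-window records into fixed-width length bins.

    Bins are half-open [lo, lo+width) except the final bin, which also
    includes the window maximum.  The default window and width give the
    eight 100-aa subsets spanning 800-1600 residues.
    """
    lo, hi = window
    if lo > hi or lo < 1:
        raise ValueError(f"invalid window {window}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = list(range(lo, hi, bin_width))
    bins: dict[str, list[AnnotationRecord]] = {
        bin_label(e, min(bin_width, hi - e)): [] for e in edges}
    labels = list(bins)
    for rec in records:
        if not lo <= rec.length <= hi:
            continue
        i = min((rec.length - lo) // bin_width, len(labels) - 1)
        bins[labels[i]].append(rec)
    return bins


def select_bin_by_pfam(
    binned: dict[str, list[AnnotationRecord]],
    cas9_pfams: frozenset[str] = CAS9_PFAMS,
    min_domains: int = 3,
) -> tuple[str, pd.DataFrame]:
    """Choose the bin with the most records carrying multi-domain Cas9 hits.

    Counts distinct Cas9-related domains per record (repeated hits of one
    domain count once).  The returned table lists, per bin, the number of
    records with >=3, >=4 and >=5 such domains plus per-domain totals; the
    chosen bin maximises the >=``min_domains`` count, ties going to the
    longer-length bin with a warning.
    """
    if not binned:
        raise ValueError("no bins to select from")
    if not cas9_pfams:
        raise ValueError("cas9_pfams must be non-empty")
    rows = []
    for label, recs in binned.items():
        counts = [len(r.pfam_hits & cas9_pfams) for r in recs]
        row = {"bin": label, "n_records": len(recs),
               "n_ge3": sum(c >= 3 for c in counts),
               "n_ge4": sum(c >= 4 for c in counts),
               "n_ge5": sum(c >= 5 for c in counts)}
        for dom in sorted(cas9_pfams):
            row[dom] = sum(dom in r.pfam_hits for r in recs)
        rows.append(row)
    table = pd.DataFrame(rows)
    key = f"n_ge{min_domains}"
    if key not in table.columns:
        table[key] = [
            sum(len(r.pfam_hits & cas9_pfams) >= min_domains for r in recs)
            for recs in binned.values()]
    if int(table[key].max()) == 0:
        raise ValueError(
            f"no bin contains records with >={min_domains} Cas9-related domains")
    best = int(table[key].max())
    tied = table.loc[table[key] == best, "bin"].tolist()
    if len(tied) > 1:
        warnings.warn(
            f"bins {tied} tied on {key}={best}; choosing the longer-length bin")
    # labels sort correctly by their numeric lower bound
    chosen = max(tied, key=lambda lab: int(lab.split("-")[0]))
    return chosen, table


def score_and_filter(
    candidates: list[AnnotationRecord],
    model: CasMinerClassifier | None = None,
    sequences: dict[str, ProteinSequence] | None = None,
    report_cutoff: float = 0.5,
    keep_cutoff: float = 0.9,
    cas9_pfams: frozenset[str] = CAS9_PFAMS,
) -> tuple[list[MiningCandidate], pd.DataFrame]:
    """Score candidates and keep those at or above ``keep_cutoff``.

    Scores come either from the fitted model applied to ``sequences`` or,
    when no model is given, from the precomputed ``score`` column of the
    annotation table.  The threshold table reports the count at strictly
    > ``report_cutoff`` (the ">50%" convention) and at >= ``keep_cutoff``
    (the ">=90%" convention); survivors are the latter.  Unscoreable
    candidates are skipped with a log message.
    """
    scored: list[MiningCandidate] = []
    if model is not None:
        seqs = []
        for rec in candidates:
            seq = (sequences or {}).get(rec.seq_id)
            if seq is None:
                logger.warning("no sequence for %s; skipped", rec.seq_id)
                continue
            seqs.append((rec, seq))
        results = dict(predict(model, [s for _, s in seqs]))
        for rec, seq in seqs:
            if seq.id not in results:
                continue
            scored.append(MiningCandidate(
                seq_id=rec.seq_id, length=rec.length,
                pfam_count=len(rec.pfam_hits & cas9_pfams),
                score=results[seq.id], repeat_count=rec.repeat_count))
    else:
        for rec in candidates:
            if rec.score is None:
                logger.warning("no score for %s and no model given; skipped",
                               rec.seq_id)
                continue
            scored.append(MiningCandidate(
                seq_id=rec.seq_id, length=rec.length,
                pfam_count=len(rec.pfam_hits & cas9_pfams),
                score=rec.score, repeat_count=rec.repeat_count))
    table = pd.DataFrame([
        {"cutoff": report_cutoff, "comparator": ">",
         "count": sum(c.score > report_cutoff for c in scored)},
        {"cutoff": keep_cutoff, "comparator": ">=",
         "count": sum(c.score >= keep_cutoff for c in scored)},
    ])
    survivors = [c for c in scored if c.score >= keep_cutoff]
    return survivors, table


def rank_by_repeats(
    survivors: list[MiningCandidate], min_repeats: int = 50
) -> list[MiningCandidate]:
    """Rank survivors with strictly more than ``min_repeats`` CRISPR repeats.

    Candidates lacking a repeat count are excluded with a log message (no
    repeat array could be located for their genome).  Survivors are ordered
    by classifier score descending and assigned final ranks 1..n.
    """
    with_repeats = []
    for c in survivors:
        if c.repeat_count is None:
            logger.info("%s has no repeat annotation; excluded from ranking",
                        c.seq_id)
            continue
        if c.repeat_count > min_repeats:
            with_repeats.append(c)
    if not with_repeats:
        warnings.warn("no candidate passes the repeat filter")
        return []
    with_repeats.sort(key=lambda c: (-c.score, c.seq_id))
    out = []
    for rank, c in enumerate(with_repeats, start=1):
        out.append(MiningCandidate(**{**c.__dict__, "final_rank": rank}))
    return out


@dataclass
class CascadeResult:
    """Stage-by-stage survivor counts plus the final ranked candidates."""

    n_input: int
    n_in_window: int
    bin_counts: dict[str, int]
    chosen_bin: str
    pfam_table: pd.DataFrame
    n_report: int
    n_keep: int
    threshold_table: pd.DataFrame
    ranked: list[MiningCandidate] = field(default_factory=list)


def run_cascade(
    records: list[AnnotationRecord],
    model: CasMinerClassifier | None = None,
    sequences: dict[str, ProteinSequence] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_width: int = DEFAULT_BIN_WIDTH,
    cas9_pfams: frozenset[str] = CAS9_PFAMS,
    min_domains: int = 3,
    report_cutoff: float = 0.5,
    keep_cutoff: float = 0.9,
    min_repeats: int = 50,
) -> CascadeResult:
    """Run the full cascade and record survivor counts at each stage."""
    lo, hi = window
    in_window = [r for r in records if lo <= r.length <= hi]
    binned = bin_by_length(in_window, window, bin_width)
    chosen, pfam_table = select_bin_by_pfam(binned, cas9_pfams, min_domains)
    survivors, thresh_table = score_and_filter(
        binned[chosen], model=model, sequences=sequences,
        report_cutoff=report_cutoff, keep_cutoff=keep_cutoff,
        cas9_pfams=cas9_pfams)
    ranked = rank_by_repeats(survivors, min_repeats=min_repeats)
    return CascadeResult(
        n_input=len(records),
        n_in_window=len(in_window),
        bin_counts={k: len(v) for k, v in binned.items()},
        chosen_bin=chosen,
        pfam_table=pfam_table,
        n_report=int(thresh_table.loc[0, "count"]),
        n_keep=int(thresh_table.loc[1, "count"]),
        threshold_table=thresh_table,
        ranked=ranked,
    )


def candidates_table(result: CascadeResult) -> pd.DataFrame:
    """Final ranked candidates as a TSV-ready table."""
    return pd.DataFrame([
        {"id": c.seq_id, "bin": c.bin_label or result.chosen_bin,
         "pfam_count": c.pfam_count, "score": c.score,
         "repeat_count": c.repeat_count, "final_rank": c.final_rank}
        for c in result.ranked
    ], columns=["id", "bin", "pfam_count", "score", "repeat_count",
                "final_rank"])
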
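"""Conservation- and saliency-guided point-mutation ranking.

Two position x amino-acid matrices are built over a reference sequence from
an alignment of its homologs:

* the conservation matrix of position-specific amino-acid probabilities
  (PSAP), i.e. pseudocounted column frequencies, and
* the characteristic matrix, the mean Grad-CAM saliency of homologs that
  carry a given residue at the column aligned to each reference position.

For each candidate substitution at a high-saliency "core site", the Diff
score in each matrix is (mutant value - wild-type value); candidates are
ranked separately by the two Diffs (descending, ties share the minimum
rank) and the total ranking score is the sum of the two ranks, with the
design list keeping totals strictly below the cutoff (default 30).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from Bio import AlignIO

from .fingerprint import gradcam
from .net import CasMinerClassifier
from .seqio import STANDARD_AA, ProteinSequence

logger = logging.getLogger("casminer")

GAP = "-"
_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}


@dataclass
class HomologAlignment:
    """A gapped alignment of homologs around one reference sequence.

    ``rows`` maps sequence id to its aligned (gapped) string; all rows have
    equal length and the reference id must be present.  ``column_map[s]``
    is the 0-based alignment column of 1-based reference position s+1.
    """

    reference_id: str
    rows: dict[str, str]
    column_map: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.reference_id not in self.rows:
            raise ValueError(
                f"reference {self.reference_id!r} not among alignment rows")
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        ref = self.rows[self.reference_id]
        self.column_map = np.array(
            [i for i, ch in enumerate(ref) if ch != GAP], dtype=int)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def reference_length(self) -> int:
        return len(self.column_map)

    def reference_sequence(self) -> ProteinSequence:
        return ProteinSequence(
            self.reference_id,
            self.rows[self.reference_id].replace(GAP, ""))


def read_alignment(path: str | Path, reference_id: str) -> HomologAlignment:
    """Read an aligned-FASTA homolog alignment."""
    aln = AlignIO.read(str(path), "fasta")
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    return HomologAlignment(reference_id=reference_id, rows=rows)


@dataclass
class ConservationMatrix:
    """PSAP matrix: P[s, a] over reference positions s and standard residues."""

    probabilities: np.ndarray  # (L, 20)
    alpha: float
    alphabet: str = STANDARD_AA

    def prob(self, site: int, residue: str) -> float:
        """Probability of ``residue`` at 1-based reference position ``site``."""
        return float(self.probabilities[site - 1, _AA_INDEX[residue]])


@dataclass
class CharacteristicMatrix:
    """Residue-stratified mean homolog saliency per reference position.

    ``values[s, a]`` is NaN where fewer than ``min_support`` homologs carry
    residue ``a`` at the column aligned to position s+1.  ``core_sites`` is
    a boolean flag per reference position.
    """

    values: np.ndarray        # (L, 20), NaN where unsupported
    support: np.ndarray       # (L, 20) int
    core_sites: np.ndarray    # (L,) bool
    mean_saliency: np.ndarray  # (L,)
    min_support: int
    alphabet: str = STANDARD_AA

    def value(self, site: int, residue: str) -> float:
        return float(self.values[site - 1, _AA_INDEX[residue]])

    def defined(self, site: int, residue: str) -> bool:
        return bool(np.isfinite(self.values[site - 1, _AA_INDEX[residue]]))


def psap(aln: HomologAlignment, alpha: float = 1.0) -> ConservationMatrix:
    """Position-specific amino-acid probabilities with pseudocount ``alpha``.

    P[s, a] = (count of a in the column aligned to s + alpha) /
    (standard-residue count in that column + 20 * alpha).  Gaps and
    non-standard letters are excluded from the counts.  A column with no
    countable residues becomes a uniform row with a warning.
    """
    if alpha < 0:
        raise ValueError("pseudocount alpha must be >= 0")
    L = aln.reference_length
    counts = np.zeros((L, 20))
    rows = list(aln.rows.values())
    for row in rows:
        chars = np.array(list(row))[aln.column_map]
        for s, ch in enumerate(chars):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[s, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    empty = totals.ravel() == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} column(s) with no countable residues; "
            "their rows are uniform")
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = (counts + alpha) / (totals + 20.0 * alpha)
    probs[empty] = 1.0 / 20.0
    return ConservationMatrix(probabilities=probs, alpha=alpha)


def characteristic_matrix(
    model: CasMinerClassifier | None,
    aln: HomologAlignment,
    min_support: int = 3,
    core_percentile: float = 75.0,
    saliency_fn: Callable[[ProteinSequence], np.ndarray] | None = None,
) -> CharacteristicMatrix:
    """Build the residue-stratified saliency matrix over the alignment.

    Each homolog is fingerprinted on its ungapped sequence (``saliency_fn``
    overrides the model's Grad-CAM, mainly for testing); saliency is
    projected through the alignment into reference coordinates.  Core sites
    are positions whose across-homolog mean saliency is at or above the
    ``core_percentile``-th percentile.
    """
    if saliency_fn is None:
        if model is None:
            raise ValueError("either a fitted model or saliency_fn is required")
        saliency_fn = lambda seq: gradcam(model, seq).saliency  # noqa: E731
    L = aln.reference_length
    sums = np.zeros((L, 20))
    support = np.zeros((L, 20), dtype=int)
    pos_sum = np.zeros(L)
    pos_n = np.zeros(L, dtype=int)
    for sid, row in aln.rows.items():
        ungapped = row.replace(GAP, "")
        try:
            seq = ProteinSequence(sid, ungapped)
            sal = np.asarray(saliency_fn(seq), dtype=float)
        except ValueError as exc:
            logger.warning("homolog %s skipped: %s", sid, exc)
            continue
        if len(sal) != len(ungapped):
            raise ValueError(
                f"saliency length {len(sal)} != sequence length "
                f"{len(ungapped)} for {sid}")
        # residue index within the homolog for every alignment column
        col_residue_idx = np.cumsum([ch != GAP for ch in row]) - 1
        for s, col in enumerate(aln.column_map):
            ch = row[col]
            if ch == GAP:
                continue
            aa = _AA_INDEX.get(ch)
            val = sal[col_residue_idx[col]]
            pos_sum[s] += val
            pos_n[s] += 1
            if aa is not None:
                sums[s, aa] += val
                support[s, aa] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(support >= max(1, min_support),
                          sums / np.maximum(support, 1), np.nan)
        mean_sal = np.where(pos_n > 0, pos_sum / np.maximum(pos_n, 1), 0.0)
    threshold = np.percentile(mean_sal, core_percentile)
    core = mean_sal >= threshold
    return CharacteristicMatrix(
        values=values, support=support, core_sites=core,
        mean_saliency=mean_sal, min_support=min_support)


@dataclass(frozen=True)
class MutationCandidate:
    """One proposed substitution with its Diff scores and ranks."""

    site: int            # 1-based reference position
    wild_type: str
    mutant: str
    diff_char: float
    diff_cons: float
    rank_char: int
    rank_cons: int

    @property
    def total_rank(self) -> int:
        return self.rank_char + self.rank_cons

    @property
    def notation(self) -> str:
        return f"{self.wild_type}{self.site}{self.mutant}"


def rank_mutations(
    C: CharacteristicMatrix,
    P: ConservationMatrix,
    ref: ProteinSequence,
    total_cutoff: int = 30,
) -> list[MutationCandidate]:
    """Enumerate, Diff-score and dual-rank substitutions at core sites.

    Candidates are (site, mutant) pairs at core sites where both the mutant
    and the wild-type characteristic values are supported.  Each list of
    Diff scores is ranked descending with ties sharing the minimum rank;
    candidates whose total rank is strictly below ``total_cutoff`` are
    returned, sorted by total rank then position then mutant residue.
    """
    if C.values.shape[0] != P.probabilities.shape[0]:
        raise ValueError("characteristic and conservation matrices disagree "
                         "on reference length")
    if len(ref) != C.values.shape[0]:
        raise ValueError("reference length does not match the matrices")
    raw = []
    for s in range(1, len(ref) + 1):
        if not C.core_sites[s - 1]:
            continue
        wt = ref.residues[s - 1]
        if wt not in _AA_INDEX or not C.defined(s, wt):
            continue
        for a in STANDARD_AA:
            if a == wt or not C.defined(s, a):
                continue
            raw.append((s, wt, a,
                        C.value(s, a) - C.value(s, wt),
                        P.prob(s, a) - P.prob(s, wt)))
    if not raw:
        warnings.warn("no mutation candidates (no supported core-site pairs)")
        return []
    diff_char = np.array([r[3] for r in raw])
    diff_cons = np.array([r[4] for r in raw])
    rank_char = rankdata(-diff_char, method="min").astype(int)
    rank_cons = rankdata(-diff_cons, method="min").astype(int)
    cands = [
        MutationCandidate(site=s, wild_type=wt, mutant=a, diff_char=dc,
                          diff_cons=dp, rank_char=int(rc), rank_cons=int(rp))
        for (s, wt, a, dc, dp), rc, rp in zip(raw, rank_char, rank_cons)
    ]
    kept = [c for c in cands if c.total_rank < total_cutoff]
    kept.sort(key=lambda c: (c.total_rank, c.site, c.mutant))
    return kept


def report_designs(
    candidates: list[MutationCandidate], path: str | Path | None = None
) -> pd.DataFrame:
    """Tabulate designs (wtPOSmut notation); optionally write a TSV."""
    df = pd.DataFrame([
        {"site": c.site, "wt": c.wild_type, "mut": c.mutant,
         "notation": c.notation, "diff_char": c.diff_char,
         "diff_cons": c.diff_cons, "rank_char": c.rank_char,
         "rank_cons": c.rank_cons, "total_rank": c.total_rank}
        for c in candidates
    ], columns=["site", "wt", "mut", "notation", "diff_char", "diff_cons",
                "rank_char", "rank_cons", "total_rank"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
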
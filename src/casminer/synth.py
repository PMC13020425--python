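"""Synthetic fixtures: motif-planted positives, homolog families, mining tables.

The generators stand in for the external resources the real pipeline mines
(UniRef sequence sets, genome annotation tables): positives are background
sequences with fixed sequence motifs planted at jittered positions (the
learnable analogue of conserved catalytic/binding segments), homolog
families are point-substituted copies of a reference with a conserved
column set, and mining tables are annotation tables whose cascade outcome
is enumerable by hand.  Everything is seed-deterministic and ships its
ground truth (motif spans, conserved columns, expected survivors) alongside
the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import HomologAlignment
from .seqio import STANDARD_AA, LabeledSequence, ProteinSequence, SequenceDataset

#: Approximate amino-acid background frequencies in well-curated protein
#: databases (Swiss-Prot composition statistics, rounded), indexed by
#: :data:`casminer.seqio.STANDARD_AA` order.
UNIPROT_FREQS = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0394, "R": 0.0553,
    "S": 0.0664, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class Motif:
    """A fixed residue string planted near a relative position.

    ``rel_position`` locates the motif start as a fraction of sequence
    length; ``jitter`` is the maximum absolute displacement in residues.
    """

    residues: str
    rel_position: float
    jitter: int = 25

    def __post_init__(self) -> None:
        if not 8 <= len(self.residues) <= 12:
            raise ValueError("motif width must be 8-12 residues")
        if not 0.0 <= self.rel_position <= 1.0:
            raise ValueError("rel_position must be in [0, 1]")


#: Three default motifs, echoing the two catalytic centres plus a binding
#: segment a Cas9 fingerprint highlights.
DEFAULT_MOTIFS = (
    Motif("DIGTNSVGWA", 0.10),
    Motif("HMIKFRGHFL", 0.50),
    Motif("WDPKKYGGFD", 0.85),
)


@dataclass
class SynthSpec:
    """Parameters of the motif-planted positive set."""

    n_sequences: int = 400
    length_range: tuple[int, int] = (800, 1200)
    motifs: tuple[Motif, ...] = DEFAULT_MOTIFS
    background: str = "uniform"   # "uniform" or "uniprot"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid length range {self.length_range}")
        need = sum(len(m.residues) for m in self.motifs)
        if need > lo:
            raise ValueError("motifs do not fit within the minimum length")

    def frequencies(self) -> np.ndarray:
        if self.background == "uniform":
            return np.full(20, 1.0 / 20.0)
        if self.background == "uniprot":
            f = np.array([UNIPROT_FREQS[a] for a in STANDARD_AA])
            return f / f.sum()
        raise ValueError(f"unknown background {self.background!r}")


def _plant(rng: np.random.Generator, length: int,
           motifs: tuple[Motif, ...]) -> list[tuple[int, int, str]]:
    """Choose non-overlapping (start, end) spans for each motif (0-based,
    half-open), re-jittering on collision up to 100 times."""
    for _ in range(100):
        spans: list[tuple[int, int, str]] = []
        ok = True
        for m in motifs:
            w = len(m.residues)
            centre = int(round(m.rel_position * (length - w)))
            start = centre + int(rng.integers(-m.jitter, m.jitter + 1))
            start = min(max(start, 0), length - w)
            span = (start, start + w, m.residues)
            if any(span[0] < e and s < span[1] for s, e, _ in spans):
                ok = False
                break
            spans.append(span)
        if ok:
            return spans
    raise RuntimeError("could not place motifs without overlap in 100 tries")


def make_positive_set(spec: SynthSpec) -> SequenceDataset:
    """Background sequences with every motif planted verbatim.

    Ground-truth motif spans (0-based half-open, per id) are stored in
    ``metadata['motif_spans']``.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies()
    aa = np.array(list(STANDARD_AA))
    records = []
    spans_by_id: dict[str, list[tuple[int, int]]] = {}
    for i in range(spec.n_sequences):
        length = int(rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1))
        residues = rng.choice(aa, size=length, p=freqs)
        spans = _plant(rng, length, spec.motifs)
        for start, end, motif in spans:
            residues[start:end] = list(motif)
        sid = f"pos{i:05d}"
        records.append(LabeledSequence(
            ProteinSequence(sid, "".join(residues)), label=1))
        spans_by_id[sid] = [(s, e) for s, e, _ in spans]
    return SequenceDataset(records, metadata={
        "source": "synth.make_positive_set",
        "seed": spec.seed,
        "length_range": spec.length_range,
        "motif_spans": spans_by_id,
    })


def make_homolog_family(
    reference: ProteinSequence,
    n: int,
    sub_rate: float,
    conserved: set[int] | frozenset[int] = frozenset(),
    seed: int = 0,
) -> HomologAlignment:
    """Indel-free homolog family around a reference.

    Each homolog substitutes every position independently at ``sub_rate``
    (``sub_rate / 10`` at 1-based positions in ``conserved``), drawing
    uniformly from the 19 other residues.  With no indels the alignment
    column map is the identity.  The family contains the reference row plus
    ``n`` homologs.
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(reference)
    rates = np.full(L, sub_rate)
    for pos in conserved:
        if not 1 <= pos <= L:
            raise ValueError(f"conserved position {pos} outside 1..{L}")
        rates[pos - 1] = sub_rate / 10.0
    ref = np.array(list(reference.residues))
    aa = np.array(list(STANDARD_AA))
    rows = {reference.id: reference.residues}
    for i in range(n):
        hit = rng.random(L) < rates
        seq = ref.copy()
        for pos in np.nonzero(hit)[0]:
            others = aa[aa != ref[pos]]
            seq[pos] = rng.choice(others)
        rows[f"hom{i:04d}"] = "".join(seq)
    return HomologAlignment(reference_id=reference.id, rows=rows)


# ----------------------------------------------------------- mining fixtures

def make_mining_table(
    records: list[dict] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Assemble an annotation table (id, length, pfam_hits, repeat_count,
    score) from record dicts; an empty spec yields a header-only table."""
    columns = ["id", "length", "pfam_hits", "repeat_count", "score"]
    df = pd.DataFrame(records or [], columns=columns)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def campaign_shape_records(seed: int = 0) -> tuple[list[dict], dict]:
    """A toy mining table shaped like a realistic campaign, plus ground truth.

    One length bin (1301-1400) dominates the multi-domain Pfam counts; its
    records carry scores straddling the 0.5 / 0.9 cutoffs and repeat counts
    straddling the strict >50 boundary, so every cascade stage is
    enumerable by hand.  The expected outcome is returned alongside the
    records as a ground-truth dict.
    """
    rng = np.random.default_rng(seed)
    doms = ["RuvC_III", "Cas9_BH", "Cas9_REC", "HNH_4", "Cas9_PI"]
    records: list[dict] = []

    def add(i, length, hits, repeats, score):
        records.append({
            "id": f"cand{i:03d}", "length": length,
            "pfam_hits": ",".join(hits),
            "repeat_count": repeats if repeats is not None else np.nan,
            "score": score})

    i = 0
    # background bins: few domains, scores below the report cutoff; lengths
    # drawn strictly inside [lo, lo+100) so nothing spills between bins
    for lo in range(800, 1600, 100):
        if lo == 1300:
            continue
        for _ in range(4):
            length = int(rng.integers(lo, lo + 100))
            add(i, length, list(rng.choice(doms, size=2, replace=False)),
                int(rng.integers(0, 20)), round(float(rng.uniform(0.0, 0.45)), 3))
            i += 1
    # the dominant bin [1300, 1400): ten multi-domain entries with hand-set
    # scores/repeats spanning the cutoffs (strict >0.5 report, >=0.9 keep,
    # strict >50 repeats)
    chosen = [
        # (n_domains, repeats, score)
        (5, 56, 0.97),    # keep; 2nd score; repeats > 50  -> final rank 2
        (5, None, 0.99),  # keep; top score but no repeat annotation -> excluded
        (4, 80, 0.95),    # keep; repeats > 50             -> final rank 3
        (5, 51, 0.98),    # keep; repeats > 50             -> final rank 1
        (4, 50, 0.93),    # keep; repeats == 50 (strict >) -> excluded
        (3, 49, 0.90),    # keep (>=0.9 boundary); repeats < 50 -> excluded
        (3, 120, 0.60),   # report only (0.5 < s < 0.9)
        (3, 30, 0.51),    # report only
        (3, 10, 0.50),    # not above the strict > 0.5 report cutoff
        (2, 5, 0.40),     # fails score; also only 2 domains
    ]
    score_to_id = {}
    for n_dom, repeats, score in chosen:
        length = int(rng.integers(1300, 1400))
        score_to_id[score] = f"cand{i:03d}"
        add(i, length, doms[:n_dom], repeats, score)
        i += 1
    # out-of-window distractors
    add(i, 700, doms[:5], 99, 0.99); i += 1
    add(i, 1700, doms[:5], 99, 0.99); i += 1

    final_ids = [score_to_id[0.98], score_to_id[0.97], score_to_id[0.95]]
    truth = {
        "chosen_bin": "1301-1400",
        "n_in_window": len(records) - 2,
        "n_bins": 8,
        "n_report": 8,          # scores strictly > 0.5 in the chosen bin
        "n_keep": 6,            # scores >= 0.9
        "final_ids_in_order": final_ids,
        "final_ranks": {sid: k + 1 for k, sid in enumerate(final_ids)},
    }
    return records, truth
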
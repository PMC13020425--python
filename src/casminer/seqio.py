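"""Protein sequence and dataset containers plus FASTA / table plumbing.

Every other module consumes the containers defined here.  Sequences are
plain amino-acid strings over the 20 standard residues plus the common
ambiguity letters (X, B, Z, U, O), case-normalised to upper on construction.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("casminer")

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / rare residue letters retained rather than dropped: X (any),
#: B (Asx), Z (Glx), U (selenocysteine), O (pyrrolysine).
EXTENDED_AA = "XBZUO"
#: Full residue alphabet accepted by the package.
ALPHABET = STANDARD_AA + EXTENDED_AA
_ALLOWED = frozenset(ALPHABET)


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence.

    Residues are upper-cased at construction and must be non-empty and drawn
    from :data:`ALPHABET`.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledSequence:
    """A sequence with a binary class label (1 = Cas9-like, 0 = negative)."""

    sequence: ProteinSequence
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class SequenceDataset:
    """An ordered collection of labelled sequences with provenance metadata.

    Ids must be unique within the dataset; `metadata` carries free-form
    provenance such as the source file, shuffle threshold and seed.
    """

    records: list[LabeledSequence] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            sid = rec.sequence.id
            if sid in seen:
                raise ValueError(f"duplicate sequence id in dataset: {sid!r}")
            seen.add(sid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.sequence.id for r in self.records]

    @property
    def sequences(self) -> list[ProteinSequence]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def label_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for r in self.records:
            counts[r.label] += 1
        return counts

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[ProteinSequence],
        label: int,
        metadata: dict | None = None,
    ) -> "SequenceDataset":
        return cls(
            records=[LabeledSequence(s, label) for s in sequences],
            metadata=dict(metadata or {}),
        )


def _open_maybe_gzip(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (optionally gzipped) protein FASTA file.

    The id is the header token before the first whitespace; residues are
    upper-cased.  Duplicate ids or empty records raise ``ValueError`` naming
    the offending record.  An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id!r} in {path}")
            seen.add(rec.id)
            residues = str(rec.seq)
            if not residues:
                raise ValueError(f"FASTA record {rec.id!r} in {path} is empty")
            out.append(ProteinSequence(rec.id, residues))
    return out


def write_fasta(records: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences to FASTA; round-trips exactly through ``read_fasta``."""
    path = Path(path)
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with _open_maybe_gzip(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


def filter_by_length(
    records: Iterable[ProteinSequence],
    min_len: int = 800,
    max_len: int = 1600,
) -> list[ProteinSequence]:
    """Keep sequences with ``min_len <= length <= max_len`` (both inclusive).

    The defaults are the genome-mining window of 800-1600 residues, which
    brackets the lengths of known Cas9 nucleases.  Order is preserved.
    """
    if min_len < 1 or max_len < 1:
        raise ValueError("length bounds must be >= 1")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]
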
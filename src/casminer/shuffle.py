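"""Partial-shuffle negative dataset generation.

Negatives are built from positives by permuting the residues at a random
subset of positions, so amino-acid composition is exactly preserved while
sequence-order features are progressively destroyed as the shuffle
threshold ``p`` grows.  Sweeping p from 0.1 to 1.0 in steps of 0.1 yields
the ten classic negative sets (10% shuffled through fully shuffled).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .seqio import LabeledSequence, ProteinSequence, SequenceDataset

DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class ShuffleConfig:
    """Fraction of positions to shuffle (``threshold`` in [0, 1]) and seed."""

    threshold: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(
                f"shuffle threshold must be in [0, 1], got {self.threshold}"
            )


def stable_seed(base_seed: int, *parts: object) -> int:
    """Derive a reproducible 31-bit sub-seed from a base seed and context.

    Uses SHA-256 so the derivation is stable across platforms and Python
    hash randomisation, and independent of record order.
    """
    key = ":".join([str(base_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def shuffle_sequence(seq: ProteinSequence, config: ShuffleConfig) -> ProteinSequence:
    """Permute the residues at ``round(p * L)`` random positions.

    Positions are chosen uniformly without replacement; the residues at the
    chosen positions are rearranged by a uniform random permutation (a
    position may map to itself).  Length and residue multiset are exactly
    preserved and the result is deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    residues = np.array(list(seq.residues))
    length = len(residues)
    k = int(round(config.threshold * length))
    if k > 1:
        positions = rng.choice(length, size=k, replace=False)
        perm = rng.permutation(k)
        residues[positions] = residues[positions[perm]]
    return ProteinSequence(seq.id, "".join(residues))


def build_negative_dataset(
    positives: SequenceDataset, config: ShuffleConfig
) -> SequenceDataset:
    """One shuffled, label-0 negative per positive.

    Ids are suffixed with the shuffle percentage to stay unique alongside the
    positives.  Each sequence gets its own sub-seed derived from
    ``(config.seed, id)`` so the output is independent of record order.
    """
    if any(rec.label != 1 for rec in positives):
        raise ValueError("build_negative_dataset expects all-positive input")
    pct = int(round(config.threshold * 100))
    records = []
    for rec in positives:
        sub = ShuffleConfig(
            threshold=config.threshold,
            seed=stable_seed(config.seed, rec.sequence.id),
        )
        shuffled = shuffle_sequence(rec.sequence, sub)
        records.append(
            LabeledSequence(
                ProteinSequence(f"{rec.sequence.id}|shuf{pct}", shuffled.residues),
                label=0,
            )
        )
    return SequenceDataset(
        records=records,
        metadata={
            "source": "shuffle",
            "threshold": config.threshold,
            "seed": config.seed,
            "n_source_positives": len(positives),
        },
    )


def shuffle_sweep(
    positives: SequenceDataset,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    base_seed: int = 0,
) -> list[SequenceDataset]:
    """Build one negative dataset per threshold (default 0.1 ... 1.0).

    Per-threshold seeds are derived deterministically from ``base_seed``.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    for t in thresholds:
        if not 0.0 < t <= 1.0:
            raise ValueError(f"sweep thresholds must lie in (0, 1], got {t}")
    out = []
    for t in thresholds:
        cfg = ShuffleConfig(threshold=t, seed=stable_seed(base_seed, "threshold", t))
        out.append(build_negative_dataset(positives, cfg))
    return out
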
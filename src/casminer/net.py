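"""Sequence encoding, the CNN-LSTM classifier, and the evaluation battery.

The classifier distinguishes Cas9-like sequences (label 1) from partially
shuffled negatives (label 0).  It is exposed as a scikit-learn-style
estimator (:class:`CasMinerClassifier`) so it composes with pipelines and
model selection; :func:`train` / :func:`predict` / :func:`evaluate` are the
thin functional surface over it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split

from ._nn import CNNLSTM, Adam, bce_with_logits, sigmoid
from .seqio import ALPHABET, ProteinSequence, SequenceDataset

logger = logging.getLogger("casminer")


# ------------------------------------------------------------------ encoding

@dataclass(frozen=True)
class EncoderSpec:
    """Residue-token alphabet and fixed model capacity.

    The default capacity of 1820 residues covers the longest sequences in
    the Cas9 positive set (801-1820 AA).  PAD is a dedicated trailing token.
    """

    alphabet: str = ALPHABET
    max_len: int = 1820

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet letters must be unique")

    @property
    def pad_index(self) -> int:
        return len(self.alphabet)

    @property
    def vocab_size(self) -> int:
        return len(self.alphabet) + 1

    def index_of(self, residue: str) -> int:
        idx = self.alphabet.find(residue)
        if idx < 0:
            raise ValueError(f"residue {residue!r} is not in the encoder alphabet")
        return idx


def encode(seq: ProteinSequence, spec: EncoderSpec) -> np.ndarray:
    """Map a sequence to a length-``max_len`` token-index vector.

    Shorter sequences are right-padded with PAD; longer ones are truncated
    at ``max_len`` with a logged warning.
    """
    lut = np.full(128, -1, dtype=np.int32)
    for i, ch in enumerate(spec.alphabet):
        lut[ord(ch)] = i
    raw = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    tokens = lut[raw]
    if (tokens < 0).any():
        bad = seq.residues[int(np.argmax(tokens < 0))]
        raise ValueError(
            f"sequence {seq.id!r}: residue {bad!r} is not in the encoder alphabet"
        )
    if len(tokens) > spec.max_len:
        logger.warning(
            "sequence %s (%d aa) truncated to max_len=%d",
            seq.id, len(tokens), spec.max_len,
        )
        tokens = tokens[: spec.max_len]
    out = np.full(spec.max_len, spec.pad_index, dtype=np.int32)
    out[: len(tokens)] = tokens
    return out


def _encode_batch(
    seqs: Sequence[ProteinSequence], spec: EncoderSpec
) -> tuple[np.ndarray, np.ndarray]:
    tokens = np.stack([encode(s, spec) for s in seqs])
    lengths = np.minimum([len(s) for s in seqs], spec.max_len).astype(np.int64)
    return tokens, lengths


# ------------------------------------------------------------------- configs

@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters (all overridable).

    Defaults: embedding 32 -> two conv blocks (64 filters, kernel 7,
    max-pool 4, ReLU) -> LSTM 64 (final valid hidden state) -> dense ReLU 32
    -> sigmoid scalar; Adam at 1e-3, batch 32, 20 epochs.
    """

    embedding_dim: int = 32
    conv_filters: tuple[int, ...] = (64, 64)
    kernel_size: int = 7
    pool_size: int = 4
    lstm_units: int = 64
    dense_units: int = 32
    dropout: float = 0.0
    lstm_pooling: str = "last"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 20
    train_fraction: float = 0.8
    split_seed: int = 0
    init_seed: int = 0

    def __post_init__(self) -> None:
        if not self.conv_filters:
            raise ValueError("at least one conv block is required (Grad-CAM target)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("embedding_dim", "kernel_size", "pool_size", "lstm_units",
                     "dense_units", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


# ------------------------------------------------------------------ estimator

class CasMinerClassifier(BaseEstimator, ClassifierMixin):
    """CNN-LSTM binary classifier over protein sequences.

    ``X`` may be residue strings or :class:`ProteinSequence` objects.  All
    randomness (initialisation, batch order, dropout) derives from
    ``random_state``, so fits are bit-reproducible on a given platform.

    Fitted attributes: ``net_`` (the network), ``encoder_``, ``classes_``,
    ``history_`` (per-epoch loss and training accuracy).
    """

    def __init__(
        self,
        embedding_dim: int = 32,
        conv_filters: tuple[int, ...] = (64, 64),
        kernel_size: int = 7,
        pool_size: int = 4,
        lstm_units: int = 64,
        dense_units: int = 32,
        dropout: float = 0.0,
        lstm_pooling: str = "last",
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 20,
        max_len: int = 1820,
        random_state: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.lstm_units = lstm_units
        self.dense_units = dense_units
        self.dropout = dropout
        self.lstm_pooling = lstm_pooling
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_len = max_len
        self.random_state = random_state

    # ------------------------------------------------------------- utilities

    @staticmethod
    def _as_sequences(X: Iterable) -> list[ProteinSequence]:
        out = []
        for i, x in enumerate(X):
            if isinstance(x, ProteinSequence):
                out.append(x)
            else:
                out.append(ProteinSequence(f"x{i}", str(x)))
        return out

    def _crop(self, tokens: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Crop a batch to the longest sequence plus a receptive-field margin.

        The margin guarantees that every activation reachable from a valid
        (non-padding) time step is computed identically at any crop width,
        so predictions never depend on batch composition.  The width is
        rounded up so every pooling stage divides evenly.
        """
        n_blocks = len(tuple(self.conv_filters))
        unit = self.pool_size ** n_blocks
        margin = (self.kernel_size // 2) * sum(
            self.pool_size**i for i in range(n_blocks))
        t = int(lengths.max()) + margin
        t = -(-t // unit) * unit
        t = int(min(self.max_len, t))
        t = max(t, self.kernel_size)
        return tokens[:, :t]

    # ------------------------------------------------------------------- fit

    def fit(self, X, y):
        seqs = self._as_sequences(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if len(seqs) != len(y):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        self.encoder_ = EncoderSpec(max_len=self.max_len)
        rng = np.random.default_rng(self.random_state)
        self.net_ = CNNLSTM(
            vocab_size=self.encoder_.vocab_size,
            pad_index=self.encoder_.pad_index,
            embedding_dim=self.embedding_dim,
            conv_filters=tuple(self.conv_filters),
            kernel_size=self.kernel_size,
            pool_size=self.pool_size,
            lstm_units=self.lstm_units,
            dense_units=self.dense_units,
            dropout=self.dropout,
            rng=rng,
            lstm_pooling=self.lstm_pooling,
        )
        self.classes_ = np.array([0, 1])
        tokens, lengths = _encode_batch(seqs, self.encoder_)
        opt = Adam(self.net_.params, lr=self.learning_rate)
        history = {"loss": [], "train_accuracy": []}
        n = len(seqs)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                tb = self._crop(tokens[idx], lengths[idx])
                logits, cache = self.net_.forward(
                    tb, lengths[idx], train=True, drop_rng=rng)
                if not np.all(np.isfinite(logits)):
                    raise FloatingPointError(
                        f"training diverged (non-finite logits) at epoch {epoch}")
                loss, dlog = bce_with_logits(logits, y[idx])
                losses.append(loss * len(idx))
                correct += int(((logits > 0) == (y[idx] > 0.5)).sum())
                grads, _ = self.net_.backward(cache, dlog)
                opt.step(self.net_.params, grads)
                self.net_.params["emb"][self.encoder_.pad_index] = 0.0
            history["loss"].append(sum(losses) / n)
            history["train_accuracy"].append(correct / n)
            logger.debug("epoch %d: loss=%.4f acc=%.4f", epoch,
                         history["loss"][-1], history["train_accuracy"][-1])
        self.history_ = history
        return self

    # --------------------------------------------------------------- predict

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        seqs = self._as_sequences(X)
        if not seqs:
            return np.zeros(0)
        logits = np.empty(len(seqs))
        for start in range(0, len(seqs), self.batch_size):
            chunk = seqs[start:start + self.batch_size]
            tokens, lengths = _encode_batch(chunk, self.encoder_)
            tb = self._crop(tokens, lengths)
            z, _ = self.net_.forward(tb, lengths, train=False, need_cache=False)
            logits[start:start + len(chunk)] = z
        return logits

    def predict_proba(self, X) -> np.ndarray:
        pos = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0.0).astype(int)

    def score_sequences(self, X) -> np.ndarray:
        """Positive-class probability per sequence, in input order."""
        return self.predict_proba(X)[:, 1]

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    # ----------------------------------------------------------- persistence

    def save(self, model_dir: str | Path) -> None:
        """Write parameters (.npz) plus config sidecar (JSON) to a directory."""
        self._check_fitted()
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        np.savez(model_dir / "params.npz", **self.net_.params)
        meta = {
            "params": self.get_params(),
            "history": getattr(self, "history_", None),
            "format_version": 1,
        }
        (model_dir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "CasMinerClassifier":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        params = meta["params"]
        params["conv_filters"] = tuple(params["conv_filters"])
        clf = cls(**params)
        clf.encoder_ = EncoderSpec(max_len=clf.max_len)
        rng = np.random.default_rng(0)
        clf.net_ = CNNLSTM(
            vocab_size=clf.encoder_.vocab_size,
            pad_index=clf.encoder_.pad_index,
            embedding_dim=clf.embedding_dim,
            conv_filters=tuple(clf.conv_filters),
            kernel_size=clf.kernel_size,
            pool_size=clf.pool_size,
            lstm_units=clf.lstm_units,
            dense_units=clf.dense_units,
            dropout=clf.dropout,
            rng=rng,
            lstm_pooling=clf.lstm_pooling,
        )
        with np.load(model_dir / "params.npz") as data:
            for k in clf.net_.params:
                clf.net_.params[k] = data[k]
        clf.classes_ = np.array([0, 1])
        clf.history_ = meta.get("history")
        return clf


# ------------------------------------------------------------------- reports

@dataclass
class EvalReport:
    """Confusion counts plus the derived metric battery."""

    tp: int
    fp: int
    tn: int
    fn: int
    test_accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    train_accuracy: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoff: float = 0.5,
) -> EvalReport:
    """Confusion counts at ``score > cutoff`` plus precision/recall/F1/AUC.

    AUC is the Mann-Whitney rank statistic (ties count 0.5).  A zero
    precision denominator is reported as precision 0 with a warning; a
    one-class input raises because AUC is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes are required (AUC undefined otherwise)")
    preds = (scores > cutoff).astype(int)
    tn, fp, fn, tp = confusion_matrix(labels, preds, labels=[0, 1]).ravel()
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n
    if tp + fp == 0:
        logger.warning("no positive predictions; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    auc = float(roc_auc_score(labels, scores))
    return EvalReport(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
                      test_accuracy=float(accuracy), precision=float(precision),
                      recall=float(recall), f1=float(f1), auc=auc)


# ---------------------------------------------------------- functional surface

def split_train_test(
    dataset: SequenceDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SequenceDataset, SequenceDataset]:
    """Stratified, seeded train/test split; union equals the input."""
    labels = dataset.labels
    counts = dataset.label_counts()
    if min(counts.values()) < 2:
        raise ValueError(
            f"each class needs >= 2 members to split, got {counts}")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed,
        stratify=np.asarray(labels))
    meta = dict(dataset.metadata)
    train = SequenceDataset([dataset.records[i] for i in sorted(train_idx)],
                            {**meta, "split": "train"})
    test = SequenceDataset([dataset.records[i] for i in sorted(test_idx)],
                           {**meta, "split": "test"})
    return train, test


def train(
    positives: SequenceDataset,
    negatives: SequenceDataset,
    cfg: ModelConfig | None = None,
    spec: EncoderSpec | None = None,
) -> tuple[CasMinerClassifier, EvalReport]:
    """Fit the classifier on a stratified split and report held-out metrics."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both positive and negative datasets must be non-empty")
    cfg = cfg or ModelConfig()
    spec = spec or EncoderSpec()
    merged = SequenceDataset(list(positives.records) + list(negatives.records))
    tr, te = split_train_test(merged, cfg.train_fraction, cfg.split_seed)
    clf = CasMinerClassifier(
        embedding_dim=cfg.embedding_dim,
        conv_filters=cfg.conv_filters,
        kernel_size=cfg.kernel_size,
        pool_size=cfg.pool_size,
        lstm_units=cfg.lstm_units,
        dense_units=cfg.dense_units,
        dropout=cfg.dropout,
        lstm_pooling=cfg.lstm_pooling,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        max_len=spec.max_len,
        random_state=cfg.init_seed,
    )
    clf.fit(tr.sequences, tr.labels)
    test_scores = clf.score_sequences(te.sequences)
    report = evaluate(test_scores, te.labels)
    train_scores = clf.score_sequences(tr.sequences)
    report.train_accuracy = float(
        ((train_scores > 0.5).astype(int) == np.asarray(tr.labels)).mean())
    return clf, report


def predict(
    model: CasMinerClassifier, records: Iterable[ProteinSequence]
) -> list[tuple[str, float]]:
    """Score each record in order; records with residues outside the encoder
    alphabet are skipped with a logged warning rather than aborting the batch."""
    out: list[tuple[str, float]] = []
    good: list[ProteinSequence] = []
    for rec in records:
        try:
            for ch in set(rec.residues):
                model.encoder_.index_of(ch)
            good.append(rec)
        except ValueError as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
    if good:
        scores = model.score_sequences(good)
        out = [(r.id, float(s)) for r, s in zip(good, scores)]
    return out
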
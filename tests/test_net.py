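"""Encoder, metric battery, gradient correctness and training behaviour."""

import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

import casminer._nn as _nn
from casminer._nn import CNNLSTM, bce_with_logits
from casminer.net import (CasMinerClassifier, EncoderSpec, ModelConfig,
                          encode, evaluate, predict, split_train_test, train)
from casminer.seqio import ProteinSequence, SequenceDataset
from casminer.shuffle import ShuffleConfig, build_negative_dataset
from casminer.synth import SynthSpec, make_positive_set
from conftest import tiny_config


# ------------------------------------------------------------------ encoding

def test_encode_pads_and_truncates(caplog):
    spec = EncoderSpec(max_len=5)
    v = encode(ProteinSequence("s", "ACD"), spec)
    assert v.tolist() == [spec.index_of("A"), spec.index_of("C"),
                          spec.index_of("D"), spec.pad_index, spec.pad_index]
    exact = encode(ProteinSequence("s", "ACDEF"), spec)
    assert spec.pad_index not in exact.tolist()
    with caplog.at_level(logging.WARNING, logger="casminer"):
        long = encode(ProteinSequence("s", "ACDEFGH"), spec)
    assert len(long) == 5 and "truncated" in caplog.text


def test_encode_rejects_unknown_residue():
    spec = EncoderSpec(alphabet="ACDEFGHIKLMNPQRSTVWY", max_len=10)
    with pytest.raises(ValueError, match="'X'"):
        encode(ProteinSequence("s", "ACDX"), spec)


# --------------------------------------------------------------------- split

def test_split_is_stratified_and_deterministic():
    pos = make_positive_set(SynthSpec(n_sequences=100, length_range=(60, 70),
                                      motifs=(), seed=0))
    neg = build_negative_dataset(pos, ShuffleConfig(threshold=1.0, seed=0))
    ds = SequenceDataset(list(pos.records) + list(neg.records))
    tr, te = split_train_test(ds, 0.8, seed=3)
    assert tr.label_counts() == {0: 80, 1: 80}
    assert te.label_counts() == {0: 20, 1: 20}
    assert sorted(tr.ids + te.ids) == sorted(ds.ids)
    tr2, te2 = split_train_test(ds, 0.8, seed=3)
    assert tr2.ids == tr.ids and te2.ids == te.ids


def test_split_requires_two_per_class():
    rec = make_positive_set(SynthSpec(n_sequences=3, length_range=(60, 61),
                                      motifs=(), seed=0)).records
    neg = build_negative_dataset(
        SequenceDataset(rec[:1]), ShuffleConfig(threshold=1.0, seed=0))
    ds = SequenceDataset(rec + list(neg.records))
    with pytest.raises(ValueError):
        split_train_test(ds, 0.5, seed=0)


# ------------------------------------------------------------------- metrics

def _brute_force_auc(pos_scores, neg_scores):
    wins = sum((p > n) + 0.5 * (p == n)
               for p in pos_scores for n in neg_scores)
    return wins / (len(pos_scores) * len(neg_scores))


def test_evaluate_matches_hand_arithmetic():
    scores = [0.9] * 8 + [0.1] + [0.9] * 2 + [0.1] * 9
    labels = [1] * 9 + [0] * 11
    rep = evaluate(scores, labels)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (8, 2, 9, 1)
    assert rep.test_accuracy == pytest.approx(0.85)
    assert rep.precision == pytest.approx(0.8)
    assert rep.recall == pytest.approx(8 / 9)
    assert rep.f1 == pytest.approx(0.8421, abs=1e-4)


def test_auc_hand_cases():
    assert evaluate([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]).auc == 1.0
    assert evaluate([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]).auc == 0.75


def test_auc_equals_pairwise_concordance():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(4, 51))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        rep = evaluate(scores, labels)
        expect = _brute_force_auc(scores[labels == 1], scores[labels == 0])
        assert rep.auc == pytest.approx(expect, abs=1e-12)


@given(st.integers(min_value=1, max_value=30), st.integers(min_value=0, max_value=10_000))
def test_auc_label_swap_symmetry(n_pos, seed):
    rng = np.random.default_rng(seed)
    n = n_pos + int(rng.integers(1, 20))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    scores = rng.random(n)
    a = evaluate(scores, labels).auc
    b = evaluate(scores, 1 - labels).auc
    assert a + b == pytest.approx(1.0)


def test_metrics_invariant_to_record_order():
    rng = np.random.default_rng(1)
    scores = rng.random(40)
    labels = (rng.random(40) > 0.5).astype(int)
    labels[:2] = [0, 1]
    rep = evaluate(scores, labels)
    perm = rng.permutation(40)
    rep2 = evaluate(scores[perm], labels[perm])
    assert rep.as_dict() == rep2.as_dict()


def test_evaluate_edge_cases():
    with pytest.raises(ValueError):
        evaluate([0.1, 0.9], [1, 1])
    rep = evaluate([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1], cutoff=0.9)
    assert rep.precision == 0.0 and rep.tp == 0


# ------------------------------------------------------- gradient correctness

def _finite_difference_check(lengths, T, conv, keys, seed=0, tol=1e-4,
                             lstm_pooling="last"):
    _nn_F = _nn._F
    _nn._F = np.float64
    try:
        rng = np.random.default_rng(seed)
        net = CNNLSTM(vocab_size=8, pad_index=7, embedding_dim=5,
                      conv_filters=conv, kernel_size=3, pool_size=2,
                      lstm_units=7, dense_units=4, dropout=0.0, rng=rng,
                      lstm_pooling=lstm_pooling)
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
        B = len(lengths)
        tokens = rng.integers(0, 7, size=(B, T)).astype(np.int32)
        for b in range(B):
            tokens[b, lengths[b]:] = 7
        y = (np.arange(B) % 2).astype(float)

        def loss_fn():
            logits, cache = net.forward(tokens, np.array(lengths))
            loss, dlog = bce_with_logits(logits, y)
            return loss, cache, dlog

        _, cache, dlog = loss_fn()
        grads, _ = net.backward(cache, dlog)
        eps = 1e-6
        for key in keys:
            flat = net.params[key].ravel()
            idxs = rng.choice(flat.size, size=min(12, flat.size), replace=False)
            for i in idxs:
                old = flat[i]
                flat[i] = old + eps
                lp, _, _ = loss_fn()
                flat[i] = old - eps
                lm, _, _ = loss_fn()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert abs(num - ana) < tol * max(1.0, abs(num)), \
                    f"{key}[{i}]: numeric {num} vs analytic {ana}"
    finally:
        _nn._F = _nn_F


@pytest.mark.parametrize("pooling", ["last", "mean"])
def test_gradients_match_finite_differences_unpadded(pooling):
    """With no padding the computation is smooth away from ReLU/pool ties,
    so analytic gradients must match central differences for every layer."""
    _finite_difference_check(
        [20, 20, 20], T=20, conv=(6, 6),
        keys=["emb", "convW0", "convW1", "convb1", "Wx", "Wh", "lstm_b",
              "fc1W", "fc1b", "fc2W", "fc2b"],
        lstm_pooling=pooling)


@pytest.mark.parametrize("pooling", ["last", "mean"])
def test_gradients_match_finite_differences_masked_single_block(pooling):
    """Length masking alone (one conv block) leaves gradients exact; the
    PAD row is deliberately frozen and excluded here."""
    _finite_difference_check(
        [13, 20, 17], T=20, conv=(6,),
        keys=["convW0", "convb0", "Wx", "Wh", "lstm_b", "fc1W", "fc2W"],
        lstm_pooling=pooling)


# ------------------------------------------------------------------ training

def test_training_learns_tiny_problem(tiny_model):
    clf, report = tiny_model
    assert report.test_accuracy >= 0.9
    assert report.auc >= 0.95
    assert len(clf.history_["loss"]) == clf.epochs


def test_prediction_is_deterministic_and_batch_independent(tiny_model,
                                                           tiny_positives):
    clf, _ = tiny_model
    seqs = tiny_positives.sequences[:10]
    a = clf.score_sequences(seqs)
    b = clf.score_sequences(seqs)
    assert np.array_equal(a, b)
    # same sequence scored alone and inside a mixed-length batch
    solo = clf.score_sequences(seqs[3:4])[0]
    assert a[3] == pytest.approx(solo, abs=1e-5)
    # duplicated input -> identical scores
    dup = clf.score_sequences([seqs[0], seqs[0]])
    assert dup[0] == dup[1]


def test_untrained_model_scores_at_chance(tiny_positives, tiny_negatives):
    cfg = tiny_config(epochs=0)
    clf, report = train(tiny_positives, tiny_negatives, cfg,
                        EncoderSpec(max_len=220))
    assert abs(report.test_accuracy - 0.5) <= 0.1
    assert clf.history_["loss"] == []


def test_training_is_seed_reproducible(tiny_positives, tiny_negatives):
    cfg = tiny_config(epochs=2)
    clf1, rep1 = train(tiny_positives, tiny_negatives, cfg,
                       EncoderSpec(max_len=220))
    clf2, rep2 = train(tiny_positives, tiny_negatives, cfg,
                       EncoderSpec(max_len=220))
    assert rep1.test_accuracy == rep2.test_accuracy
    s1 = clf1.score_sequences(tiny_positives.sequences[:5])
    s2 = clf2.score_sequences(tiny_positives.sequences[:5])
    assert np.array_equal(s1, s2)


def test_predict_skips_unencodable_records(tiny_model, caplog):
    import copy

    from casminer.seqio import STANDARD_AA

    clf, _ = tiny_model
    # a shallow copy with a standard-residues-only encoder: records carrying
    # ambiguity letters become unencodable and must be skipped, not fatal
    restricted = copy.copy(clf)
    restricted.encoder_ = EncoderSpec(alphabet=STANDARD_AA, max_len=220)
    ok = ProteinSequence("ok", "ACDEFGHIKLMNPQRSTVWY" * 3)
    bad = ProteinSequence("bad", "ACDEFGHIKXBZ")
    with caplog.at_level(logging.WARNING, logger="casminer"):
        out = predict(restricted, [ok, bad])
    assert [i for i, _ in out] == ["ok"]
    assert "bad" in caplog.text


def test_predict_empty_input(tiny_model):
    clf, _ = tiny_model
    assert predict(clf, []) == []


def test_save_load_round_trip(tiny_model, tiny_positives, tmp_path):
    clf, _ = tiny_model
    clf.save(tmp_path / "model")
    back = CasMinerClassifier.load(tmp_path / "model")
    seqs = tiny_positives.sequences[:5]
    assert np.allclose(back.score_sequences(seqs), clf.score_sequences(seqs))


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(conv_filters=())
    with pytest.raises(ValueError):
        ModelConfig(train_fraction=1.0)
    with pytest.raises(ValueError):
        ModelConfig(batch_size=0)
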
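"""Seq2seq model contracts: training, fusion, beam search, persistence."""

import math

import numpy as np
import pytest

from atcgen import (
    AtcCode,
    CompoundRecord,
    Seq2SeqConfig,
    beam_generate,
    beam_search,
    greedy_generate,
    load_model,
    save_model,
    train_seq2seq,
)
from atcgen import nn
from atcgen.seq2seq import Seq2SeqModel, _pad_batch, make_pairs
from atcgen.tokenizer import build_vocab, tokenize


def one_record():
    return [CompoundRecord("c1", "abcab", frozenset({AtcCode("A02BC")}))]


@pytest.mark.parametrize("architecture", ["bilstm", "transformer"])
def test_single_example_memorization(architecture):
    recs = one_record()
    cfg = Seq2SeqConfig(
        architecture=architecture,
        seed=0,
        dropout=0.0,
        max_epochs=250,
        patience=250,
        batch_size=1,
        learning_rate=1e-2,
    )
    model = train_seq2seq(recs, recs, cfg)
    assert min(model.val_loss_trace) < 0.1
    assert greedy_generate(model, "abcab").code_string == "A02BC"


def test_training_is_deterministic_given_seed(tiny_grammar):
    _, records, _ = tiny_grammar
    cfg = Seq2SeqConfig(architecture="bilstm", seed=3, max_epochs=4, patience=10)
    m1 = train_seq2seq(records[:40], records[40:50], cfg)
    m2 = train_seq2seq(records[:40], records[40:50], cfg)
    assert m1.val_loss_trace == m2.val_loss_trace
    for a, b in zip(m1.state_arrays(), m2.state_arrays()):
        np.testing.assert_array_equal(a, b)


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        train_seq2seq([], [], Seq2SeqConfig())


def test_decoder_distributions_sum_to_one(tiny_model):
    model, held_out = tiny_model
    src = tokenize(held_out[0].smiles, model.src_vocab)
    ctx = model.init_generation(src, None)
    prefixes = np.array([[1], [1]])  # two identical start-only hypotheses
    lp = model.step_logprobs(ctx, prefixes)
    np.testing.assert_allclose(np.exp(lp).sum(axis=-1), 1.0, atol=1e-5)


def test_beam_one_equals_greedy(tiny_model):
    model, held_out = tiny_model
    for rec in held_out[:5]:
        greedy = greedy_generate(model, rec.smiles)
        beam = beam_generate(model, rec.smiles, beam_width=1, k=1)[0]
        assert greedy.code_string == beam.code_string
        assert greedy.log_prob == pytest.approx(beam.log_prob)


def test_beam_candidates_distinct_sorted_nonpositive(tiny_model):
    model, held_out = tiny_model
    cands = beam_generate(model, held_out[0].smiles, beam_width=10, k=10)
    strings = [c.code_string for c in cands]
    assert len(strings) == len(set(strings)) == 10
    lps = [c.log_prob for c in cands]
    assert all(lp <= 0.0 for lp in lps)
    assert lps == sorted(lps, reverse=True)


def test_beam_matches_exhaustive_enumeration_on_toy_decoder():
    # stationary toy decoder over tokens {end: 0.2, a: 0.5, b: 0.3}
    table = np.log(np.array([1e-12, 1e-12, 0.2, 1e-12, 0.5, 0.3]))

    def step(prefixes):
        return np.tile(table, (prefixes.shape[0], 1))

    got = beam_search(step, vocab_size=6, beam_width=500, k=12, max_len=3)

    probs = {2: 0.2, 4: 0.5, 5: 0.3}
    enum: dict[tuple, float] = {}

    def expand(seq, lp):
        if seq and seq[-1] == 2:
            enum[tuple(seq[:-1])] = max(enum.get(tuple(seq[:-1]), -np.inf), lp)
            return
        if len(seq) == 3:
            enum[tuple(seq)] = max(enum.get(tuple(seq), -np.inf), lp)
            return
        for tok, p in probs.items():
            expand(seq + [tok], lp + math.log(p))

    expand([], 0.0)
    want = sorted(enum.items(), key=lambda kv: (-kv[1], kv[0]))[:12]
    assert [(tuple(s), pytest.approx(lp)) for s, lp in got] == [
        (s, pytest.approx(lp)) for s, lp in want
    ]


def test_beam_k_larger_than_width_rejected(tiny_model):
    model, held_out = tiny_model
    with pytest.raises(ValueError):
        beam_generate(model, held_out[0].smiles, beam_width=2, k=5)
    with pytest.raises(ValueError):
        beam_generate(model, "", beam_width=2, k=1)


class TestFusion:
    def _multimodal_model(self):
        vocab = build_vocab(["abc"])
        tgt = build_vocab(["A01AA"])
        cfg = Seq2SeqConfig(architecture="bilstm", multimodal=True, seed=0)
        return Seq2SeqModel(cfg, vocab, tgt, descriptor_dim=4)

    def test_zero_descriptor_gives_finite_fused_state(self):
        model = self._multimodal_model()
        src, lengths = _pad_batch([tokenize("abc", model.src_vocab)])
        h0, c0 = model.encode(src, lengths, np.zeros((1, 4)))
        assert np.isfinite(h0.data).all() and np.isfinite(c0.data).all()

    def test_different_descriptors_change_fused_state(self):
        model = self._multimodal_model()
        src, lengths = _pad_batch([tokenize("abc", model.src_vocab)])
        h_a, _ = model.encode(src, lengths, np.zeros((1, 4)))
        h_b, _ = model.encode(src, lengths, np.ones((1, 4)))
        assert np.abs(h_a.data - h_b.data).max() > 1e-8

    def test_unimodal_fuse_is_identity_passthrough(self):
        vocab = build_vocab(["abc"])
        cfg = Seq2SeqConfig(architecture="transformer", seed=0)
        model = Seq2SeqModel(cfg, vocab, build_vocab(["A01AA"]), None)
        mem = nn.Tensor(np.ones((1, 3, cfg.hidden_dim)))
        assert model.fuse(mem, None) is mem

    def test_wrong_descriptor_length_rejected(self):
        model = self._multimodal_model()
        src, lengths = _pad_batch([tokenize("abc", model.src_vocab)])
        with pytest.raises(ValueError):
            model.encode(src, lengths, np.zeros((1, 7)))

    def test_multimodal_training_requires_descriptors(self):
        cfg = Seq2SeqConfig(multimodal=True)
        with pytest.raises(ValueError):
            train_seq2seq(one_record(), [], cfg)


def test_checkpoint_round_trip(tiny_model, tmp_path):
    model, held_out = tiny_model
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    for rec in held_out[:3]:
        a = greedy_generate(model, rec.smiles)
        b = greedy_generate(loaded, rec.smiles)
        assert a.code_string == b.code_string
        assert a.log_prob == pytest.approx(b.log_prob)
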
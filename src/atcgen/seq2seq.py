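"""Sequence-to-sequence ATC code generators.

Two encoder–decoder architectures map a character-tokenized SMILES string
to a 5-character ATC code:

* **BiLSTM** — a bidirectional LSTM encoder whose forward and backward
  final hidden/cell states are concatenated and linearly bridged (tanh) to
  the initial state of a unidirectional LSTM decoder.
* **Transformer** — standard pre-norm encoder/decoder blocks with
  sinusoidal positions, multi-head self- and cross-attention.

Either architecture can be made **multimodal**: a standardized molecular
descriptor vector is fused with the encoded SMILES before decoding.  For
the BiLSTM the descriptor vector is concatenated to the combined final
encoder state ahead of the bridge layers; for the Transformer it is
concatenated to every encoder memory position and projected back to the
model dimension.  The decoder interface is unchanged, so unimodal and
multimodal models generate identically.

Training minimizes token-level cross-entropy with teacher forcing
(padding masked) under Adam, early-stopping on validation loss.  A
multi-code compound contributes one (SMILES, code) training pair per code.
Generation uses beam search over full sequence log-probabilities with no
length normalization; candidates are distinct finished strings ranked by
total log-probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .atc import CompoundRecord
from .tokenizer import (
    END_IDX,
    PAD_IDX,
    START_IDX,
    TokenVocabulary,
    build_vocab,
    detokenize,
)


@dataclass
class Seq2SeqConfig:
    """Hyperparameters; defaults are sized for desk-scale experiments."""

    architecture: str = "bilstm"  # "bilstm" | "transformer"
    multimodal: bool = False
    embedding_dim: int = 32
    hidden_dim: int = 64  # per-direction LSTM width / transformer d_model
    num_layers: int = 1
    num_heads: int = 2
    ffn_dim: int = 128
    dropout: float = 0.1
    learning_rate: float | None = None  # per-architecture default when None
    weight_decay: float = 0.0
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("bilstm", "transformer"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def effective_learning_rate(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-2 if self.architecture == "bilstm" else 3e-3


@dataclass(frozen=True)
class GeneratedCandidate:
    """A generated target string with its total sequence log-probability."""

    code_string: str
    log_prob: float


def _pad_batch(seqs: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), PAD_IDX, dtype=np.int64)
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out, lengths


def _sinusoid(T: int, D: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(D)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / D)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class Seq2SeqModel(nn.Module):
    """BiLSTM or Transformer encoder–decoder over character vocabularies."""

    def __init__(
        self,
        config: Seq2SeqConfig,
        src_vocab: TokenVocabulary,
        tgt_vocab: TokenVocabulary,
        descriptor_dim: int | None = None,
    ):
        if config.multimodal and not descriptor_dim:
            raise ValueError("multimodal model requires a descriptor dimension")
        self.config = config
        self.src_vocab = src_vocab
        self.tgt_vocab = tgt_vocab
        self.descriptor_dim = descriptor_dim if config.multimodal else None
        rng = np.random.default_rng(config.seed)
        E, H = config.embedding_dim, config.hidden_dim
        Vs, Vt = len(src_vocab), len(tgt_vocab)
        self.emb_src = nn.Embedding(rng, Vs, E)
        self.emb_tgt = nn.Embedding(rng, Vt, E)
        ddim = self.descriptor_dim or 0
        if config.architecture == "bilstm":
            self.enc_f = nn.LSTMCell(rng, E, H)
            self.enc_b = nn.LSTMCell(rng, E, H)
            self.bridge_h = nn.Linear(rng, 2 * H + ddim, H)
            self.bridge_c = nn.Linear(rng, 2 * H + ddim, H)
            # the fused encoder state initializes the decoder AND is fed
            # back as context at every decoding step (eases the single-state
            # information bottleneck)
            self.dec = nn.LSTMCell(rng, E + H, H)
            self.out = nn.Linear(rng, H, Vt)
        else:
            D = H
            self.in_proj = nn.Linear(rng, E, D)
            self.enc_layers = [
                _TransformerLayer(rng, D, config.num_heads, config.ffn_dim, cross=False)
                for _ in range(config.num_layers)
            ]
            self.dec_layers = [
                _TransformerLayer(rng, D, config.num_heads, config.ffn_dim, cross=True)
                for _ in range(config.num_layers)
            ]
            self.enc_norm_g = nn.Tensor(np.ones(D), requires_grad=True)
            self.enc_norm_b = nn.Tensor(np.zeros(D), requires_grad=True)
            self.dec_norm_g = nn.Tensor(np.ones(D), requires_grad=True)
            self.dec_norm_b = nn.Tensor(np.zeros(D), requires_grad=True)
            if config.multimodal:
                self.fuse_proj = nn.Linear(rng, D + ddim, D)
            self.out = nn.Linear(rng, D, Vt)
        if config.architecture == "bilstm" and config.multimodal:
            pass  # fusion happens inside the bridge layers (wider input)
        self.val_loss_trace: list[float] = []

    # ------------------------------------------------------------------
    # encoding
    # ------------------------------------------------------------------
    def _check_desc(self, desc: np.ndarray | None, batch: int) -> np.ndarray | None:
        if not self.config.multimodal:
            return None
        if desc is None:
            raise ValueError("multimodal model requires descriptor vectors")
        desc = np.atleast_2d(np.asarray(desc, dtype=float))
        if desc.shape != (batch, self.descriptor_dim):
            raise ValueError(
                f"descriptor shape {desc.shape} != ({batch}, {self.descriptor_dim})"
            )
        return desc

    def _run_lstm_dir(self, cell, src, lengths, reverse, train, rng):
        B, T = src.shape
        H = self.config.hidden_dim
        h = nn.Tensor(np.zeros((B, H)))
        c = nn.Tensor(np.zeros((B, H)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            x = self.emb_src(src[:, t])
            x = nn.dropout(x, self.config.dropout, rng, train)
            h_new, c_new = cell(x, h, c)
            m = (t < lengths).astype(float)[:, None]  # freeze state on padding
            h = nn.add(nn.mul(h_new, m), nn.mul(h, 1.0 - m))
            c = nn.add(nn.mul(c_new, m), nn.mul(c, 1.0 - m))
        return h, c

    def fuse(self, encoder_output, descriptor: np.ndarray | None):
        """Fuse encoder output with a descriptor vector.

        Unimodal models pass the encoder output through unchanged.  For the
        BiLSTM, ``encoder_output`` is the concatenated final (h, c) pair and
        fusion happens in the bridge layers; for the Transformer it is the
        (B, T, D) memory, fused per position.
        """
        if self.config.architecture == "bilstm":
            h_cat, c_cat = encoder_output
            if self.config.multimodal:
                d = nn.Tensor(descriptor)
                h_cat = nn.concat([h_cat, d], axis=-1)
                c_cat = nn.concat([c_cat, d], axis=-1)
            return nn.tanh(self.bridge_h(h_cat)), nn.tanh(self.bridge_c(c_cat))
        memory = encoder_output
        if not self.config.multimodal:
            return memory
        B, T, _ = memory.shape
        tiled = np.repeat(np.asarray(descriptor)[:, None, :], T, axis=1)
        fused = nn.concat([memory, nn.Tensor(tiled)], axis=-1)
        return nn.tanh(self.fuse_proj(fused))

    def encode(self, src, lengths, desc, train=False, rng=None):
        rng = rng or np.random.default_rng(0)
        desc = self._check_desc(desc, src.shape[0])
        if self.config.architecture == "bilstm":
            h_f, c_f = self._run_lstm_dir(self.enc_f, src, lengths, False, train, rng)
            h_b, c_b = self._run_lstm_dir(self.enc_b, src, lengths, True, train, rng)
            h_cat = nn.concat([h_f, h_b], axis=-1)
            c_cat = nn.concat([c_f, c_b], axis=-1)
            return self.fuse((h_cat, c_cat), desc)
        B, T = src.shape
        x = self.emb_src(src)  # (B, T, E)
        x = self.in_proj(x)
        x = nn.add_const(x, _sinusoid(T, self.config.hidden_dim)[None])
        x = nn.dropout(x, self.config.dropout, rng, train)
        pad_mask = self._key_mask(src, T)
        for layer in self.enc_layers:
            x = layer(x, None, pad_mask, None, train, rng, self.config.dropout)
        x = nn.layer_norm(x, self.enc_norm_g, self.enc_norm_b)
        return self.fuse(x, desc)

    def _key_mask(self, src, Tq) -> np.ndarray:
        B, Tk = src.shape
        m = np.where(src == PAD_IDX, -1e9, 0.0)  # (B, Tk)
        m = np.repeat(m[:, None, None, :], self.config.num_heads, axis=1)
        return np.broadcast_to(m, (B, self.config.num_heads, Tq, Tk)).reshape(
            B * self.config.num_heads, Tq, Tk
        )

    # ------------------------------------------------------------------
    # decoding
    # ------------------------------------------------------------------
    def _decode_logits(self, enc, src, tgt_in, train=False, rng=None):
        """Teacher-forced decoder logits, shape (B, L, V_tgt)."""
        rng = rng or np.random.default_rng(0)
        B, L = tgt_in.shape
        if self.config.architecture == "bilstm":
            h, c = enc
            ctx = h  # fused encoder state, re-fed at every step
            step_logits = []
            for t in range(L):
                x = self.emb_tgt(tgt_in[:, t])
                x = nn.dropout(x, self.config.dropout, rng, train)
                h, c = self.dec(nn.concat([x, ctx], axis=-1), h, c)
                step_logits.append(nn.reshape(self.out(h), (B, 1, -1)))
            return nn.concat(step_logits, axis=1)
        memory = enc
        D = self.config.hidden_dim
        y = self.emb_tgt(tgt_in)
        y = self.in_proj(y)
        y = nn.add_const(y, _sinusoid(L, D)[None])
        y = nn.dropout(y, self.config.dropout, rng, train)
        causal = np.triu(np.full((L, L), -1e9), k=1)
        cross_mask = self._key_mask(src, L)
        for layer in self.dec_layers:
            y = layer(y, memory, causal, cross_mask, train, rng, self.config.dropout)
        y = nn.layer_norm(y, self.dec_norm_g, self.dec_norm_b)
        return self.out(y)

    def loss(self, src, lengths, desc, tgt, train=False, rng=None):
        """Mean masked cross-entropy for (start-shifted) target sequences."""
        tgt_in = tgt[:, :-1]
        tgt_out = tgt[:, 1:]
        enc = self.encode(src, lengths, desc, train, rng)
        logits = self._decode_logits(enc, src, tgt_in, train, rng)
        B, L, V = logits.shape
        flat = nn.reshape(logits, (B * L, V))
        return nn.masked_cross_entropy(
            flat, tgt_out.reshape(-1), (tgt_out != PAD_IDX).reshape(-1)
        )

    def step_logprobs(self, gen_ctx, prefixes: np.ndarray) -> np.ndarray:
        """Next-token log-probabilities for each hypothesis prefix.

        ``gen_ctx`` comes from :meth:`init_generation`; ``prefixes`` is an
        (n_hyp, t) int array of token indices starting with the start token.
        """
        with nn.no_grad():
            n = prefixes.shape[0]
            if self.config.architecture == "bilstm":
                h0, c0, _src = gen_ctx
                h = nn.Tensor(np.repeat(h0.data, n, axis=0))
                c = nn.Tensor(np.repeat(c0.data, n, axis=0))
                ctx = h
                for t in range(prefixes.shape[1]):
                    x = self.emb_tgt(prefixes[:, t])
                    h, c = self.dec(nn.concat([x, ctx], axis=-1), h, c)
                logits = self.out(h)
                return nn.log_softmax(logits, axis=-1).data
            memory, src = gen_ctx
            mem = nn.Tensor(np.repeat(memory.data, n, axis=0))
            src_rep = np.repeat(src, n, axis=0)
            logits = self._decode_logits(mem, src_rep, prefixes)
            last = logits.data[:, -1, :]
            last = last - last.max(axis=-1, keepdims=True)
            return last - np.log(np.exp(last).sum(axis=-1, keepdims=True))

    def init_generation(self, src_tokens: list[int], desc: np.ndarray | None):
        with nn.no_grad():
            src = np.asarray([src_tokens], dtype=np.int64)
            lengths = np.array([len(src_tokens)])
            enc = self.encode(src, lengths, desc, train=False)
            if self.config.architecture == "bilstm":
                h0, c0 = enc
                return (h0, c0, src)
            return (enc, src)


class _TransformerLayer(nn.Module):
    """Pre-norm block: self-attention (+ optional cross-attention) + FFN."""

    def __init__(self, rng, d_model, n_heads, ffn_dim, cross: bool):
        self.self_attn = nn.MultiHeadAttention(rng, d_model, n_heads)
        self.cross_attn = (
            nn.MultiHeadAttention(rng, d_model, n_heads) if cross else None
        )
        self.ff1 = nn.Linear(rng, d_model, ffn_dim)
        self.ff2 = nn.Linear(rng, ffn_dim, d_model)
        self.norms = [
            (
                nn.Tensor(np.ones(d_model), requires_grad=True),
                nn.Tensor(np.zeros(d_model), requires_grad=True),
            )
            for _ in range(3 if cross else 2)
        ]

    def __call__(self, x, memory, self_mask, cross_mask, train, rng, p):
        g, b = self.norms[0]
        h = nn.layer_norm(x, g, b)
        x = nn.add(x, nn.dropout(self.self_attn(h, h, self_mask), p, rng, train))
        ni = 1
        if self.cross_attn is not None:
            g, b = self.norms[ni]
            h = nn.layer_norm(x, g, b)
            x = nn.add(
                x, nn.dropout(self.cross_attn(h, memory, cross_mask), p, rng, train)
            )
            ni += 1
        g, b = self.norms[ni]
        h = nn.layer_norm(x, g, b)
        x = nn.add(x, nn.dropout(self.ff2(nn.relu(self.ff1(h))), p, rng, train))
        return x


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------
def make_pairs(
    records: list[CompoundRecord], src_vocab, tgt_vocab
) -> tuple[list[list[int]], list[list[int]], list[str]]:
    """Expand records to one (SMILES, code) token pair per annotated code."""
    from .tokenizer import tokenize

    srcs, tgts, ids = [], [], []
    for rec in records:
        if not rec.atc_codes:
            continue
        for code in sorted(rec.code_strings()):
            srcs.append(tokenize(rec.smiles, src_vocab))
            tgts.append(tokenize(code, tgt_vocab))
            ids.append(rec.compound_id)
    return srcs, tgts, ids


def train_seq2seq(
    train_records: list[CompoundRecord],
    val_records: list[CompoundRecord],
    config: Seq2SeqConfig,
    descriptors: dict[str, np.ndarray] | None = None,
    src_vocab: TokenVocabulary | None = None,
    tgt_vocab: TokenVocabulary | None = None,
) -> Seq2SeqModel:
    """Fit a generator on (SMILES, code) pairs with early stopping.

    ``descriptors`` maps compound_id to a standardized vector and is
    required iff ``config.multimodal``.
    """
    if not train_records:
        raise ValueError("empty training set")
    if config.multimodal:
        if descriptors is None:
            raise ValueError("multimodal training requires descriptors")
        missing = [
            r.compound_id
            for r in train_records + val_records
            if r.compound_id not in descriptors
        ]
        if missing:
            raise ValueError(f"descriptors missing for compounds: {missing[:5]}")
    src_vocab = src_vocab or build_vocab([r.smiles for r in train_records])
    tgt_vocab = tgt_vocab or build_vocab(
        [c for r in train_records for c in r.code_strings()]
    )
    ddim = None
    if config.multimodal:
        ddim = len(next(iter(descriptors.values())))
    model = Seq2SeqModel(config, src_vocab, tgt_vocab, descriptor_dim=ddim)
    rng = np.random.default_rng(config.seed + 1)

    def batch_arrays(srcs, tgts, ids, idx):
        src, lengths = _pad_batch([srcs[i] for i in idx])
        tgt, _ = _pad_batch([tgts[i] for i in idx])
        desc = None
        if config.multimodal:
            desc = np.stack([descriptors[ids[i]] for i in idx])
        return src, lengths, desc, tgt

    tr = make_pairs(train_records, src_vocab, tgt_vocab)
    va = make_pairs(val_records, src_vocab, tgt_vocab) if val_records else tr
    opt = nn.Adam(
        model.parameters(),
        lr=config.effective_learning_rate,
        weight_decay=config.weight_decay,
    )
    n = len(tr[0])
    best = (np.inf, None)
    bad_epochs = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            src, lengths, desc, tgt = batch_arrays(*tr, idx)
            loss = model.loss(src, lengths, desc, tgt, train=True, rng=rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
        with nn.no_grad():
            vl = 0.0
            nv = len(va[0])
            for lo in range(0, nv, 256):
                idx = np.arange(lo, min(lo + 256, nv))
                src, lengths, desc, tgt = batch_arrays(*va, idx)
                vl += model.loss(src, lengths, desc, tgt).item() * len(idx)
            vl /= nv
        model.val_loss_trace.append(vl)
        if vl < best[0] - 1e-6:
            best = (vl, [p.copy() for p in model.state_arrays()])
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model


# ----------------------------------------------------------------------
# beam search
# ----------------------------------------------------------------------
def beam_search(
    step_logprobs_fn,
    vocab_size: int,
    beam_width: int,
    k: int,
    max_len: int,
    start_idx: int = START_IDX,
    end_idx: int = END_IDX,
) -> list[tuple[list[int], float]]:
    """Breadth-limited best-first search over token sequences.

    ``step_logprobs_fn(prefixes)`` maps an (n, t) prefix array to (n, V)
    next-token log-probabilities.  Returns up to ``k`` distinct finished
    sequences (token lists without start/end) with total log-probability,
    sorted by non-increasing score.  Sequences finish at the end token or
    at ``max_len`` generated tokens.  No length normalization is applied.
    """
    if k > beam_width:
        raise ValueError("k must not exceed beam_width")
    live: list[tuple[list[int], float]] = [([start_idx], 0.0)]
    finished: dict[tuple, float] = {}
    for _ in range(max_len):
        if not live:
            break
        prefixes = np.asarray([seq for seq, _ in live], dtype=np.int64)
        lp = step_logprobs_fn(prefixes)  # (n, V)
        scores = np.asarray([s for _, s in live])[:, None] + lp
        flat = scores.ravel()
        n_take = min(beam_width, flat.size)
        top = np.argpartition(-flat, n_take - 1)[:n_take]
        top = top[np.argsort(-flat[top], kind="stable")]
        new_live = []
        for j in top:
            hyp, tok = divmod(int(j), vocab_size)
            seq = live[hyp][0] + [tok]
            score = float(flat[j])
            if tok == end_idx:
                key = tuple(seq[1:-1])
                if key not in finished or score > finished[key]:
                    finished[key] = score
            elif len(new_live) < beam_width:
                new_live.append((seq, score))
        live = new_live
        if len(finished) >= beam_width and live and max(
            s for _, s in live
        ) < min(sorted(finished.values(), reverse=True)[:beam_width]):
            break
    for seq, score in live:  # force-finish at max_len
        key = tuple(seq[1:])
        if key not in finished or score > finished[key]:
            finished[key] = score
    ranked = sorted(finished.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(list(seq), score) for seq, score in ranked[:k]]


def beam_generate(
    model: Seq2SeqModel,
    smiles: str,
    descriptor: np.ndarray | None = None,
    beam_width: int = 10,
    k: int = 1,
    max_len: int = 8,
) -> list[GeneratedCandidate]:
    """Generate up to ``k`` distinct candidate codes for one compound."""
    if not smiles:
        raise ValueError("empty SMILES string")
    if max_len < 6:
        raise ValueError("max_len must be at least 6 (5 characters + end)")
    from .tokenizer import tokenize

    src_tokens = tokenize(smiles, model.src_vocab)
    desc = None
    if model.config.multimodal:
        desc = np.atleast_2d(np.asarray(descriptor, dtype=float))
    ctx = model.init_generation(src_tokens, desc)
    seqs = beam_search(
        lambda prefixes: model.step_logprobs(ctx, prefixes),
        vocab_size=len(model.tgt_vocab),
        beam_width=beam_width,
        k=k,
        max_len=max_len,
    )
    return [
        GeneratedCandidate(detokenize([*seq, END_IDX], model.tgt_vocab), score)
        for seq, score in seqs
    ]


def greedy_generate(
    model: Seq2SeqModel,
    smiles: str,
    descriptor: np.ndarray | None = None,
    max_len: int = 8,
) -> GeneratedCandidate:
    """Greedy (argmax) decoding; equivalent to beam search with width 1."""
    return beam_generate(model, smiles, descriptor, beam_width=1, k=1, max_len=max_len)[
        0
    ]


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------
def save_model(model: Seq2SeqModel, path: str | Path) -> None:
    meta = {
        "config": asdict(model.config),
        "src_vocab": model.src_vocab.token_to_index,
        "tgt_vocab": model.tgt_vocab.token_to_index,
        "descriptor_dim": model.descriptor_dim,
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> Seq2SeqModel:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["meta"]))
    model = Seq2SeqModel(
        Seq2SeqConfig(**meta["config"]),
        TokenVocabulary(meta["src_vocab"]),
        TokenVocabulary(meta["tgt_vocab"]),
        descriptor_dim=meta["descriptor_dim"],
    )
    n = len(model.parameters())
    model.load_state_arrays([archive[f"p{i}"] for i in range(n)])
    return model
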
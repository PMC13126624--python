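"""Meta-model: decide how many generated ATC codes to emit per compound.

A generator can produce a ranked list of candidate codes, but the number of
codes actually annotated varies per compound.  The meta-model looks only at
the ten highest candidate log-probabilities and predicts the cut-off k that
maximizes the compound's exact-match F1 — a 10-way classifier (two fully
connected layers) trained on labels obtained by brute-force F1 maximization
over k on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .metrics import per_compound_f1
from .seq2seq import GeneratedCandidate, Seq2SeqModel, beam_generate

SENTINEL = -1e9  #: pad value for missing candidate slots
K_MAX = 10


@dataclass
class MetaSample:
    """Top-10 candidate log-probabilities (sentinel-padded) and optimal k."""

    top_logprobs: np.ndarray
    optimal_k: int

    def __post_init__(self) -> None:
        self.top_logprobs = np.asarray(self.top_logprobs, dtype=float)
        if self.top_logprobs.shape != (K_MAX,):
            raise ValueError("top_logprobs must have length 10")
        real = self.top_logprobs[self.top_logprobs > SENTINEL / 2]
        if np.any(np.diff(real) > 1e-9):
            raise ValueError("log-probabilities must be sorted non-increasing")
        if not 1 <= self.optimal_k <= max(len(real), 1):
            raise ValueError("optimal_k exceeds the number of real candidates")


def optimal_k(
    candidates: list[GeneratedCandidate] | list[str],
    actual: set[str],
    k_max: int = K_MAX,
) -> int:
    """Smallest k in 1..k_max maximizing exact-match F1 of the top-k set."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if not actual:
        raise ValueError("actual code set must be non-empty")
    strings = [
        c.code_string if isinstance(c, GeneratedCandidate) else c for c in candidates
    ]
    k_max = min(k_max, len(strings))
    best_k, best_f1 = 1, -1.0
    for k in range(1, k_max + 1):
        f1 = per_compound_f1(strings[:k], actual)
        if f1 > best_f1 + 1e-12:
            best_k, best_f1 = k, f1
    return best_k


def build_meta_training_set(
    model: Seq2SeqModel,
    compounds,
    descriptors: dict[str, np.ndarray] | None = None,
    k_max: int = K_MAX,
    beam_width: int = K_MAX,
) -> list[MetaSample]:
    """Generate k_max candidates per compound and label with the optimal k."""
    samples = []
    for rec in compounds:
        desc = descriptors.get(rec.compound_id) if descriptors else None
        cands = beam_generate(
            model, rec.smiles, desc, beam_width=max(beam_width, k_max), k=k_max
        )
        lp = np.full(K_MAX, SENTINEL)
        lp[: len(cands)] = [c.log_prob for c in cands]
        samples.append(MetaSample(lp, optimal_k(cands, rec.code_strings(), k_max)))
    return samples


@dataclass
class MetaModel:
    """Two-layer feed-forward 10-way classifier over the cut-off k."""

    hidden: int
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    feat_mean: np.ndarray
    feat_std: np.ndarray
    clip_floor: float
    base_model_fingerprint: str = ""

    def _features(self, top_logprobs: np.ndarray) -> np.ndarray:
        x = np.clip(np.atleast_2d(top_logprobs), self.clip_floor, 0.0)
        return (x - self.feat_mean) / self.feat_std

    def _logits(self, x: np.ndarray) -> np.ndarray:
        h = np.tanh(x @ self.w1 + self.b1)
        return h @ self.w2 + self.b2


def train_meta(
    samples: list[MetaSample],
    hidden: int = 32,
    epochs: int = 300,
    lr: float = 1e-2,
    seed: int = 0,
    clip_floor: float = -50.0,
    base_model_fingerprint: str = "",
) -> MetaModel:
    """Fit the k-classifier with cross-entropy under Adam.

    Inputs are raw log-probabilities clipped at ``clip_floor`` (so sentinel
    slots become a finite "no candidate" level) and standardized with
    statistics stored in the model.
    """
    if len({s.optimal_k for s in samples}) < 2:
        # degenerate but legal: constant predictor
        k = samples[0].optimal_k if samples else 1
        return _constant_meta(k, hidden, clip_floor, base_model_fingerprint)
    X = np.clip(np.stack([s.top_logprobs for s in samples]), clip_floor, 0.0)
    y = np.array([s.optimal_k - 1 for s in samples])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    rng = np.random.default_rng(seed)
    w1 = nn.glorot(rng, K_MAX, hidden)
    b1 = nn.Tensor(np.zeros(hidden), requires_grad=True)
    w2 = nn.glorot(rng, hidden, K_MAX)
    b2 = nn.Tensor(np.zeros(K_MAX), requires_grad=True)
    opt = nn.Adam([w1, b1, w2, b2], lr=lr)
    mask = np.ones(len(y), dtype=bool)
    for _ in range(epochs):
        h = nn.tanh(nn.add(nn.matmul(nn.Tensor(Xs), w1), b1))
        logits = nn.add(nn.matmul(h, w2), b2)
        loss = nn.masked_cross_entropy(logits, y, mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return MetaModel(
        hidden=hidden,
        w1=w1.data,
        b1=b1.data,
        w2=w2.data,
        b2=b2.data,
        feat_mean=mean,
        feat_std=std,
        clip_floor=clip_floor,
        base_model_fingerprint=base_model_fingerprint,
    )


def _constant_meta(k, hidden, clip_floor, fingerprint) -> MetaModel:
    b2 = np.zeros(K_MAX)
    b2[k - 1] = 10.0
    return MetaModel(
        hidden=hidden,
        w1=np.zeros((K_MAX, hidden)),
        b1=np.zeros(hidden),
        w2=np.zeros((hidden, K_MAX)),
        b2=b2,
        feat_mean=np.zeros(K_MAX),
        feat_std=np.ones(K_MAX),
        clip_floor=clip_floor,
        base_model_fingerprint=fingerprint,
    )


def predict_k(meta: MetaModel, top_logprobs: np.ndarray) -> int:
    """Predicted number of codes to emit, in 1..10."""
    top_logprobs = np.asarray(top_logprobs, dtype=float)
    if top_logprobs.shape[-1] != K_MAX:
        raise ValueError("input vector must have length 10")
    logits = meta._logits(meta._features(top_logprobs))
    return int(np.argmax(logits, axis=-1)[0]) + 1


def adaptive_prediction_sets(
    meta: MetaModel, candidate_lists: list[list[GeneratedCandidate]]
) -> list[list[str]]:
    """Cut each ranked candidate list at the meta-predicted k."""
    out = []
    for cands in candidate_lists:
        lp = np.full(K_MAX, SENTINEL)
        lp[: min(len(cands), K_MAX)] = [c.log_prob for c in cands[:K_MAX]]
        k = min(predict_k(meta, lp), max(len(cands), 1))
        out.append([c.code_string for c in cands[:k]])
    return out
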
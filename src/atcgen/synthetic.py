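"""Synthetic SMILES-like/ATC-like datasets with controllable structure.

Real compound data couples a string representation to hierarchical
multilabel codes through chemistry that no desk-scale fixture can imitate;
what can be imitated is the *statistical shape* of the task: string motifs
that determine code characters, descriptor features that carry redundant or
complementary signal, a label-count distribution where most compounds have
one code and a minority have several, and label noise.

A :class:`GrammarSpec` draws random strings over a small alphabet and
derives each compound's codes deterministically from character motifs.
For the code at slot *j* (a compound with m codes uses slots 0..m−1):

* level 1 letter ← the character at position *j* (a positional motif);
* level 2 digit pair ← the capped count of marker character 4+*j*;
* level 3 letter ← the capped count of marker character 8+*j*;
* level 4 letter ← the character at position −(*j*+1) from the end.

Count motifs spread their evidence over the whole string, which is the
regime sequence encoders handle well; the two positional motifs anchor the
string's ends.  Descriptor features are noisy normalized character counts,
so descriptor-based learners see a (redundant) view of the same motifs.
With ``descriptor_only_signal`` enabled, the level-4 character is instead
driven by a latent factor visible only in descriptor feature 0 and
independent of the string — a construction that separates unimodal from
multimodal models by design.

Generated records are valid inputs to the whole pipeline: codes match the
ATC pattern, never fall in the excluded "V" group, and strings contain no
fragment separator, so ``filter_dataset`` passes them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atc import AtcCode, CompoundRecord
from .chem import DescriptorMatrix

_L1 = "ABCDGHJL"
_L2 = [f"{d:02d}" for d in range(1, 13)]
_L3 = "ABCDEFGH"
_L4 = "ABCDEFGH"
_SIGNAL_L4 = ("A", "B")  # level-4 letters driven by the latent factor


@dataclass
class GrammarSpec:
    """Parameters of the synthetic compound grammar."""

    alphabet: str = "abcdefghijkl"
    min_len: int = 8
    max_len: int = 30
    label_count_probs: tuple[float, ...] = (0.7, 0.2, 0.07, 0.03)
    n_descriptors: int = 16
    descriptor_sigma: float = 0.1
    descriptor_only_signal: bool = False
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.label_count_probs) - 1.0) > 1e-9:
            raise ValueError("label count probabilities must sum to 1")
        if self.min_len < 2 * len(self.label_count_probs):
            raise ValueError(
                "min_len too short: front and back positional motifs of the "
                "deepest label slot would overlap"
            )
        if self.n_descriptors < 1:
            raise ValueError("need at least one descriptor feature")

    # motif→character maps (fixed, total over the alphabet)
    def _m1(self, ch: str) -> str:
        return _L1[self.alphabet.index(ch) % len(_L1)]

    def _m4(self, ch: str) -> str:
        return _L4[(self.alphabet.index(ch) * 3 + 1) % len(_L4)]

    def code_for_slot(self, s: str, j: int, latent: int | None = None) -> str:
        """The code read off the slot-``j`` motifs (oracle rule)."""
        A = len(self.alphabet)
        c2 = _L2[min(s.count(self.alphabet[(4 + j) % A]), len(_L2) - 1)]
        c3 = _L3[min(s.count(self.alphabet[(8 + j) % A]), len(_L3) - 1)]
        c4 = (
            _SIGNAL_L4[latent]
            if self.descriptor_only_signal
            else self._m4(s[-(j + 1)])
        )
        return self._m1(s[j]) + c2 + c3 + c4

    def oracle_codes(self, s: str, n_codes: int, latent: int | None = None) -> set[str]:
        return {self.code_for_slot(s, j, latent) for j in range(n_codes)}


def generate_dataset(
    spec: GrammarSpec, n: int
) -> tuple[list[CompoundRecord], DescriptorMatrix]:
    """Draw ``n`` synthetic compounds with codes and descriptor rows."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    A = len(spec.alphabet)
    records: list[CompoundRecord] = []
    rows = np.zeros((n, spec.n_descriptors))
    for i in range(n):
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        s = "".join(spec.alphabet[j] for j in rng.integers(0, A, size=length))
        n_codes = 1 + int(
            rng.choice(len(spec.label_count_probs), p=spec.label_count_probs)
        )
        latent = int(rng.integers(0, 2)) if spec.descriptor_only_signal else None
        codes = spec.oracle_codes(s, n_codes, latent)
        if spec.label_noise > 0:
            noisy = set()
            for c in codes:
                if rng.random() < spec.label_noise:
                    noisy.add(_random_code(rng))
                else:
                    noisy.add(c)
            codes = noisy

        counts = np.array([s.count(ch) for ch in spec.alphabet], dtype=float)
        counts /= max(length, 1)
        feats = np.resize(counts, spec.n_descriptors).copy()
        if spec.n_descriptors > len(spec.alphabet):
            feats[len(spec.alphabet)] = length / spec.max_len
        if spec.descriptor_only_signal:
            feats[0] = 2.0 * latent - 1.0  # the only trace of the latent factor
        rows[i] = feats + rng.normal(0.0, spec.descriptor_sigma, spec.n_descriptors)
        records.append(
            CompoundRecord(
                compound_id=f"syn{i:05d}",
                smiles=s,
                atc_codes=frozenset(AtcCode(c) for c in codes),
                source="synthetic",
            )
        )
    names = [f"d{j:02d}" for j in range(spec.n_descriptors)]
    return records, DescriptorMatrix(names=names, values=rows)


def _random_code(rng: np.random.Generator) -> str:
    return (
        _L1[rng.integers(0, len(_L1))]
        + _L2[rng.integers(0, len(_L2))]
        + _L3[rng.integers(0, len(_L3))]
        + _L4[rng.integers(0, len(_L4))]
    )


def descriptor_map(
    records: list[CompoundRecord], matrix: DescriptorMatrix
) -> dict[str, np.ndarray]:
    """Compound_id → descriptor row, aligned by position."""
    return {r.compound_id: matrix.values[i] for i, r in enumerate(records)}
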
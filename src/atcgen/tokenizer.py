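"""Character-level tokenization of SMILES and ATC strings.

Both source (SMILES) and target (ATC) strings are tokenized character by
character; multi-character element symbols such as ``Cl`` are deliberately
split into two tokens (``C``, ``l``).  Four special tokens occupy fixed,
reserved indices so that vocabularies are stable across save/load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

PAD, START, END, UNK = "<pad>", "<s>", "</s>", "<unk>"
SPECIALS = (PAD, START, END, UNK)
PAD_IDX, START_IDX, END_IDX, UNK_IDX = 0, 1, 2, 3


@dataclass
class TokenVocabulary:
    """Bijective map between single-character tokens and integer indices."""

    token_to_index: dict[str, int]

    def __post_init__(self) -> None:
        for tok, idx in zip(SPECIALS, range(4)):
            if self.token_to_index.get(tok) != idx:
                raise ValueError(f"special token {tok!r} must have index {idx}")
        self.index_to_token = {i: t for t, i in self.token_to_index.items()}
        if len(self.index_to_token) != len(self.token_to_index):
            raise ValueError("token_to_index is not injective")

    def __len__(self) -> int:
        return len(self.token_to_index)

    def encode_char(self, ch: str) -> int:
        return self.token_to_index.get(ch, UNK_IDX)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.token_to_index, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        return cls(json.loads(Path(path).read_text()))


def build_vocab(strings: list[str]) -> TokenVocabulary:
    """Build a character vocabulary from a corpus of strings.

    Non-special tokens are assigned indices 4.. in sorted character order,
    making the vocabulary deterministic for a given character set.
    """
    if not strings:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    chars = sorted({ch for s in strings for ch in s})
    mapping = {tok: i for i, tok in enumerate(SPECIALS)}
    for i, ch in enumerate(chars, start=4):
        mapping[ch] = i
    return TokenVocabulary(mapping)


def tokenize(s: str, vocab: TokenVocabulary) -> list[int]:
    """Encode ``s`` character-wise, wrapped in start/end indices."""
    return [START_IDX, *(vocab.encode_char(ch) for ch in s), END_IDX]


def detokenize(indices: list[int], vocab: TokenVocabulary) -> str:
    """Inverse of :func:`tokenize`; special tokens are dropped."""
    out = []
    for i in indices:
        if i in (PAD_IDX, START_IDX):
            continue
        if i == END_IDX:
            break
        out.append(vocab.index_to_token.get(i, UNK))
    return "".join(out)
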
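"""WHO Anatomical Therapeutic Chemical (ATC) codes and compound records.

An ATC code, truncated to its first four hierarchical levels, is a
5-character string ``LDDLL`` (letter, digit, digit, letter, letter), e.g.
``A02BC``: anatomical main group ``A``, therapeutic subgroup ``02``,
pharmacological subgroup ``B``, chemical subgroup ``C``.  Level *n*
corresponds to a prefix of length 1, 3, 4 or 5.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

ATC_PATTERN = re.compile(r"^[A-Z][0-9]{2}[A-Z][A-Z]$")

#: prefix length of each hierarchical level (1-based)
LEVEL_PREFIX_LEN = {1: 1, 2: 3, 3: 4, 4: 5}


def level_prefix(code: str, n: int) -> str:
    """Return the level-``n`` prefix of a 5-character ATC code.

    ``n`` must be in 1..4; the prefix lengths are 1, 3, 4 and 5.
    """
    if n not in LEVEL_PREFIX_LEN:
        raise ValueError(f"ATC level must be in 1..4, got {n}")
    if len(code) != 5:
        raise ValueError(f"ATC code must have 5 characters, got {code!r}")
    return code[: LEVEL_PREFIX_LEN[n]]


@dataclass(frozen=True, order=True)
class AtcCode:
    """A validated 4-level (5-character) ATC code."""

    code: str

    def __post_init__(self) -> None:
        if not ATC_PATTERN.match(self.code):
            raise ValueError(f"invalid ATC code {self.code!r}")

    def prefix(self, n: int) -> str:
        return level_prefix(self.code, n)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


@dataclass
class CompoundRecord:
    """A compound: canonical SMILES plus its annotated ATC codes.

    ``smiles`` is expected to be in standardized canonical form so that
    string equality is a valid deduplication key across sources.
    """

    compound_id: str
    smiles: str
    atc_codes: frozenset[AtcCode]
    source: str = ""
    mol_weight: float | None = None

    def __post_init__(self) -> None:
        self.atc_codes = frozenset(self.atc_codes)

    @property
    def is_multicode(self) -> bool:
        return len(self.atc_codes) > 1

    def code_strings(self) -> set[str]:
        return {c.code for c in self.atc_codes}

    def with_codes(self, codes) -> "CompoundRecord":
        return CompoundRecord(
            compound_id=self.compound_id,
            smiles=self.smiles,
            atc_codes=frozenset(codes),
            source=self.source,
            mol_weight=self.mol_weight,
        )
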
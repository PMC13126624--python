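"""Data partitioning for the two evaluation scenarios.

*New-drug annotation*: compounds are partitioned into train/validation/test
so that no canonical SMILES appears in more than one partition, stratified
on the single- vs multi-code indicator so every partition carries the
global multi-code fraction (up to integer granularity).

*Drug repurposing*: the split is over codes, not compounds.  Every
single-code compound's code goes to training; each multi-code compound's
codes are shuffled and split with ⌈m/2⌉ codes to training and the rest to
test, so the model must generate held-out indications for compounds it has
seen.  Validation compounds are drawn out of the training list, again
stratified on the multi-code indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atc import CompoundRecord


@dataclass
class SplitResult:
    """Disjoint train/validation/test partitions plus the seed that made them.

    In the repurposing scenario the train/validation records carry only
    their assigned code subsets and ``test_codes`` maps compound_id to the
    held-out codes (the test records carry exactly those).
    """

    train: list[CompoundRecord]
    validation: list[CompoundRecord]
    test: list[CompoundRecord]
    seed: int
    scenario: str = "newdrug"
    test_codes: dict[str, frozenset] | None = None


def _stratum_counts(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items over partitions."""
    raw = [n * r for r in ratios]
    counts = [math.floor(x) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # largest remainder first
    for i in order[:rem]:
        counts[i] += 1
    return counts


def new_drug_split(
    records: list[CompoundRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitResult:
    """Stratified compound-level train/validation/test split."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    if len(records) < len(ratios):
        raise ValueError("fewer records than partitions")
    rng = np.random.default_rng(seed)
    parts: tuple[list, list, list] = ([], [], [])
    for is_multi in (False, True):
        stratum = [r for r in records if r.is_multicode == is_multi]
        idx = rng.permutation(len(stratum))
        counts = _stratum_counts(len(stratum), ratios)
        pos = 0
        for part, c in zip(parts, counts):
            part.extend(stratum[i] for i in idx[pos : pos + c])
            pos += c
    return SplitResult(*parts, seed=seed, scenario="newdrug")


def repurposing_split(
    records: list[CompoundRecord],
    val_fraction: float = 0.1,
    seed: int = 0,
) -> SplitResult:
    """Code-level split: known indications train, held-out indications test."""
    rng = np.random.default_rng(seed)
    train_side: list[CompoundRecord] = []
    test_side: list[CompoundRecord] = []
    test_codes: dict[str, frozenset] = {}
    for rec in records:
        codes = sorted(rec.code_strings())
        if len(codes) == 1:
            train_side.append(rec)
            continue
        perm = rng.permutation(len(codes))
        n_train = math.ceil(len(codes) / 2)
        tr = frozenset(codes[i] for i in perm[:n_train])
        te = frozenset(codes[i] for i in perm[n_train:])
        train_side.append(_with(rec, tr))
        test_side.append(_with(rec, te))
        test_codes[rec.compound_id] = te

    # carve validation out of the training compounds, stratified on the
    # ORIGINAL multi-code indicator
    val: list[CompoundRecord] = []
    train: list[CompoundRecord] = []
    multi_ids = set(test_codes)
    for is_multi in (False, True):
        stratum = [r for r in train_side if (r.compound_id in multi_ids) == is_multi]
        idx = rng.permutation(len(stratum))
        n_val = int(round(val_fraction * len(stratum)))
        val.extend(stratum[i] for i in idx[:n_val])
        train.extend(stratum[i] for i in idx[n_val:])
    return SplitResult(
        train, val, test_side, seed=seed, scenario="repurposing", test_codes=test_codes
    )


def _with(rec: CompoundRecord, code_strings: frozenset) -> CompoundRecord:
    from .atc import AtcCode

    return rec.with_codes(frozenset(AtcCode(c) for c in code_strings))
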
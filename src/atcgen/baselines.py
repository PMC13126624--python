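"""Baseline predictors: per-level random sampler and hierarchical classifiers.

Both baselines predict an ATC code level by level and concatenate the
choices.  The random baseline samples each level's continuation from the
empirical distribution observed in training, conditioned on the prefix
chosen so far (falling back to the level's marginal for unseen prefixes).
The hierarchical classifiers train one probabilistic multiclass model per
level: the first level consumes molecular descriptors only, and each deeper
level additionally receives one-hot encodings of the characters chosen at
the previous levels, sampling each level's output from the model's class
probabilities.

Level 2 (the two-digit therapeutic subgroup) is treated as a single
categorical unit rather than digit-by-digit, matching its semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atc import CompoundRecord

# per-level (start, end) character spans within the 5-character code
_SEGMENTS = {1: (0, 1), 2: (1, 3), 3: (3, 4), 4: (4, 5)}
LEVELS = (1, 2, 3, 4)


@dataclass
class LevelDistribution:
    """Empirical conditional distributions of level continuations.

    ``conditional[n]`` maps each observed level-(n−1) prefix to a
    (continuations, probabilities) pair; ``marginal[n]`` is the fallback
    distribution for prefixes never seen in training.
    """

    conditional: dict[int, dict[str, tuple[list[str], np.ndarray]]]
    marginal: dict[int, tuple[list[str], np.ndarray]]


def fit_level_distribution(train_records: list[CompoundRecord]) -> LevelDistribution:
    """Count level continuations over all (compound, code) pairs."""
    if not train_records:
        raise ValueError("empty training set")
    cond: dict[int, dict[str, dict[str, int]]] = {n: {} for n in LEVELS}
    marg: dict[int, dict[str, int]] = {n: {} for n in LEVELS}
    for rec in train_records:
        for code in sorted(rec.code_strings()):
            for n in LEVELS:
                lo, hi = _SEGMENTS[n]
                prefix, seg = code[:lo], code[lo:hi]
                cond[n].setdefault(prefix, {})
                cond[n][prefix][seg] = cond[n][prefix].get(seg, 0) + 1
                marg[n][seg] = marg[n].get(seg, 0) + 1

    def normalize(counts: dict[str, int]):
        keys = sorted(counts)
        p = np.array([counts[s] for s in keys], dtype=float)
        return keys, p / p.sum()

    return LevelDistribution(
        conditional={
            n: {pre: normalize(c) for pre, c in cond[n].items()} for n in LEVELS
        },
        marginal={n: normalize(marg[n]) for n in LEVELS},
    )


def _sample_code(dist: LevelDistribution, rng: np.random.Generator) -> str:
    code = ""
    for n in LEVELS:
        entry = dist.conditional[n].get(code, dist.marginal[n])
        segs, p = entry
        code += segs[rng.choice(len(segs), p=p)]
    return code


def random_predict(
    dist: LevelDistribution, seed: int, k: int = 1, max_tries: int = 1000
) -> list[str]:
    """Draw up to ``k`` distinct codes by level-wise conditional sampling."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    tries = 0
    while len(out) < k and tries < max_tries:
        code = _sample_code(dist, rng)
        tries += 1
        if code not in seen:
            seen.add(code)
            out.append(code)
    return out


def ranked_codes(dist: LevelDistribution, k: int = 1) -> list[str]:
    """Deterministic ranked code list: greedy joint-probability beam.

    Used as a cheap fixture generator; ranks full codes by the product of
    their conditional level probabilities.
    """
    beams: list[tuple[str, float]] = [("", 0.0)]
    for n in LEVELS:
        nxt = []
        for prefix, score in beams:
            segs, p = dist.conditional[n].get(prefix, dist.marginal[n])
            for s, pr in zip(segs, p):
                nxt.append((prefix + s, score + np.log(pr)))
        nxt.sort(key=lambda t: (-t[1], t[0]))
        beams = nxt[: max(k * 4, 16)]
    return [c for c, _ in beams[:k]]


class HierarchicalBaseline:
    """Per-level probabilistic classifiers with previous-level feedback.

    ``make_estimator(level)`` must return an unfitted scikit-learn style
    classifier exposing ``fit`` and ``predict_proba`` (e.g. a random forest
    or an MLP); the learner is pluggable by design.
    """

    def __init__(self, make_estimator):
        self.make_estimator = make_estimator
        self.models: dict[int, object] = {}
        self.classes: dict[int, list[str]] = {}
        self.prefix_categories: dict[int, list[str]] = {}

    def _encode_prefix(self, n: int, prefix: str) -> np.ndarray:
        cats = self.prefix_categories[n]
        v = np.zeros(len(cats))
        if prefix in cats:
            v[cats.index(prefix)] = 1.0
        return v

    def fit(
        self,
        records: list[CompoundRecord],
        descriptors: dict[str, np.ndarray],
    ) -> "HierarchicalBaseline":
        pairs = [
            (descriptors[r.compound_id], code)
            for r in records
            for code in sorted(r.code_strings())
        ]
        for n in LEVELS:
            lo, hi = _SEGMENTS[n]
            self.prefix_categories[n] = sorted({code[:lo] for _, code in pairs})
            X, y = [], []
            for desc, code in pairs:
                X.append(np.concatenate([desc, self._encode_prefix(n, code[:lo])]))
                y.append(code[lo:hi])
            model = self.make_estimator(n)
            model.fit(np.stack(X), np.array(y))
            self.models[n] = model
            self.classes[n] = list(model.classes_)
        return self

    def predict(self, descriptor: np.ndarray, seed: int) -> str:
        """Sample one code, feeding each level's choice to the next."""
        rng = np.random.default_rng(seed)
        code = ""
        for n in LEVELS:
            model = self.models.get(n)
            if model is None:
                raise ValueError(f"no fitted model for level {n}")
            x = np.concatenate([descriptor, self._encode_prefix(n, code)])[None, :]
            p = model.predict_proba(x)[0]
            p = p / p.sum()
            code += self.classes[n][rng.choice(len(p), p=p)]
        return code

    def predict_many(self, descriptor: np.ndarray, seed: int, k: int = 1) -> list[str]:
        rng = np.random.default_rng(seed)
        out, seen = [], set()
        for _ in range(1000):
            if len(out) >= k:
                break
            code = self.predict(descriptor, int(rng.integers(0, 2**31 - 1)))
            if code not in seen:
                seen.add(code)
                out.append(code)
        return out
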
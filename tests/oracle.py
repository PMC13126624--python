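"""Independent brute-force evaluators used as oracles in tests.

These walk the metric definitions literally — quantifying over every
(prediction, actual, level) triple from the full code sets — without any of
the survivor bookkeeping the library implementation uses.
"""

from __future__ import annotations

_PREFIX_LEN = {0: 0, 1: 1, 2: 3, 3: 4, 4: 5}


def _match(a: str, b: str, n: int) -> bool:
    return a[: _PREFIX_LEN[n]] == b[: _PREFIX_LEN[n]]


def brute_level_metrics(instances):
    """L-Precision/L-Recall per level straight from the definitions.

    ``instances``: list of (predicted list, actual set) pairs.
    Returns (l_precision, l_recall, evaluated_counts, correct_counts) dicts
    keyed by level, with None for undefined levels.
    """
    l_prec: dict[int, float | None] = {}
    l_rec: dict[int, float | None] = {}
    evaluated: dict[int, int] = {}
    correct: dict[int, int] = {}

    def in_C(pred, actual, n):  # compound has >=1 level-n-correct prediction
        if n == 0:
            return True
        return any(_match(p, y, n) for p in pred for y in actual)

    for n in (1, 2, 3, 4):
        members = [
            (pred, actual)
            for pred, actual in instances
            if in_C(pred, actual, n - 1)
        ]
        evaluated[n] = len(members)
        correct[n] = sum(
            1 for pred, actual in instances if in_C(pred, actual, n)
        )
        if not members:
            l_prec[n] = None
            l_rec[n] = None
            continue
        ps, rs = [], []
        for pred, actual in members:
            # restricted sets per the definitions (vs the FULL other side)
            pred_n = [
                p
                for p in pred
                if n == 1 or any(_match(p, y, n - 1) for y in actual)
            ]
            act_n = [
                y
                for y in actual
                if n == 1 or any(_match(p, y, n - 1) for p in pred)
            ]
            n_correct_pred = sum(
                1 for p in pred_n if any(_match(p, y, n) for y in act_n)
            )
            n_correct_act = sum(
                1 for y in act_n if any(_match(p, y, n) for p in pred_n)
            )
            ps.append(n_correct_pred / len(pred_n) if pred_n else 0.0)
            rs.append(n_correct_act / len(act_n) if act_n else 0.0)
        l_prec[n] = sum(ps) / len(members)
        l_rec[n] = sum(rs) / len(members)
    return l_prec, l_rec, evaluated, correct


def brute_exact_prf(instances):
    """Example-based exact precision/recall/F1 by direct set arithmetic."""
    ps, rs, fs = [], [], []
    for pred, actual in instances:
        pred = list(dict.fromkeys(pred))
        inter = len(set(pred) & set(actual))
        p = inter / len(pred) if pred else 0.0
        r = inter / len(actual)
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(f)
    m = len(instances)
    return sum(ps) / m, sum(rs) / m, sum(fs) / m


def brute_best_k(candidates, actual, k_max):
    """Exhaustive optimal cut-off: smallest k maximizing exact F1."""
    best_k, best_f1 = 1, -1.0
    for k in range(1, min(k_max, len(candidates)) + 1):
        pred = list(dict.fromkeys(candidates[:k]))
        inter = len(set(pred) & set(actual))
        p = inter / len(pred)
        r = inter / len(actual)
        f = 2 * p * r / (p + r) if p + r else 0.0
        if f > best_f1 + 1e-12:
            best_k, best_f1 = k, f
    return best_k
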
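"""Hierarchical (level-wise) and exact evaluation metrics for ATC generation.

Generated ATC codes are scored two ways:

* **Exact metrics** treat each compound's predicted and actual code sets as
  flat label sets and report example-based precision, recall and F1 over
  complete 4-level codes.

* **Level-wise metrics** (L-Precision / L-Recall) score each hierarchical
  level separately, restricting attention at level *n* to compounds — and,
  within a compound, to codes — that were already correct through level
  *n*−1.  A compound with no correct prediction at level *n* drops out of
  all deeper levels, so a mistake at an early level is penalized once
  rather than cascading.

Formally, with C⁰ the full compound set and Cⁿ the compounds having at
least one level-*n*-correct prediction, for each compound α let Ŷαⁿ (Yαⁿ)
be its predicted (actual) codes whose level-(n−1) prefix is matched on the
other side (all codes for n = 1).  Then

    L-Precision(C, n) = 1/|Cⁿ⁻¹| · Σ_{α∈Cⁿ⁻¹} |{ŷ∈Ŷαⁿ : ∃y∈Yαⁿ, y≈ₙŷ}| / |Ŷαⁿ|
    L-Recall(C, n)    = 1/|Cⁿ⁻¹| · Σ_{α∈Cⁿ⁻¹} |{y∈Yαⁿ : ∃ŷ∈Ŷαⁿ, y≈ₙŷ}| / |Yαⁿ|

where y ≈ₙ ŷ means equal level-*n* prefixes.  A level whose evaluation
set Cⁿ⁻¹ is empty is reported as undefined (None), never as zero.

Generated strings that are not valid 5-character codes are retained in the
predicted sets and can only ever score as incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .atc import LEVEL_PREFIX_LEN, AtcCode

LEVELS = (1, 2, 3, 4)


def _prefix(code: str, n: int) -> str:
    # tolerant prefix for possibly-invalid generated strings
    return code[: LEVEL_PREFIX_LEN[n]]


@dataclass
class EvaluationInstance:
    """One compound's predicted code strings and actual code set."""

    predicted: list[str]
    actual: set[str]

    def __post_init__(self) -> None:
        if not self.actual:
            raise ValueError("actual code set must be non-empty")
        self.actual = {a.code if isinstance(a, AtcCode) else a for a in self.actual}
        self.predicted = list(dict.fromkeys(self.predicted))  # dedupe, keep order


@dataclass
class LevelMetricsReport:
    """L-Precision/L-Recall per level plus exact example-based P/R/F1.

    ``evaluated_counts[n]`` is |Cⁿ⁻¹|, the number of compounds entering the
    level-*n* average; ``correct_counts[n]`` is |Cⁿ|.  Undefined levels
    carry ``None`` metrics and an evaluated count of 0.
    """

    l_precision: dict[int, float | None]
    l_recall: dict[int, float | None]
    evaluated_counts: dict[int, int]
    correct_counts: dict[int, int]
    exact_precision: float | None = None
    exact_recall: float | None = None
    exact_f1: float | None = None

    def as_dict(self) -> dict:
        return {
            "l_precision": {str(n): self.l_precision[n] for n in LEVELS},
            "l_recall": {str(n): self.l_recall[n] for n in LEVELS},
            "evaluated_counts": {str(n): self.evaluated_counts[n] for n in LEVELS},
            "correct_counts": {str(n): self.correct_counts[n] for n in LEVELS},
            "exact_precision": self.exact_precision,
            "exact_recall": self.exact_recall,
            "exact_f1": self.exact_f1,
        }


def compute_level_metrics(
    instances: list[EvaluationInstance],
) -> LevelMetricsReport:
    """Evaluate L-Precision and L-Recall for levels 1..4."""
    if not instances:
        raise ValueError("no instances to evaluate")
    l_precision: dict[int, float | None] = {}
    l_recall: dict[int, float | None] = {}
    evaluated_counts: dict[int, int] = {}
    correct_counts: dict[int, int] = {}

    # survivors: (predicted, actual) restricted sets per compound in C^{n-1}
    survivors = [(inst.predicted, inst.actual) for inst in instances]
    for n in LEVELS:
        evaluated_counts[n] = len(survivors)
        if not survivors:
            l_precision[n] = None
            l_recall[n] = None
            correct_counts[n] = 0
            continue
        prec_sum = 0.0
        rec_sum = 0.0
        next_survivors = []
        for pred, actual in survivors:
            actual_prefixes = {_prefix(y, n) for y in actual}
            pred_prefixes = {_prefix(p, n) for p in pred}
            correct_pred = [p for p in pred if _prefix(p, n) in actual_prefixes]
            correct_actual = [y for y in actual if _prefix(y, n) in pred_prefixes]
            prec_sum += len(correct_pred) / len(pred) if pred else 0.0
            rec_sum += len(correct_actual) / len(actual)
            if correct_pred:
                next_survivors.append((correct_pred, set(correct_actual)))
        l_precision[n] = prec_sum / len(survivors)
        l_recall[n] = rec_sum / len(survivors)
        correct_counts[n] = len(next_survivors)
        survivors = next_survivors

    report = LevelMetricsReport(
        l_precision=l_precision,
        l_recall=l_recall,
        evaluated_counts=evaluated_counts,
        correct_counts=correct_counts,
    )
    p, r, f = compute_exact_prf(instances)
    report.exact_precision, report.exact_recall, report.exact_f1 = p, r, f
    return report


def compute_exact_prf(
    instances: list[EvaluationInstance], f1_of_means: bool = False
) -> tuple[float, float, float]:
    """Example-based precision/recall/F1 over complete 4-level codes.

    Per compound: P = |Ŷ∩Y|/|Ŷ| (0 when no predictions), R = |Ŷ∩Y|/|Y|,
    F1 their harmonic mean (0 when both vanish); means over compounds are
    reported.  With ``f1_of_means`` the F1 is instead the harmonic mean of
    the mean precision and mean recall.
    """
    if not instances:
        raise ValueError("no instances to evaluate")
    ps, rs, fs = [], [], []
    for inst in instances:
        hits = len(set(inst.predicted) & inst.actual)
        p = hits / len(inst.predicted) if inst.predicted else 0.0
        r = hits / len(inst.actual)
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(f)
    mp = sum(ps) / len(ps)
    mr = sum(rs) / len(rs)
    if f1_of_means:
        mf = 2 * mp * mr / (mp + mr) if (mp + mr) > 0 else 0.0
    else:
        mf = sum(fs) / len(fs)
    return mp, mr, mf


def per_compound_f1(predicted: list[str], actual: set[str]) -> float:
    """Exact-match F1 for one compound's prediction set."""
    predicted = list(dict.fromkeys(predicted))
    hits = len(set(predicted) & set(actual))
    if hits == 0:
        return 0.0
    p = hits / len(predicted)
    r = hits / len(actual)
    return 2 * p * r / (p + r)
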
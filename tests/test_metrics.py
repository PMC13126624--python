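"""Level-wise and exact metric behaviour against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atcgen import compute_exact_prf, compute_level_metrics, level_prefix
from atcgen.metrics import EvaluationInstance

from .oracle import brute_exact_prf, brute_level_metrics


def inst(pred, actual):
    return EvaluationInstance(predicted=list(pred), actual=set(actual))


@pytest.mark.parametrize(
    "code,n,expected",
    [("A02BC", 1, "A"), ("A02BC", 2, "A02"), ("A02BC", 3, "A02B"), ("A02BC", 4, "A02BC")],
)
def test_level_prefix_lengths(code, n, expected):
    assert level_prefix(code, n) == expected


def test_level_prefix_rejects_bad_level():
    with pytest.raises(ValueError):
        level_prefix("A02BC", 5)


def test_perfect_predictions_score_one_everywhere():
    instances = [
        inst(["A02BC", "C07AB"], {"A02BC", "C07AB"}),
        inst(["B01AC"], {"B01AC"}),
    ]
    rep = compute_level_metrics(instances)
    for n in (1, 2, 3, 4):
        assert rep.l_precision[n] == 1.0
        assert rep.l_recall[n] == 1.0
        assert rep.evaluated_counts[n] == 2
    assert (rep.exact_precision, rep.exact_recall, rep.exact_f1) == (1.0, 1.0, 1.0)


def test_partially_correct_compound_walks_the_hierarchy():
    # one compound, two actual codes, one prediction sharing levels 1-3 with
    # one of them but missing at level 4
    rep = compute_level_metrics([inst(["A02BA"], {"A02BC", "C07AB"})])
    assert [rep.l_precision[n] for n in (1, 2, 3, 4)] == [1.0, 1.0, 1.0, 0.0]
    assert [rep.l_recall[n] for n in (1, 2, 3, 4)] == [0.5, 1.0, 1.0, 0.0]
    assert rep.correct_counts[3] == 1
    assert rep.correct_counts[4] == 0


def test_total_miss_leaves_deeper_levels_undefined():
    rep = compute_level_metrics([inst(["B01AC"], {"A02BC"})])
    assert rep.l_precision[1] == 0.0 and rep.l_recall[1] == 0.0
    assert rep.correct_counts[1] == 0
    for n in (2, 3, 4):
        assert rep.l_precision[n] is None
        assert rep.l_recall[n] is None
        assert rep.evaluated_counts[n] == 0


def test_empty_prediction_set_counts_as_level1_miss():
    rep = compute_level_metrics([inst([], {"A02BC"})])
    assert rep.l_precision[1] == 0.0
    assert rep.evaluated_counts[2] == 0


def test_exact_prf_set_arithmetic():
    p, r, f = compute_exact_prf([inst(["A02BC"], {"A02BC", "C07AB"})])
    assert (p, r) == (1.0, 0.5)
    assert f == pytest.approx(2 / 3)
    p, r, f = compute_exact_prf([inst(["X01AA"], {"A02BC"})])
    assert (p, r, f) == (0.0, 0.0, 0.0)


def _random_instances(rng, n, allow_invalid=False):
    letters, digits = "AB", "01"

    def code():
        return (
            rng.choice(list(letters))
            + rng.choice(list(digits))
            + rng.choice(list(digits))
            + rng.choice(list(letters))
            + rng.choice(list(letters))
        )

    out = []
    for _ in range(n):
        n_pred = rng.integers(0, 6)
        n_act = rng.integers(1, 6)
        pred = [code() for _ in range(n_pred)]
        if allow_invalid and n_pred and rng.random() < 0.3:
            pred[0] = pred[0][:4]  # malformed length-4 string
        out.append((list(dict.fromkeys(pred)), {code() for _ in range(n_act)}))
    return out


def test_matches_bruteforce_enumerator_on_random_instances():
    rng = np.random.default_rng(12345)
    raw = _random_instances(rng, 200, allow_invalid=True)
    instances = [inst(p, a) for p, a in raw]
    rep = compute_level_metrics(instances)
    bp, br, bev, bco = brute_level_metrics(raw)
    for n in (1, 2, 3, 4):
        assert rep.l_precision[n] == pytest.approx(bp[n])
        assert rep.l_recall[n] == pytest.approx(br[n])
        assert rep.evaluated_counts[n] == bev[n]
        assert rep.correct_counts[n] == bco[n]
    ep, er, ef = brute_exact_prf(raw)
    assert rep.exact_precision == pytest.approx(ep)
    assert rep.exact_recall == pytest.approx(er)
    assert rep.exact_f1 == pytest.approx(ef)


def test_evaluated_counts_are_non_increasing():
    rng = np.random.default_rng(7)
    instances = [inst(p, a) for p, a in _random_instances(rng, 50)]
    rep = compute_level_metrics(instances)
    counts = [len(instances)] + [rep.correct_counts[n] for n in (1, 2, 3, 4)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    for n in (1, 2, 3, 4):
        assert rep.evaluated_counts[n] == counts[n - 1]


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, deadline=None)
def test_adding_a_correct_code_never_decreases_level1_or_exact_recall(seed):
    # deeper levels are conditional on the level-(n-1)-correct cohort, which
    # itself grows when codes are added, so only level 1 and the exact
    # metrics carry an unconditional monotonicity guarantee
    rng = np.random.default_rng(seed)
    raw = _random_instances(rng, 10)
    target = int(rng.integers(0, len(raw)))
    pred, actual = raw[target]
    missing = [y for y in actual if y not in pred]
    if not missing:
        return
    augmented = list(raw)
    augmented[target] = (pred + [missing[0]], actual)
    before = compute_level_metrics([inst(p, a) for p, a in raw])
    after = compute_level_metrics([inst(p, a) for p, a in augmented])
    assert after.l_recall[1] >= before.l_recall[1] - 1e-12
    assert after.exact_recall >= before.exact_recall - 1e-12
    # the evaluated cohorts themselves only ever grow
    for n in (1, 2, 3, 4):
        assert after.correct_counts[n] >= before.correct_counts[n]


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, deadline=None)
def test_single_prediction_single_actual_precision_equals_recall(seed):
    rng = np.random.default_rng(seed)
    raw = [(p[:1] or ["A01AA"], {next(iter(a))}) for p, a in _random_instances(rng, 20)]
    rep = compute_level_metrics([inst(p, a) for p, a in raw])
    for n in (1, 2, 3, 4):
        assert rep.l_precision[n] == rep.l_recall[n]
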
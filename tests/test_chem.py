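"""Standardization, filtering, merging, descriptors and tokenization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atcgen import (
    AtcCode,
    CompoundRecord,
    SmilesParseError,
    build_vocab,
    compute_descriptors,
    detokenize,
    filter_dataset,
    fit_apply_standardization,
    merge_sources,
    prune_descriptors,
    standardize_smiles,
    tokenize,
)
from atcgen.chem import DescriptorMatrix
from atcgen.tokenizer import END_IDX, START_IDX, TokenVocabulary


def rec(smiles, codes, cid="x", mw=None):
    return CompoundRecord(
        compound_id=cid,
        smiles=smiles,
        atc_codes=frozenset(AtcCode(c) for c in codes),
        mol_weight=mw,
    )


class TestStandardizeSmiles:
    def test_strips_counterion_and_neutralizes(self):
        # sodium acetate -> acetic acid (frozen RDKit output)
        assert standardize_smiles("[Na+].CC(=O)[O-]") == "CC(=O)O"

    def test_neutral_molecule_is_fixed_point(self):
        assert standardize_smiles("C") == "C"

    @pytest.mark.parametrize(
        "raw", ["[Na+].CC(=O)[O-]", "c1ccccc1", "CC(N)C(=O)O", "OC(=O)c1ccccc1O"]
    )
    def test_idempotent(self, raw):
        once = standardize_smiles(raw)
        assert standardize_smiles(once) == once

    @pytest.mark.parametrize("raw", ["C(", "", "not_a_smiles(("])
    def test_unparsable_input_raises(self, raw):
        with pytest.raises(SmilesParseError):
            standardize_smiles(raw)


class TestFilterDataset:
    def test_v_group_excluded_except_v03ax(self):
        removed = filter_dataset([rec("CC", {"V08AB"})])
        kept = filter_dataset([rec("CC", {"V03AX"})])
        assert removed == []
        assert len(kept) == 1

    def test_mixed_codes_keep_compound_with_v_codes_dropped(self):
        out = filter_dataset([rec("CC", {"V08AB", "A02BC"})])
        assert len(out) == 1
        assert out[0].code_strings() == {"A02BC"}

    def test_molecular_weight_cutoff_is_inclusive(self):
        assert filter_dataset([rec("CC", {"A02BC"}, mw=901)]) == []
        assert len(filter_dataset([rec("CC", {"A02BC"}, mw=900)])) == 1
        # no recorded weight: the cutoff does not apply
        assert len(filter_dataset([rec("CC", {"A02BC"})])) == 1

    def test_multicomponent_and_missing_fields_removed(self):
        records = [
            rec("CC.CC", {"A02BC"}),
            CompoundRecord("y", "", frozenset({AtcCode("A02BC")})),
            CompoundRecord("z", "CC", frozenset()),
        ]
        assert filter_dataset(records) == []


class TestMergeSources:
    def test_shared_smiles_union_codes(self):
        a = [rec("CCO", {"A02BC"}, cid="a")]
        b = [rec("CCO", {"C07AB"}, cid="b")]
        merged = merge_sources([a, b])
        assert len(merged) == 1
        assert merged[0].code_strings() == {"A02BC", "C07AB"}

    def test_disjoint_sources_concatenate(self):
        merged = merge_sources([[rec("CCO", {"A02BC"})], [rec("CCN", {"B01AC"})]])
        assert len(merged) == 2

    def test_idempotent_on_identical_records(self):
        a = [rec("CCO", {"A02BC"})]
        merged = merge_sources([a, a])
        assert len(merged) == 1
        assert merged[0].code_strings() == {"A02BC"}

    def test_output_smiles_unique_and_codes_conserved(self):
        rng = np.random.default_rng(0)
        pool = ["CCO", "CCN", "CCC", "c1ccccc1"]
        codes = ["A02BC", "B01AC", "C07AB", "D01AE"]
        lists = [
            [rec(rng.choice(pool), {rng.choice(codes)}, cid=f"c{i}{j}") for j in range(5)]
            for i in range(3)
        ]
        merged = merge_sources(lists)
        smiles = [r.smiles for r in merged]
        assert len(smiles) == len(set(smiles))
        all_in = {(r.smiles, c) for lst in lists for r in lst for c in r.code_strings()}
        all_out = {(r.smiles, c) for r in merged for c in r.code_strings()}
        assert all_in == all_out


class TestDescriptors:
    def test_rows_deterministic_and_weight_positive(self):
        m = compute_descriptors(["CCO", "CCO"])
        assert np.array_equal(m.values[0], m.values[1], equal_nan=True)
        wt = m.values[0][m.names.index("MolWt")]
        assert np.isfinite(wt) and wt > 0

    def test_empty_input_keeps_name_list(self):
        m = compute_descriptors([])
        assert m.values.shape == (0, len(m.names))
        assert len(m.names) > 100

    def test_prune_drops_constant_and_collinear_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        values = np.column_stack([x, 2 * x, np.ones(50), rng.normal(size=50)])
        m = DescriptorMatrix(names=list("abcd"), values=values)
        pruned = prune_descriptors(m, corr_threshold=0.95)
        assert list(pruned.kept_mask) == [True, False, False, True]

    def test_prune_keeps_independent_columns(self):
        rng = np.random.default_rng(1)
        m = DescriptorMatrix(
            names=[f"d{i}" for i in range(10)], values=rng.normal(size=(100, 10))
        )
        pruned = prune_descriptors(m, corr_threshold=0.95)
        assert pruned.kept_mask.all()
        kept = pruned.kept_values()
        corr = np.abs(np.corrcoef(kept.T) - np.eye(kept.shape[1]))
        assert corr.max() <= 0.95

    def test_prune_rejects_bad_threshold(self):
        m = DescriptorMatrix(names=["a"], values=np.zeros((3, 1)))
        with pytest.raises(ValueError):
            prune_descriptors(m, corr_threshold=1.5)

    def test_standardization_closed_form_and_imputation(self):
        values = np.array([[1.0, 5.0], [2.0, np.nan], [3.0, 5.0]])
        m = DescriptorMatrix(names=["a", "b"], values=values)
        out = fit_apply_standardization(m, [0, 1, 2])
        np.testing.assert_allclose(
            out.values[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4
        )
        # column b: NaN imputed with median 5 -> zero variance -> all zeros
        np.testing.assert_allclose(out.values[:, 1], [0.0, 0.0, 0.0])
        assert np.isfinite(out.values).all()

    def test_statistics_fit_only_on_training_rows(self):
        values = np.array([[0.0], [2.0], [100.0]])
        m = DescriptorMatrix(names=["a"], values=values)
        out = fit_apply_standardization(m, [0, 1])  # row 2 excluded from fit
        np.testing.assert_allclose(out.values[:2, 0], [-1.0, 1.0])
        assert out.values[2, 0] == pytest.approx(99.0)


class TestTokenization:
    def test_code_string_tokenizes_character_wise(self):
        vocab = build_vocab(["A02BC"])
        ids = tokenize("A02BC", vocab)
        assert ids[0] == START_IDX and ids[-1] == END_IDX
        assert len(ids) == 7
        assert detokenize(ids, vocab) == "A02BC"

    def test_empty_string_wraps_only_specials(self):
        vocab = build_vocab(["AB"])
        assert tokenize("", vocab) == [START_IDX, END_IDX]

    def test_two_letter_element_splits_into_two_tokens(self):
        vocab = build_vocab(["ClC"])
        ids = tokenize("ClC", vocab)
        assert len(ids) == 5  # start, C, l, C, end

    def test_unknown_characters_map_to_unk(self):
        vocab = build_vocab(["AB"])
        from atcgen.tokenizer import UNK_IDX

        assert tokenize("AZB", vocab)[2] == UNK_IDX

    @given(st.text(alphabet="CNOPSclBr=#()[]123", max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_over_known_alphabet(self, s):
        vocab = build_vocab(["CNOPSclBr=#()[]123"])
        assert detokenize(tokenize(s, vocab), vocab) == s

    def test_vocabulary_json_round_trip(self, tmp_path):
        vocab = build_vocab(["A02BC", "B01AC"])
        path = tmp_path / "vocab.json"
        vocab.save(path)
        loaded = TokenVocabulary.load(path)
        assert loaded.token_to_index == vocab.token_to_index
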
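"""Consensus nsSNP screen: cutoffs, missing-value policy, agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vardyn.errors import ScoreTableError
from vardyn.screen import (
    CutoffTable, TOOLS, VariantRecord, apply_cutoffs, consensus,
    load_packaged_table, parse_substitution, read_score_table,
    tool_agreement_matrix,
)
from vardyn.synthetic import ScoreTableSpec, generate_score_table


@pytest.fixture(scope="module")
def packaged_records():
    return read_score_table(load_packaged_table())


def _record(scores, rs_id="rs1", substitution="G1050V"):
    base = {c: None for c in (
        "SIFT", "PolyPhen2_HumDiv", "PolyPhen2_HumVar", "MAPP", "PANTHER",
        "SNP_GO", "PhD_SNP", "PredictSNP", "PROVEAN", "I_Mutant3",
    )}
    base.update(scores)
    wild, pos, mutant = parse_substitution(substitution)
    return VariantRecord(rs_id, substitution, wild, pos, mutant, base)


class TestParseSubstitution:
    @pytest.mark.parametrize("text,expected", [
        ("G1050V", ("G", 1050, "V")),
        ("S1067C", ("S", 1067, "C")),
        ("s741c", ("S", 741, "C")),
    ])
    def test_valid_forms(self, text, expected):
        assert parse_substitution(text) == expected

    @pytest.mark.parametrize("text", ["G1050G", "X10V", "G10", "1050V", ""])
    def test_invalid_forms_rejected(self, text):
        with pytest.raises(ScoreTableError):
            parse_substitution(text)

    @given(
        wild=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        pos=st.integers(1, 99999),
        mutant=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    )
    def test_roundtrip_of_valid_substitutions(self, wild, pos, mutant):
        text = f"{wild}{pos}{mutant}"
        if wild == mutant:
            with pytest.raises(ScoreTableError):
                parse_substitution(text)
        else:
            assert parse_substitution(text) == (wild, pos, mutant)


class TestCutoffs:
    def test_published_rows_counted_as_printed(self, packaged_records):
        by_sub = {r.substitution: r for r in packaged_records}
        expectations = {
            "S741C": (8, 1),   # MAPP missing
            "Y793C": (7, 2),   # MAPP and SNP&GO missing
            "G1050V": (7, 2),
            "S1067C": (7, 2),
        }
        for sub, (n_del, n_nc) in expectations.items():
            calls = apply_cutoffs(by_sub[sub])
            assert sum(c == "deleterious" for c in calls.values()) == n_del
            assert sum(c == "no_call" for c in calls.values()) == n_nc

    def test_sift_boundary_inclusive(self):
        calls = apply_cutoffs(_record({"SIFT": "0.050"}))
        assert calls["SIFT"] == "deleterious"
        assert apply_cutoffs(_record({"SIFT": "0.051"}))["SIFT"] == "neutral"

    def test_imutant_boundary_exclusive(self):
        assert apply_cutoffs(_record({"I_Mutant3": "-0.5"}))["I_Mutant3"] == "neutral"
        assert apply_cutoffs(_record({"I_Mutant3": "-0.51"}))["I_Mutant3"] == "deleterious"

    def test_polyphen_requires_both_models(self):
        both = _record({"PolyPhen2_HumDiv": "0.95", "PolyPhen2_HumVar": "0.95"})
        assert apply_cutoffs(both)["PolyPhen2"] == "deleterious"
        one_low = _record({"PolyPhen2_HumDiv": "0.95",
                           "PolyPhen2_HumVar": "0.85"})
        assert apply_cutoffs(one_low)["PolyPhen2"] == "neutral"
        one_missing = _record({"PolyPhen2_HumDiv": "0.95"})
        assert apply_cutoffs(one_missing)["PolyPhen2"] == "no_call"

    def test_categorical_tools_accept_labels_and_scores(self):
        assert apply_cutoffs(_record({"PredictSNP": "D"}))["PredictSNP"] == "deleterious"
        assert apply_cutoffs(_record({"PredictSNP": "N"}))["PredictSNP"] == "neutral"
        assert apply_cutoffs(_record({"MAPP": "0.7"}))["MAPP"] == "deleterious"

    def test_non_numeric_cell_names_tool(self):
        with pytest.raises(ScoreTableError, match="SIFT"):
            apply_cutoffs(_record({"SIFT": "high"}))

    def test_missing_cells_are_no_calls_everywhere(self):
        calls = apply_cutoffs(_record({}))
        assert set(calls.values()) == {"no_call"}


class TestConsensus:
    def test_packaged_table_flags_the_four_variants(self, packaged_records):
        table = consensus(packaged_records, min_tools=7)
        flagged = table[table.is_consensus_deleterious]
        assert sorted(flagged.substitution) == ["G1050V", "S1067C", "S741C",
                                                "Y793C"]
        assert flagged.n_deleterious.min() == 7
        # sorted by support: S741C (8 tools) first
        assert table.iloc[0].substitution == "S741C"

    def test_nine_tool_requirement_cannot_be_met_with_missing_cells(
        self, packaged_records
    ):
        table = consensus(packaged_records, min_tools=9)
        assert not table.is_consensus_deleterious.any()

    def test_empty_score_row_is_not_flagged(self):
        table = consensus([_record({})])
        assert table.n_deleterious.tolist() == [0]
        assert not table.is_consensus_deleterious.any()

    def test_counts_monotone_under_threshold_tightening(self):
        df = generate_score_table(ScoreTableSpec(
            n_variants=120, planted_deleterious=frozenset(range(40)),
            missing_rate=0.1, pass_probability=0.7,
            neutral_pass_probability=0.3, seed=13,
        ))
        records = read_score_table(df)
        previous = None
        for sift_max in (0.2, 0.1, 0.05, 0.02, 0.01):
            cutoffs = CutoffTable(sift_max=sift_max)
            totals = (consensus(records, cutoffs)
                      .sort_values("rs_id").n_deleterious.to_numpy())
            if previous is not None:
                assert np.all(totals <= previous)
            previous = totals

    def test_no_call_column_never_counts(self):
        rec_full = _record({"SIFT": "0.01", "PROVEAN": "-5"})
        rec_extra_missing = _record({"SIFT": "0.01", "PROVEAN": "-5",
                                     "MAPP": None})
        t1 = consensus([rec_full]).n_deleterious
        t2 = consensus([rec_extra_missing]).n_deleterious
        assert t1.tolist() == t2.tolist() == [2]


class TestAgreement:
    def test_identical_tools_have_phi_one(self):
        df = generate_score_table(ScoreTableSpec(
            n_variants=50, planted_deleterious=frozenset(range(25)),
            missing_rate=0.0, pass_probability=1.0,
            neutral_pass_probability=0.0, seed=1,
        ))
        phi, undefined = tool_agreement_matrix(read_score_table(df))
        # perfectly planted table: every tool call matches every other
        assert np.allclose(phi.to_numpy(), 1.0)
        assert not undefined.to_numpy().any()

    def test_independent_tools_have_small_phi(self):
        df = generate_score_table(ScoreTableSpec(
            n_variants=500, planted_deleterious=frozenset(),
            missing_rate=0.0, pass_probability=0.5,
            neutral_pass_probability=0.5, seed=2,
        ))
        phi, _ = tool_agreement_matrix(read_score_table(df))
        off = phi.to_numpy()[~np.eye(len(TOOLS), dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.15

    def test_matrix_symmetric_with_unit_diagonal(self, packaged_records):
        phi, _ = tool_agreement_matrix(packaged_records)
        m = phi.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)

    def test_constant_tool_is_flagged_undefined(self, packaged_records):
        # PredictSNP is 'D' in every packaged row -> no variance
        _, undefined = tool_agreement_matrix(packaged_records)
        assert undefined.loc["PredictSNP", "SIFT"]


class TestReading:
    def test_unicode_minus_and_dash_missing(self, tmp_path):
        path = tmp_path / "scores.csv"
        path.write_text(
            "rs_id,substitution,SIFT,PolyPhen2_HumDiv,PolyPhen2_HumVar,"
            "MAPP,PANTHER,SNP_GO,PhD_SNP,PredictSNP,PROVEAN,I_Mutant3\n"
            "rs1,G1050V,0,1,0.999,-,0.568,-,0.733,D,−6.192,−0.58\n"
        )
        rec = read_score_table(path)[0]
        calls = apply_cutoffs(rec)
        assert calls["PROVEAN"] == "deleterious"
        assert calls["MAPP"] == "no_call"

    def test_empty_table_rejected(self):
        with pytest.raises(ScoreTableError):
            read_score_table(pd.DataFrame(columns=["substitution"]))
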
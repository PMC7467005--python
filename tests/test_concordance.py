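import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from karyotag.cohort_data import (
    CLASS_TABLES,
    N_ASSAYED,
    PARITY,
    calls_from_class_tables,
    parity_table,
)
from karyotag.concordance import (
    AgreementCategory,
    ConcordanceError,
    class_contingency,
    classify,
    classify_calls,
    contingency_to_frame,
    fisher_exact_2x2,
    load_triplicate_calls,
    parity_test,
    render_heatmap,
    round_half_up,
    save_triplicate_calls,
    summarize,
)


def make_calls(rows):
    """rows: (specimen_id, numeric_code, inversion, cyt, oa, gt)"""
    return pd.DataFrame(
        [
            {
                "specimen_id": s, "species": None, "numeric_code": c,
                "inversion_id": inv,
                "cyt": np.nan if cyt is None else float(cyt),
                "oa": np.nan if oa is None else float(oa),
                "gt": np.nan if gt is None else float(gt),
            }
            for s, c, inv, cyt, oa, gt in rows
        ]
    )


class TestClassify:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((2, 2, 2), AgreementCategory.ALL_AGREE),
            ((1, 2, 2), AgreementCategory.MOL_AGREE_CYT_DIFF),
            ((0, 1, 0), AgreementCategory.CYT_GT_AGREE_OA_DIFF),
            ((0, 0, 1), AgreementCategory.CYT_OA_AGREE_GT_DIFF),
            ((0, 1, 2), AgreementCategory.ALL_DIFFER),
            ((0, None, 0), AgreementCategory.INCOMPLETE),
            ((None, None, None), AgreementCategory.INCOMPLETE),
        ],
    )
    def test_examples(self, triple, expected):
        assert classify(*triple) == expected

    def test_out_of_domain_rejected(self):
        with pytest.raises(ConcordanceError):
            classify(3, 0, 0)
        with pytest.raises(ConcordanceError):
            classify(0, 0.5, 0)

    @given(
        st.sampled_from([0, 1, 2, None]),
        st.sampled_from([0, 1, 2, None]),
        st.sampled_from([0, 1, 2, None]),
    )
    def test_symmetric_in_molecular_methods(self, cyt, oa, gt):
        swap = {
            AgreementCategory.CYT_GT_AGREE_OA_DIFF:
                AgreementCategory.CYT_OA_AGREE_GT_DIFF,
            AgreementCategory.CYT_OA_AGREE_GT_DIFF:
                AgreementCategory.CYT_GT_AGREE_OA_DIFF,
        }
        a, b = classify(cyt, oa, gt), classify(cyt, gt, oa)
        assert b == swap.get(a, a)


class TestSummarize:
    def test_published_2la_block_reproduces_summary_counts(self):
        """Expanding the published genotype-class tables reproduces the
        published agreement summary: 875 (92.30%) three-way agreement and 73
        (7.70%) cytogenetic-vs-molecular discordances for 2La over 948."""
        calls = calls_from_class_tables(CLASS_TABLES, N_ASSAYED)
        table = summarize(calls).set_index(["inversion_id", "category"])
        agree = table.loc[("2La", "three_way_agree")]
        disc = table.loc[("2La", "cyt_vs_molecular")]
        assert (agree["count"], agree["percent"]) == (875, 92.30)
        assert (disc["count"], disc["percent"]) == (73, 7.70)
        assert agree["n_assayed"] == 948

    def test_single_concordant_specimen(self):
        table = summarize(make_calls([("s1", 1, "2La", 1, 1, 1)]))
        row = table.set_index("category").loc["three_way_agree"]
        assert row["count"] == 1 and row["percent"] == 100.00

    def test_all_incomplete_gives_zero_denominator_row(self):
        table = summarize(make_calls([("s1", 1, "2La", 1, None, 1)] * 3))
        assert (table["n_assayed"] == 0).all()
        assert table["percent"].isna().all()
        assert (table.loc[0, "n_incomplete"]) == 3

    def test_category_counts_sum_to_n_assayed(self):
        calls = calls_from_class_tables(CLASS_TABLES, N_ASSAYED)
        table = summarize(calls)
        sums = table.groupby("inversion_id")["count"].sum()
        ns = table.groupby("inversion_id")["n_assayed"].first()
        assert (sums == ns).all()

    def test_half_up_rounding(self):
        assert round_half_up(7.695) == 7.70
        assert round_half_up(92.295) == 92.30
        assert round_half_up(0.125) == 0.13


class TestClassContingency:
    def test_published_2la_block_round_trips(self):
        calls = calls_from_class_tables(CLASS_TABLES, N_ASSAYED)
        tables = class_contingency(calls)
        t = tables["2La"]
        assert np.trace(t) == 875
        assert t.sum() - np.trace(t) == 73
        np.testing.assert_array_equal(t, CLASS_TABLES["2La"])

    def test_all_concordant_toy_set_is_diagonal(self):
        calls = make_calls(
            [("s1", 1, "2Rb", 0, 0, 0), ("s2", 2, "2Rb", 1, 1, 1),
             ("s3", 3, "2Rb", 2, 2, 2), ("s4", 4, "2Rb", 1, 1, 1)]
        )
        t = class_contingency(calls)["2Rb"]
        assert np.all(t == np.diag([1, 2, 1]))

    def test_molecular_disagreements_excluded(self):
        calls = make_calls(
            [("s1", 1, "2Rb", 0, 1, 0),  # cyt+gt vs oa: excluded
             ("s2", 2, "2Rb", 2, 2, 2)]
        )
        t = class_contingency(calls)["2Rb"]
        assert t.sum() == 1 and t[2, 2] == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_cross_table_identity_on_random_call_sets(self, seed):
        """diagonal = three-way count; off-diagonal = cyt-vs-molecular count;
        total = n_assayed minus the molecular-disagreement categories."""
        rng = np.random.default_rng(seed)
        n = 60
        vals = rng.choice([0, 1, 2, None], size=(n, 3), p=[0.4, 0.3, 0.2, 0.1])
        calls = make_calls(
            [(f"s{i}", i + 1, "2La", *vals[i]) for i in range(n)]
        )
        table = summarize(calls).set_index("category")
        t = class_contingency(calls).get("2La", np.zeros((3, 3), dtype=int))
        assert np.trace(t) == table.loc["three_way_agree", "count"]
        assert t.sum() - np.trace(t) == table.loc["cyt_vs_molecular", "count"]
        others = (
            table.loc["cyt_gt_vs_oa", "count"]
            + table.loc["cyt_oa_vs_gt", "count"]
            + table.loc["three_way_differ", "count"]
        )
        assert t.sum() == table.loc["three_way_agree", "n_assayed"] - others

    def test_published_2rb_subtraction_identity(self):
        """The published cohort satisfies 948 - 905 = 43 molecular
        disagreements for 2Rb."""
        t = CLASS_TABLES["2Rb"]
        assert N_ASSAYED["2Rb"] - t.sum() == 43

    def test_contingency_frame_layout(self):
        frame = contingency_to_frame(class_contingency(
            calls_from_class_tables(CLASS_TABLES, N_ASSAYED)))
        assert len(frame) == 3 * len(CLASS_TABLES)
        assert set(frame.columns) == {"inversion_id", "cyt", "mol_0", "mol_1", "mol_2"}


def fisher_oracle(table):
    """Full enumeration of the hypergeometric null over all tables with the
    observed margins (independent of the implementation under test)."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c

    def point(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    observed = point(a)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= observed * (1 + 1e-7))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),
            ([[10, 0], [0, 10]], 2 / math.comb(20, 10)),
        ],
    )
    def test_derived_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-9)

    def test_negative_entry_rejected(self):
        with pytest.raises(ConcordanceError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 12, size=(2, 2))
        p = fisher_exact_2x2(t)
        if t.sum() and t.sum(axis=0).min() and t.sum(axis=1).min():
            assert p == pytest.approx(fisher_oracle(t), rel=1e-9)
        assert 0 < p <= 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_transpose_invariant_and_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 25, size=(2, 2))
        p = fisher_exact_2x2(t)
        assert p == pytest.approx(fisher_exact_2x2(t.T), rel=1e-12)
        assert p == pytest.approx(
            stats.fisher_exact(t, alternative="two-sided")[1], rel=1e-6, abs=1e-12
        )


class TestParityTest:
    def test_published_margins_build_expected_table(self):
        """280 odd / 677 even specimens with 169 of 170 discordances in the
        even half yields the 2x2 [[1, 279], [169, 508]] and a vanishingly
        small Fisher p."""
        t = parity_table()
        np.testing.assert_array_equal(t, [[1, 279], [169, 508]])
        p = fisher_exact_2x2(t)
        assert p == pytest.approx(fisher_oracle(t), rel=1e-6)
        assert p < 1e-20

    def test_balanced_table_is_null(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_even_only_discordances_detected(self):
        rows = []
        for i in range(1, 201):
            cat_disc = i % 2 == 0 and i <= 80  # discordances only in evens
            rows.append(
                ("s%d" % i, i, "2La", 0 if not cat_disc else 1, 0, 0)
            )
        pt = parity_test(make_calls(rows))
        np.testing.assert_array_equal(pt.table, [[0, 100], [40, 60]])
        assert pt.n_discordant == 40 and pt.n_even_discordant == 40
        assert pt.fisher_p < 1e-9
        assert pt.chi2_p < 1e-9
        assert pt.chi2_yates < pt.chi2  # continuity correction shrinks chi2

    def test_zero_discordances_degenerate(self):
        rows = [("s%d" % i, i, "2La", 1, 1, 1) for i in range(1, 21)]
        with pytest.warns(UserWarning, match="degenerate"):
            pt = parity_test(make_calls(rows))
        assert pt.fisher_p == 1.0 and pt.chi2_p == 1.0

    def test_specimen_unit_collapses_multiple_inversions(self):
        rows = [
            ("s1", 1, "2La", 1, 0, 0), ("s1", 1, "2Rb", 0, 0, 0),
            ("s2", 2, "2La", 0, 0, 0), ("s2", 2, "2Rb", 0, 0, 0),
        ]
        pt = parity_test(make_calls(rows), unit="specimen")
        assert pt.table.sum() == 2  # one row per specimen
        assert pt.n_discordant == 1

    def test_empty_selection_rejected(self):
        with pytest.raises(ConcordanceError):
            parity_test(make_calls([("s1", 1, "2La", 1, 1, 1)]),
                        inversions=["2Ru"])


class TestIO:
    def test_triplicate_csv_round_trip(self, tmp_path):
        calls = make_calls(
            [("s1", 1, "2La", 0, 1, None), ("s2", 2, "2Rb", 2, 2, 2)]
        )
        path = tmp_path / "calls.csv"
        save_triplicate_calls(calls, path)
        again = load_triplicate_calls(path)
        assert list(again.columns[:4]) == list(calls.columns[:4])
        assert again["cyt"].tolist() == [0.0, 2.0]
        assert np.isnan(again["gt"].iloc[0])

    def test_heatmap_written(self, tmp_path):
        rows = [(f"s{i}", i, inv, 1, 1, 1) for i in range(1, 11)
                for inv in ("2La", "2Rb")]
        out = tmp_path / "heat.png"
        render_heatmap(make_calls(rows), out)
        assert out.stat().st_size > 0

    def test_heatmap_empty_input_rejected(self, tmp_path):
        with pytest.raises(ConcordanceError):
            render_heatmap(make_calls([]), tmp_path / "x.png")
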
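import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaps import (PipelineConfig, bh_fdr, induction_fc,
                   promoter_strength_diff, ranksum_p, screen_recurrent,
                   simulate_screen, wilcoxon_case)
from cnaps.expr_assoc import ExpressionMatrix, fisher_table_from_flags
from cnaps.segio import DataError
from conftest import make_expression
from oracles import bh_oracle, fisher_exact_oracle, ranksum_exact_oracle


def flat_expression(gene_values: dict, n_samples=6, cancer_type="CT"):
    """Every sample of the cancer type shares each gene's value."""
    samples = [f"S{i}" for i in range(n_samples)]
    data = {g: {s: v for s in samples} for g, v in gene_values.items()}
    return make_expression(data, {s: cancer_type for s in samples})


class TestPromoterStrength:
    def test_equal_medians_give_zero(self):
        expr = flat_expression({"A": 10.0, "B": 10.0})
        assert promoter_strength_diff("A", "B", "CT", expr) == 0.0

    def test_log2_median_difference(self):
        expr = flat_expression({"A": 31.0, "B": 7.0})
        assert promoter_strength_diff("A", "B", "CT", expr) \
            == pytest.approx(2.0)

    def test_two_fold_gate_is_one_in_log2(self, cfg):
        assert math.log2(cfg.stronger_promoter_fold) == 1.0

    def test_affected_samples_excluded_from_baseline(self):
        data = {"A": {"S0": 100.0, "S1": 100.0, "S2": 100.0},
                "B": {"S0": 999.0, "S1": 7.0, "S2": 7.0}}
        expr = make_expression(data, {s: "CT" for s in data["A"]})
        # S0 carries the event: its inflated B value must not raise median3
        d = promoter_strength_diff("A", "B", "CT", expr, affected=["S0"])
        assert d == pytest.approx(math.log2(101) - math.log2(8))

    def test_no_unaffected_samples_rejected(self):
        expr = flat_expression({"A": 1.0, "B": 1.0}, n_samples=2)
        with pytest.raises(DataError):
            promoter_strength_diff("A", "B", "CT", expr,
                                   affected=["S0", "S1"])


class TestInduction:
    def test_affected_at_median_is_zero(self):
        expr = flat_expression({"B": 12.0})
        assert induction_fc("B", ["S0"], "CT", expr) == pytest.approx([0.0])

    def test_eightfold_at_large_values(self):
        data = {"B": {"S0": 8000.0, "S1": 1000.0, "S2": 1000.0,
                      "S3": 1000.0}}
        expr = make_expression(data, {s: "CT" for s in data["B"]})
        (val,) = induction_fc("B", ["S0"], "CT", expr)
        assert val == pytest.approx(3.0, abs=0.01)

    def test_pseudocount_with_zero_median(self):
        data = {"B": {"S0": 7.0, "S1": 0.0, "S2": 0.0, "S3": 0.0}}
        expr = make_expression(data, {s: "CT" for s in data["B"]})
        (val,) = induction_fc("B", ["S0"], "CT", expr)
        assert val == pytest.approx(3.0)

    def test_monotone_in_affected_expression(self):
        base = {"B": {"S0": 100.0, "S1": 10.0, "S2": 10.0}}
        labels = {s: "CT" for s in base["B"]}
        lo = induction_fc("B", ["S0"], "CT", make_expression(base, labels))
        base["B"]["S0"] = 200.0
        hi = induction_fc("B", ["S0"], "CT", make_expression(base, labels))
        assert hi[0] > lo[0]


class TestFisher:
    def test_balanced_table_p_one(self):
        stronger = [True] * 10 + [False] * 10
        induced = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        ft = fisher_table_from_flags(stronger, induced)
        assert ft.p_value == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self):
        flags = np.array([True] * 10 + [False] * 10)
        ft = fisher_table_from_flags(flags, flags)
        expected = 2 / math.comb(20, 10)
        assert ft.p_value == pytest.approx(expected, rel=1e-9)
        assert ft.p_value == pytest.approx(
            fisher_exact_oracle(ft.table), rel=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            stronger = rng.random(30) < 0.5
            induced = rng.random(30) < 0.5
            ft = fisher_table_from_flags(stronger, induced)
            if not math.isnan(ft.odds_ratio):
                assert ft.p_value == pytest.approx(
                    fisher_exact_oracle(ft.table), rel=1e-9)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ft = fisher_table_from_flags([True, True], [True, False])
        assert ft.p_value == 1.0


class TestRankSum:
    def test_exact_small_sample(self):
        assert ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(
            ranksum_exact_oracle([1, 2, 3], [4, 5, 6]))

    def test_exact_matches_enumeration_random(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pooled = rng.permutation(rng.normal(size=9))
            x, y = pooled[:4], pooled[4:]
            assert ranksum_p(x, y) == pytest.approx(
                ranksum_exact_oracle(list(x), list(y)), rel=1e-9)

    def test_all_tied_gives_one(self):
        assert ranksum_p([5, 5], [5, 5, 5]) == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5, 0.5, size=5)
        y = rng.normal(0, 0.5, size=100)
        assert ranksum_p(x, y) < 0.01

    def test_wilcoxon_case_on_matrix(self):
        data = {"B": {f"S{i}": float(v) for i, v in
                      enumerate([1, 2, 3, 4, 5, 6])}}
        expr = make_expression(data, {f"S{i}": "CT" for i in range(6)})
        # affected {S3,S4,S5} hold the linear values {4,5,6}
        p = wilcoxon_case("B", ["S3", "S4", "S5"], "CT", expr)
        assert p == pytest.approx(0.1)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_keep_value(self):
        assert bh_fdr([0.05] * 10) == pytest.approx([0.05] * 10)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_hand_step_up_and_monotone_on_sorted(self, ps):
        q = bh_fdr(ps)
        assert q == pytest.approx(bh_oracle(ps))
        q_sorted = bh_fdr(sorted(ps))
        assert all(a <= b + 1e-12 for a, b in zip(q_sorted, q_sorted[1:]))


class TestScreen:
    def test_affected_identical_to_unaffected_not_significant(self):
        expr = flat_expression({"A": 100.0, "B": 10.0}, n_samples=8)
        events = pd.DataFrame([
            {"sample": s, "cancer_type": "CT", "gene5": "A", "gene3": "B",
             "pair": "A::B"} for s in ("S0", "S1", "S2")])
        out = screen_recurrent(events, expr)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["degenerate"] and row["p_value"] == 1.0
        assert not row["significant"]
        assert row["mean_induction"] == pytest.approx(0.0)

    def test_weak_promoter_pairs_not_candidates(self):
        expr = flat_expression({"A": 10.0, "B": 10.0}, n_samples=8)
        events = pd.DataFrame([
            {"sample": s, "cancer_type": "CT", "gene5": "A", "gene3": "B",
             "pair": "A::B"} for s in ("S0", "S1")])
        assert screen_recurrent(events, expr).empty

    def test_planted_induction_detected(self):
        events, expr, induced = simulate_screen(seed=42)
        out = screen_recurrent(events, expr)
        hit = out[out["pair"] == induced[0]]
        assert len(hit) == 1 and bool(hit["significant"].iloc[0])
        assert hit["q_value"].iloc[0] <= 0.1
        assert hit["mean_induction"].iloc[0] == pytest.approx(3.0, abs=1.0)

    def test_invariant_to_sample_and_gene_order(self):
        events, expr, _ = simulate_screen(seed=43, n_candidates=10)
        rng = np.random.default_rng(0)
        shuffled = ExpressionMatrix(
            expr.values.sample(frac=1, random_state=1)[
                rng.permutation(expr.values.columns)],
            expr.labels)
        a = screen_recurrent(events, expr).reset_index(drop=True)
        b = screen_recurrent(events, shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_gene_excluded(self):
        events, expr, _ = simulate_screen(seed=44, n_candidates=5)
        trimmed = ExpressionMatrix(expr.values.drop(index=["P3_002"]),
                                   expr.labels)
        out = screen_recurrent(events, trimmed)
        assert "P5_002::P3_002" not in set(out["pair"])
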
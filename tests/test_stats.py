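"""Frequency statistics: crosstabs, exact and permutation tests, trends."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import hypergeom

from mitocline import (
    FreqTestResult,
    HgCall,
    bonferroni,
    compare_groups,
    crosstab,
    fisher_exact_2x2,
    percentages,
    permutation_fisher,
    simulate_cohort,
    trend_slope,
    yearly_trend,
)
from mitocline.danish_cohort import (
    MACRO_COUNTS,
    PERIOD_COUNTS,
    PERIOD_TOTALS,
    R_HG_COUNTS,
    SUBHG_COUNTS,
)
from mitocline.simulate import denmark_model, true_calls
from mitocline.stats import _log_table_prob


def _expand(counts_by_label, level="macro"):
    """Counts -> (HgCall list, metadata) with a single group."""
    calls, i = [], 0
    for label, n in counts_by_label.items():
        for _ in range(n):
            call = HgCall(sample_id=f"s{i}", status="full")
            if level == "macro":
                call.macro_hg = label
            elif level == "hg":
                call.macro_hg = "R"
                call.hg = label
            else:
                call.macro_hg, call.hg, call.sub_hg = "R", "H", label
            calls.append(call)
            i += 1
    meta = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "birth_year": 1990,
            "region": "Capital",
            "metro": False,
        }
    )
    return calls, meta


class TestCrosstab:
    def test_macro_percentages_match_published_table(self):
        calls, meta = _expand(MACRO_COUNTS)
        table = crosstab(calls, meta, grouping="region", level="macro")
        pct = percentages(table)
        assert pct.loc["Capital", "L0"] == 0.1
        assert pct.loc["Capital", "R"] == 90.6
        assert pct.loc["Capital", "N"] == 7.0
        assert table.loc["Capital"].sum() == 24216

    def test_hg_percentages_within_r(self):
        calls, meta = _expand(R_HG_COUNTS, level="hg")
        pct = percentages(crosstab(calls, meta, grouping="region", level="hg"))
        assert pct.loc["Capital", "H"] == 50.0

    def test_subhg_bin_percentages(self):
        calls, meta = _expand(SUBHG_COUNTS["H"], level="subhg")
        pct = percentages(crosstab(calls, meta, grouping="region", level="subhg"))
        assert pct.loc["Capital", "H1-H30b-H79a"] == 37.6

    def test_empty_input_gives_empty_table(self):
        assert crosstab([], pd.DataFrame()).empty

    def test_sample_without_metadata_is_an_error(self):
        calls, meta = _expand({"R": 2})
        with pytest.raises(ValueError, match="s1"):
            crosstab(calls, meta.iloc[:1], grouping="region")

    def test_row_percentages_sum_to_100(self, tree_and_panel, model):
        tree, _ = tree_and_panel
        cohort = simulate_cohort(model, tree, 3000, seed=13)
        calls = true_calls(cohort, tree)
        pct = percentages(crosstab(calls, cohort, grouping="region"), decimals=1)
        assert (np.abs(pct.sum(axis=1) - 100.0) <= 0.2 + 1e-9).all()

    def test_period_binning_drops_out_of_bin_years(self, tree_and_panel, model):
        tree, _ = tree_and_panel
        cohort = simulate_cohort(model, tree, 2000, seed=14)
        calls = true_calls(cohort, tree)
        bins = [(1981, 1986), (2000, 2005)]
        table = crosstab(calls, cohort, grouping="period", bins=bins)
        in_bins = cohort["birth_year"].between(1981, 1986) | cohort[
            "birth_year"
        ].between(2000, 2005)
        assert table.to_numpy().sum() == int(in_bins.sum())
        assert list(table.index) == ["1981-1986", "2000-2005"]


def brute_force_two_sided_p(a, b, c, d):
    """Exhaustive hypergeometric oracle: sum P(T) over all tables with the
    observed margins whose probability does not exceed the observed one."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    p_obs = hypergeom(n, row1, col1).pmf(a)
    total = 0.0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        pk = hypergeom(n, row1, col1).pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestFisher:
    @pytest.mark.parametrize(
        "hg, printed",
        [("L", 1.14e-10), ("M", 3.73e-08), ("H", 2.98e-03), ("J", 0.53)],
    )
    def test_reproduces_published_period_p_values(self, hg, printed):
        n1, n2 = PERIOD_TOTALS
        a, c = PERIOD_COUNTS[hg]
        p = fisher_exact_2x2(a, n1 - a, c, n2 - c)
        assert p == pytest.approx(printed, rel=5e-3)

    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 9, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                brute_force_two_sided_p(a, b, c, d), rel=1e-9
            )

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-8
            )

    def test_symmetric_under_row_and_column_swaps(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 25, size=4)
            p = fisher_exact_2x2(a, b, c, d)
            assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-10)
            assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, rel=1e-10)

    def test_all_zero_table_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


def brute_force_rxc_p(table):
    """Exact r x c p by enumerating all tables with the observed margins."""
    table = np.asarray(table)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    obs = _log_table_prob(table)

    def gen(remaining_rows, col_left):
        if len(remaining_rows) == 1:
            if all(x >= 0 for x in col_left):
                yield [list(col_left)]
            return
        r = remaining_rows[0]
        ranges = [range(0, min(r, c) + 1) for c in col_left]
        for cells in product(*ranges):
            if sum(cells) != r:
                continue
            rest = tuple(c - x for c, x in zip(col_left, cells))
            for tail in gen(remaining_rows[1:], rest):
                yield [list(cells)] + tail

    total = 0.0
    for t in gen(list(rows), tuple(cols)):
        t = np.array(t)
        lp = _log_table_prob(t)
        if lp <= obs + 1e-9:
            total += np.exp(lp)
    return min(total, 1.0)


class TestPermutation:
    def test_2x2_delegates_to_exact(self):
        res = permutation_fisher(np.array([[8, 4562], [67, 5468]]), seed=3)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.14e-10, rel=5e-3)

    def test_null_table_gives_large_p(self):
        t = np.array([[50, 50], [100, 100], [20, 20]])
        res = permutation_fisher(t, n_perm=10_000, seed=4)
        assert res.method == "monte_carlo"
        assert res.p_value > 0.5

    def test_converges_to_exhaustive_rxc_oracle(self):
        t = np.array([[6, 1], [2, 5], [1, 4]])
        p_exact = brute_force_rxc_p(t)
        res = permutation_fisher(t, n_perm=20_000, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(res.p_value - p_exact) <= 3 * se + 1e-4

    def test_fixed_seed_is_deterministic(self):
        t = np.array([[10, 3], [4, 9], [2, 2]])
        p1 = permutation_fisher(t, n_perm=2_000, seed=6).p_value
        p2 = permutation_fisher(t, n_perm=2_000, seed=6).p_value
        assert p1 == p2

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            permutation_fisher(np.array([[0, 0], [1, 2], [3, 4]]))


class TestBonferroni:
    def _result(self, hg, p):
        return FreqTestResult(hg, (0, 0, 0, 0), p, "exact")

    def test_period_changes_match_published_narrative(self):
        """With alpha 0.05 over 14 groups, the L and M increases are
        significant while U (p = 0.02) is not."""
        n1, n2 = PERIOD_TOTALS
        results = []
        for hg in ("L", "M", "U"):
            a, c = PERIOD_COUNTS[hg]
            results.append(
                self._result(hg, fisher_exact_2x2(a, n1 - a, c, n2 - c))
            )
        bonferroni(results, alpha=0.05, m=14)
        decisions = {r.haplogroup: r.significant for r in results}
        assert decisions == {"L": True, "M": True, "U": False}

    def test_m_one_reduces_to_raw_alpha(self):
        (r,) = bonferroni([self._result("x", 0.02)], alpha=0.05, m=1)
        assert r.significant

    def test_decisions_monotone_in_p(self):
        ps = [0.0001, 0.003, 0.004, 0.02, 0.5]
        results = bonferroni(
            [self._result(str(i), p) for i, p in enumerate(ps)], alpha=0.05, m=14
        )
        flags = [r.significant for r in results]
        assert flags == sorted(flags, reverse=True)

    def test_m_smaller_than_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([self._result("a", 0.1)] * 3, m=2)


class TestTrend:
    def test_recovers_configured_slope(self, tree_and_panel):
        tree, _ = tree_and_panel
        model = denmark_model()
        cohort = simulate_cohort(model, tree, 30_000, seed=15)
        calls = true_calls(cohort, tree)
        series = yearly_trend(calls, cohort, "M", level="paper")
        slope, se = trend_slope(series)
        expected = sum(t for h, t in model.trend.items() if h in
                       {"C", "D4", "D5", "D6", "E", "G", "M", "M1", "M2", "M3",
                        "M30", "M4", "M5", "M6", "M7", "M8a", "M9", "Z"})
        assert abs(slope - expected) <= 3 * se

    def test_constant_haplogroup_has_null_slope(self, tree_and_panel):
        tree, _ = tree_and_panel
        model = denmark_model()
        cohort = simulate_cohort(model, tree, 30_000, seed=16)
        calls = true_calls(cohort, tree)
        series = yearly_trend(calls, cohort, "J", level="paper")
        slope, se = trend_slope(series)
        assert abs(slope) <= 3 * se

    def test_restricted_denominator_counts_only_the_macro(self):
        calls = []
        meta_rows = []
        for i in range(100):
            macro = "R" if i % 2 == 0 else "M"
            hg = "U" if i % 4 == 0 else ("H" if macro == "R" else "UNASSIGNED")
            call = HgCall(f"s{i}", macro_hg=macro, status="full")
            call.hg = hg
            calls.append(call)
            meta_rows.append((f"s{i}", 1981 + (i // 2) % 2, "Capital", False))
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "birth_year", "region", "metro"]
        )
        series = yearly_trend(calls, meta, "U", restrict_macro="R")
        # denominators are the R-macro totals, not the cohort totals
        assert series["denominator"].sum() == 50
        assert series["count"].sum() == 25

    def test_wilson_interval_contains_the_point_estimate(self, tree_and_panel):
        tree, _ = tree_and_panel
        model = denmark_model()
        cohort = simulate_cohort(model, tree, 5_000, seed=17)
        calls = true_calls(cohort, tree)
        series = yearly_trend(calls, cohort, "H", level="paper")
        assert (series["ci_low"] <= series["proportion"]).all()
        assert (series["proportion"] <= series["ci_high"]).all()
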
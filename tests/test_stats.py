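"""Contingency statistics: chi-square/phi, exact Fisher, Spearman, ANOVA."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from hydroquant.stats import (
    ContingencyTable,
    anova_bonferroni,
    build_group_symptom_table,
    chi_square,
    fisher_exact_rxc,
    spearman,
)
from hydroquant.tables import PRINTED_CHI2, available_tables, load_table

import pandas as pd


def brute_force_fisher(counts):
    """Oracle: plain recursive enumeration of all fixed-margin tables."""
    counts = np.asarray(counts, dtype=int)
    R, C = counts.sum(axis=1), counts.sum(axis=0)
    n = counts.sum()

    def log_fact(x):
        return math.lgamma(x + 1)

    logconst = sum(map(log_fact, R)) + sum(map(log_fact, C)) - log_fact(n)

    def table_logp(t):
        return logconst - sum(log_fact(v) for row in t for v in row)

    obs = table_logp(counts)
    total = 0.0

    def fill(row, remaining_cols, rows_acc):
        nonlocal total
        if row == len(R) - 1:
            last = remaining_cols
            if min(last) < 0:
                return
            t = rows_acc + [list(last)]
            lp = table_logp(t)
            if lp <= obs + 1e-7:
                total += math.exp(lp)
            return
        for cells in itertools.product(*(range(c + 1) for c in remaining_cols)):
            if sum(cells) != R[row]:
                continue
            fill(row + 1, [c - x for c, x in zip(remaining_cols, cells)], rows_acc + [list(cells)])

    fill(0, list(C), [])
    return total


class TestChiSquare:
    @pytest.mark.parametrize("table_id", list(PRINTED_CHI2))
    def test_printed_statistics_reproduced(self, table_id):
        res = chi_square(load_table(table_id))
        printed = PRINTED_CHI2[table_id]
        assert res.statistic == pytest.approx(printed["chi2"], abs=0.05)
        assert res.df == printed["df"]
        assert res.phi == pytest.approx(printed["phi"], abs=0.05)
        assert res.p < 0.05

    def test_independent_table_gives_zero(self):
        t = ContingencyTable(np.outer([2, 3], [4, 6]))
        res = chi_square(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.phi == pytest.approx(0.0, abs=1e-9)

    def test_perfect_association_2x2(self):
        res = chi_square(ContingencyTable([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.phi == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square(ContingencyTable([[0, 0], [3, 4]]))

    def test_phi_invariant_under_count_scaling(self):
        base = np.array([[5, 2, 1], [1, 6, 3]])
        r1 = chi_square(ContingencyTable(base))
        r3 = chi_square(ContingencyTable(base * 3))
        assert r3.statistic == pytest.approx(3 * r1.statistic)
        assert r3.phi == pytest.approx(r1.phi)


class TestFisher:
    def test_2x2_known_value(self):
        res = fisher_exact_rxc(ContingencyTable([[3, 1], [1, 3]]))
        assert res.p == pytest.approx(0.4857142857, abs=1e-9)
        assert res.n_tables == 5

    def test_matches_scipy_on_2x2(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = rng.integers(0, 8, (2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            mine = fisher_exact_rxc(ContingencyTable(t)).p
            ref = sps.fisher_exact(t).pvalue
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_degenerate_single_row_or_column(self):
        assert fisher_exact_rxc(ContingencyTable([[1, 2, 3]])).p == 1.0
        assert fisher_exact_rxc(ContingencyTable([[1], [4]])).p == 1.0

    def test_matches_brute_force_enumeration_on_small_rxc(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 6:
            shape = rng.choice([(2, 3), (3, 3), (2, 4)])
            t = rng.integers(0, 5, tuple(shape))
            if t.sum() == 0 or t.sum() > 30:
                continue
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            mine = fisher_exact_rxc(ContingencyTable(t)).p
            oracle = brute_force_fisher(t)
            assert mine == pytest.approx(oracle, rel=1e-9)
            checked += 1

    def test_monte_carlo_converges_to_exact(self):
        t = ContingencyTable([[8, 3, 2], [2, 6, 4], [1, 2, 12]])
        exact = fisher_exact_rxc(t).p
        mc = fisher_exact_rxc(t, method="monte_carlo", reps=100_000, seed=5)
        assert abs(mc.p - exact) <= 3 * mc.mc_se

    def test_monte_carlo_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            fisher_exact_rxc(ContingencyTable([[1, 2], [3, 4]]), method="monte_carlo")

    def test_oversize_table_suggests_monte_carlo(self):
        big = np.full((6, 6), 2)
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact_rxc(ContingencyTable(big))


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [2.0, 4.0, 6.0, 8.0, 10.0])[0] == pytest.approx(1.0)
        assert spearman(x, [10.0, 8.0, 6.0, 4.0, 2.0])[0] == pytest.approx(-1.0)

    def test_rank_formula_value(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_exact_permutation_p_small_n(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        _, p = spearman(x, y)
        # exact two-sided permutation p for rho=0.8 at n=5 is 16/120
        assert p == pytest.approx(16 / 120)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        groups = np.array(["a"] * 10 + ["b"] * 12)
        f_stat, p, pairwise = anova_bonferroni(groups, np.concatenate([a, b]))
        t_stat, t_p = sps.ttest_ind(a, b)
        assert f_stat == pytest.approx(t_stat**2)
        assert p == pytest.approx(t_p)
        assert pairwise[("a", "b")] == pytest.approx(min(1.0, t_p))

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 30)
        groups = np.repeat(["a", "b", "c"], 10)
        _, _, pairwise = anova_bonferroni(groups, vals)
        assert all(0 < v <= 1 for v in pairwise.values())

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(6)
        reps, n, k = 1000, 10, 3
        data = rng.normal(0, 1, (reps, k, n))
        _, p = sps.f_oneway(*(data[:, i, :] for i in range(k)), axis=-1)
        rate = float(np.mean(p < 0.05))
        assert 0.035 <= rate <= 0.065

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_bonferroni(np.array(["a"] * 5), np.arange(5.0))


class TestGroupSymptomTables:
    def test_presence_coding_matches_bundled_table(self):
        records = []
        bundled = load_table("eh_presence_all")
        for j, group in enumerate(bundled.col_labels):
            present = bundled.counts[0, j]
            absent = bundled.counts[1, j]
            records += [{"group": group, "eh": True}] * present
            records += [{"group": group, "eh": False}] * absent
        ct = build_group_symptom_table(pd.DataFrame(records), "eh")
        res = chi_square(ct)
        assert res.statistic == pytest.approx(29.1, abs=0.05)
        assert res.df == 2

    def test_three_level_coding_df4(self):
        bundled = load_table("tinnitus3_all")
        records = []
        for i, level in enumerate(bundled.row_labels):
            for j, group in enumerate(bundled.col_labels):
                records += [{"group": group, "tinnitus": level}] * bundled.counts[i, j]
        ct = build_group_symptom_table(pd.DataFrame(records), "tinnitus")
        res = chi_square(ct)
        assert res.df == 4
        assert res.statistic == pytest.approx(16.3, abs=0.05)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            build_group_symptom_table(pd.DataFrame(), "x")

    def test_all_bundled_tables_load(self):
        for tid in available_tables():
            t = load_table(tid)
            assert (t.counts >= 0).all() and t.n > 0
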
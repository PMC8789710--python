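"""Exact nonparametric tests, correlations and cohort table builders.

Enumeration-based implementations are checked against independent
brute-force oracles that compute the null distributions by a different
route (sign products and pairwise comparisons instead of rank-matrix
algebra), and against scipy on tie-free inputs.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pvloop.cohortstats import (
    CohortRow,
    CohortTable,
    TABLE_ROWS,
    build_tables,
    cohort_table,
    kendall_tau_b,
    mann_whitney_exact,
    paired_wilcoxon,
    pearson_r,
    subgroup_delta_test,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def wilcoxon_oracle(d):
    """Two-sided exact signed-rank p via direct sign-product enumeration."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = ranks.sum()
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - m / 2) >= abs(w_obs - m / 2) - 1e-12:
            count += 1
    return count / total


def mwu_oracle(x, y):
    """Two-sided exact Mann-Whitney p via pairwise-comparison counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = x.size
    n = pooled.size

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(n) if i not in idx]]
        gt = sum(1.0 for a in xs for b in ys if a > b)
        ties = sum(0.5 for a in xs for b in ys if a == b)
        return gt + ties

    u_obs = u_of(tuple(range(nx)))
    mid = nx * (n - nx) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if abs(u_of(idx) - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


def taub_oracle(x, y):
    """Kendall tau-b from explicit pair enumeration with tie terms."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            nc += 1
        else:
            nd += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom


# ---------------------------------------------------------------------------


class TestPairedWilcoxon:
    def test_three_positive_pairs(self):
        res = paired_wilcoxon([0, 0, 0], [1, 2, 3])
        assert res.p == pytest.approx(0.25)
        assert res.test == "wilcoxon-signed-rank-exact"

    def test_balanced_antisymmetric_pairs(self):
        res = paired_wilcoxon([0, 0, 0, 0], [1, -1, 2, -2])
        assert res.p == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_differences_discarded_and_counted(self):
        res = paired_wilcoxon([1, 2, 3, 4, 5], [1, 3, 4, 5, 6])
        assert res.n == 4
        assert "1 zero difference" in res.note

    @given(st.lists(st.integers(-20, 20), min_size=3, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, diffs):
        d = np.asarray(diffs, float)
        if np.all(d == 0):
            return
        if (d != 0).sum() < 3:
            return
        res = paired_wilcoxon(np.zeros_like(d), d)
        assert res.p == pytest.approx(wilcoxon_oracle(d), abs=1e-12)

    def test_matches_scipy_on_tie_free_input(self, rng):
        for _ in range(20):
            d = rng.standard_normal(8)
            p_ours = paired_wilcoxon(np.zeros(8), d).p
            p_scipy = sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_large_n_normal_approximation_reasonable(self, rng):
        d = rng.standard_normal(40) + 0.8
        res = paired_wilcoxon(np.zeros(40), d)
        assert res.test == "wilcoxon-signed-rank-normal"
        p_scipy = sps.wilcoxon(
            d, alternative="two-sided", method="approx", correction=False
        ).pvalue
        assert res.p == pytest.approx(p_scipy, abs=1e-9)


class TestMannWhitney:
    def test_complete_separation_4v4(self):
        res = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.p == pytest.approx(2 / 70)

    def test_identical_multisets(self):
        res = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0, 2.0])

    @given(
        st.lists(st.integers(-10, 10), min_size=2, max_size=4),
        st.lists(st.integers(-10, 10), min_size=2, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, x, y):
        res = mann_whitney_exact(x, y)
        assert res.p == pytest.approx(mwu_oracle(x, y), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_input(self, rng):
        for _ in range(20):
            x = rng.standard_normal(4)
            y = rng.standard_normal(5)
            p_ours = mann_whitney_exact(x, y).p
            p_scipy = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-12)


class TestCorrelations:
    def test_perfect_concordance(self):
        res = kendall_tau_b([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.estimate == pytest.approx(1.0)

    def test_perfect_discordance(self):
        res = kendall_tau_b([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.estimate == pytest.approx(-1.0)

    def test_tied_example_matches_pair_enumeration(self):
        x = [1, 2, 2, 3]
        y = [1, 2, 3, 3]
        res = kendall_tau_b(x, y)
        assert res.estimate == pytest.approx(taub_oracle(x, y), abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=8),
        st.lists(st.integers(0, 5), min_size=3, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_taub_matches_oracle(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        res = kendall_tau_b(x, y)
        assert res.estimate == pytest.approx(taub_oracle(x, y), abs=1e-12)
        assert -1.0 <= res.estimate <= 1.0

    def test_degenerate_input_flagged_not_hidden(self):
        res = kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.estimate)
        assert "degenerate" in res.note

    def test_pearson_collinear(self):
        res = pearson_r([1, 2, 3], [2, 4, 6])
        assert res.estimate == pytest.approx(1.0)

    def test_pearson_affine_invariance(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        r1 = pearson_r(x, y).estimate
        r2 = pearson_r(3.0 * x + 7.0, 0.1 * y - 2.0).estimate
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_pearson_matches_covariance_formula(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r = pearson_r(x, y).estimate
        manual = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCohortTables:
    def test_default_cohort_contains_all_table_rows(self, default_cohort_table):
        tables = build_tables(default_cohort_table)
        summary = tables["summary"]
        for row in TABLE_ROWS:
            assert row in summary.index
        # clinical-table row names are all represented
        for stem in ("HR", "EF", "SV", "SVI", "SW", "CO", "CI", "EDV", "ESV",
                     "EDP", "ESP", "PRSW", "TAU", "SCI"):
            assert any(r.startswith(stem + " ") for r in summary.index)

    def test_significance_marker_iff_p_below_alpha(self, default_cohort_table):
        summary = build_tables(default_cohort_table)["summary"]
        finite = summary[np.isfinite(summary["p"])]
        assert (finite["significant"] == (finite["p"] < 0.05)).all()

    def test_paired_p_matches_direct_test(self, default_cohort_table):
        summary = build_tables(default_cohort_table)["summary"]
        pre = default_cohort_table.values("ef", "pre") * 100
        post = default_cohort_table.values("ef", "post") * 100
        assert summary.loc["EF (%)", "p"] == pytest.approx(
            paired_wilcoxon(pre, post).p
        )

    def test_single_patient_no_tests(self, default_cohort_table):
        single = CohortTable(rows=default_cohort_table.rows[:1])
        tables = build_tables(single)
        summary = tables["summary"]
        assert summary["pre_sd"].isna().all()
        assert summary["p"].isna().all()
        assert list(tables) == ["summary"]

    def test_subgroup_delta_test_runs(self, default_cohort_table):
        labels = default_cohort_table.rows[0].labels
        for g in labels:
            mask = default_cohort_table.group_mask(g)
            if mask.any() and not mask.all():
                res = subgroup_delta_test(default_cohort_table, "ef", g)
                assert 0 <= res.p <= 1
                break
        else:
            pytest.skip("cohort has no mixed subgroup at this seed")

    def test_missing_pair_rejected(self, default_cohort_table):
        row = default_cohort_table.rows[0]
        with pytest.raises(ValueError):
            CohortTable(rows=[CohortRow(patient_id="x", pre=row.pre, post=None)])


class TestCalibration:
    def test_type_one_error_at_most_nominal(self, rng):
        # permutation null: symmetric continuous differences, n = 8
        reps = 2000
        rej = sum(
            paired_wilcoxon(np.zeros(8), rng.standard_normal(8)).p < 0.05
            for _ in range(reps)
        )
        assert rej / reps <= 0.05
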
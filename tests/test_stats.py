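"""ANCOVA, BH-FDR and Cohen's d against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fceeg.errors import InputError
from fceeg.stats import ancova_group, bh_fdr, cohens_d, run_group_comparison


def normal_equations_f(values, g, ages):
    """Explicit projection-formula oracle for the group partial F-test."""
    from scipy import stats as sstats

    n = len(values)
    X = np.column_stack([np.ones(n), g, ages])
    bhat = np.linalg.solve(X.T @ X, X.T @ values)
    sse_f = float(values @ values - bhat @ X.T @ values)
    Xr = X[:, [0, 2]]
    br = np.linalg.solve(Xr.T @ Xr, Xr.T @ values)
    sse_r = float(values @ values - br @ Xr.T @ values)
    f = (sse_r - sse_f) / (sse_f / (n - 3))
    return f, float(sstats.f.sf(f, 1, n - 3))


class TestAncova:
    def test_identical_group_distributions_give_null_result(self):
        vals = np.tile([1.0, 2.0, 3.5, 4.0, 9.0], 2)
        groups = ["patient"] * 5 + ["control"] * 5
        ages = np.r_[30, 40, 50, 60, 70, 30, 40, 50, 60, 70.0]
        res = ancova_group(vals, groups, ages)
        assert res.f_stat == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = 10
            vals = rng.standard_normal(n) + rng.uniform(-1, 1)
            g = rng.integers(0, 2, n)
            while g.sum() < 2 or (1 - g).sum() < 2:
                g = rng.integers(0, 2, n)
            ages = rng.uniform(20, 80, n)
            res = ancova_group(vals, g, ages)
            f_or, p_or = normal_equations_f(vals, g, ages)
            assert res.f_stat == pytest.approx(f_or, abs=1e-8)
            assert res.p_value == pytest.approx(p_or, abs=1e-8)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 24
        vals = rng.standard_normal(n)
        g = np.r_[np.ones(10), np.zeros(14)]
        ages = rng.uniform(20, 80, n)
        res = ancova_group(vals, g, ages)
        fit = sm.OLS(vals, np.column_stack([np.ones(n), g, ages])).fit()
        assert res.f_stat == pytest.approx(fit.tvalues[1] ** 2, rel=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_constant_age_reduces_to_one_way_anova(self, rng):
        from scipy import stats as sstats

        vals = rng.standard_normal(16)
        g = np.r_[np.ones(7), np.zeros(9)]
        with pytest.warns(UserWarning, match="singular design"):
            res = ancova_group(vals, g, np.full(16, 44.0))
        f_anova, p_anova = sstats.f_oneway(vals[g == 1], vals[g == 0])
        assert res.f_stat == pytest.approx(f_anova, abs=1e-8)
        assert res.p_value == pytest.approx(p_anova, abs=1e-8)
        assert not res.age_adjusted

    def test_zero_residual_variance_reports_p_zero(self):
        vals = np.r_[np.ones(3), np.zeros(3)]
        g = ["patient"] * 3 + ["control"] * 3
        with pytest.warns(UserWarning, match="degenerate"):
            res = ancova_group(vals, g, [30, 40, 50, 30, 40, 50.0])
        assert res.p_value == 0.0

    def test_group_size_precondition(self):
        with pytest.raises(InputError):
            ancova_group([1, 2, 3], ["patient", "control", "control"],
                         [30, 40, 50])

    def test_age_adjustment_shrinks_confounded_group_effect(self, rng):
        """When age drives the outcome and is confounded with group, the
        age-adjusted F must typically be smaller than the unadjusted one."""
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            n1, n2 = 12, 12
            ages = np.r_[rng.uniform(50, 80, n1), rng.uniform(20, 50, n2)]
            g = np.r_[np.ones(n1), np.zeros(n2)]
            vals = 0.05 * ages + rng.standard_normal(n1 + n2)
            adj = ancova_group(vals, g, ages).f_stat
            unadj = ancova_group(vals, g, np.full(n1 + n2, 0.0) + rng.standard_normal(n1 + n2) * 1e-12).f_stat
            if adj < unadj:
                wins += 1
        assert wins > n_rep / 2

    def test_sign_agreement_with_cohens_d(self, rng):
        # with a genuine group effect and group-independent ages, the
        # adjusted group coefficient and d point the same way
        agree = 0
        n_rep = 200
        for _ in range(n_rep):
            effect = rng.choice([-1.5, 1.5])
            vals = rng.standard_normal(30)
            vals[:15] += effect
            g = np.r_[np.ones(15), np.zeros(15)]
            ages = rng.uniform(20, 80, 30)  # independent of group
            res = ancova_group(vals, g, ages)
            d = cohens_d(vals[:15], vals[15:])
            if np.sign(res.group_coef) == np.sign(d):
                agree += 1
        assert agree >= 0.99 * n_rep


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.037]), [0.037])

    def test_arithmetic_sequence_collapses_to_max(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adj, 0.05)

    def test_matches_step_up_definition(self, rng):
        def step_up(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, m / rank * p[i])
                adj[i] = running
            return adj

        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), step_up(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.random(8)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.1, 1.2])

    def test_family_permutation_leaves_multiset_unchanged(self, rng):
        p = rng.random(5)
        perm = rng.permutation(5)
        a1 = np.sort(bh_fdr(p))
        a2 = np.sort(bh_fdr(p[perm]))
        np.testing.assert_allclose(a1, a2)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_step_up_properties_hold_for_any_p_list(self, p):
        adj = bh_fdr(p)
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # monotone: sorting by raw p sorts adjusted p
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # the smallest adjusted p equals min over j of (m/rank_j) p_(j)
        m = len(p)
        ranks = np.empty(m)
        ranks[order] = np.arange(1, m + 1)
        assert adj.min() == pytest.approx(
            min(1.0, np.min(m / ranks * p)), abs=1e-12
        )


class TestCohensD:
    def test_identical_means_give_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_label_swap_flips_sign(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(12) + 0.5
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(InputError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


def noise_feature_table(rng, n_pat=21, n_ctl=37, tasks=("t",), bands=("alpha",)):
    regions = ["frontal", "central", "temporal", "parietal", "occipital"]
    rows = []
    ages = np.r_[rng.uniform(23, 80, n_pat), rng.uniform(20, 60, n_ctl)]
    groups = ["patient"] * n_pat + ["control"] * n_ctl
    for task in tasks:
        for band in bands:
            for region in regions:
                vals = rng.standard_normal(n_pat + n_ctl)
                for i, (g, a, v) in enumerate(zip(groups, ages, vals)):
                    rows.append(
                        {"subject_id": f"s{i}", "group": g, "age": a,
                         "task": task, "band": band, "region": region,
                         "value": v}
                    )
    return pd.DataFrame(rows)


class TestRunGroupComparison:
    def test_null_families_control_false_discoveries(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            table = noise_feature_table(rng)
            out = run_group_comparison(table)
            hits += out["significant"].any()
        rate = hits / n_rep
        assert 0.02 <= rate <= 0.09  # nominal 0.05 under the global null

    def test_constant_p_family_all_significant(self, monkeypatch):
        table = noise_feature_table(np.random.default_rng(0))
        import fceeg.stats as fstats

        monkeypatch.setattr(
            fstats, "ancova_group",
            lambda v, g, a: fstats.AncovaResult(5.0, 0.04, 0.1, 1, 55, True),
        )
        out = fstats.run_group_comparison(table)
        np.testing.assert_allclose(out["p_fdr"], 0.04)
        assert out["significant"].all()

    def test_medium_effect_flag_follows_d(self, rng):
        table = noise_feature_table(rng)
        # inject a strong parietal shift
        sel = (table["region"] == "parietal") & (table["group"] == "patient")
        table.loc[sel, "value"] += 2.0
        out = run_group_comparison(table)
        row = out[out["feature"] == "parietal"].iloc[0]
        assert row["medium_effect"] and row["cohens_d"] > 0.5
        assert out["medium_effect"].equals(out["cohens_d"].abs() > 0.5)

    def test_raw_p_mode_for_singleton_families(self, rng):
        table = noise_feature_table(rng)
        out = run_group_comparison(table, fdr_within_family=False)
        np.testing.assert_allclose(out["p_fdr"], out["p_raw"])

    def test_missing_cells_skip_family_with_warning(self, rng):
        table = noise_feature_table(rng)
        table = table[~((table["region"] == "occipital")
                        & (table["group"] == "patient"))]
        with pytest.warns(UserWarning, match="skipped"):
            out = run_group_comparison(table)
        assert len(out) == 0
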
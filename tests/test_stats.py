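"""Covariate-adjusted group statistics: oracles, calibration and df structure."""

import numpy as np
import pytest

from braindyn.stats import (
    DesignSpec,
    ancova_univariate,
    fdr_bh,
    mancova_wilks,
    paired_t,
    pearson_fisher_ci,
    spearman_partial_bootstrap,
)


def null_design(rng, n=60, k=3, n_cov=4):
    group = np.repeat(["A", "B"], n // 2)
    cov = rng.standard_normal((n, n_cov))
    resp = rng.dirichlet(np.ones(k) * 5, size=n)
    return DesignSpec(group, cov, resp)


class TestMancova:
    def test_study_design_df(self, rng):
        d = null_design(rng, n=88, k=3, n_cov=4)
        _, df1, df2, _ = mancova_wilks(d)
        assert (df1, df2) == (2, 81)

    def test_matches_statsmodels_manova(self, rng):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        d = null_design(rng, n=50)
        f, df1, df2, p = mancova_wilks(d)
        df = pd.DataFrame(d.covariates, columns=["c1", "c2", "c3", "c4"])
        df["grp"] = (d.group == "B").astype(float)
        df["y1"], df["y2"] = d.responses[:, 0], d.responses[:, 1]
        tab = MANOVA.from_formula(
            "y1 + y2 ~ grp + c1 + c2 + c3 + c4", data=df
        ).mv_test().results["grp"]["stat"]
        row = tab.loc["Wilks' lambda"]
        assert f == pytest.approx(float(row["F Value"]), abs=1e-8)
        assert p == pytest.approx(float(row["Pr > F"]), abs=1e-8)

    def test_pillai_coincides_with_wilks_for_single_df(self, rng):
        d = null_design(rng, n=50)
        w = mancova_wilks(d, statistic="wilks")
        v = mancova_wilks(d, statistic="pillai")
        assert w[0] == pytest.approx(v[0], abs=1e-9)
        assert w[3] == pytest.approx(v[3], abs=1e-9)

    def test_dropped_state_does_not_change_statistic(self, rng):
        d = null_design(rng, n=40)
        results = [mancova_wilks(d, drop_state=j) for j in range(3)]
        for r in results[1:]:
            assert r[0] == pytest.approx(results[0][0], abs=1e-9)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(2024)
        rejections = sum(
            mancova_wilks(null_design(rng))[3] < 0.05 for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(40):
            d = null_design(rng, n=60)
            resp = d.responses.copy()
            shift = np.where(d.group == "B", 0.11, 0.0)
            resp[:, 0] += shift
            resp[:, 1] -= shift / 2
            resp[:, 2] -= shift / 2
            d2 = DesignSpec(d.group, d.covariates, resp)
            hits += mancova_wilks(d2)[3] < 0.05
        assert hits / 40 > 0.8

    def test_rank_deficient_design_rejected(self, rng):
        d = null_design(rng, n=40)
        cov = d.covariates.copy()
        cov[:, 1] = cov[:, 0]
        with pytest.raises(ValueError):
            mancova_wilks(DesignSpec(d.group, cov, d.responses))


class TestAncova:
    def test_study_design_df(self, rng):
        d = null_design(rng, n=88)
        _, df1, df2, _ = ancova_univariate(d)
        assert (df1, df2) == (1, 82)

    def test_orthogonal_group_gives_zero_f(self, rng):
        # each B subject is an exact copy of an A subject, so the group
        # coefficient is identically zero
        n = 40
        group = np.repeat(["A", "B"], n // 2)
        cov = rng.standard_normal((n // 2, 2))
        cov = np.vstack([cov, cov])
        resp = rng.dirichlet(np.ones(3) * 5, size=n // 2)
        resp = np.vstack([resp, resp])
        d = DesignSpec(group, cov, resp)
        f, *_ = ancova_univariate(d)
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_matches_nested_rss_oracle(self, rng):
        n = 44
        d = null_design(rng, n=n)
        f, df1, df2, p = ancova_univariate(d, state=1)
        g = (d.group == "B").astype(float)
        x_full = np.column_stack([np.ones(n), g, d.covariates])
        x_red = np.column_stack([np.ones(n), d.covariates])
        y = d.responses[:, 1]

        def rss(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return r @ r

        f_oracle = (rss(x_red) - rss(x_full)) / (rss(x_full) / (n - 6))
        assert f == pytest.approx(f_oracle, abs=1e-10)


class TestFdrBH:
    def test_single_value_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_inputs_unchanged(self):
        assert np.allclose(fdr_bh([0.2, 0.2, 0.2]), 0.2)

    def test_matches_bruteforce_step_up(self, rng):
        p = rng.uniform(size=20)
        mine = fdr_bh(p)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            adj[i] = prev
        assert np.allclose(mine, adj, atol=1e-12)

    def test_monotone_and_idempotent(self, rng):
        p = np.sort(rng.uniform(size=15))
        adj = fdr_bh(p)
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.allclose(fdr_bh(adj), fdr_bh(adj))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestFisherCI:
    def test_symmetric_about_zero(self):
        lo, hi = pearson_fisher_ci(0.0, 200)
        assert lo == pytest.approx(-hi)

    def test_anchor_value(self):
        lo, hi = pearson_fisher_ci(0.73, 116)
        assert 0.6 < lo < 0.73 < hi < 0.85

    def test_coverage_in_simulation(self):
        rng = np.random.default_rng(3)
        rho, n, covered = 0.5, 50, 0
        n_sim = 400
        for _ in range(n_sim):
            z = rng.standard_normal((2, n))
            x = z[0]
            y = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
            r = np.corrcoef(x, y)[0, 1]
            lo, hi = pearson_fisher_ci(r, n)
            covered += lo <= rho <= hi
        assert 0.91 <= covered / n_sim <= 0.98

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_fisher_ci(0.5, 3)


class TestSpearmanPartial:
    def test_identity_without_covariates(self, rng):
        x = rng.standard_normal(30)
        rho, p, ci = spearman_partial_bootstrap(x, x, n_boot=50, seed=0)
        assert rho == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        from scipy.stats import rankdata

        n = 50
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        cov = rng.standard_normal((n, 3))
        rho, p, ci = spearman_partial_bootstrap(x, y, cov, n_boot=10, seed=0)
        xm = np.column_stack([np.ones(n), cov])
        proj = np.eye(n) - xm @ np.linalg.pinv(xm)
        rx, ry = proj @ rankdata(x), proj @ rankdata(y)
        oracle = (rx @ ry) / (np.linalg.norm(rx) * np.linalg.norm(ry))
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin_on_ranked_covariates(self, rng):
        # pingouin's Spearman partial correlation ranks every variable;
        # feeding it rank-transformed covariates makes the two procedures
        # coincide and provides an independent implementation check
        import pandas as pd
        import pingouin as pg
        from scipy.stats import rankdata

        n = 60
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        cov_ranked = np.column_stack([rankdata(c) for c in cov.T])
        rho, p, ci = spearman_partial_bootstrap(x, y, cov_ranked, n_boot=10, seed=0)
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_null_ci_covers_zero(self):
        rng = np.random.default_rng(11)
        covered = 0
        n_sim = 60
        for i in range(n_sim):
            x = rng.standard_normal(100)
            y = rng.standard_normal(100)
            rho, p, (lo, hi) = spearman_partial_bootstrap(
                x, y, rng.standard_normal((100, 2)), n_boot=200, seed=i
            )
            covered += lo <= 0 <= hi
        assert covered / n_sim >= 0.85

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_partial_bootstrap(np.ones(20), np.arange(20.0))


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)
        assert df == 2

    def test_df_structure(self, rng):
        a = rng.standard_normal(116)
        b = rng.standard_normal(116)
        _, df, _ = paired_t(a, b)
        assert df == 115

    def test_matches_textbook_formula(self, rng):
        a, b = rng.standard_normal(25), rng.standard_normal(25)
        t, df, p = paired_t(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(25))
        assert t == pytest.approx(t_oracle, abs=1e-12)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
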
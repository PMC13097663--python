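import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphodiverge.errors import ValidationError
from morphodiverge.rrpp_stats import (
    ModelSpec,
    anova_table,
    effect_size,
    fit_rrpp,
    format_p,
    pairwise_groups,
)


def one_way_data(seed=0, n_per=5, shift=(0.0, 0.5, 1.0)):
    rng = np.random.default_rng(seed)
    g = np.repeat(["a", "b", "c"], n_per)
    y = rng.standard_normal(3 * n_per) + np.repeat(shift, n_per)
    return y, pd.DataFrame({"grp": g})


class TestFitRrpp:
    def test_f_matches_classical_one_way_anova(self):
        y, df = one_way_data(seed=1)
        fit = fit_rrpp(y, ModelSpec(["grp"], df), iter=99, seed=0)
        g = df["grp"].to_numpy()
        oracle = stats.f_oneway(*(y[g == l] for l in "abc")).statistic
        assert fit.table.loc["grp", "F"] == pytest.approx(oracle, rel=1e-12)
        assert fit.table.loc["grp", "df"] == 2
        assert fit.df_residual == 12

    def test_exhaustive_permutation_matches_brute_force(self):
        # two groups of 3: enumerate all 720 residual permutations
        rng = np.random.default_rng(7)
        y = rng.standard_normal(6) + np.array([0, 0, 0, 1.2, 1.2, 1.2])
        df = pd.DataFrame({"grp": ["a"] * 3 + ["b"] * 3})
        perms = np.array(list(itertools.permutations(range(6))))
        identity_first = np.vstack([np.arange(6), perms[~(perms == np.arange(6)).all(1)]])
        fit = fit_rrpp(y, ModelSpec(["grp"], df), permutations=identity_first, seed=0)

        # brute force: F of every permuted response, counted against observed
        g = df["grp"].to_numpy()

        def F(v):
            return stats.f_oneway(v[g == "a"], v[g == "b"]).statistic

        yc = y - y.mean()  # residuals of the intercept-only null model
        stats_all = np.array([F(y.mean() + yc[list(p)]) for p in identity_first])
        p_brute = np.mean(stats_all >= stats_all[0] - 1e-12)
        assert fit.table.loc["grp", "p"] == pytest.approx(p_brute, abs=1e-12)

    def test_reproducible_given_seed(self):
        y, df = one_way_data(seed=3)
        a = fit_rrpp(y, ModelSpec(["grp"], df), iter=199, seed=42)
        b = fit_rrpp(y, ModelSpec(["grp"], df), iter=199, seed=42)
        assert a.table.equals(b.table)
        np.testing.assert_array_equal(
            a.permutation_distributions["grp"], b.permutation_distributions["grp"]
        )

    def test_ss_partition(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "sex": rng.choice(["M", "F"], n),
                "grp": rng.choice(["a", "b", "c"], n),
            }
        )
        Y = rng.standard_normal((n, 6))
        fit = fit_rrpp(Y, ModelSpec(["x", "sex", "grp", "sex:grp"], df), iter=49, seed=1)
        total = fit.table["SS"].sum() + fit.ss_residual
        assert total == pytest.approx(fit.ss_total, rel=1e-10)
        assert all(fit.table["p"] >= 1 / 50)

    def test_constant_response_column_handled(self, rng):
        y, df = one_way_data(seed=4)
        Y = np.column_stack([y, np.full_like(y, 2.5)])
        fit = fit_rrpp(Y, ModelSpec(["grp"], df), iter=49, seed=1)
        assert np.isfinite(fit.table.loc["grp", "F"])

    def test_fully_aliased_term_rejected(self, rng):
        df = pd.DataFrame({"a": ["x", "x", "y", "y"] * 3, "b": ["x", "x", "y", "y"] * 3})
        Y = rng.standard_normal(12)
        with pytest.raises(ValidationError, match="aliased"):
            fit_rrpp(Y, ModelSpec(["a", "b"], df), iter=9, seed=0)

    def test_nested_island_term_df(self, rng):
        n = 60
        region = np.repeat(["N", "S"], n // 2)
        island = np.array(
            [f"{r}{i % 3}" for r, i in zip(region, range(n))]
        )  # 3 islands per region
        df = pd.DataFrame({"region": region, "island": island})
        Y = rng.standard_normal(n)
        fit = fit_rrpp(Y, ModelSpec(["region", "region:island"], df), iter=49, seed=0)
        assert fit.table.loc["region", "df"] == 1
        assert fit.table.loc["region:island", "df"] == 4  # 6 islands - 2 regions

    def test_type_one_error_calibrated(self):
        # null responses: rejection rate at alpha=0.05 within binomial bounds
        rng = np.random.default_rng(99)
        df = pd.DataFrame({"grp": np.repeat(["a", "b", "c"], 8)})
        rej = 0
        n_sim = 200
        for _ in range(n_sim):
            y = rng.standard_normal(24)
            fit = fit_rrpp(y, ModelSpec(["grp"], df), iter=99, seed=int(rng.integers(2**31)))
            rej += fit.table.loc["grp", "p"] <= 0.05
        assert 0.02 <= rej / n_sim <= 0.09

    def test_power_increases_with_effect_size(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"grp": np.repeat(["a", "b"], 10)})
        powers = []
        for shift in (0.0, 0.8, 1.6):
            rej = 0
            for _ in range(60):
                y = rng.standard_normal(20)
                y[10:] += shift
                fit = fit_rrpp(y, ModelSpec(["grp"], df), iter=99,
                               seed=int(rng.integers(2**31)))
                rej += fit.table.loc["grp", "p"] <= 0.05
            powers.append(rej / 60)
        assert powers[0] < powers[1] < powers[2]


class TestAnovaTable:
    def test_partition_rows(self):
        y, df = one_way_data(seed=2)
        fit = fit_rrpp(y, ModelSpec(["grp"], df), iter=99, seed=0)
        t = anova_table(fit)
        assert t.loc["Total", "SS"] == pytest.approx(
            t.loc["grp", "SS"] + t.loc["Residuals", "SS"]
        )
        assert t.loc["grp", "Rsq"] + t.loc["Residuals", "Rsq"] == pytest.approx(1.0)
        assert t.loc["Total", "Rsq"] == 1.0


class TestEffectSize:
    def test_zero_when_observed_at_mean(self):
        assert effect_size(2.0, np.array([1.0, 2.0, 3.0])) == 0.0

    def test_hand_vector(self):
        assert effect_size(3.0, np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)

    def test_degenerate_distribution_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            z = effect_size(5.0, np.array([2.0, 2.0, 2.0]))
        assert z == 0.0


class TestPairwise:
    def test_observed_d_matches_direct_ls_means(self):
        y, df = one_way_data(seed=6, shift=(0.0, 1.0, 2.5))
        full = fit_rrpp(y, ModelSpec(["grp"], df), iter=199, seed=3)
        null = fit_rrpp(y, ModelSpec([], df), iter=199, seed=3)
        pw = pairwise_groups(full, null, "grp")
        g = df["grp"].to_numpy()
        for pair in pw.table.index:
            a, b = pair.split(":")
            direct = abs(y[g == a].mean() - y[g == b].mean())
            assert pw.table.loc[pair, "d"] == pytest.approx(direct, rel=1e-9)

    def test_null_groups_rarely_significant(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"grp": np.repeat(["a", "b"], 12)})
        ps = []
        for _ in range(50):
            y = rng.standard_normal(24)
            full = fit_rrpp(y, ModelSpec(["grp"], df), iter=99,
                            seed=int(rng.integers(2**31)))
            null = fit_rrpp(y, ModelSpec([], df), iter=99, seed=full.seed)
            pw = pairwise_groups(full, null, "grp")
            ps.append(float(pw.table["p"].iloc[0]))
        assert np.mean(np.array(ps) > 0.05) >= 0.85

    def test_covariate_adjustment_via_null_model(self, rng):
        # group means differ only through a shared covariate; pairwise with a
        # covariate null model must not flag the groups
        n = 60
        x = rng.standard_normal(n)
        g = np.where(x > 0, "hi", "lo")  # grouping correlated with covariate
        y = 2.0 * x + 0.3 * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "grp": g})
        full = fit_rrpp(y, ModelSpec(["x", "grp"], df), iter=199, seed=8)
        null = fit_rrpp(y, ModelSpec(["x"], df), iter=199, seed=8)
        pw = pairwise_groups(full, null, "grp")
        assert pw.table["p"].iloc[0] > 0.05

    def test_ucl_and_p_consistency(self):
        y, df = one_way_data(seed=8, shift=(0.0, 3.0, 6.0))
        full = fit_rrpp(y, ModelSpec(["grp"], df), iter=199, seed=3)
        null = fit_rrpp(y, ModelSpec([], df), iter=199, seed=3)
        pw = pairwise_groups(full, null, "grp")
        for pair, row in pw.table.iterrows():
            dist = pw.permuted_d[pair]
            assert row["p"] == pytest.approx(
                np.mean(dist >= row["d"] * (1 - 1e-12)), abs=1e-12
            )
            assert row["UCL95"] == pytest.approx(np.percentile(dist, 95))
            assert row["d"] >= 0

    def test_empty_group_level_rejected(self, rng):
        df = pd.DataFrame({"grp": ["a"] * 5 + ["b"] * 5})
        y = rng.standard_normal(10)
        full = fit_rrpp(y, ModelSpec(["grp"], df), iter=49, seed=0)
        null = fit_rrpp(y, ModelSpec([], df), iter=49, seed=0)
        pw = pairwise_groups(full, null, "grp")  # sanity: works with 2 levels
        assert len(pw.table) == 1
        with pytest.raises(ValidationError):
            pairwise_groups(full, null, "species")


def test_format_p():
    assert format_p(0.0001, 9999) == "< 0.001"
    assert format_p(0.2, 9999) == "0.2"
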
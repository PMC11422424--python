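"""Group-comparison statistics: frozen table values, oracles, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ematraj.stats import (
    VariableSpec,
    bh_fdr,
    characterize_clusters,
    oneway_anova,
    oneway_anova_from_stats,
    pearson_chi2,
    summarize_trajectory,
    welch_t,
    welch_t_from_stats,
)

# Published contingency tables of the pooled psychosis EMA cohort (counts
# reconstructed from the printed tables): used as frozen regression values.
CLUSTER_COMPOSITION = [[2, 1, 12], [23, 19, 43]]       # HC/RE/PD by cluster
SEX_BY_CLUSTER = [[1, 14], [38, 47]]                    # female/male
EDUCATION_BY_CLUSTER = [[2, 2, 5, 2, 0, 2], [27, 19, 11, 0, 2, 2]]
ANTIPSYCHOTICS_BY_CLUSTER = [[10, 1], [39, 1]]          # yes/no
GENDER_BY_GROUP = [[9, 16], [16, 39], [14, 6]]          # female/male x HC/PD/RE
LIVING_BY_GROUP = [[7, 12, 6], [37, 13, 5], [4, 12, 4]]


class TestSummarizeTrajectory:
    def test_constant_series(self):
        s = summarize_trajectory([4.0] * 42)
        assert s.mean_rating == 4.0
        assert s.corrected_variance == 0.0

    def test_alternating_series_closed_form(self):
        traj = [1.0, 3.0] * 21
        s = summarize_trajectory(traj)
        assert s.mean_rating == 2.0
        # s^2 = 42/41, corrected = s^2 / 2
        assert s.corrected_variance == pytest.approx(42.0 / 41.0 / 2.0)

    def test_matches_two_pass_variance(self):
        traj = np.tile(np.arange(1.0, 8.0), 6)
        s = summarize_trajectory(traj)
        mean = traj.mean()
        var = ((traj - mean) ** 2).sum() / (len(traj) - 1)
        assert s.corrected_variance == pytest.approx(var / mean, rel=1e-12)


class TestWelch:
    def test_identical_groups_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(x, x)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_published_summary_stats(self):
        # negative-symptom scores by cluster (n/mean/sd from the printed table)
        res = welch_t_from_stats(12, 20.3, 4.3, 43, 13.8, 5.1)
        assert res.t == pytest.approx(4.44, abs=0.005)

    def test_matches_scipy_to_1e10(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(loc=0.3, size=rng.integers(3, 30))
            res = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert res.df == pytest.approx(ref.df, abs=1e-10)

    def test_ci_covers_difference_direction(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 1, 40)
        b = rng.normal(1, 1, 40)
        res = welch_t(a, b)
        assert res.ci_low < a.mean() - b.mean() < res.ci_high
        assert res.ci_low > 0

    def test_reduces_to_pooled_t_with_equal_n_and_var(self):
        # equal sizes and equal sample variances: Welch df = pooled df
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 1.5
        res = welch_t(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labs = ["a"] * 3 + ["b"] * 3
        res = oneway_anova(vals, labs)
        assert res.F == pytest.approx(0.0)

    def test_two_groups_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(0.8, 1, size=9)
        res = oneway_anova(np.r_[a, b], ["a"] * 12 + ["b"] * 9)
        t_ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t_ref.statistic**2, rel=1e-10)

    def test_published_age_summaries(self):
        # age by study group (25/55/20; printed means and sds)
        res = oneway_anova_from_stats(
            [25, 55, 20], [36.4, 39.9, 37.2], [8.2, 10.3, 14.7]
        )
        assert res.F == pytest.approx(1.07, abs=0.005)
        assert (res.df1, res.df2) == (2, 97)

    def test_matches_scipy_to_1e10(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 15)) for _ in range(3)]
            vals = np.concatenate(groups)
            labs = np.repeat([0, 1, 2], [len(g) for g in groups])
            res = oneway_anova(vals, labs)
            ref = sps.f_oneway(*groups)
            assert res.F == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "table,expected,decimals",
        [
            (CLUSTER_COMPOSITION, 4.53, 2),
            (SEX_BY_CLUSTER, 7.75, 2),
            (EDUCATION_BY_CLUSTER, 18.00, 2),
            (ANTIPSYCHOTICS_BY_CLUSTER, 0.99, 2),
            (GENDER_BY_GROUP, 10.444, 3),
            (LIVING_BY_GROUP, 18.901, 3),
        ],
    )
    def test_published_tables_reproduced(self, table, expected, decimals):
        res = pearson_chi2(table)
        assert round(res.X2, decimals) == expected

    def test_2x2_closed_form(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            res = pearson_chi2([[a, b], [c, d]])
            N = a + b + c + d
            closed = N * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert res.X2 == pytest.approx(closed, abs=1e-10)
            assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[0, 0], [1, 2]])

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[1, 2]])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_step_up_forcing(self):
        out = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    @settings(derandomize=True, max_examples=50)
    @given(
        ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30)
    )
    def test_matches_statsmodels_exactly(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = bh_fdr(ps)
        _, ref, _, _ = multipletests(ps, method="fdr_bh")
        assert np.allclose(ours, ref, atol=0.0, rtol=0.0, equal_nan=False)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestTypeICalibration:
    def test_null_rejection_rate_nominal(self):
        # null cohorts: two groups of AR(1) composite trajectories with the
        # same latent mean; the Welch test on mean ratings must reject at
        # roughly the nominal 5% level
        rng = np.random.default_rng(2024)
        n_rep, n_per_group, phi, sd = 1000, 15, 0.5, 0.5
        rejections = 0
        for _ in range(n_rep):
            z = np.empty((2 * n_per_group, 42))
            z[:, 0] = rng.normal(0, sd / np.sqrt(1 - phi**2), 2 * n_per_group)
            eps = rng.normal(0, sd, size=(2 * n_per_group, 42))
            for t in range(1, 42):
                z[:, t] = phi * z[:, t - 1] + eps[:, t]
            ratings = np.clip(np.rint(1 + np.maximum(z, 0)), 1, 7)
            means = ratings.mean(axis=1)
            res = welch_t(means[:n_per_group], means[n_per_group:])
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestCharacterizeClusters:
    def _data(self):
        rng = np.random.default_rng(6)
        ids = [f"P{i}" for i in range(60)]
        labels = pd.Series([1] * 30 + [2] * 30, index=ids)
        data = pd.DataFrame(
            {
                "mean_rating": np.r_[rng.normal(4, 0.3, 30), rng.normal(1.5, 0.3, 30)],
                "corrected_variance": rng.normal(0.2, 0.05, 60),
                "group": ["PD"] * 40 + ["HC"] * 20,
                "panss_neg": np.r_[rng.normal(20, 4, 30), rng.normal(14, 4, 30)],
            },
            index=ids,
        )
        return labels, data

    def test_planted_effect_survives_fdr(self):
        labels, data = self._data()
        out = characterize_clusters(
            labels,
            data,
            [
                VariableSpec("mean_rating", "cluster_characterization"),
                VariableSpec("corrected_variance", "cluster_characterization"),
                VariableSpec("group", "demographics", kind="categorical"),
            ],
        )
        row = out[out["variable"] == "mean_rating"].iloc[0]
        assert row["p_fdr"] < 0.05
        assert row["test"] == "welch_t"

    def test_null_copies_produce_no_survivals(self):
        rng = np.random.default_rng(7)
        ids = [f"P{i}" for i in range(40)]
        labels = pd.Series([1, 2] * 20, index=ids)
        data = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)},
                            index=ids)
        out = characterize_clusters(
            labels, data,
            [VariableSpec("x", "clinical"), VariableSpec("y", "clinical")],
        )
        assert (out["p_fdr"] > 0.05).all()

    def test_families_corrected_separately(self):
        labels, data = self._data()
        out = characterize_clusters(
            labels,
            data,
            [
                VariableSpec("mean_rating", "cluster_characterization"),
                VariableSpec("corrected_variance", "cluster_characterization"),
                VariableSpec("panss_neg", "clinical",
                             subset=("group", "PD")),
            ],
        )
        # clinical family has a single test: its FDR-adjusted p equals raw p
        clin = out[out["family"] == "clinical"].iloc[0]
        assert clin["p_fdr"] == pytest.approx(clin["p"])

    def test_pd_only_subset_restricts_sample(self):
        labels, data = self._data()
        out = characterize_clusters(
            labels, data,
            [VariableSpec("panss_neg", "clinical", subset=("group", "PD"))],
        )
        # 40 PD -> Welch df must be < 40
        assert out.iloc[0]["df"] < 40

    def test_single_level_variable_skipped(self):
        labels, data = self._data()
        data["constant"] = 1.0
        with pytest.warns(UserWarning, match="single level"):
            out = characterize_clusters(
                labels, data, [VariableSpec("constant", "clinical")]
            )
        assert out.empty
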
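"""Profiling statistics: correlations, PCA, Welch/ANOVA group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nucleomorph as nm
from nucleomorph.errors import InsufficientDataError
from nucleomorph.profiling import (
    pca_profile, significance_tier, welch_anova_tests,
)


def _df(**columns):
    d = dict(columns)
    d.setdefault("grp", ["a"] * len(next(iter(columns.values()))))
    return pd.DataFrame(d)


class TestCorrelate:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        df = _df(x=rng.normal(size=30), y=rng.normal(size=30))
        corr = nm.correlate(df, "grp", params=("x", "y"))
        assert corr.r["a"].loc["x", "x"] == 1.0
        assert corr.r["a"].loc["y", "y"] == 1.0

    def test_near_linear_relation_r_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        df = _df(x=x, y=2 * x + rng.normal(0, 1e-8, size=100))
        corr = nm.correlate(df, "grp", params=("x", "y"))
        assert corr.r["a"].loc["x", "y"] == pytest.approx(1.0, abs=1e-6)
        assert corr.p["a"].loc["x", "y"] < 1e-10

    def test_zero_variance_parameter_undefined_not_zero(self):
        df = _df(x=np.arange(10.0), y=np.ones(10))
        corr = nm.correlate(df, "grp", params=("x", "y"))
        assert np.isnan(corr.r["a"].loc["x", "y"])
        assert np.isnan(corr.p["a"].loc["x", "y"])

    def test_matrices_symmetric_bounded(self, mixed_measured):
        corr = nm.correlate(mixed_measured, "true_cell_type")
        for group, r in corr.r.items():
            arr = r.to_numpy()
            assert np.allclose(arr, arr.T, equal_nan=True)
            finite = arr[np.isfinite(arr)]
            assert (np.abs(finite) <= 1 + 1e-12).all()
            assert np.allclose(np.diag(arr), 1.0)

    def test_nuclear_and_cc_content_strongly_related(self, mixed_measured):
        # generator couples chromocenter content to total content via RHF;
        # the measured table must recover a significant positive correlation
        df = mixed_measured.assign(all="all")
        corr = nm.correlate(df, "all", params=("content_nu", "content_cc"))
        assert corr.r["all"].loc["content_nu", "content_cc"] > 0.5
        assert corr.p["all"].loc["content_nu", "content_cc"] < 0.001

    def test_significance_tiers(self):
        assert significance_tier(0.0001) == "***"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.2) == ""

    def test_small_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0], "grp": ["a", "a"]})
        with pytest.raises(InsufficientDataError):
            nm.correlate(df, "grp", params=("x", "y"))


class TestPCA:
    def test_perfectly_correlated_parameters_pc1_explains_all(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        df = _df(x=x, y=3 * x + 1)
        prof = pca_profile(df, params=("x", "y"))
        assert prof.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_of_z_scored_data(self, mixed_measured):
        params = ("size_um2", "content_nu", "density_nu", "heterogeneity", "rhf")
        prof = pca_profile(mixed_measured, params=params)
        data = mixed_measured[list(params)].to_numpy(float)
        z = (data - data.mean(0)) / data.std(0)
        scores = prof.scores[[c for c in prof.scores if c.startswith("PC")]].to_numpy()
        recon = scores @ prof.loadings.to_numpy().T
        assert np.allclose(recon, z, atol=1e-9)

    def test_sign_pinning_deterministic(self, mixed_measured):
        p1 = pca_profile(mixed_measured, group_col="true_cell_type")
        p2 = pca_profile(mixed_measured, group_col="true_cell_type")
        assert np.array_equal(
            p1.scores.drop(columns="true_cell_type").to_numpy(),
            p2.scores.drop(columns="true_cell_type").to_numpy(),
        )
        for col in p1.loadings:
            pivot = p1.loadings[col].abs().idxmax()
            assert p1.loadings.loc[pivot, col] > 0

    def test_constant_parameter_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        df = _df(x=rng.normal(size=30), y=rng.normal(size=30), z=np.ones(30))
        with pytest.warns(UserWarning, match="dropping"):
            prof = pca_profile(df, params=("x", "y", "z"))
        assert prof.dropped == ("z",)
        assert list(prof.loadings.index) == ["x", "y"]

    def test_guard_and_endopolyploid_clusters_most_separated(self, mixed_measured):
        prof = pca_profile(mixed_measured, group_col="true_cell_type")
        cent = prof.scores.groupby("true_cell_type")[["PC1", "PC2"]].mean()
        import itertools

        dist = {
            frozenset((a, b)): float(np.hypot(*(cent.loc[a] - cent.loc[b])))
            for a, b in itertools.combinations(cent.index, 2)
        }
        assert max(dist, key=dist.get) == frozenset(("GC", "EC"))

    def test_single_group_still_produces_scores(self):
        rng = np.random.default_rng(4)
        df = _df(x=rng.normal(size=20), y=rng.normal(size=20))
        prof = pca_profile(df, group_col="grp", params=("x", "y"))
        assert len(prof.scores) == 20

    def test_explained_variance_non_increasing(self, mixed_measured):
        prof = pca_profile(mixed_measured)
        assert (np.diff(prof.explained_variance_ratio) <= 1e-12).all()


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"v": np.concatenate([x, x]),
                           "grp": ["a"] * 20 + ["b"] * 20})
        table = nm.compare_groups(df, "grp", "v")
        welch = table[table["test"] == "welch_t"].iloc[0]
        anova = table[table["test"] == "anova"].iloc[0]
        assert welch["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert welch["p_value"] == pytest.approx(1.0, abs=1e-12)
        assert anova["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_three_sigma_shift_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(3.0, 1.0, 50)
        table = welch_anova_tests({"a": a, "b": b})
        assert (table["p_value"] < 0.001).all()

    def test_anova_power_one_shifted_group(self):
        # three groups, one shifted by 1.5 sd, n=30: rejects at 0.05 with
        # power > 0.9 (checked over 200 replicates)
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(200):
            groups = {
                "a": rng.normal(0, 1, 30),
                "b": rng.normal(0, 1, 30),
                "c": rng.normal(1.5, 1, 30),
            }
            table = welch_anova_tests(groups)
            p = float(table.loc[table["test"] == "anova", "p_value"].iloc[0])
            hits += p < 0.05
        assert hits / 200 > 0.9

    def test_welch_reduces_to_student_with_equal_variances(self):
        # identical sample variances and sizes: Welch df equals Student df
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 0.7
        welch = stats.ttest_ind(a, b, equal_var=False)
        student = stats.ttest_ind(a, b, equal_var=True)
        table = welch_anova_tests({"a": a, "b": b})
        ours = table[table["test"] == "welch_t"].iloc[0]
        assert ours["statistic"] == pytest.approx(student.statistic, abs=1e-6)
        assert ours["p_value"] == pytest.approx(student.pvalue, abs=1e-6)
        assert welch.pvalue == pytest.approx(student.pvalue, abs=1e-12)

    def test_type_one_error_at_nominal_level(self, welch_type1_rate):
        assert abs(welch_type1_rate - 0.05) <= 0.01

    def test_degenerate_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_anova_tests({"a": np.array([1.0])})
        with pytest.raises(InsufficientDataError):
            welch_anova_tests({"a": np.array([1.0, 2.0]), "b": np.array([3.0])})

    def test_bh_adjustment_optional(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "v": rng.normal(size=60),
            "grp": np.repeat(["a", "b", "c"], 20),
        })
        table = nm.compare_groups(df, "grp", "v", bh_adjust=True)
        pairwise = table[table["test"] == "welch_t"]
        assert (pairwise["p_adjusted"] >= pairwise["p_value"] - 1e-12).all()


class TestGroupSummary:
    def test_summary_quartiles(self, mixed_measured):
        summary = nm.group_summary(mixed_measured, "true_cell_type")
        rhf = summary[summary["parameter"] == "rhf"].set_index("group")
        assert (rhf["q1"] <= rhf["median"]).all()
        assert (rhf["median"] <= rhf["q3"]).all()
        assert rhf.loc["GC", "mean"] > rhf.loc["EC", "mean"]
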
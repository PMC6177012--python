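"""Normalization, fold change, t-tests, correlation and PCA."""

import numpy as np
import pandas as pd
import pytest
import scipy.special

from midflux.errors import ValidationError
from midflux.stats import (
    SampleTable,
    compare_to_control,
    fold_change_vs_control,
    normalize_table,
    pca_scores,
    pearson_correlation,
    ttest_bonferroni,
)


def make_table(rows, metabolites):
    """rows: (sample_id, group, mass, is_intensity, *values)"""
    df = pd.DataFrame(
        rows, columns=["sample_id", "group", "mass_mg", "is_intensity", *metabolites]
    ).set_index("sample_id")
    return SampleTable(data=df, normalized=False)


def student_t_oracle(a, b):
    """Independent closed-form oracle: pooled-variance t and the two-tailed
    p from the regularized incomplete beta function."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = scipy.special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, df, p


class TestNormalize:
    def test_stated_rule(self):
        """intensity / mass / (IS / reference)."""
        t = make_table([("s1", "g", 10.0, 2.0, 1000.0)], ["lactate"])
        out = normalize_table(t, is_reference_intensity=1.0)
        assert out.data.loc["s1", "lactate"] == pytest.approx(50.0)
        assert "is_intensity" not in out.data.columns
        assert out.normalized

    def test_is_equal_to_reference_is_pure_mass_normalization(self):
        t = make_table(
            [("s1", "g", 4.0, 3.0, 100.0), ("s2", "g", 8.0, 3.0, 100.0)],
            ["lactate"],
        )
        out = normalize_table(t, is_reference_intensity=3.0)
        assert out.data.loc["s1", "lactate"] == pytest.approx(25.0)
        assert out.data.loc["s2", "lactate"] == pytest.approx(12.5)

    def test_mass_linearity(self):
        t = make_table(
            [("s1", "g", 5.0, 1.0, 300.0), ("s2", "g", 10.0, 1.0, 300.0)],
            ["lactate"],
        )
        out = normalize_table(t, is_reference_intensity=1.0)
        assert out.data.loc["s1", "lactate"] == 2 * out.data.loc["s2", "lactate"]

    def test_scale_equivariance(self):
        """Scaling a sample's intensities and its IS by c changes nothing."""
        base = [("s1", "g", 5.0, 2.0, 100.0, 40.0), ("s2", "g", 6.0, 3.0, 90.0, 50.0)]
        scaled = [base[0], ("s2", "g", 6.0, 3.0 * 7, 90.0 * 7, 50.0 * 7)]
        metabs = ["lactate", "2HG"]
        a = normalize_table(make_table(base, metabs), is_reference_intensity=2.0)
        b = normalize_table(make_table(scaled, metabs), is_reference_intensity=2.0)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_default_reference_is_cohort_median(self):
        t = make_table(
            [("s1", "g", 1.0, 2.0, 10.0), ("s2", "g", 1.0, 4.0, 10.0),
             ("s3", "g", 1.0, 8.0, 10.0)],
            ["lactate"],
        )
        out = normalize_table(t)  # median IS = 4
        assert out.data.loc["s2", "lactate"] == pytest.approx(10.0)

    def test_bad_mass_names_sample(self):
        t = make_table([("bad_s", "g", 0.0, 1.0, 10.0)], ["lactate"])
        with pytest.raises(ValidationError, match="bad_s"):
            normalize_table(t)


class TestFoldChange:
    def test_control_maps_to_one_and_test_scales(self):
        t = make_table(
            [("c1", "ctrl", 1, 1, 2.0), ("c2", "ctrl", 1, 1, 2.0),
             ("c3", "ctrl", 1, 1, 2.0), ("t1", "mut", 1, 1, 3.0)],
            ["lactate"],
        )
        t.normalized = True
        rel = fold_change_vs_control(t, "ctrl")
        np.testing.assert_allclose(
            rel.loc[["c1", "c2", "c3"], "lactate"], 1.0
        )
        assert rel.loc["t1", "lactate"] == pytest.approx(1.5)

    def test_zero_control_mean_excluded(self):
        t = make_table(
            [("c1", "ctrl", 1, 1, 0.0, 5.0), ("c2", "ctrl", 1, 1, 0.0, 5.0),
             ("t1", "mut", 1, 1, 2.0, 6.0)],
            ["dead", "lactate"],
        )
        t.normalized = True
        rel = fold_change_vs_control(t, "ctrl")
        assert "dead" not in rel.columns and "lactate" in rel.columns

    def test_unknown_control_rejected(self):
        t = make_table([("s1", "g", 1, 1, 1.0)], ["lactate"])
        with pytest.raises(ValidationError):
            fold_change_vs_control(t, "nope")


class TestTTestBonferroni:
    def test_matches_incomplete_beta_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t_exp, df_exp, p_exp = student_t_oracle(a, b)
        out = ttest_bonferroni({"lactate": (a, b)}, m=1)
        row = out.iloc[0]
        assert row["t"] == pytest.approx(t_exp, abs=1e-9)
        assert row["t"] == pytest.approx(-3.6742346, abs=1e-6)
        assert row["df"] == df_exp == 4
        assert row["p"] == pytest.approx(p_exp, abs=1e-9)
        assert row["p"] == pytest.approx(0.0214, abs=5e-4)

    def test_family_size_scales_p(self):
        out = ttest_bonferroni({"lactate": ([1, 2, 3], [4, 5, 6])}, m=8)
        row = out.iloc[0]
        assert row["p_adj"] == pytest.approx(8 * row["p"])
        assert row["p_adj"] == pytest.approx(0.171, abs=2e-3)
        assert not row["significant"]

    def test_identical_groups_are_null(self):
        out = ttest_bonferroni({"x": ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])})
        assert out.iloc[0]["t"] == 0.0
        assert out.iloc[0]["p"] == 1.0

    @pytest.mark.parametrize("p", [1e-6, 1e-3, 0.01, 0.2, 0.9])
    @pytest.mark.parametrize("m", [1, 2, 8, 100])
    def test_bonferroni_dominance_grid(self, p, m):
        """p_adj = min(1, m*p) >= p, with equality at m=1."""
        p_adj = min(1.0, m * p)
        assert p_adj >= p
        if m == 1:
            assert p_adj == p

    def test_zero_variance_distinct_means_degenerate(self):
        out = ttest_bonferroni({"x": ([1.0, 1.0], [2.0, 2.0])})
        row = out.iloc[0]
        assert row["degenerate"] and row["p"] == 0.0 and np.isinf(row["t"])

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = ttest_bonferroni({"x": ([1.0], [1.0, 2.0])})
        assert out.empty

    def test_family_smaller_than_tests_rejected(self):
        groups = {"a": ([1, 2], [3, 4]), "b": ([1, 2], [3, 4])}
        with pytest.raises(ValidationError, match="family size"):
            ttest_bonferroni(groups, m=1)

    def test_welch_option_differs_under_unequal_variance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, -10.0, 50.0, 20.0, 0.0]
        student = ttest_bonferroni({"x": (a, b)}, equal_var=True).iloc[0]
        welch = ttest_bonferroni({"x": (a, b)}, equal_var=False).iloc[0]
        assert welch["df"] != student["df"]


class TestCompareToControl:
    def test_pairwise_deletion_for_missing_values(self):
        t = make_table(
            [("c1", "ctrl", 1, 1, 1.0, 2.0), ("c2", "ctrl", 1, 1, 1.1, 2.1),
             ("c3", "ctrl", 1, 1, 0.9, np.nan),
             ("m1", "mut", 1, 1, 2.0, 4.0), ("m2", "mut", 1, 1, 2.1, 4.1)],
            ["lactate", "2HG"],
        )
        t.normalized = True
        out = compare_to_control(t, "ctrl").set_index("metabolite")
        # 2HG test used n=2 vs n=2 -> df 2; lactate n=2 vs n=3 -> df 3
        assert out.loc["2HG", "df"] == 2
        assert out.loc["lactate", "df"] == 3

    def test_multi_group_requires_explicit_test_group(self):
        t = make_table(
            [("a", "g1", 1, 1, 1.0), ("b", "g2", 1, 1, 1.0), ("c", "g3", 1, 1, 1.0)],
            ["lactate"],
        )
        t.normalized = True
        with pytest.raises(ValidationError, match="test_group"):
            compare_to_control(t, "g1")


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(5.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_independent_data_has_small_r(self):
        """Null Monte-Carlo: for independent draws at n=400, |r| stays
        well below 0.2 for the seeded draws."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            r, _ = pearson_correlation(
                rng.standard_normal(400), rng.standard_normal(400)
            )
            assert abs(r) < 0.2


class TestPCA:
    def _random_table(self, seed=5, n=12, k=6):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.lognormal(0, 0.3, size=(n, k)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"met{j}" for j in range(k)],
        )
        df.insert(0, "group", ["a"] * (n // 2) + ["b"] * (n - n // 2))
        t = SampleTable(data=df, normalized=True)
        return t

    def test_rank_one_structure_loads_on_pc1(self):
        """A pure colinear group-mean shift with no noise puts all
        variance on PC1."""
        rows = [("c%d" % i, "ctrl", 1, 1, 1.0, 10.0) for i in range(3)]
        rows += [("m%d" % i, "mut", 1, 1, 2.0, 20.0) for i in range(3)]
        t = make_table(rows, ["a", "b"])
        t.normalized = True
        res = pca_scores(t, scaling="center_only")
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("scaling", ["autoscale", "center_only"])
    def test_loadings_orthonormal(self, scaling):
        res = pca_scores(self._random_table(), scaling=scaling)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_explained_variance_non_increasing_and_bounded(self):
        res = pca_scores(self._random_table())
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    @pytest.mark.parametrize("scaling", ["autoscale", "center_only"])
    def test_reconstruction_with_all_components(self, scaling):
        t = self._random_table()
        res = pca_scores(t, scaling=scaling)
        X = t.intensities().to_numpy()
        X = X - X.mean(axis=0)
        if scaling == "autoscale":
            X = X / t.intensities().std(axis=0, ddof=1).to_numpy()
        S = res.scores.drop(columns="group").to_numpy()
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(S @ L.T, X, atol=1e-8)

    def test_permutation_equivariance(self):
        t = self._random_table()
        perm = np.random.default_rng(3).permutation(len(t.data))
        tp = SampleTable(data=t.data.iloc[perm], normalized=True)
        a = pca_scores(t).scores.drop(columns="group")
        b = pca_scores(tp).scores.drop(columns="group")
        pd.testing.assert_frame_equal(a.iloc[perm].abs(), b.abs(), atol=1e-8)

    def test_sign_convention_deterministic(self):
        res = pca_scores(self._random_table())
        for pc in res.loadings.columns:
            col = res.loadings[pc]
            assert col.iloc[int(np.argmax(col.abs().to_numpy()))] > 0

    def test_zero_variance_metabolite_dropped(self):
        rows = [("s%d" % i, "g", 1, 1, 5.0, float(i), float(2 * i)) for i in range(4)]
        t = make_table(rows, ["flat", "a", "b"])
        t.normalized = True
        res = pca_scores(t)
        assert res.dropped_metabolites == ["flat"]
        assert "flat" not in res.loadings.index

    def test_single_sample_rejected(self):
        t = make_table([("s1", "g", 1, 1, 1.0, 2.0)], ["a", "b"])
        t.normalized = True
        with pytest.raises(ValidationError):
            pca_scores(t)
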
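"""Descriptive statistics, correlation matrices and metal clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aquarisk.stats import (
    cluster_metals,
    correlation_long,
    correlation_matrix,
    describe,
    describe_table,
)


def vector_with_moments(mean, sd, n, rng):
    """Construct a vector with the exact requested sample mean and SD."""
    v = rng.standard_normal(n)
    v = (v - v.mean()) / v.std(ddof=1)
    return v * sd + mean


class TestDescribe:
    def test_tap_water_arsenic_cv(self, rng):
        """mean 1.05, SD 3.84 -> CV ~ 365.7 (published prints 365), 'high'."""
        v = vector_with_moments(1.05, 3.84, 21, rng)
        r = describe(v, "As", "TW")
        assert r.mean == pytest.approx(1.05, rel=1e-9)
        assert r.sd == pytest.approx(3.84, rel=1e-9)
        assert r.cv == pytest.approx(365.0, rel=0.01)
        assert r.cv_label == "high"

    def test_constant_vector(self):
        r = describe([2.0, 2.0, 2.0])
        assert r.sd == 0.0 and r.cv == 0.0 and r.cv_label == "low"

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            r = describe([5.0])
        assert r.sd == 0.0 and r.n == 1

    def test_zero_mean_with_spread_is_na(self):
        r = describe([-1.0, 1.0])
        assert r.cv is None and r.cv_label == "n/a"

    @settings(max_examples=50, derandomize=True)
    @given(
        vals=st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=3, max_size=30),
        factor=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_permutation_and_scale_behaviour(self, vals, factor):
        """Permutation-invariant; mean/sd scale, CV invariant to positive scaling."""
        base = describe(vals)
        perm = describe(list(reversed(vals)))
        assert perm.mean == pytest.approx(base.mean, rel=1e-12)
        assert perm.sd == pytest.approx(base.sd, rel=1e-9, abs=1e-12)
        scaled = describe([v * factor for v in vals])
        assert scaled.mean == pytest.approx(base.mean * factor, rel=1e-9)
        assert scaled.sd == pytest.approx(base.sd * factor, rel=1e-6, abs=1e-9)
        if base.cv is not None and base.sd > 1e-9:
            assert scaled.cv == pytest.approx(base.cv, rel=1e-6, abs=1e-9)

    def test_describe_table_long_format(self, small_campaign):
        from aquarisk.campaign import samples_to_frame

        df = samples_to_frame(small_campaign)
        out = describe_table(df, ["As_mgL", "pH"], group_col="source_type")
        assert len(out) == 6  # 2 variables x 3 groups
        assert set(out.columns) >= {"variable", "group", "n", "mean", "sd", "cv", "cv_label"}


class TestCorrelation:
    def test_diagonal_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        r, p = correlation_matrix(df, list("abcd"))
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(p, p.T, equal_nan=True)

    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10]})
        r, p = correlation_matrix(df, ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 1e-6

    def test_bivariate_normal_recovers_rho(self, rng):
        n, rho = 10_000, 0.8
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        r, _ = correlation_matrix(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert abs(r.loc["x", "y"] - rho) < 3 / np.sqrt(n)

    def test_affine_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["u", "v"])
        r0, _ = correlation_matrix(df, ["u", "v"])
        df2 = df.assign(u=3.0 * df["u"] + 7.0)
        r1, _ = correlation_matrix(df2, ["u", "v"])
        assert r1.loc["u", "v"] == pytest.approx(r0.loc["u", "v"], rel=1e-9)

    def test_zero_variance_flagged_nan(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "k": np.full(20, 3.0)})
        with pytest.warns(UserWarning):
            r, _ = correlation_matrix(df, ["x", "k"])
        assert np.isnan(r.loc["x", "k"])

    def test_spearman_option_and_long_format(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        r, p = correlation_matrix(df, list("abc"), method="spearman")
        long = correlation_long(r, p)
        assert len(long) == 3
        assert set(long.columns) == {"var1", "var2", "r", "p", "stars"}


class TestClustering:
    def test_duplicated_variables_merge_first_at_zero(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        tree = cluster_metals(df, ["a", "b", "c"])
        first = tree.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # a and b
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_two_identical_plus_orthogonal_topology(self, rng):
        n = 40
        x = rng.normal(size=n)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=n)})
        tree = cluster_metals(df, ["a", "b", "c"])
        cut = tree.cut(2)
        assert cut["a"] == cut["b"] != cut["c"]

    def test_planted_blocks_recovered(self, rng):
        """Two blocks of correlated metals; cut at 2 recovers the blocks.

        Oracle: pairwise distances between z-scored profiles are smaller
        within blocks than across, by construction."""
        n = 100
        f1 = rng.standard_normal(n)
        f2 = rng.standard_normal(n)
        noise = 0.2
        df = pd.DataFrame(
            {
                "As": f1 + noise * rng.standard_normal(n),
                "Pb": f1 + noise * rng.standard_normal(n),
                "Ni": f1 + noise * rng.standard_normal(n),
                "Fe": f2 + noise * rng.standard_normal(n),
                "Mn": f2 + noise * rng.standard_normal(n),
                "Zn": f2 + noise * rng.standard_normal(n),
            }
        )
        # brute-force oracle on the planted design
        z = {c: (df[c] - df[c].mean()) / df[c].std(ddof=1) for c in df}
        within = np.linalg.norm(z["As"] - z["Pb"])
        across = np.linalg.norm(z["As"] - z["Fe"])
        assert within < across
        tree = cluster_metals(df, list(df.columns))
        cut = tree.cut(2)
        assert cut["As"] == cut["Pb"] == cut["Ni"]
        assert cut["Fe"] == cut["Mn"] == cut["Zn"]
        assert cut["As"] != cut["Fe"]

    def test_heights_nondecreasing_and_merge_count(self, small_campaign):
        from aquarisk.campaign import samples_to_frame
        from aquarisk.reference import METALS

        df = samples_to_frame(small_campaign)
        cols = [f"{m}_mgL" for m in METALS]
        tree = cluster_metals(df, cols)
        heights = tree.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
        assert tree.merges.shape[0] == len(tree.labels) - 1

    def test_variable_order_invariance_up_to_ties(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("wxyz"))
        t1 = cluster_metals(df, ["w", "x", "y", "z"])
        t2 = cluster_metals(df, ["z", "y", "x", "w"])
        assert np.allclose(np.sort(t1.merges[:, 2]), np.sort(t2.merges[:, 2]))

    def test_zero_variance_excluded_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20),
                           "k": np.full(20, 1.0)})
        with pytest.warns(UserWarning):
            tree = cluster_metals(df, ["a", "b", "k"])
        assert tree.labels == ("a", "b")

    def test_fewer_than_two_variables_rejected(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            cluster_metals(df, ["a"])
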
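"""MICI algebra, k-NN pruning behaviour and subset quality metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from earsim.selection import (
    choose_k,
    mici,
    mici_matrix,
    select_features,
    select_for_pair,
    subset_quality,
    zscore_normalize,
)


def zscore(x):
    return (x - x.mean()) / x.std()


class TestZScore:
    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5.0, 3.0, size=(50, 4)), columns=list("abcd"))
        z, constant = zscore_normalize(df)
        assert constant == []
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.var(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_constant_column_flagged_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        z, constant = zscore_normalize(df)
        assert constant == ["b"]
        assert np.allclose(z["b"], 0.0)

    def test_separate_vs_pooled_differ_when_means_differ(self):
        a = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        b = pd.DataFrame({"x": [10.0, 11.0, 12.0]})
        za, _ = zscore_normalize(a)
        zb, _ = zscore_normalize(b)
        pooled, _ = zscore_normalize(pd.concat([a, b], ignore_index=True))
        assert np.allclose(za["x"], zb["x"])
        assert not np.allclose(pooled["x"][:3], za["x"])


class TestMICI:
    def test_perfectly_dependent_pair_is_zero(self):
        rng = np.random.default_rng(1)
        x = zscore(rng.standard_normal(100))
        assert mici(x, 2.0 * x) == pytest.approx(0.0, abs=1e-12)
        assert mici(x, -x) == pytest.approx(0.0, abs=1e-12)

    def test_unit_variance_closed_form(self):
        """On standardized columns the formula collapses to 1 - |rho|."""
        rng = np.random.default_rng(2)
        x = zscore(rng.standard_normal(500))
        noise = zscore(rng.standard_normal(500))
        y = zscore(0.6 * x + 0.8 * noise)
        rho = np.corrcoef(x, y)[0, 1]
        assert mici(x, y) == pytest.approx(1.0 - abs(rho), abs=1e-10)

    def test_var4_var1_uncorrelated(self):
        """var x = 4, var y = 1, rho = 0 -> lambda2 = 1 exactly."""
        n = 1000
        rng = np.random.default_rng(3)
        x = zscore(rng.standard_normal(n)) * 2.0
        y = zscore(rng.standard_normal(n))
        # orthogonalize to force rho = 0 exactly
        y = zscore(y - (y @ x) / (x @ x) * x)
        assert mici(x, y) == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_identity_on_random_standardized_pairs(self, seed):
        rng = np.random.default_rng(seed)
        x = zscore(rng.standard_normal(64))
        y = zscore(rng.standard_normal(64))
        assert mici(x, y) == pytest.approx(1.0 - abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_zero_variance_defined_zero(self):
        assert mici(np.ones(10), np.arange(10.0)) == 0.0

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
        z, _ = zscore_normalize(df)
        mat = mici_matrix(z)
        for a in z.columns:
            for b in z.columns:
                expected = 0.0 if a == b else mici(z[a].to_numpy(), z[b].to_numpy())
                assert mat.loc[a, b] == pytest.approx(expected, abs=1e-10)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)


def correlated_frame(n=60, seed=5):
    """Four features where d = a + small noise (a/d nearly duplicate)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    c = rng.standard_normal(n)
    d = a + 1e-3 * rng.standard_normal(n)
    df = pd.DataFrame({"a": a, "b": b, "c": c, "d": d})
    return zscore_normalize(df)[0]


class TestSelection:
    def test_duplicate_column_pruned(self):
        z = correlated_frame()
        z["dup"] = z["a"]
        res = select_features(z, k=1)
        assert not ({"a", "dup"} <= set(res.selected))

    def test_near_duplicate_pair_pruned_first(self):
        z = correlated_frame()
        res = select_features(z, k=1)
        # the a/d pair has the smallest 1-NN radius: one of them discards the other
        discards = {kept: set(gone) for kept, gone in res.discard_log.items()}
        assert ("a" in discards and "d" in discards["a"]) or (
            "d" in discards and "a" in discards["d"]
        )

    def test_subset_size_non_increasing_in_k(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((80, 10)))
        df.columns = [f"f{i}" for i in range(10)]
        z, _ = zscore_normalize(df)
        sizes = [len(select_features(z, k).selected) for k in range(1, 8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_discard_log_partitions_features(self):
        z = correlated_frame()
        res = select_features(z, k=2)
        discarded = {f for gone in res.discard_log.values() for f in gone}
        assert set(res.selected) | discarded == set(z.columns)
        assert not set(res.selected) & discarded

    def test_invalid_k(self):
        z = correlated_frame()
        with pytest.raises(ValueError):
            select_features(z, k=0)
        with pytest.raises(ValueError):
            select_features(z, k=4)


class TestSubsetQuality:
    def test_identity_covariance_max_entropy(self):
        rng = np.random.default_rng(7)
        n, d = 20000, 4
        df = pd.DataFrame(rng.standard_normal((n, d)), columns=list("abcd"))
        rep_h, red = subset_quality(df, list("abcd"))
        assert rep_h == pytest.approx(np.log(d), abs=0.01)
        assert red < 0.05

    def test_perfectly_correlated_pair(self):
        x = np.random.default_rng(8).standard_normal(100)
        df = pd.DataFrame({"a": x, "b": 3.0 * x})
        rep_h, red = subset_quality(df, ["a", "b"])
        assert rep_h == pytest.approx(0.0, abs=1e-9)
        assert red == pytest.approx(1.0)

    def test_redundancy_rate_is_mean_abs_corr(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(20000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(20000)
        df = pd.DataFrame({"a": x, "b": y})
        _, red = subset_quality(df, ["a", "b"])
        assert red == pytest.approx(0.5, abs=0.02)


class TestChooseK:
    def test_single_element_grid(self):
        z = correlated_frame()
        k, _ = choose_k(z, [2])
        assert k == 2

    def test_duplicated_features_resolved(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal((60, 3))
        df = pd.DataFrame(
            np.hstack([base, base + 1e-6 * rng.standard_normal((60, 3))]),
            columns=list("abcABC"),
        )
        z, _ = zscore_normalize(df)
        _, res = choose_k(z)
        # no duplicate pair survives
        pairs = {frozenset(p) for p in (("a", "A"), ("b", "B"), ("c", "C"))}
        kept = set(res.selected)
        assert not any(p <= kept for p in pairs)

    def test_deterministic(self):
        z = correlated_frame()
        assert choose_k(z)[0] == choose_k(z)[0]

    def test_empty_grid(self):
        z = correlated_frame()
        with pytest.raises(ValueError):
            choose_k(z, [])


def test_select_for_pair_shares_one_subset():
    rng = np.random.default_rng(11)
    da = pd.DataFrame(rng.standard_normal((30, 6)), columns=list("abcdef"))
    db = pd.DataFrame(rng.standard_normal((30, 6)) + 5.0, columns=list("abcdef"))
    res = select_for_pair(da, db)
    assert set(res.selected) <= set("abcdef")
    assert len(res.selected) >= 2
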
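"""PDF estimation contracts, JSD algebra against brute-force/scipy oracles,
JSD-FSI aggregation and pair combinatorics."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from earsim.features import FeatureDataset
from earsim.montage import MONTAGE_21, infer_role
from earsim.similarity import (
    PairScore,
    estimate_pdf,
    jsd,
    jsd_fsi,
    pair_class,
    similarity_report,
)


class TestEstimatePDF:
    def test_identical_samples_identical_pdfs(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        p, q = estimate_pdf(x, x.copy())
        assert np.allclose(p.prob, q.prob)
        assert np.allclose(p.grid, q.grid)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            p, q = estimate_pdf(rng.standard_normal(30), rng.exponential(size=40))
            assert p.prob.sum() == pytest.approx(1.0, abs=1e-9)
            assert q.prob.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p.prob >= 0) and np.all(q.prob >= 0)

    def test_two_constants_become_disjoint_point_masses(self):
        p, q = estimate_pdf(np.full(10, -2.0), np.full(10, 3.0))
        assert np.count_nonzero(p.prob) == 1
        assert np.count_nonzero(q.prob) == 1
        assert np.argmax(p.prob) != np.argmax(q.prob)
        assert jsd(p, q) == pytest.approx(1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="minimum size"):
            estimate_pdf(np.arange(3.0), np.arange(10.0))

    def test_nan_values_dropped_before_size_check(self):
        a = np.array([1.0, np.nan, 2.0, 3.0, np.nan, 4.0, 5.0])
        p, q = estimate_pdf(a, np.arange(10.0))
        assert p.prob.sum() == pytest.approx(1.0, abs=1e-9)

    def test_histogram_estimator_available(self):
        rng = np.random.default_rng(2)
        p, q = estimate_pdf(
            rng.standard_normal(40), rng.standard_normal(40), estimator="histogram"
        )
        assert p.estimator == "histogram"
        assert p.prob.sum() == pytest.approx(1.0, abs=1e-9)


def brute_jsd(p, q):
    """Direct base-2 summation of the KL-to-mixture definition."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = (p + q) / 2.0
    kl_pm = sum(pi * np.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0)
    kl_qm = sum(qi * np.log2(qi / mi) for qi, mi in zip(q, m) if qi > 0)
    return (kl_pm + kl_qm) / 2.0


class TestJSD:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd(p, p.copy()) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_supports_is_one(self):
        assert jsd(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_worked_two_bin_example(self):
        """p=(1,0), q=(0.5,0.5) -> 0.3113 by direct base-2 summation."""
        val = jsd(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert val == pytest.approx(0.3113, abs=1e-4)

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.dirichlet(np.ones(rng.integers(2, 12)))
            q = rng.dirichlet(np.ones(len(p)))
            v = jsd(p, q)
            assert v == jsd(q, p)
            assert -1e-12 <= v <= 1.0 + 1e-12

    def test_brute_force_oracle_to_1e12(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(2, 20)
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            assert jsd(p, q) == pytest.approx(brute_jsd(p, q), abs=1e-12)

    def test_matches_scipy_squared_distance(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(16))
        q = rng.dirichlet(np.ones(16))
        assert jsd(p, q) == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        p, _ = estimate_pdf(rng.standard_normal(20), rng.standard_normal(20))
        q, _ = estimate_pdf(rng.standard_normal(20) + 50, rng.standard_normal(20) + 50)
        with pytest.raises(ValueError, match="grid"):
            jsd(p, q)


def make_fd(channel, data, stage="NREM"):
    return FeatureDataset("S01", channel, stage, pd.DataFrame(data))


class TestJsdFsi:
    def test_self_comparison_is_one(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"f1": rng.standard_normal(30), "f2": rng.standard_normal(30)})
        score = jsd_fsi(make_fd("A", df), make_fd("B", df.copy()), ["f1", "f2"])
        assert score.score == pytest.approx(1.0)

    def test_disjoint_features_score_zero(self):
        a = pd.DataFrame({"f1": np.full(10, 0.0)})
        b = pd.DataFrame({"f1": np.full(10, 100.0)})
        score = jsd_fsi(make_fd("A", a), make_fd("B", b), ["f1"])
        assert score.score == pytest.approx(0.0)

    def test_mean_of_one_minus_jsd(self):
        """Two features with JSD j1 and j2 -> score = 1 - (j1+j2)/2."""
        rng = np.random.default_rng(8)
        a = pd.DataFrame({"f1": rng.standard_normal(60), "f2": rng.standard_normal(60)})
        b = pd.DataFrame({"f1": rng.standard_normal(60) + 1.0, "f2": rng.standard_normal(60) + 3.0})
        score = jsd_fsi(make_fd("A", a), make_fd("B", b), ["f1", "f2"])
        expected = np.mean([1.0 - v for v in score.per_feature.values()])
        assert score.score == pytest.approx(expected, abs=1e-12)
        assert score.per_feature["f2"] > score.per_feature["f1"]

    def test_short_feature_skipped_and_excluded_from_n(self):
        rng = np.random.default_rng(9)
        a = pd.DataFrame(
            {"f1": rng.standard_normal(20),
             "f2": np.r_[rng.standard_normal(3), [np.nan] * 17]}
        )
        b = pd.DataFrame({"f1": rng.standard_normal(20), "f2": rng.standard_normal(20)})
        score = jsd_fsi(make_fd("A", a), make_fd("B", b), ["f1", "f2"])
        assert score.skipped == ["f2"]
        assert score.n_features == 1

    def test_no_usable_features_raises(self):
        a = pd.DataFrame({"f1": [np.nan] * 10})
        b = pd.DataFrame({"f1": np.arange(10.0)})
        with pytest.raises(ValueError, match="no usable"):
            jsd_fsi(make_fd("A", a), make_fd("B", b), ["f1"])


class TestPairClass:
    @pytest.mark.parametrize(
        "ra,rb,cls",
        [
            ("scalp-EEG", "in-ear", "PSG-to-in-ear"),
            ("EOG", "in-ear", "PSG-to-in-ear"),
            ("scalp-EEG", "scalp-EEG", "scalp-to-scalp"),
            ("mastoid", "scalp-EEG", "scalp-to-scalp"),
            ("EOG", "EOG", "EOG-to-EOG"),
            ("scalp-EEG", "EOG", "scalp-to-EOG"),
        ],
    )
    def test_classes(self, ra, rb, cls):
        assert pair_class(ra, rb) == cls


class TestPairCombinatorics:
    def _datasets(self, channels, n=8, n_feat=2, seed=0):
        rng = np.random.default_rng(seed)
        datasets, roles = {}, {}
        for ch in channels:
            datasets[ch] = {
                "NREM": make_fd(
                    ch,
                    {f"f{i}": rng.standard_normal(n) for i in range(n_feat)},
                )
            }
            roles[ch] = infer_role(ch)
        return datasets, roles

    def test_montage_emits_21_and_210_scores(self):
        """Full 21-channel montage + CH1: 21 in-ear pairs and C(21,2)=210
        PSG-to-PSG pairs per stage."""
        channels = list(MONTAGE_21) + ["CH1"]
        datasets, roles = self._datasets(channels)
        scores, _ = similarity_report(datasets, roles, k_grid=[1])
        inear = scores[scores["pair_class"] == "PSG-to-in-ear"]
        psg = scores[scores["pair_class"] != "PSG-to-in-ear"]
        assert len(inear) == 21
        assert len(psg) == 210

    def test_each_pair_computed_once(self):
        channels = ["C3-M2", "O1-M2", "E1-M2", "CH1"]
        datasets, roles = self._datasets(channels)
        scores, _ = similarity_report(datasets, roles, k_grid=[1])
        pairs = {frozenset((a, b)) for a, b in zip(scores["chan_a"], scores["chan_b"])}
        assert len(pairs) == len(scores)

    def test_symmetry_of_score(self):
        rng = np.random.default_rng(10)
        a = pd.DataFrame({"f1": rng.standard_normal(25), "f2": rng.standard_normal(25)})
        b = pd.DataFrame({"f1": rng.standard_normal(25) + 0.5, "f2": rng.standard_normal(25)})
        s_ab = jsd_fsi(make_fd("A", a), make_fd("B", b), ["f1", "f2"])
        s_ba = jsd_fsi(make_fd("B", b), make_fd("A", a), ["f1", "f2"])
        assert s_ab.score == pytest.approx(s_ba.score, abs=1e-12)
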
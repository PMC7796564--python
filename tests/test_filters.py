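"""Welch and information-theoretic feature filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dilearn as dl
from dilearn.filters import (
    FeatureRanking,
    estimate_fdr,
    info_rank_1d,
    info_rank_2d,
    top_n,
    welch_rank,
)


def brute_welch(a, b):
    """Independent oracle: Welch t from the textbook formula."""
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestWelch:
    def test_hand_computed_t(self):
        X = pd.DataFrame({"f": [0, 1, 2, 3, 4, 5]})
        y = [1, 1, 1, 0, 0, 0]
        r = welch_rank(X, y)
        assert r.table.loc[0, "score"] == pytest.approx(3.674, abs=1e-3)

    def test_identical_classes_score_zero(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]})
        r = welch_rank(X, [1, 1, 0, 0])
        assert r.table.loc[0, "score"] == pytest.approx(0.0)
        assert r.table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_constant_feature_degenerate(self):
        X = pd.DataFrame({"f": [3.0] * 8})
        r = welch_rank(X, [1, 1, 1, 1, 0, 0, 0, 0])
        assert r.table.loc[0, "score"] == 0.0
        assert r.table.loc[0, "p_value"] == 1.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.standard_normal((20, 10))
            y = np.array([1] * 9 + [0] * 11)
            r = welch_rank(pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(10)]), y)
            table = r.table.set_index("feature_id")
            for j in range(10):
                t, p = brute_welch(X[y == 1, j], X[y == 0, j])
                assert table.loc[f"f{j:02d}", "score"] == pytest.approx(abs(t), abs=1e-10)
                assert table.loc[f"f{j:02d}", "p_value"] == pytest.approx(p, abs=1e-10)

    def test_strong_feature_ranks_first(self):
        rng = np.random.default_rng(11)
        n = 200
        y = np.array([1] * 100 + [0] * 100)
        X = rng.standard_normal((n, 500))
        X[:, 137] += 3.0 * y
        cols = [f"f{i:03d}" for i in range(500)]
        r = welch_rank(pd.DataFrame(X, columns=cols), y)
        assert r.table.loc[0, "feature_id"] == "f137"


class TestInfo1D:
    def test_perfect_binary_feature_is_one_bit(self):
        y = np.array([1, 0] * 20)
        X = pd.DataFrame({"f": y.astype(float)})
        r = info_rank_1d(X, y, bins=2, n_discretizations=5, seed=0)
        assert r.table.loc[0, "score"] == pytest.approx(1.0, abs=1e-12)
        assert r.table.loc[0, "p_value"] < 1e-6

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 2000)
        X = pd.DataFrame({"f": rng.standard_normal(2000)})
        r = info_rank_1d(X, y, seed=0)
        assert r.table.loc[0, "score"] < 0.005

    def test_constant_feature_zero_gain(self):
        y = np.array([1, 0] * 10)
        X = pd.DataFrame({"f": np.ones(20)})
        r = info_rank_1d(X, y, seed=0)
        assert r.table.loc[0, "score"] == 0.0
        assert r.table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_scores_nonnegative(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((60, 200)))
        y = rng.integers(0, 2, 60)
        r = info_rank_1d(X, y, bins=3, n_discretizations=10, seed=1)
        assert (r.table["score"] >= -1e-12).all()

    def test_null_type_one_error_calibrated(self):
        """On null data the p-value distribution should put ~alpha mass below alpha."""
        alpha = 0.05
        fractions = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.standard_normal((100, 1000)))
            y = rng.integers(0, 2, 100)
            r = info_rank_1d(X, y, seed=seed)
            fractions.append((r.table["p_value"] < alpha).mean())
        # binomial noise around alpha for 1000 features; the G-test on
        # averaged gains is mildly conservative, so allow a one-sided margin
        assert np.mean(fractions) < alpha + 3 * np.sqrt(alpha * (1 - alpha) / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((50, 30)))
        y = rng.integers(0, 2, 50)
        r1 = info_rank_1d(X, y, seed=9)
        r2 = info_rank_1d(X, y, seed=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)


def xor_frame(n=400, seed=0):
    """Balanced XOR construction: y is the parity of two binary features,
    each marginally independent of y, plus noise features."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    y = (a + b) % 2
    X = pd.DataFrame(
        {
            "xa": a.astype(float),
            "xb": b.astype(float),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        }
    )
    return X, y


class TestInfo2D:
    def test_xor_pair_found_only_by_2d(self):
        X, y = xor_frame(seed=1)
        r1 = info_rank_1d(X, y, n_discretizations=10, seed=0).table.set_index("feature_id")
        r2 = info_rank_2d(X, y, n_discretizations=10, seed=0).table.set_index("feature_id")
        assert r1.loc["xa", "score"] < 0.05
        assert r1.loc["xb", "score"] < 0.05
        assert r2.loc["xa", "score"] > 0.9
        assert r2.loc["xb", "score"] > 0.9

    def test_perfect_feature_keeps_its_information(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 200)
        X = pd.DataFrame(
            {"perfect": y.astype(float), "n1": rng.standard_normal(200), "n2": rng.standard_normal(200)}
        )
        s1 = info_rank_1d(X, y, n_discretizations=10, seed=0).table.set_index("feature_id")
        s2 = info_rank_2d(X, y, n_discretizations=10, seed=0).table.set_index("feature_id")
        assert s2.loc["perfect", "score"] >= s1.loc["perfect", "score"] - 0.05

    def test_single_feature_falls_back_to_1d(self):
        y = np.array([1, 0] * 10)
        X = pd.DataFrame({"f": y.astype(float)})
        with pytest.warns(UserWarning):
            r = info_rank_2d(X, y, n_discretizations=5, seed=0)
        assert r.method == "info2d"
        assert r.table.loc[0, "score"] == pytest.approx(1.0, abs=1e-12)

    def test_null_scores_small(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((300, 20)))
        y = rng.integers(0, 2, 300)
        r = info_rank_2d(X, y, n_discretizations=10, seed=0)
        assert r.table["score"].max() < 0.15


class TestSelection:
    def _ranking(self, ids, scores, pvals=None):
        table = pd.DataFrame(
            {
                "feature_id": ids,
                "score": scores,
                "p_value": pvals if pvals is not None else np.zeros(len(ids)),
            }
        )
        order = np.lexsort((table["feature_id"], -table["score"]))
        return FeatureRanking(table=table.iloc[order].reset_index(drop=True), method="welch")

    def test_top_n_basic_and_overlong(self):
        r = self._ranking([f"f{i}" for i in range(10)], np.arange(10)[::-1])
        assert len(top_n(r, 3)) == 3
        assert len(top_n(r, 99)) == 10

    def test_ties_broken_lexically(self):
        r = self._ranking(["zeta", "alpha", "mid"], [1.0, 1.0, 2.0])
        assert list(top_n(r, 2).table["feature_id"]) == ["mid", "alpha"]

    def test_fdr_null_is_one(self):
        rng = np.random.default_rng(0)
        p = rng.random(10000)
        r = self._ranking([f"f{i:05d}" for i in range(10000)], -p, p)
        assert estimate_fdr(r, 100) > 0.8

    def test_fdr_known_value(self):
        # p_(100) = 5e-4 among 10000 features -> 5e-4 * 10000 / 100 = 0.05
        p = np.concatenate([np.linspace(1e-6, 5e-4, 100), np.linspace(0.6, 1.0, 9900)])
        r = self._ranking([f"f{i:05d}" for i in range(10000)], -p, p)
        assert estimate_fdr(r, 100) == pytest.approx(0.05, rel=0.05)

    def test_fdr_all_zero_pvalues(self):
        r = self._ranking([f"f{i}" for i in range(50)], np.arange(50)[::-1], np.zeros(50))
        for k in (1, 25, 50):
            assert estimate_fdr(r, k) == 0.0
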
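"""Transforms, dissimilarities and permutation tests at community level."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

import skbio.stats.distance as skdist

from extremesoil.community import (
    DistanceMatrix,
    bray_curtis_matrix,
    community_resistance_resilience,
    hellinger_transform,
    mantel_test,
    permanova,
    rarefy_counts,
)
from extremesoil.design import records_to_frame
from extremesoil.simulate import CommunitySimParams, StrategySpec, simulate_asv_counts


class TestHellinger:
    def test_single_support_row(self):
        t = pd.DataFrame([[4, 0]], index=["a"])
        out = hellinger_transform(t)
        assert out.iloc[0].tolist() == [1.0, 0.0]

    def test_equal_counts_row(self):
        t = pd.DataFrame([[3, 3, 3, 3]], index=["a"])
        assert np.allclose(hellinger_transform(t).iloc[0], 0.5)

    @given(
        arrays(np.int64, (5, 4), elements=st.integers(0, 100)).filter(
            lambda a: (a.sum(axis=1) > 0).all()
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_rows_have_unit_sum_of_squares(self, counts):
        out = hellinger_transform(pd.DataFrame(counts))
        assert np.allclose(np.square(out.to_numpy()).sum(axis=1), 1.0)

    def test_empty_row_names_the_sample(self):
        t = pd.DataFrame([[1, 2], [0, 0]], index=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            hellinger_transform(t)


class TestRarefaction:
    def test_row_sums_equal_depth(self, random_counts):
        out = rarefy_counts(random_counts, 30, seed=1)
        assert (out.sum(axis=1) == 30).all()

    def test_full_depth_returns_same_multiset(self, random_counts):
        row = random_counts.iloc[[0]]
        depth = int(row.sum(axis=1).iloc[0])
        out = rarefy_counts(row, depth, seed=3)
        assert (out.to_numpy() == row.to_numpy()).all()

    def test_never_exceeds_original_counts(self, random_counts):
        out = rarefy_counts(random_counts, 25, seed=5)
        assert (out.to_numpy() <= random_counts.to_numpy()).all()

    def test_mean_matches_hypergeometric_closed_form(self):
        row = pd.DataFrame([[40, 30, 20, 10]], index=["a"])
        depth = 50
        gen = np.random.default_rng(7)
        draws = np.stack(
            [rarefy_counts(row, depth, seed=gen).to_numpy()[0] for _ in range(600)]
        )
        expected = depth * row.to_numpy()[0] / 100
        assert np.allclose(draws.mean(axis=0), expected, atol=0.6)

    def test_depth_errors(self, random_counts):
        with pytest.raises(ValueError):
            rarefy_counts(random_counts, 0)
        with pytest.raises(ValueError):
            rarefy_counts(random_counts, 10_000)
        depth = int(random_counts.sum(axis=1).median())  # some rows fall below
        with pytest.warns(UserWarning):
            out = rarefy_counts(random_counts, depth, drop_small=True)
        assert len(out) < len(random_counts)
        assert (out.sum(axis=1) == depth).all()


class TestBrayCurtis:
    def test_identical_rows_give_zero(self):
        t = pd.DataFrame([[1, 2, 3], [1, 2, 3]])
        assert bray_curtis_matrix(t).data[0, 1] == 0

    def test_disjoint_supports_give_one(self):
        t = pd.DataFrame([[1, 0], [0, 5]])
        assert bray_curtis_matrix(t).data[0, 1] == 1

    def test_hand_example(self):
        t = pd.DataFrame([[2, 2], [1, 3]])
        assert bray_curtis_matrix(t).data[0, 1] == pytest.approx(0.25)

    @given(
        arrays(
            np.float64, (10, 8),
            elements=st.floats(0, 50, allow_nan=False, allow_infinity=False),
        ).filter(lambda a: (a.sum(axis=1) > 0).all())
    )
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_pair_loop(self, values):
        dm = bray_curtis_matrix(pd.DataFrame(values)).data
        for i in range(10):
            for j in range(i + 1, 10):
                denom = (values[i] + values[j]).sum()
                expected = np.abs(values[i] - values[j]).sum() / denom
                assert abs(dm[i, j] - expected) < 1e-12

    def test_double_zero_rows_flagged(self):
        t = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"))
        with pytest.raises(ValueError):
            bray_curtis_matrix(t, strict=True)
        dm = bray_curtis_matrix(t, strict=False)
        assert np.isnan(dm.data[0, 1])
        assert np.isfinite(dm.data[0, 2])


class TestPermanova:
    def _euclid_1d(self, y):
        ids = tuple(f"s{i}" for i in range(len(y)))
        return DistanceMatrix(ids, squareform(pdist(np.asarray(y)[:, None])))

    def test_matches_classical_anova_in_euclidean_1d_limit(self, rng):
        y = rng.normal(0, 1, 12)
        y[:6] += 1.5
        d = self._euclid_1d(y)
        fac = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=list(d.ids))
        res = permanova(d, fac, ["g"], n_permutations=99, seed=0)
        assert res.pseudo_f[0] == pytest.approx(
            f_oneway(y[:6], y[6:]).statistic, rel=1e-10
        )

    def test_r2_terms_sum_to_one(self, rng):
        x = rng.normal(size=(16, 5))
        d = DistanceMatrix(
            tuple(f"s{i}" for i in range(16)), squareform(pdist(x, "braycurtis"))
        )
        fac = pd.DataFrame(
            {"g": list("abcd") * 4, "h": ["x"] * 8 + ["y"] * 8}, index=list(d.ids)
        )
        res = permanova(d, fac, ["g", "h"], n_permutations=99, seed=1)
        assert sum(res.r2) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_skbio_single_factor(self, rng):
        x = np.abs(rng.normal(size=(14, 6)))
        dm = squareform(pdist(x, "braycurtis"))
        ids = [f"s{i}" for i in range(14)]
        labels = ["a"] * 7 + ["b"] * 7
        res = permanova(
            DistanceMatrix(tuple(ids), dm),
            pd.DataFrame({"g": labels}, index=ids),
            ["g"],
            n_permutations=999,
            seed=0,
        )
        sk = skdist.permanova(skdist.DistanceMatrix(dm, ids), grouping=labels,
                              permutations=999)
        assert res.pseudo_f[0] == pytest.approx(sk["test statistic"], rel=1e-9)
        assert abs(res.p[0] - sk["p-value"]) < 0.05

    def test_strong_shift_reaches_smallest_attainable_p(self, rng):
        x = rng.normal(size=(12, 4))
        x[:6] += 25.0
        d = DistanceMatrix(
            tuple(f"s{i}" for i in range(12)), squareform(pdist(x))
        )
        fac = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=list(d.ids))
        res = permanova(d, fac, ["g"], n_permutations=199, seed=2)
        assert res.p[0] == pytest.approx(1 / 200)

    def test_constant_factor_errors(self, rng):
        d = self._euclid_1d(rng.normal(size=8))
        fac = pd.DataFrame({"g": ["a"] * 8}, index=list(d.ids))
        with pytest.raises(ValueError, match="constant"):
            permanova(d, fac, ["g"], n_permutations=99)


class TestMantel:
    def _random_dm(self, rng, n=9):
        x = rng.normal(size=(n, 3))
        ids = tuple(f"s{i}" for i in range(n))
        return DistanceMatrix(ids, squareform(pdist(x)))

    def test_self_correlation_is_one(self, rng):
        d = self._random_dm(rng)
        res = mantel_test(d, d, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_skbio_spearman_statistic(self, rng):
        d1 = self._random_dm(rng)
        d2 = self._random_dm(rng)
        res = mantel_test(d1, d2, n_permutations=199, seed=1)
        r, p, _ = skdist.mantel(
            skdist.DistanceMatrix(d1.data, d1.ids),
            skdist.DistanceMatrix(d2.data, d2.ids),
            method="spearman", permutations=199, alternative="two-sided",
        )
        assert res.r == pytest.approx(r, rel=1e-9)
        assert abs(res.p - p) < 0.1

    def test_too_few_samples_errors(self, rng):
        d = self._random_dm(rng, n=3)
        with pytest.raises(ValueError):
            mantel_test(d, d)

    def test_default_permutation_count(self, rng):
        d1, d2 = self._random_dm(rng), self._random_dm(rng)
        assert mantel_test(d1, d2, seed=0).n_permutations == 999


class TestResistanceScores:
    def _scores(self, strategies, seed=0, n_countries=3):
        from extremesoil.design import build_design

        meta = records_to_frame(build_design(n_countries).records("amplicon"))
        params = CommunitySimParams(n_taxa=40, overdispersion=0.0, rng_seed=seed)
        table, _ = simulate_asv_counts(meta, strategies, params)
        return community_resistance_resilience(table, meta)

    def test_identical_profile_scores_zero(self):
        t = pd.DataFrame(
            [[5, 5], [5, 5]], index=["site1_heat_S1_amplicon", "site1_control_S1_amplicon"]
        )
        meta = pd.DataFrame(
            {
                "sample_id": list(t.index),
                "country": "AA",
                "site": "site1",
                "treatment": ["heat", "control"],
                "sampling": "S1",
            }
        )
        out = community_resistance_resilience(t, meta, transform=None)
        assert out["score"].iloc[0] == pytest.approx(0.0)
        assert out["kind"].iloc[0] == "resistance"

    def test_disjoint_profile_scores_minus_one(self):
        t = pd.DataFrame(
            [[5, 0], [0, 5]], index=["s_heat", "s_ctrl"]
        )
        meta = pd.DataFrame(
            {
                "sample_id": list(t.index),
                "country": "AA",
                "site": "x",
                "treatment": ["heat", "control"],
                "sampling": "S4",
            }
        )
        out = community_resistance_resilience(t, meta, transform=None)
        assert out["score"].iloc[0] == pytest.approx(-1.0)
        assert out["kind"].iloc[0] == "resilience"

    def test_larger_planted_impact_lowers_resistance(self):
        taxa = [f"t{i + 1:04d}" for i in range(5)]
        strategies = [StrategySpec(t, "heat", 0.04, 0.0) for t in taxa] + [
            StrategySpec(t, "drought", 0.005, 0.0) for t in taxa
        ]
        scores = self._scores(strategies, seed=11)
        s1 = scores[scores["kind"] == "resistance"]
        heat = s1[s1["treatment"] == "heat"]["score"].mean()
        drought = s1[s1["treatment"] == "drought"]["score"].mean()
        assert heat < drought

    def test_missing_control_pair_warns_and_skips(self):
        t = pd.DataFrame([[5, 1]], index=["lonely_heat"])
        meta = pd.DataFrame(
            {
                "sample_id": ["lonely_heat"],
                "country": "AA",
                "site": "x",
                "treatment": ["heat"],
                "sampling": "S1",
            }
        )
        with pytest.warns(UserWarning, match="no control pair"):
            out = community_resistance_resilience(t, meta, transform=None)
        assert out.empty
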
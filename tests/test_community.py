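import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from mitopool.community import (
    DissimilarityMatrix,
    chao2,
    jaccard,
    kruskal_stress,
    nmds,
    procrustes_protest,
    welch_from_estimates,
)

# community fixtures with values frozen from an independent
# community-ecology implementation of the same estimators
QUANT = pd.DataFrame(
    np.array([
        [2.804, 0.215, 1.356, 0.15, 0.778],
        [1.964, 0.995, 0.176, 0.407, 0.866],
        [1.628, 0.171, 1.329, 0.334, 0.915],
        [2.16, 0.301, 0.232, 0.396, 0.779],
    ]).T,
    columns=list("abcd"),
)
QUANT_REF_ROW0 = [0.0, 0.4892657125, 0.2788051209, 0.3727821150]
BINARY = pd.DataFrame(
    np.array([[1, 1, 0, 1, 0], [0, 1, 1, 0, 1], [1, 0, 0, 1, 1], [1, 1, 1, 0, 0]]).T,
    columns=list("abcd"),
)
BINARY_REF_ROW0 = [0.0, 0.8, 0.5, 0.5]
INCIDENCE = pd.DataFrame(
    np.array([
        [1, 1, 1, 0, 0, 1, 1, 0, 1, 1, 0, 1],
        [0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0],
        [0, 0, 1, 0, 1, 0, 1, 1, 1, 1, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1],
        [0, 1, 0, 1, 1, 0, 0, 0, 1, 0, 1, 0],
        [1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 1, 0],
    ]).T,
    index=[f"sp{i}" for i in range(12)],
    columns=[f"s{i}" for i in range(6)],
)
CLASSIC_REF = dict(chao=12.05952, se=0.272401)


class TestJaccard:
    def test_identical_samples_have_zero_dissimilarity(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        for binary in (True, False):
            assert jaccard(m, binary=binary).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_have_dissimilarity_one(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 2.0]})
        for binary in (True, False):
            assert jaccard(m, binary=binary).values[0, 1] == pytest.approx(1.0)

    def test_hand_values(self):
        mb = pd.DataFrame({"a": [1, 1, 1, 0], "b": [0, 1, 1, 1]}, dtype=float)
        assert jaccard(mb, binary=True).values[0, 1] == pytest.approx(0.5)
        mq = pd.DataFrame({"a": [2.0, 1.0], "b": [1.0, 1.0]})
        assert jaccard(mq, binary=False).values[0, 1] == pytest.approx(1 / 3)

    def test_quantitative_matches_frozen_reference(self):
        d = jaccard(QUANT, binary=False)
        assert d.values[0] == pytest.approx(QUANT_REF_ROW0, abs=1e-9)

    def test_binary_matches_frozen_reference(self):
        d = jaccard(BINARY, binary=True)
        assert d.values[0] == pytest.approx(BINARY_REF_ROW0, abs=1e-12)

    def test_binary_equals_quantitative_on_01_data(self):
        d1 = jaccard(BINARY, binary=True)
        d2 = jaccard(BINARY.astype(float), binary=False)
        assert d1.values == pytest.approx(d2.values, abs=1e-12)

    def test_all_zero_sample_error_names_the_sample(self):
        m = pd.DataFrame({"good": [1.0, 0.0], "empty": [0.0, 0.0]})
        with pytest.raises(ValueError, match="empty"):
            jaccard(m, binary=False)


class TestNmds:
    def test_equilateral_three_points_embed_exactly(self):
        d = DissimilarityMatrix(list("abc"), np.array(
            [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]
        ))
        res = nmds(d, k=2, n_restarts=5, seed=0)
        assert res.stress < 1e-6

    def test_recovers_exactly_embeddable_configuration(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(6, 2))
        dist = squareform(pdist(pts))
        dist /= dist.max()  # keep within [0, 1]; ranks unchanged
        res = nmds(DissimilarityMatrix([str(i) for i in range(6)], dist), seed=1)
        assert res.stress < 1e-4

    def test_restart_dominance(self):
        rng = np.random.default_rng(3)
        vals = squareform(rng.uniform(0.2, 1.0, 15))
        d = DissimilarityMatrix([str(i) for i in range(6)], vals)
        s1 = nmds(d, n_restarts=1, seed=5).stress
        s10 = nmds(d, n_restarts=10, seed=5).stress
        assert s10 <= s1 + 1e-12

    def test_beats_metric_pcoa_start(self):
        from mitopool.community import _pcoa_start

        rng = np.random.default_rng(9)
        vals = squareform(rng.uniform(0.2, 1.0, 45))
        d = DissimilarityMatrix([str(i) for i in range(10)], vals)
        res = nmds(d, n_restarts=8, seed=2)
        assert res.stress <= kruskal_stress(_pcoa_start(vals, 2), vals) + 1e-9

    def test_configuration_is_centred(self):
        rng = np.random.default_rng(11)
        vals = squareform(rng.uniform(0.2, 1.0, 15))
        res = nmds(DissimilarityMatrix(list("abcdef"), vals), seed=0)
        assert res.configuration.mean(axis=0) == pytest.approx([0, 0], abs=1e-9)


class TestProcrustes:
    def test_rigid_rotation_gives_r_one_and_min_p(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Y = 2.5 * X @ R + 7.0
        res = procrustes_protest(X, Y, n_permutations=999, seed=1)
        assert res.m_squared == pytest.approx(0.0, abs=1e-12)
        assert res.correlation_r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_r_in_unit_interval_and_joint_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X, Y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        res = procrustes_protest(X, Y, n_permutations=99, seed=2)
        assert 0 <= res.correlation_r <= 1
        perm = rng.permutation(8)
        res2 = procrustes_protest(X[perm], Y[perm], n_permutations=99, seed=2)
        assert res2.correlation_r == pytest.approx(res.correlation_r)

    def test_null_p_values_are_uniform(self):
        """Independent random configurations: protest p-values over 200 seeds
        pass a KS test against uniform at alpha=0.01."""
        ps = []
        for s in range(200):
            rng = np.random.default_rng(10_000 + s)
            X, Y = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
            ps.append(procrustes_protest(X, Y, n_permutations=199, seed=rng).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert min(ps) > 0  # add-one rule: p never zero

    def test_rank_deficient_input_raises(self):
        X = np.zeros((6, 2))
        X[:, 0] = np.arange(6)
        with pytest.raises(ValueError, match="rank"):
            procrustes_protest(X, np.random.default_rng(0).normal(size=(6, 2)))


class TestChao2:
    def test_no_singletons_means_no_extrapolation(self):
        inc = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 0, 1], [0, 1, 1, 1]],
            index=list("abc"), columns=list("wxyz"),
        )
        res = chao2(inc)
        assert res.q1 == 0
        assert res.chao2 == res.s_obs
        assert res.se == 0.0

    def test_stated_toy_summary(self):
        """s_obs=20, q1=4, q2=2, m=10 -> bias-corrected chao2 = 21.8."""
        rows = []
        rows += [[1] * 10] * 8          # widespread species
        rows += [[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]] * 6  # tripletons
        rows += [[1, 1, 0, 0, 0, 0, 0, 0, 0, 0]] * 2  # duplicates (q2)
        rows += [[1, 0, 0, 0, 0, 0, 0, 0, 0, 0]] * 4  # uniques (q1)
        inc = pd.DataFrame(rows, index=[f"sp{i}" for i in range(20)])
        res = chao2(inc)
        assert (res.s_obs, res.q1, res.q2, res.m) == (20, 4, 2, 10)
        assert res.chao2 == pytest.approx(21.8)

    def test_classic_variant_matches_frozen_reference(self):
        res = chao2(INCIDENCE, variant="classic")
        assert res.chao2 == pytest.approx(CLASSIC_REF["chao"], abs=1e-4)
        assert res.se == pytest.approx(CLASSIC_REF["se"], abs=1e-5)

    def test_estimate_never_below_observed_richness(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            inc = pd.DataFrame(rng.random((15, 6)) < 0.3)
            if not inc.to_numpy().any():
                continue
            res = chao2(inc)
            assert res.chao2 >= res.s_obs
            assert res.q1 + res.q2 <= res.s_obs

    def test_species_in_three_or_more_samples_give_exact_richness(self):
        inc = pd.DataFrame(np.ones((7, 5), dtype=int))
        res = chao2(inc)
        assert res.chao2 == res.s_obs == 7

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            chao2(pd.DataFrame([[1], [0]]))


class TestWelch:
    def test_morphology_vs_mitogenome_estimates(self):
        res = welch_from_estimates(56.3, 15.9, 10, 47.9, 11.8, 10)
        assert res.t == pytest.approx(0.42, abs=0.01)
        assert res.df == pytest.approx(16.6, abs=0.1)
        assert res.p == pytest.approx(0.68, abs=0.01)

    def test_morphology_vs_metabarcoding_estimates(self):
        res = welch_from_estimates(56.3, 15.9, 10, 36.0, 7.6, 10)
        assert res.t == pytest.approx(1.15, abs=0.01)
        assert res.df == pytest.approx(12.9, abs=0.1)
        assert res.p == pytest.approx(0.27, abs=0.01)

    def test_equal_estimates(self):
        res = welch_from_estimates(40.0, 5.0, 10, 40.0, 5.0, 10)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
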
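"""Distances, NMDS/PCA, envfit, bioenv, PERMANOVA, clustering, networks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from sedncycle.community import (
    Ordination,
    bioenv,
    bray_curtis,
    coexpression_network,
    envfit,
    hcluster,
    nmds,
    pca,
    permanova,
)


def euclid_dm(X, ids=None):
    return DistanceMatrix(squareform(pdist(X)), ids=ids)


class TestBrayCurtis:
    def test_identical_disjoint_and_mirror_rows(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [2.0, 0.0], [0.0, 2.0]],
            index=["a", "b", "c", "d"],
        )
        d = bray_curtis(m)
        assert d["a", "b"] == 0.0
        assert d["c", "d"] == 1.0

    def test_all_zero_pair_convention(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(m)
        assert d[0, 1] == 0.0

    def test_bounds_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(size=(7, 11)))
        d = bray_curtis(m).data
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[-1.0, 2.0], [1.0, 1.0]]))


class TestNMDS:
    def test_embeddable_configuration_reaches_near_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(9, 2))
        ord_ = nmds(euclid_dm(pts), k=2, restarts=2, seed=1)
        assert ord_.stress < 1e-3

    def test_same_seed_reproduces_coordinates(self):
        rng = np.random.default_rng(5)
        M = rng.uniform(0.2, 1.0, size=(8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        d = DistanceMatrix(M)
        a = nmds(d, restarts=3, seed=11)
        b = nmds(d, restarts=3, seed=11)
        assert np.array_equal(a.coords.to_numpy(), b.coords.to_numpy())

    def test_more_restarts_never_increase_stress(self):
        rng = np.random.default_rng(6)
        M = rng.uniform(0.2, 1.0, size=(8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        d = DistanceMatrix(M)
        s1 = nmds(d, restarts=1, seed=2).stress
        s10 = nmds(d, restarts=10, seed=2).stress
        assert s10 <= s1 + 1e-12

    def test_too_few_samples_rejected(self):
        d = euclid_dm(np.eye(3))
        with pytest.raises(ValueError):
            nmds(d, k=2)


class TestPCA:
    def test_perfectly_correlated_variables_give_single_axis(self):
        x = np.arange(6.0)
        table = pd.DataFrame({"v1": x, "v2": 3 * x + 1}).T
        ord_ = pca(table)
        assert ord_.explained[0] == pytest.approx(1.0)

    def test_isotropic_data_splits_variance_evenly(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(rng.normal(size=(2, 4000)), index=["a", "b"])
        ord_ = pca(table, scale=True)
        assert ord_.explained[0] == pytest.approx(0.5, abs=0.05)

    def test_single_sample_and_constant_variable(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame({"v": [1.0]}).T[[0]])
        table = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 7.0], "s3": [1.0, 2.0]},
                             index=["const", "var"])
        with pytest.warns(UserWarning, match="constant"):
            ord_ = pca(table)
        assert ord_.coords.shape[0] == 3


class TestEnvfit:
    def test_variable_equal_to_axis_gives_perfect_fit(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a1", "a2"])
        env = pd.DataFrame({"v": coords["a1"].to_numpy()})
        res = envfit(Ordination(coords), env, permutations=99, seed=0)
        assert res.table.loc["v", "r2"] == pytest.approx(1.0)
        assert res.table.loc["v", "p"] == pytest.approx(1 / 100)
        # direction cosines form a unit vector along axis 1
        assert abs(res.table.loc["v", "axis1"]) == pytest.approx(1.0, abs=1e-9)

    def test_null_pvalues_are_roughly_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(99)
        ps = []
        for i in range(200):
            coords = pd.DataFrame(rng.normal(size=(12, 2)))
            env = pd.DataFrame({"v": rng.normal(size=12)})
            ps.append(envfit(Ordination(coords), env,
                             permutations=99, seed=i).table["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_variable_and_zero_permutations(self):
        coords = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 2)))
        env = pd.DataFrame({"v": np.ones(6)})
        res = envfit(Ordination(coords), env, permutations=9, seed=0)
        assert np.isnan(res.table.loc["v", "r2"])
        with pytest.raises(ValueError):
            envfit(Ordination(coords), env, permutations=0)


class TestBioenv:
    def make_gradient(self, n=12, seed=4):
        rng = np.random.default_rng(seed)
        grad = np.linspace(0, 1, n)
        comm = np.array([np.exp(-((grad - c) ** 2) / 0.15) for c in
                         np.linspace(0, 1, 20)]).T
        comm += rng.normal(0, 0.01, comm.shape)
        ids = [f"s{i}" for i in range(n)]
        d = bray_curtis(pd.DataFrame(np.clip(comm, 0, None), index=ids))
        env = pd.DataFrame(
            {
                "gradient_exp": np.exp(grad),  # monotone transform of the driver
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            },
            index=ids,
        )
        return d, env

    def test_monotone_driver_variable_wins(self):
        d, env = self.make_gradient()
        res = bioenv(d, env, max_subset=2)
        assert res.best_subset == ("gradient_exp",)
        assert res.rho > 0.9

    def test_pure_noise_scores_near_zero(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(12)]
        d = euclid_dm(rng.normal(size=(12, 5)), ids=ids)
        env = pd.DataFrame(rng.normal(size=(12, 3)),
                           index=ids, columns=["a", "b", "c"])
        res = bioenv(d, env)
        assert res.rho <= 0.5

    def test_agrees_with_reference_implementation(self):
        from skbio.stats.distance import bioenv as skbio_bioenv

        d, env = self.make_gradient()
        mine = bioenv(d, env)
        theirs = skbio_bioenv(d, env)
        best_theirs = theirs["correlation"].idxmax()
        assert set(mine.best_subset) == set(best_theirs.split(", "))
        # scaling constants differ (ddof), which can flip float-level ties
        # in the rank vectors; agreement is to ~1e-3 rather than exact
        assert mine.rho == pytest.approx(theirs["correlation"].max(), abs=1e-3)

    def test_empty_env_and_budget(self):
        d = euclid_dm(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            bioenv(d, pd.DataFrame(index=range(5)))


class TestPermanova:
    def test_statistic_matches_reference_implementation(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(21)
        X = rng.normal(size=(14, 4))
        X[7:] += 1.5
        d = euclid_dm(X)
        labels = ["a"] * 7 + ["b"] * 7
        mine = permanova(d, labels, permutations=99, seed=0)
        theirs = skbio_permanova(d, grouping=labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_separated_clusters_reach_minimal_pvalue(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        X[6:] += 50.0
        mine = permanova(euclid_dm(X), ["a"] * 6 + ["b"] * 6,
                         permutations=199, seed=1)
        assert mine.p == pytest.approx(1 / 200)

    def test_one_group_rejected_and_singletons_warn(self):
        d = euclid_dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4)
        with pytest.warns(UserWarning, match="size 1"):
            res = permanova(d, ["a", "b", "c", "d"])
        assert res.p is None


class TestHcluster:
    def test_identical_profiles_merge_first(self):
        m = pd.DataFrame(
            [[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        res = hcluster(m)
        first = res.cut(2)
        assert first["a"] == first["b"] != first["c"]

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        res = hcluster(m)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_cut_recovers_separated_groups(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(
            np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(8, 0.1, (5, 3))]),
            index=[f"x{i}" for i in range(10)],
        )
        groups = hcluster(m).cut(2)
        assert len(set(groups.iloc[:5])) == 1
        assert groups.iloc[0] != groups.iloc[9]

    def test_nan_rejected_with_offending_row(self):
        m = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            hcluster(m)


class TestCoexpressionNetwork:
    def test_identical_and_weak_and_anticorrelated_pairs(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        noise = rng.normal(size=8)
        m = pd.DataFrame(
            {
                "a": base,
                "b": base * 2 + 1,  # r = 1 with a
                "c": -base,  # r = -1 with a
                "d": base * 0.3 + noise,  # weak
            }
        ).T
        net = coexpression_network(m, threshold=0.8)
        pairs = set(map(tuple, net.edges[["feature_a", "feature_b"]].to_numpy()))
        assert ("a", "b") in pairs
        assert ("a", "c") in pairs  # |r| rule keeps anti-correlation
        r_ac = net.edges.set_index(["feature_a", "feature_b"]).loc[("a", "c"), "r"]
        assert r_ac == pytest.approx(-1.0)
        assert not any("d" in p for p in pairs)
        assert "d" in net.nodes  # isolated nodes retained

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(6, 10)))
        perm = rng.permutation(10)
        a = coexpression_network(m).edges
        b = coexpression_network(m.iloc[:, perm]).edges
        pd.testing.assert_frame_equal(a, b)

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.normal(size=(5, 8)))
        m2 = m.copy()
        m2.iloc[0] = 3.5 * m2.iloc[0] + 7.0
        assert coexpression_network(m).edges.equals(coexpression_network(m2).edges)

    def test_sparse_feature_excluded_with_warning(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [np.nan, np.nan, 1.0, 2.0]],
            index=["ok", "sparse"],
        )
        with pytest.warns(UserWarning, match="sparse"):
            net = coexpression_network(m, min_n=3)
        assert net.excluded == ["sparse"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            coexpression_network(pd.DataFrame([[1.0, 2.0]]))
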
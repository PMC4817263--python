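"""Beta diversity, geographic/environmental distances, Mantel, PERMANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from phylogeodiv import beta
from phylogeodiv.io import parse_newick
from phylogeodiv.simulate import simulate_tree


def _random_distance(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    labels = [f"S{i}" for i in range(n)]
    return pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)


class TestUniFrac:
    def test_identical_communities_zero(self, balanced4):
        comm = pd.DataFrame([[1, 1, 0, 0], [2, 3, 0, 0]],
                            index=["x", "y"], columns=list("ABCD"))
        assert beta.unifrac(balanced4, comm, "unweighted").at["x", "y"] == 0

    def test_disjoint_clades_distance_one(self, balanced4):
        comm = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]],
                            index=["x", "y"], columns=list("ABCD"))
        assert beta.unifrac(balanced4, comm, "unweighted").at["x", "y"] == (
            pytest.approx(1.0))

    def test_matches_per_edge_classification_oracle(self):
        tree = simulate_tree(15, seed=17)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rng = np.random.default_rng(3)
        s1 = set(rng.choice(labels, 6, replace=False))
        s2 = set(rng.choice(labels, 5, replace=False))
        comm = pd.DataFrame(
            [[int(t in s1) for t in labels], [int(t in s2) for t in labels]],
            index=["x", "y"], columns=labels)
        got = beta.unifrac(tree, comm, "unweighted").at["x", "y"]

        # oracle: walk every edge, classify its subtree against both sites
        unique = shared = 0.0
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            below = {l.taxon.label for l in node.leaf_iter()}
            in1, in2 = bool(below & s1), bool(below & s2)
            if in1 and in2:
                shared += node.edge.length
            elif in1 or in2:
                unique += node.edge.length
        assert got == pytest.approx(unique / (unique + shared))

    def test_cross_check_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity.beta import unweighted_unifrac
        import io as _io
        newick = "((A:1,B:1):1,(C:1,D:1):1);"
        comm = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0]],
                            index=["x", "y"], columns=list("ABCD"))
        ours = beta.unifrac(parse_newick(newick), comm,
                            "unweighted").at["x", "y"]
        sk_tree = skbio.TreeNode.read(_io.StringIO(newick))
        theirs = unweighted_unifrac([1, 1, 0, 0], [1, 0, 1, 0],
                                    list("ABCD"), sk_tree)
        assert ours == pytest.approx(float(theirs))

    def test_weighted_variant_bounded_and_zero_on_identical(self, balanced4):
        comm = pd.DataFrame([[3, 1, 0, 2], [3, 1, 0, 2], [0, 0, 5, 1]],
                            index=["x", "y", "z"], columns=list("ABCD"))
        d = beta.unifrac(balanced4, comm, "abundance_weighted")
        assert d.at["x", "y"] == pytest.approx(0.0)
        assert 0 < d.at["x", "z"] <= 1

    def test_empty_site_rejected(self, balanced4):
        comm = pd.DataFrame([[1, 1, 0, 0], [0, 0, 0, 0]],
                            index=["x", "y"], columns=list("ABCD"))
        with pytest.raises(ValueError, match="empty"):
            beta.unifrac(balanced4, comm)


class TestUniFracSignificance:
    def test_disjoint_clades_minimal_p(self, balanced4):
        comm = pd.DataFrame([[5, 5, 0, 0], [0, 0, 5, 5]],
                            index=["x", "y"], columns=list("ABCD"))
        p = beta.unifrac_significance(balanced4, comm, n_perm=99, seed=0)
        assert p.at["x", "y"] == pytest.approx(1 / 100)

    def test_panmictic_pair_not_extreme(self):
        tree = simulate_tree(12, seed=5)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        rng = np.random.default_rng(8)
        counts = rng.multinomial(30, np.ones(12) / 12, size=2)
        comm = pd.DataFrame(counts, index=["x", "y"], columns=labels)
        p = beta.unifrac_significance(tree, comm, n_perm=99, seed=1)
        assert p.at["x", "y"] > 0.05


class TestBrayCurtis:
    def test_formula_examples(self):
        comm = pd.DataFrame([[1, 1], [1, 1]], index=["x", "y"])
        assert beta.bray_curtis(comm).at["x", "y"] == 0
        comm = pd.DataFrame([[2, 0], [0, 2]], index=["x", "y"])
        assert beta.bray_curtis(comm).at["x", "y"] == pytest.approx(1.0)
        comm = pd.DataFrame([[6, 2], [2, 2]], index=["x", "y"])
        assert beta.bray_curtis(comm).at["x", "y"] == pytest.approx(4 / 12)

    def test_unweighted_view_collapses_to_presence(self):
        comm = pd.DataFrame([[10, 1, 0], [1, 10, 5]], index=["x", "y"])
        d = beta.bray_curtis(comm, view="unweighted")
        assert d.at["x", "y"] == pytest.approx(1 / 5)


class TestGeographicEnvironmental:
    def test_haversine_analytic(self):
        sites = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [0, 180]},
                             index=["a", "b"])
        d = beta.haversine_matrix(sites)
        assert d.at["a", "b"] == pytest.approx(math.pi * 6371.0088, rel=1e-6)
        assert d.at["a", "a"] == 0

    def test_haversine_metric_properties(self):
        rng = np.random.default_rng(2)
        sites = pd.DataFrame({
            "latitude": rng.uniform(-80, 80, 20),
            "longitude": rng.uniform(-180, 180, 20)})
        d = beta.haversine_matrix(sites).values
        assert np.allclose(d, d.T)
        for i, j, k in itertools.combinations(range(20), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-6

    def test_env_distance_two_site_example(self):
        sites = pd.DataFrame({"pH": [5.0, 7.0]}, index=["a", "b"])
        d = beta.env_distance(sites, ["pH"])
        assert d.at["a", "b"] == pytest.approx(2.0)

    def test_env_distance_matches_zscore_oracle(self):
        rng = np.random.default_rng(4)
        sites = pd.DataFrame(rng.normal(size=(6, 3)),
                             columns=["pH", "som", "temp"],
                             index=[f"s{i}" for i in range(6)])
        d = beta.env_distance(sites, ["pH", "som", "temp"])
        z = (sites - sites.mean()) / sites.std(ddof=0)
        for a, b in itertools.combinations(sites.index, 2):
            expected = math.sqrt(((z.loc[a] - z.loc[b]) ** 2).sum())
            assert d.at[a, b] == pytest.approx(expected)

    def test_zero_variance_variable_dropped(self):
        sites = pd.DataFrame({"pH": [5.0, 7.0], "som": [3.0, 3.0]},
                             index=["a", "b"])
        with pytest.warns(UserWarning, match="som"):
            d = beta.env_distance(sites, ["pH", "som"])
        assert d.at["a", "b"] == pytest.approx(2.0)


class TestMantel:
    def test_self_correlation(self):
        d = _random_distance(6, 1)
        res = beta.mantel(d, d.copy(), n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_exhaustive_matches_enumeration_oracle(self):
        d1 = _random_distance(5, 2)
        d2 = _random_distance(5, 3)
        res = beta.mantel(d1, d2, exhaustive=True)

        def r_of(perm):
            m = d2.values[np.ix_(perm, perm)]
            iu = np.triu_indices(5, 1)
            return np.corrcoef(d1.values[iu], m[iu])[0, 1]

        r_obs = r_of(list(range(5)))
        hits = sum(r_of(list(p)) >= r_obs - 1e-12
                   for p in itertools.permutations(range(5)))
        assert res.statistic == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(hits / math.factorial(5))
        assert res.r_squared == pytest.approx(r_obs ** 2)

    def test_cross_check_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel
        d1, d2 = _random_distance(8, 5), _random_distance(8, 6)
        res = beta.mantel(d1, d2, n_perm=499, seed=1)
        r, p, _ = sk_mantel(DistanceMatrix(d1.values, list(d1.index)),
                            DistanceMatrix(d2.values, list(d2.index)),
                            permutations=499, alternative="greater")
        assert res.statistic == pytest.approx(float(r))
        assert abs(res.p_value - float(p)) < 0.1

    def test_constant_matrix_rejected(self):
        d = _random_distance(4, 1)
        ones = pd.DataFrame(1.0 - np.eye(4), index=d.index, columns=d.index)
        with pytest.raises(ValueError, match="constant"):
            beta.mantel(ones, d)


class TestPermanova:
    def test_exhaustive_matches_ss_decomposition_oracle(self):
        d = _random_distance(6, 7)
        factor = pd.Series(["g1", "g1", "g1", "g2", "g2", "g2"],
                           index=d.index, name="grp")
        res = beta.permanova(d, factor, exhaustive=True)

        # oracle: explicit within-group sum-of-squares partition
        def f_and_r2(groups):
            n = 6
            d2 = d.values ** 2
            ss_total = d2[np.triu_indices(n, 1)].sum() / n
            ss_within = 0.0
            for g in set(groups):
                idx = [i for i, x in enumerate(groups) if x == g]
                sub = d2[np.ix_(idx, idx)]
                ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            ss_among = ss_total - ss_within
            f = (ss_among / 1) / (ss_within / (n - 2))
            return f, ss_among / ss_total

        f_obs, r2_obs = f_and_r2(list(factor))
        assert res.statistic == pytest.approx(f_obs)
        assert res.r_squared == pytest.approx(r2_obs)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            f, _ = f_and_r2([factor.iloc[i] for i in perm])
            hits += f >= f_obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(hits / total)

    def test_cross_check_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_p
        d = _random_distance(9, 8)
        factor = pd.Series(["a"] * 4 + ["b"] * 5, index=d.index, name="grp")
        res = beta.permanova(d, factor, n_perm=99, seed=0)
        sk = sk_p(DistanceMatrix(d.values, list(d.index)),
                  grouping=list(factor), permutations=99)
        assert res.statistic == pytest.approx(float(sk["test statistic"]))

    def test_scale_invariance_of_r2(self):
        d = _random_distance(7, 9)
        cov = pd.Series(np.arange(7.0), index=d.index, name="x")
        r1 = beta.permanova(d, cov, n_perm=49, seed=1)
        r2 = beta.permanova(d * 3.5, cov, n_perm=49, seed=1)
        assert r1.r_squared == pytest.approx(r2.r_squared)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_unstructured_groups_not_significant(self):
        # distances identical within and between groups: F = 1 exactly and
        # the permutation distribution is degenerate, so p = 1
        labels = list("abcdef")
        d = pd.DataFrame(1.0 - np.eye(6), index=labels, columns=labels)
        factor = pd.Series(["x"] * 3 + ["y"] * 3, index=labels, name="g")
        res = beta.permanova(d, factor, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_constant_variable_rejected(self):
        d = _random_distance(5, 10)
        with pytest.raises(ValueError):
            beta.permanova(d, pd.Series(np.ones(5), index=d.index, name="c"))


class TestCorrelationTable:
    def test_self_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        table = pd.DataFrame({"x": x, "y": -x, "z": rng.normal(size=10)})
        out = beta.correlation_table(table)
        assert out["r"].at["x", "x"] == pytest.approx(1.0)
        assert out["r"].at["x", "y"] == pytest.approx(-1.0)

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        out = beta.correlation_table(table)
        r = out["r"].at["a", "b"]
        t = r * math.sqrt(10 / (1 - r ** 2))
        p = 2 * stats.t.sf(abs(t), df=10)
        assert out["p"].at["a", "b"] == pytest.approx(p)

    def test_constant_column_reported_missing(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        out = beta.correlation_table(table)
        assert np.isnan(out["r"].at["a", "c"])
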
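"""Statistical parsimony networks, nesting, Dc/Dn and inference."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phylogeodiv import haplonet


class TestParsimonyLimit:
    def test_probability_matches_log_space_oracle(self):
        # independent closed form: exp(sum log(1 - i/L))
        for length in (100, 377, 600):
            for j in (1, 3, 6, 10):
                expected = math.exp(sum(
                    math.log(1 - i / length) for i in range(1, j)))
                assert haplonet.parsimony_probability(j, length) == (
                    pytest.approx(expected))

    def test_high_confidence_forces_single_steps(self):
        assert haplonet.parsimony_limit(377, confidence=0.999999) == 1

    def test_limit_nondecreasing_in_length(self):
        limits = [haplonet.parsimony_limit(m) for m in (50, 100, 377, 1000)]
        assert limits == sorted(limits)
        assert limits[-1] > 1


class TestBuildNetwork:
    def test_single_step_chain(self):
        haps = {"A": "AAAA", "B": "AAAT", "C": "AATT"}
        g = haplonet.build_network(haps, limit=5)
        assert set(g.edges) == {("A", "B"), ("B", "C")} or (
            {tuple(sorted(e)) for e in g.edges} == {("A", "B"), ("B", "C")})
        assert all(g.nodes[n]["kind"] == "observed" for n in g)

    def test_intermediates_inserted_for_multi_step(self):
        haps = {"A": "AAAA", "B": "AATT"}
        g = haplonet.build_network(haps, limit=5)
        inferred = [n for n in g if g.nodes[n]["kind"] == "inferred"]
        assert len(inferred) == 1
        assert nx.shortest_path_length(g, "A", "B") == 2

    def test_beyond_limit_stays_disconnected(self):
        haps = {"A": "AAAAAA", "B": "TTTTAA"}  # hamming 4 > limit 3
        g = haplonet.build_network(haps, limit=3)
        assert not nx.has_path(g, "A", "B")
        assert nx.number_connected_components(g) == 2

    def test_simulated_haplotypes_graph_hamming_consistency(self):
        from phylogeodiv.simulate import evolve_sequences, simulate_tree
        tree = simulate_tree(20, seed=21)
        seqs = evolve_sequences(tree, 120, 0.02, seed=21)
        uniq = {}
        for name, s in sorted(seqs.items()):
            if s not in uniq.values():
                uniq[name] = s
        limit = 6
        g = haplonet.build_network(uniq, limit=limit)
        observed = [n for n in g if g.nodes[n]["kind"] == "observed"]
        # every observed-observed edge is exactly one mutational step
        for u, v in g.edges:
            if u in uniq and v in uniq:
                assert haplonet.hamming(uniq[u], uniq[v]) == 1
        # any pair within the limit is connected at most at its hamming dist
        for a, b in itertools.combinations(observed, 2):
            hd = haplonet.hamming(uniq[a], uniq[b])
            if hd <= limit:
                assert nx.shortest_path_length(g, a, b) <= hd

    def test_node_order_invariance(self):
        haps = {"A": "AAAA", "B": "AAAT", "C": "AATT", "D": "TATT"}
        g1 = haplonet.build_network(haps, limit=4)
        g2 = haplonet.build_network(dict(reversed(list(haps.items()))),
                                    limit=4)
        assert sorted(dict(g1.degree).items()) == sorted(
            dict(g2.degree).items())


class TestResolveLoops:
    def _four_cycle(self, freqs):
        g = nx.cycle_graph(["A", "B", "C", "D"])
        for n, f in freqs.items():
            g.nodes[n]["kind"] = "observed"
            g.nodes[n]["count"] = f
        return g

    def test_removes_edge_between_lowest_frequency_nodes(self):
        g = self._four_cycle({"A": 10, "B": 1, "C": 1, "D": 5})
        out = haplonet.resolve_loops(g)
        assert not out.has_edge("B", "C")
        assert nx.is_connected(out)

    def test_acyclic_input_unchanged(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_node_attributes(g, 1, "count")
        out = haplonet.resolve_loops(g)
        assert sorted(out.edges) == sorted(g.edges)

    def test_output_acyclic_components_unchanged(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(15, 0.25, seed=5)
        g = nx.relabel_nodes(g, {i: f"h{i}" for i in range(15)})
        for n in g:
            g.nodes[n]["count"] = int(rng.integers(1, 10))
        out = haplonet.resolve_loops(g)
        assert len(nx.cycle_basis(out)) == 0
        assert (sorted(map(sorted, nx.connected_components(out)))
                == sorted(map(sorted, nx.connected_components(g))))


class TestNestClades:
    def test_three_node_path_golden(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_node_attributes(g, "observed", "kind")
        design = haplonet.nest_clades(g)
        level1 = {frozenset(m) for m in design.levels[0].values()}
        assert level1 == {frozenset({"A", "B"}), frozenset({"C"})}
        # the two 1-step clades unite at the next level
        assert len(design.levels[1]) == 1

    def test_single_haplotype_trivial(self):
        g = nx.Graph()
        g.add_node("A", kind="observed")
        design = haplonet.nest_clades(g)
        assert design.n_levels == 0
        assert design.clades_at(0) == ["A"]

    def test_partition_at_every_level(self):
        from phylogeodiv.simulate import evolve_sequences, simulate_tree
        tree = simulate_tree(15, seed=30)
        seqs = evolve_sequences(tree, 100, 0.03, seed=30)
        uniq = {}
        for name, s in sorted(seqs.items()):
            if s not in uniq.values():
                uniq[name] = s
        g = haplonet.resolve_loops(haplonet.build_network(uniq, limit=8))
        for comp in nx.connected_components(g):
            design = haplonet.nest_clades(g.subgraph(comp).copy())
            nodes = set(comp)
            for level in range(design.n_levels + 1):
                covered = []
                for cid in design.clades_at(level):
                    covered.extend(design.members(cid))
                assert sorted(covered) == sorted(nodes)
            assert design.n_levels <= len(nodes)

    def test_loopy_network_rejected(self):
        g = nx.cycle_graph(["A", "B", "C", "D"])
        with pytest.raises(ValueError, match="loops"):
            haplonet.nest_clades(g)


def _design_from_path(labels):
    g = nx.path_graph(labels)
    nx.set_node_attributes(g, "observed", "kind")
    return haplonet.nest_clades(g)


class TestCladeDistances:
    def test_point_clade_has_zero_dc(self):
        design = _design_from_path(["A", "B"])
        coords = pd.DataFrame({
            "haplotype_id": ["A", "A", "B"],
            "latitude": [40.0, 40.0, 50.0],
            "longitude": [-90.0, -90.0, -80.0]})
        table = haplonet.clade_distances(design, coords)
        row = table[table["clade"] == "A"].iloc[0]
        assert row["dc"] == pytest.approx(0.0)

    def test_symmetric_pair_dc_equals_radius(self):
        design = _design_from_path(["A", "B"])
        coords = pd.DataFrame({
            "haplotype_id": ["A", "A"],
            "latitude": [10.0, -10.0],
            "longitude": [0.0, 0.0]})
        table = haplonet.clade_distances(design, coords)
        row = table[table["clade"] == "A"].iloc[0]
        radius = haplonet.great_circle_km(10.0, 0.0, 0.0, 0.0)
        assert row["dc"] == pytest.approx(radius, rel=1e-6)

    def test_matches_brute_force_averaging(self):
        design = _design_from_path(["A", "B", "C"])
        rng = np.random.default_rng(9)
        coords = pd.DataFrame({
            "haplotype_id": rng.choice(["A", "B", "C"], 12),
            "latitude": rng.uniform(25, 60, 12),
            "longitude": rng.uniform(-120, -70, 12)})
        table = haplonet.clade_distances(design, coords).set_index("clade")
        # recompute one 1-step clade by direct averaging
        cid = "C1.1"
        members = haplonet.NestedDesign.haplotypes(design, cid)
        sub = coords[coords["haplotype_id"].isin(members)]
        phi = np.radians(sub["latitude"].values)
        lam = np.radians(sub["longitude"].values)
        xyz = np.array([np.cos(phi) * np.cos(lam),
                        np.cos(phi) * np.sin(lam), np.sin(phi)]).mean(axis=1)
        xyz /= np.linalg.norm(xyz)
        clat = math.degrees(math.asin(xyz[2]))
        clon = math.degrees(math.atan2(xyz[1], xyz[0]))
        dc = np.mean([haplonet.great_circle_km(a, b, clat, clon)
                      for a, b in zip(sub["latitude"], sub["longitude"])])
        assert table.at[cid, "dc"] == pytest.approx(dc, rel=1e-9)
        # Dc never exceeds the widest pairwise member spread
        for cid in table.index:
            members = design.haplotypes(cid)
            sub = coords[coords["haplotype_id"].isin(members)]
            if len(sub) < 2:
                continue
            widest = max(
                haplonet.great_circle_km(a1, b1, a2, b2)
                for (a1, b1), (a2, b2) in itertools.combinations(
                    zip(sub["latitude"], sub["longitude"]), 2))
            assert table.at[cid, "dc"] <= widest + 1e-9


class TestNCAPermutation:
    def test_confined_clade_flagged_small(self):
        design = _design_from_path(["A", "B", "C", "D", "E"])
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(12):  # A confined to one point
            rows.append(("A", 40.0, -90.0))
        for hap in ["B", "C", "D", "E"]:
            for _ in range(6):  # the rest spread over the continent
                rows.append((hap, rng.uniform(25, 65),
                             rng.uniform(-125, -70)))
        coords = pd.DataFrame(rows, columns=["haplotype_id", "latitude",
                                             "longitude"])
        res = haplonet.nca_permutation(design, coords, n_perm=999, seed=0)
        row = res[res["clade"] == "A"].iloc[0]
        assert row["dc_small"]
        assert row["p_dc_small"] <= 0.05

    def test_single_clade_group_gets_no_flags(self):
        design = _design_from_path(["A", "B"])
        coords = pd.DataFrame({
            "haplotype_id": ["A", "B", "A", "B"],
            "latitude": [40, 50, 42, 48],
            "longitude": [-90, -80, -88, -82]})
        res = haplonet.nca_permutation(design, coords, n_perm=49, seed=1)
        top = res[res["parent"] == ""]
        assert not top[["dc_small", "dc_large"]].any().any() or len(top) > 1


class TestInterpret:
    def _result(self, flags_by_clade, contrasts=None, alpha=0.05):
        rows = []
        for clade, (is_tip, flags) in flags_by_clade.items():
            row = {"clade": clade, "parent": "C2.1", "is_tip": is_tip,
                   "dc_small": False, "dc_large": False,
                   "dn_small": False, "dn_large": False}
            row.update(flags)
            rows.append(row)
        df = pd.DataFrame(rows)
        df.attrs["alpha"] = alpha
        if contrasts is not None:
            df.attrs["interior_tip_contrasts"] = contrasts
        return df

    def test_no_flags_means_no_association(self):
        res = self._result({"a": (True, {}), "b": (False, {})})
        assert haplonet.interpret(res, "C2.1") == "no significant association"

    def test_expansion_chain(self):
        res = self._result({"a": (True, {"dc_large": True}),
                            "b": (False, {})})
        assert haplonet.interpret(res, "C2.1") == "contiguous range expansion"

    def test_isolation_by_distance_chain(self):
        res = self._result({"a": (True, {"dc_small": True}),
                            "b": (False, {"dc_large": True})})
        assert haplonet.interpret(res, "C2.1") == (
            "restricted gene flow with isolation by distance")

    def test_unknown_pattern_inconclusive(self):
        res = self._result({"a": (True, {"dn_small": True}),
                            "b": (False, {})})
        assert haplonet.interpret(res, "C2.1") == "inconclusive"

    def test_malformed_table_rejected(self):
        res = self._result({"a": (True, {"dc_large": True}),
                            "b": (False, {})})
        with pytest.raises(ValueError):
            haplonet.interpret(res, "C2.1", [{"no_label": 1}])

    def test_custom_table_from_file(self, tmp_path):
        import json
        table = [{"label": "custom", "all_of": ["tip_dc_large"]}]
        p = tmp_path / "rules.json"
        p.write_text(json.dumps(table))
        res = self._result({"a": (True, {"dc_large": True}),
                            "b": (False, {})})
        assert haplonet.interpret(res, "C2.1", p) == "custom"
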
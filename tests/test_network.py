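"""Contingency matrix, SFN projection, and network statistics."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from splicefn.network import (
    build_contingency,
    build_sfn,
    network_stats,
    rank_hubs,
    weighted_degrees,
)
from splicefn.model import OrganismDataset, POLYFORM

from conftest import make_dataset


class TestContingency:
    def test_cells_count_annotated_proteins(self):
        ds = make_dataset({"tu1": [{"A"}, {"A"}, {"B"}]})
        df = build_contingency(ds)
        fl_a = ds.catalogue.id_of(("A",))
        fl_b = ds.catalogue.id_of(("B",))
        assert df.loc["tu1", fl_a] == 2
        assert df.loc["tu1", fl_b] == 1

    def test_monoform_single_cell(self):
        ds = make_dataset({"tu1": [{"A"}, {"A"}, {"A"}]})
        df = build_contingency(ds)
        assert df.shape == (1, 1)
        assert df.iloc[0, 0] == 3

    def test_empty_dataset(self):
        df = build_contingency(OrganismDataset("x", []))
        assert df.empty

    def test_row_sums_cover_fl_sets(self, small_dataset):
        df = build_contingency(small_dataset)
        for tu in small_dataset.annotated_tus():
            assert df.loc[tu.tu_id].sum() >= len(tu.fls)
            nonzero = set(df.columns[df.loc[tu.tu_id] > 0])
            assert nonzero == tu.fls


def brute_force_edges(dataset):
    """Independent enumeration: weight = #polyform TUs containing both FLs."""
    weights = {}
    for tu in dataset.tus:
        if tu.tu_class != POLYFORM:
            continue
        for pair in combinations(sorted(tu.fls), 2):
            weights[pair] = weights.get(pair, 0) + 1
    return weights


class TestBuildSFN:
    def test_shared_pair_weight_accumulates(self):
        ds = make_dataset(
            {"tu1": [{"A"}, {"B"}], "tu2": [{"A"}, {"B"}]}
        )
        g = build_sfn(ds)
        assert g.number_of_edges() == 1
        (u, v), = g.edges()
        assert g[u][v]["weight"] == 2

    def test_triangle_from_three_fls(self):
        ds = make_dataset({"tu1": [{"A"}, {"B"}, {"C"}]})
        g = build_sfn(ds)
        assert g.number_of_edges() == 3
        assert all(g[u][v]["weight"] == 1 for u, v in g.edges())

    def test_all_monoform_has_no_edges(self):
        ds = make_dataset({"tu1": [{"A"}], "tu2": [{"B"}]})
        assert build_sfn(ds).number_of_edges() == 0

    def test_include_isolated_adds_degree0_fls(self):
        ds = make_dataset({"tu1": [{"A"}, {"B"}], "tu2": [{"C"}]})
        g0 = build_sfn(ds, include_isolated=False)
        g1 = build_sfn(ds, include_isolated=True)
        assert g1.number_of_nodes() == g0.number_of_nodes() + 1
        assert g1.number_of_edges() == g0.number_of_edges()

    def test_randomized_brute_force_oracle(self):
        rng = np.random.default_rng(2010)
        for _ in range(30):
            n_tus = int(rng.integers(1, 7))
            specs = {}
            for i in range(n_tus):
                n_prot = int(rng.integers(1, 5))
                specs[f"tu{i}"] = [
                    {f"K{rng.integers(0, 6)}"} for _ in range(n_prot)
                ]
            ds = make_dataset(specs)
            g = build_sfn(ds)
            expected = brute_force_edges(ds)
            got = {
                tuple(sorted((u, v))): g[u][v]["weight"] for u, v in g.edges()
            }
            assert got == expected

    def test_total_weight_identity(self):
        from splicefn.simulate import SimConfig, generate_organism

        ds = generate_organism(SimConfig(n_tus=2000, seed=17))
        g = build_sfn(ds)
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        expected = sum(
            math.comb(len(tu.fls), 2)
            for tu in ds.tus
            if tu.tu_class == POLYFORM
        )
        assert total == expected


class TestNetworkStats:
    def test_triangle_is_regular(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        s = network_stats(g)
        assert (s.n_nodes, s.n_edges) == (3, 3)
        assert s.avg_neighbors == pytest.approx(2.0)
        assert s.heterogeneity == pytest.approx(0.0)
        assert s.avg_neighbors == pytest.approx(2 * s.n_edges / s.n_nodes)

    def test_star_heterogeneity(self):
        g = nx.star_graph(3)
        s = network_stats(g)
        assert s.avg_neighbors == pytest.approx(1.5)
        assert s.heterogeneity == pytest.approx(math.sqrt(0.75) / 1.5)

    def test_components(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        s = network_stats(g)
        assert s.n_components == 2
        assert s.component_sizes == [2, 2]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            network_stats(nx.Graph())


class TestRankHubs:
    def test_star_center_first(self):
        g = nx.star_graph(3)
        hubs = rank_hubs(g, 1)
        assert hubs[0][0] == 0 and hubs[0][1] == 3

    def test_tie_broken_by_id(self):
        g = nx.Graph([("b", "c"), ("a", "c"), ("a", "b")])
        assert [h[0] for h in rank_hubs(g, 3)] == ["a", "b", "c"]

    def test_n_capped_at_node_count(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert len(rank_hubs(g, 5)) == 3

    def test_degree_is_distinct_neighbors_not_weight(self):
        ds = make_dataset(
            {"tu1": [{"A"}, {"B"}], "tu2": [{"A"}, {"B"}], "tu3": [{"A"}, {"C"}]}
        )
        g = build_sfn(ds)
        fl_a = ds.catalogue.id_of(("A",))
        hubs = dict((h[0], h[1]) for h in rank_hubs(g, 10, ds))
        assert hubs[fl_a] == 2  # two neighbors, though summed weight is 3
        assert weighted_degrees(g)[fl_a] == 3

    def test_keywords_resolved_from_catalogue(self):
        ds = make_dataset({"tu1": [{"A"}, {"B", "C"}]})
        hubs = rank_hubs(build_sfn(ds), 2, ds)
        kw_by_id = {h[0]: h[2] for h in hubs}
        assert kw_by_id[ds.catalogue.id_of(("B", "C"))] == ("B", "C")
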
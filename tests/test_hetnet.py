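import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pocos import (
    build_network,
    candidate_frontier,
    discover_netpocos,
    discover_pocos,
    gene_frequency_report,
    select_models,
)
from pocos.errors import EmptyNetworkError
from pocos.hetnet import reachability_for
from pocos.poco_search import PoCo, PoCoCollection
from conftest import make_dataset


def genes(*rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def bfs_frontier_oracle(network, sources, max_hops=3):
    """Depth-limited BFS over the full heterogeneous graph."""
    g = network.to_networkx()
    out = set()
    for src in sources:
        lengths = nx.single_source_shortest_path_length(g, src, cutoff=max_hops)
        out |= {
            node
            for node, dist in lengths.items()
            if g.nodes[node]["kind"] == "locus" and 0 < dist <= max_hops
        }
    return out - set(sources)


def random_network(rng, n_loci=8, n_genes=10, p_lg=0.25, p_gg=0.2):
    ds = make_dataset(
        rng.integers(0, 3, size=(n_loci, 6)).astype(np.int8), [1, 1, 1, 0, 0, 0]
    )
    gene_rows = [(f"g{i}", "1", 10_000_000 * (i + 1), 10_000_000 * (i + 1) + 100)
                 for i in range(n_genes)]
    eqtl = [
        (lid, f"g{i}")
        for lid in ds.locus_ids
        for i in range(n_genes)
        if rng.random() < p_lg
    ]
    ppi = [
        (f"g{i}", f"g{j}")
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if rng.random() < p_gg
    ]
    if not eqtl:  # guarantee a non-empty locus set
        eqtl = [(ds.locus_ids[0], "g0")]
    net = build_network(
        ds,
        genes(*gene_rows),
        pd.DataFrame(eqtl, columns=["locus_id", "gene_id"]),
        pd.DataFrame(ppi, columns=["gene_id_a", "gene_id_b"]),
    )
    return ds, net


class TestBuild:
    def test_roi_window_boundary(self):
        ds = make_dataset(
            [[0, 1, 2], [0, 1, 2]], [1, 0, 0], positions=[20_000, 19_999]
        )
        net = build_network(ds, genes(("gX", "1", 70_000, 90_000)))
        assert ("rs1", "gX") in net.roi_edges  # 20,000 == 70,000 - 50,000
        assert ("rs2", "gX") not in net.roi_edges  # one base outside
        assert net.locus_ids == ["rs1"]

    def test_downstream_window_boundary(self):
        ds = make_dataset([[0, 1, 2]], [1, 0, 0], positions=[140_000])
        net = build_network(ds, genes(("gX", "1", 70_000, 90_000)))
        assert ("rs1", "gX") in net.roi_edges  # 140,000 == 90,000 + 50,000

    def test_chromosome_mismatch_gives_no_edge(self):
        ds = make_dataset([[0, 1, 2]], [1, 0, 0], chrom="2", positions=[80_000])
        with pytest.raises(EmptyNetworkError):
            build_network(ds, genes(("gX", "1", 70_000, 90_000)))

    def test_unknown_eqtl_pairs_dropped(self):
        ds = make_dataset([[0, 1, 2]], [1, 0, 0], positions=[80_000])
        eqtl = pd.DataFrame(
            [("rs1", "gX"), ("rsNOPE", "gX"), ("rs1", "gNOPE")],
            columns=["locus_id", "gene_id"],
        )
        net = build_network(ds, genes(("gX", "1", 70_000, 90_000)), eqtl)
        assert net.eqtl_edges == [("rs1", "gX")]

    def test_ppi_self_loops_dropped(self):
        ds = make_dataset([[0, 1, 2]], [1, 0, 0], positions=[80_000])
        ppi = pd.DataFrame([("gX", "gX")], columns=["gene_id_a", "gene_id_b"])
        net = build_network(ds, genes(("gX", "1", 70_000, 90_000)), None, ppi)
        assert net.ppi_edges == []

    def test_disconnected_locus_excluded_from_u(self):
        ds = make_dataset(
            [[0, 1, 2], [0, 1, 2]], [1, 0, 0], positions=[80_000, 900_000]
        )
        net = build_network(ds, genes(("gX", "1", 70_000, 90_000)))
        assert net.locus_ids == ["rs1"]


class TestFrontier:
    def build_chain(self):
        """c1-v1-c2 (shared RoI), v1-v2 PPI, c3 in RoI of v2, v2-v3 PPI,
        c4 in RoI of v3 (4 hops from c1)."""
        ds = make_dataset(
            np.tile([0, 1, 2], (4, 1)).astype(np.int8),
            [1, 0, 0],
            positions=[80_000, 81_000, 1_080_000, 2_080_000],
            ids=["c1", "c2", "c3", "c4"],
        )
        gene_table = genes(
            ("v1", "1", 70_000, 90_000),
            ("v2", "1", 1_070_000, 1_090_000),
            ("v3", "1", 2_070_000, 2_090_000),
        )
        ppi = pd.DataFrame(
            [("v1", "v2"), ("v2", "v3")], columns=["gene_id_a", "gene_id_b"]
        )
        return build_network(ds, gene_table, None, ppi)

    def test_two_hop_shared_gene(self):
        net = self.build_chain()
        assert "c2" in candidate_frontier(net, {"c1"})

    def test_three_hop_via_ppi(self):
        net = self.build_chain()
        assert "c3" in candidate_frontier(net, {"c1"})

    def test_four_hops_excluded(self):
        net = self.build_chain()
        assert "c4" not in candidate_frontier(net, {"c1"})

    def test_eqtl_paths_counted_uniformly(self):
        ds = make_dataset(
            np.tile([0, 1, 2], (2, 1)).astype(np.int8),
            [1, 0, 0],
            positions=[5_000_000, 6_000_000],
            ids=["c1", "c2"],
        )
        eqtl = pd.DataFrame(
            [("c1", "v1"), ("c2", "v1")], columns=["locus_id", "gene_id"]
        )
        net = build_network(ds, genes(("v1", "1", 70_000, 90_000)), eqtl)
        assert candidate_frontier(net, {"c1"}) == {"c2"}

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(40):
            ds, net = random_network(rng)
            for lid in net.locus_ids:
                assert candidate_frontier(net, {lid}) == bfs_frontier_oracle(
                    net, {lid}
                )

    def test_multi_source_frontier_matches_oracle(self, rng):
        ds, net = random_network(rng, n_loci=10)
        k = max(2, len(net.locus_ids) // 2)
        sources = set(net.locus_ids[:k])
        assert candidate_frontier(net, sources) == bfs_frontier_oracle(
            net, sources
        )


class TestNetPocos:
    def make_module_instance(self):
        """Three informative loci share hub gene vH; three background loci
        sit in RoI of distant unconnected genes."""
        counts = [
            [1, 1, 0, 0, 0, 0, 0, 0],
            [0, 0, 1, 1, 0, 0, 0, 0],
            [0, 0, 0, 0, 1, 0, 0, 0],
            [1, 0, 1, 0, 1, 0, 1, 0],
            [0, 1, 0, 1, 0, 0, 0, 1],
            [1, 1, 1, 0, 1, 0, 1, 1],
        ]
        pheno = [1, 1, 1, 1, 1, 0, 0, 0]
        positions = [80_000, 81_000, 82_000, 10_080_000, 10_081_000, 20_080_000]
        ids = ["m1", "m2", "m3", "b1", "b2", "b3"]
        ds = make_dataset(counts, pheno, positions=positions, ids=ids)
        gene_table = genes(
            ("vH", "1", 70_000, 90_000),
            ("vB", "1", 10_070_000, 10_090_000),
            ("vC", "1", 20_070_000, 20_090_000),
        )
        net = build_network(ds, gene_table)
        return ds, net

    def test_planted_module_recovered_as_first_netpoco(self):
        ds, net = self.make_module_instance()
        profiles = select_models(ds)
        collection = discover_netpocos(ds, profiles, net)
        assert len(collection) >= 1
        assert set(collection[0].loci) == {"m1", "m2", "m3"}

    def make_trap_instance(self):
        """zx has the globally best gain at step two but is reachable from
        none of the hub loci a1..a3."""
        counts = [
            [1, 1, 0, 0, 0, 0],  # a1
            [0, 0, 1, 0, 0, 0],  # a2
            [0, 0, 0, 1, 0, 0],  # a3
            [0, 0, 1, 1, 0, 0],  # zx
        ]
        pheno = [1, 1, 1, 1, 0, 0]
        positions = [80_000, 81_000, 82_000, 20_080_000]
        ds = make_dataset(
            counts, pheno, positions=positions, ids=["a1", "a2", "a3", "zx"]
        )
        gene_table = genes(
            ("vH", "1", 70_000, 90_000), ("vC", "1", 20_070_000, 20_090_000)
        )
        return ds, build_network(ds, gene_table)

    def test_frontier_constraint_blocks_global_best(self):
        ds, net = self.make_trap_instance()
        profiles = select_models(ds)
        collection = discover_netpocos(ds, profiles, net)
        assert len(collection) == 1
        assert collection[0].loci == ["a1", "a2", "a3"]  # zx never added

    def test_every_addition_within_hop_bound_of_predecessors(self):
        ds, net = self.make_module_instance()
        profiles = select_models(ds)
        collection = discover_netpocos(ds, profiles, net)
        assert len(collection) >= 1
        for poco in collection:
            for i, lid in enumerate(poco.loci[1:], start=1):
                assert lid in bfs_frontier_oracle(net, set(poco.loci[:i]))

    def test_constrained_search_differs_from_free_search(self):
        ds, net = self.make_trap_instance()
        profiles = select_models(ds)
        constrained = discover_netpocos(ds, profiles, net)
        free = discover_pocos(ds, profiles)
        assert [p.loci for p in free] == [["a1", "zx"]]
        assert [p.loci for p in constrained] == [["a1", "a2", "a3"]]

    def test_reachability_reindexing_handles_missing_loci(self):
        ds, net = self.make_module_instance()
        order = ["zz_not_in_net", "m2", "m1"]
        reach = reachability_for(net, order)
        assert reach[0].sum() == 0 and reach[:, 0].sum() == 0
        assert reach[1, 2] and reach[2, 1]


class TestGeneFrequency:
    def test_counts_and_tie_order(self):
        ds, net = TestNetPocos().make_module_instance()
        collection = PoCoCollection(
            [
                PoCo(["m1", "m2"], 4, 0, [("m1", 0.5), ("m2", 0.5)]),
                PoCo(["m3"], 2, 0, [("m3", 0.4)]),
                PoCo(["b1"], 2, 1, [("b1", 0.2)]),
            ]
        )
        report = gene_frequency_report(collection, net, top_k=10)
        assert report.iloc[0].tolist() == ["vH", 2]
        assert report.iloc[1].tolist() == ["vB", 1]

    def test_selected_subset_and_top_k(self):
        ds, net = TestNetPocos().make_module_instance()
        collection = PoCoCollection(
            [
                PoCo(["m1"], 1, 0, []),
                PoCo(["b1"], 1, 0, []),
            ]
        )
        report = gene_frequency_report(
            collection, net, selected_pocos=[0], top_k=1
        )
        assert report["gene_id"].tolist() == ["vH"]
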
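"""Set integration, enrichment, hub connectivity, network assembly/export."""

import pandas as pd
import pytest

from conftest import hypergeom_tail_oracle
from mirmeta.cohort import DegenerateInputError
from mirmeta.datasets import HUB_GENES, load_overlap_genes
from mirmeta.litmine import hypergeom_upper_tail
from mirmeta.network import (
    GeneSet,
    assemble_network,
    connectivity_ztest,
    export_network,
    import_network,
    intersect_sets,
    pathway_enrichment,
    read_gmt,
    write_gmt,
)
from mirmeta.synth import gen_pathways

# degrees printed alongside the 20-hub-gene interaction lists
PUBLISHED_DEGREES = {
    "RAC1": 10, "NRAS": 8, "TRAF6": 7, "ERBB4": 5, "NOTCH2": 5, "PTGS2": 5,
    "ELAVL1": 4, "PARK2": 4, "SMAD4": 4, "YES1": 4, "RACGAP1": 3,
    "HEYL": 1, "IL17A": 1, "IQGAP1": 1, "IRAK1": 1, "NOVA1": 1,
    "OTUD7B": 1, "PTPRE": 1, "ROBO1": 1, "SORT1": 1,
}

PUBLISHED_TAILS = {
    10: 0.007305, 8: 0.044385, 7: 0.091440, 5: 0.276934,
    4: 0.412161, 3: 0.558826, 1: 0.812719,
}


class TestIntersect:
    def test_simple_overlap(self):
        a = GeneSet.from_iterable("a", ["A", "B", "C"])
        b = GeneSet.from_iterable("b", ["B", "C", "D"])
        assert intersect_sets(a, b).members == frozenset({"B", "C"})

    def test_disjoint_sets_yield_empty(self):
        a = GeneSet.from_iterable("a", ["A"])
        b = GeneSet.from_iterable("b", ["B"])
        assert len(intersect_sets(a, b)) == 0

    def test_commutative_associative_idempotent(self):
        a = GeneSet.from_iterable("a", "ABCDE")
        b = GeneSet.from_iterable("b", "CDEFG")
        c = GeneSet.from_iterable("c", "EGHIA")
        assert intersect_sets(a, b).members == intersect_sets(b, a).members
        assert (
            intersect_sets(intersect_sets(a, b), c).members
            == intersect_sets(a, intersect_sets(b, c)).members
        )
        assert intersect_sets(a, a).members == a.members

    def test_planted_overlap_sizes_recovered(self):
        # literature list (1800) ∩ prediction list (251) sharing 104 symbols
        shared = [f"SHARED{i:04d}" for i in range(104)]
        lit = GeneSet.from_iterable("lit", shared + [f"LIT{i:05d}" for i in range(1696)])
        pred = GeneSet.from_iterable("pred", shared + [f"PRED{i:04d}" for i in range(147)])
        assert len(lit) == 1800 and len(pred) == 251
        assert len(intersect_sets(lit, pred)) == 104


class TestEnrichment:
    def test_zero_overlap_scores_one(self):
        query = GeneSet.from_iterable("q", ["X1", "X2"])
        paths = [GeneSet.from_iterable("pw", ["Y1", "Y2", "Y3"])]
        out = pathway_enrichment(query, paths, background=100)
        assert out.loc[0, "p"] == 1.0

    def test_matches_cocitation_tail_parameterization(self):
        # population 20, pathway 5, query 4, overlap 2 — identical tail as
        # the co-citation statistic with (N, n, m, k) = (20, 5, 4, 2)
        query = GeneSet.from_iterable("q", ["A", "B", "X1", "X2"])
        pw = GeneSet.from_iterable("pw", ["A", "B", "Y1", "Y2", "Y3"])
        out = pathway_enrichment(query, [pw], background=20)
        assert out.loc[0, "p"] == pytest.approx(hypergeom_tail_oracle(20, 5, 4, 2), abs=1e-14)
        assert out.loc[0, "p"] == pytest.approx(
            hypergeom_upper_tail(20, 5, 4, 2), abs=1e-15
        )

    def test_planted_pathway_ranks_first(self):
        overlap = load_overlap_genes()
        background = overlap + [f"BG{i:05d}" for i in range(2000)]
        paths = gen_pathways(overlap, background, n_pathways=10, seed=4)
        out = pathway_enrichment(GeneSet.from_iterable("q", overlap), paths)
        assert out.loc[0, "pathway"] == "PLANTED"
        assert out.loc[0, "p"] < out.loc[1, "p"]

    def test_pathway_member_outside_background_rejected(self):
        query = GeneSet.from_iterable("q", ["A"])
        pw = GeneSet.from_iterable("pw", ["A", "STRAY"])
        bg = GeneSet.from_iterable("bg", ["A", "B", "C"])
        with pytest.raises(ValueError, match="outside the background"):
            pathway_enrichment(query, [pw], background=bg)

    def test_gmt_round_trip(self, tmp_path):
        sets = [GeneSet.from_iterable("pw1", "ABC"), GeneSet.from_iterable("pw2", "BCDE")]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert [(s.name, s.members) for s in back] == [(s.name, s.members) for s in sets]


class TestConnectivity:
    def test_degrees_match_published_column(self, hub_network):
        for gene, degree in PUBLISHED_DEGREES.items():
            assert hub_network.degree(gene) == degree

    def test_tail_probabilities_match_published_values(self, hub_network):
        out = connectivity_ztest(hub_network, HUB_GENES)
        for row in out.itertuples():
            assert row.p == pytest.approx(PUBLISHED_TAILS[row.degree], abs=5e-7), row.gene

    def test_p_strictly_decreasing_in_degree(self, hub_network):
        out = connectivity_ztest(hub_network, HUB_GENES)
        by_degree = out.drop_duplicates("degree").sort_values("degree")
        assert by_degree["p"].is_monotonic_decreasing

    def test_mean_degree_gene_scores_half(self):
        edges = pd.DataFrame(
            {"a": ["A", "A", "A", "B"], "b": ["B", "C", "D", "C"]}
        )
        net = assemble_network([(edges, "ppi")])
        # degrees: A=3, B=2, C=2, D=1 → B and C sit at the mean (2)
        out = connectivity_ztest(net)
        row = out.set_index("gene").loc["B"]
        assert row["z"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(0.5, abs=1e-12)

    def test_uniform_degrees_are_degenerate(self):
        edges = pd.DataFrame({"a": ["A", "C"], "b": ["B", "D"]})
        net = assemble_network([(edges, "ppi")])
        with pytest.raises(DegenerateInputError):
            connectivity_ztest(net)

    def test_degree_sum_equals_twice_edges(self, hub_network):
        out = connectivity_ztest(hub_network, HUB_GENES)
        assert out["degree"].sum() == 2 * len(hub_network.edges)


class TestAssembly:
    def test_shared_edge_carries_both_tags_counted_once(self):
        t1 = pd.DataFrame({"a": ["X"], "b": ["Y"]})
        t2 = pd.DataFrame({"a": ["Y"], "b": ["X"]})
        net = assemble_network([(t1, "ppi"), (t2, "literature")])
        assert len(net.edges) == 1
        assert net.edge_sources("X", "Y") == {"ppi", "literature"}

    def test_empty_sources_give_empty_network(self):
        net = assemble_network([])
        assert len(net) == 0 and len(net.edges) == 0

    def test_published_edge_list_has_20_nodes_34_edges(self, hub_network):
        assert len(hub_network) == 20
        assert len(hub_network.edges) == 34  # sum of printed degrees = 68

    def test_self_loops_dropped_and_counted(self):
        edges = pd.DataFrame({"a": ["A", "B"], "b": ["A", "C"]})
        net = assemble_network([(edges, "ppi")])
        assert len(net.edges) == 1
        assert net.graph.graph["self_loops_dropped"] == 1


class TestExport:
    def test_path_graph_writes_two_sif_lines(self, tmp_path):
        edges = pd.DataFrame({"a": ["A", "B"], "b": ["B", "C"]})
        net = assemble_network([(edges, "ppi")])
        out = tmp_path / "net.sif"
        export_network(net, out, format="sif")
        assert len(out.read_text().strip().splitlines()) == 2

    @pytest.mark.parametrize("fmt", ["sif", "graphml"])
    def test_round_trip_preserves_edges_and_tags(self, hub_network, tmp_path, fmt):
        out = tmp_path / f"net.{fmt}"
        export_network(hub_network, out, format=fmt)
        back = import_network(out, format=fmt)
        assert set(back.nodes) == set(hub_network.nodes)
        assert back.edges == hub_network.edges
        assert back.edge_sources("RAC1", "TRAF6") == hub_network.edge_sources("RAC1", "TRAF6")

    def test_empty_network_exports_valid_empty_file(self, tmp_path):
        net = assemble_network([])
        out = tmp_path / "empty.sif"
        export_network(net, out, format="sif")
        assert out.read_text() == ""
        assert len(import_network(out).edges) == 0

    def test_unknown_format_rejected(self, hub_network, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(hub_network, tmp_path / "x", format="dot")
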
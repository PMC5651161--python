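"""Edge-table reading, network serialization, and the BFS crawler."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfnet import (
    CrawlError,
    EdgeTableFormatError,
    EdgeTableRowError,
    EdgeTableSpec,
    FANTOM_STYLE,
    REGULONDB_STYLE,
    RegulatoryNetwork,
    SignedInteraction,
    crawl,
    crawl_all,
    read_edge_table,
    read_network,
    write_network,
)
from tfnet.simulate import GeneratorConfig, as_provider, generate

from conftest import build_net


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestEdgeTableSpec:
    def test_requires_exactly_one_value_column(self):
        with pytest.raises(EdgeTableFormatError):
            EdgeTableSpec(weight_col="weight", effect_col="effect")
        with pytest.raises(EdgeTableFormatError):
            EdgeTableSpec(weight_col=None, effect_col=None)


class TestReadEdgeTable:
    def test_promoter_duplicates_stream_then_collapse(self, tmp_path):
        p = write(tmp_path, "t.tsv",
                  "source\ttarget\tweight\tpromoter\n"
                  "SOX2\tSRF\t4.857\tp1\n"
                  "SOX2\tSRF\t0.834\tp2\n"
                  "SOX2\tSRF\t0.845\tp3\n")
        recs = list(read_edge_table(p, FANTOM_STYLE))
        assert len(recs) == 3
        assert [r.promoter_id for r in recs] == ["p1", "p2", "p3"]
        net = RegulatoryNetwork.from_interactions(recs)
        assert net.n_edges == 1 and net.weight("SOX2", "SRF") == 4.857

    def test_categorical_effects_map_to_unit_weights(self, tmp_path):
        p = write(tmp_path, "r.tsv",
                  "source\ttarget\teffect\n"
                  "Fis\tcrp\trepression\n"
                  "Crp\taraC\tactivation\n"
                  "Crp\tmarA\tdual\n")
        recs = list(read_edge_table(p, REGULONDB_STYLE))
        assert [r.weight for r in recs] == [-1.0, 1.0, 0.0]

    def test_empty_file_with_header_streams_nothing(self, tmp_path):
        p = write(tmp_path, "e.tsv", "source\ttarget\tweight\n")
        assert list(read_edge_table(p)) == []

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "# generated table\nsource\ttarget\tweight\n\n# mid comment\nA\tB\t1.5\n")
        (rec,) = list(read_edge_table(p))
        assert (rec.source, rec.target, rec.weight) == ("A", "B", 1.5)

    def test_missing_column_is_format_error(self, tmp_path):
        p = write(tmp_path, "m.tsv", "source\ttarget\nA\tB\n")
        with pytest.raises(EdgeTableFormatError, match="weight"):
            list(read_edge_table(p))

    @pytest.mark.parametrize("row,complaint", [
        ("A\tB\tnot_a_number", "unparseable weight"),
        ("A\t\t1.0", "missing endpoint"),
        ("\tB\t1.0", "missing endpoint"),
    ])
    def test_bad_rows_reported_with_line_number(self, tmp_path, row, complaint):
        p = write(tmp_path, "b.tsv", f"source\ttarget\tweight\nA\tB\t1.0\n{row}\n")
        with pytest.raises(EdgeTableRowError, match=f"line 3: {complaint}"):
            list(read_edge_table(p))

    def test_unknown_effect_is_row_error(self, tmp_path):
        p = write(tmp_path, "u.tsv", "source\ttarget\teffect\nA\tB\tmaybe\n")
        with pytest.raises(EdgeTableRowError, match="line 2"):
            list(read_edge_table(p, REGULONDB_STYLE))


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(3))
    def test_edge_tsv_round_trip_is_identity(self, tmp_path, seed):
        cfg = GeneratorConfig(n_master=2, n_tf=8, n_effector=25, seed=seed)
        records, _ = generate(cfg)
        net = RegulatoryNetwork.from_interactions(records)
        path = tmp_path / "net.tsv"
        write_network(net, path, "edge-tsv")
        assert read_network(path, "edge-tsv") == net

    def test_graphml_round_trip_is_identity(self, tmp_path):
        net = build_net([("A", "B", 1.25), ("B", "C", -0.5)])
        net.add_gene("A", avg_transcript_count=1628.215)
        path = tmp_path / "net.graphml"
        write_network(net, path, "graphml")
        back = read_network(path, "graphml")
        assert back == net
        assert back.annotations("A")["avg_transcript_count"] == 1628.215

    def test_isolated_nodes_survive_edge_tsv(self, tmp_path):
        net = build_net([("A", "B", 1.0)])
        net.add_gene("LONER")
        path = tmp_path / "net.tsv"
        write_network(net, path, "edge-tsv")
        assert read_network(path, "edge-tsv") == net

    def test_empty_network_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_network(RegulatoryNetwork(), path, "edge-tsv")
        assert path.read_text() == "source\ttarget\tweight\n"
        assert read_network(path) == RegulatoryNetwork()

    def test_rows_sorted_by_source_then_target(self, tmp_path):
        net = build_net([("B", "A", 1.0), ("A", "C", 2.0), ("A", "B", 3.0)])
        path = tmp_path / "net.tsv"
        write_network(net, path, "edge-tsv")
        rows = [l.split("\t")[:2] for l in path.read_text().splitlines()[1:]]
        assert rows == [["A", "B"], ["A", "C"], ["B", "A"]]

    def test_sif_read_back_assigns_unit_weights(self, tmp_path):
        net = build_net([("A", "B", 4.2), ("B", "C", -1.0)])
        path = tmp_path / "net.sif"
        write_network(net, path, "sif")
        assert "reg" in path.read_text()
        back = read_network(path, "sif")
        assert set(back.genes) == {"A", "B", "C"}
        assert back.weight("A", "B") == 1.0  # SIF drops weights

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown network format"):
            write_network(RegulatoryNetwork(), tmp_path / "x", "gexf")


class TestCrawl:
    def test_crawl_equals_bulk_load_on_connected_instance(self, small_instance):
        _, records, manifest = small_instance
        bulk = RegulatoryNetwork.from_interactions(records)
        provider = as_provider(records)
        seeds = [m.gene for m in manifest]
        crawled = crawl_all(provider, seeds)
        assert crawled == bulk

    def test_seed_recovers_only_its_component(self):
        comp1 = [("A", "B", 1.0), ("B", "C", 2.0)]
        comp2 = [("X", "Y", -1.0)]
        records = [SignedInteraction(s, t, w) for s, t, w in comp1 + comp2]
        provider = as_provider(records)
        got = crawl(provider, "B")
        assert got == build_net(comp1)
        both = crawl_all(provider, ["A", "X"])
        assert both == build_net(comp1 + comp2)

    def test_lonely_seed_yields_single_node_network(self):
        provider = as_provider([])
        net = crawl(provider, "ONLY")
        assert net.genes == ["ONLY"] and net.n_edges == 0

    def test_repeated_seed_idempotent(self):
        records = [SignedInteraction("A", "B", 1.0)]
        provider = as_provider(records)
        assert crawl_all(provider, ["A", "A", "A"]) == crawl(as_provider(records), "A")

    def test_empty_seed_list_gives_empty_network(self):
        assert crawl_all(as_provider([]), []) == RegulatoryNetwork()

    def test_provider_queried_at_most_twice_per_gene(self, small_instance):
        _, records, _ = small_instance
        provider = as_provider(records)
        net = crawl(provider, records[0].source)
        assert sum(provider.calls.values()) <= 2 * net.n_genes
        assert max(provider.calls.values()) <= 2

    def test_provider_failure_carries_partial_network_and_symbol(self):
        records = [SignedInteraction("A", "B", 1.0), SignedInteraction("B", "C", 1.0)]

        class Flaky:
            def __init__(self):
                self._inner = as_provider(records)

            def regulators_of(self, gene):
                if gene == "C":
                    raise OSError("backend down")
                return self._inner.regulators_of(gene)

            def targets_of(self, gene):
                return self._inner.targets_of(gene)

        with pytest.raises(CrawlError, match="'C'") as exc_info:
            crawl(Flaky(), "A")
        err = exc_info.value
        assert err.symbol == "C"
        assert err.partial.has_edge("A", "B")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), start=st.integers(0, 10_000))
    def test_crawl_bulk_load_equivalence_property(self, seed, start):
        """Any seed gene of a connected instance reconstructs the whole graph."""
        cfg = GeneratorConfig(n_master=1, n_tf=6, n_effector=12,
                              duplicate_rate=0.5, seed=seed)
        records, manifest = generate(cfg)
        bulk = RegulatoryNetwork.from_interactions(records)
        provider = as_provider(records)
        crawled = crawl_all(provider, [m.gene for m in manifest])
        assert crawled == bulk
        # single-seed crawl from an arbitrary gene recovers its component,
        # a subgraph of the full network
        genes = bulk.genes
        one = crawl(as_provider(records), genes[start % len(genes)])
        assert set(one.genes) <= set(bulk.genes)
        for s, t, w in one.edges():
            assert bulk.weight(s, t) == w
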
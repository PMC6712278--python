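"""Sequence similarity networks and cross-catalog near-identity sharing."""

import numpy as np
import pytest

from gusmap import synth
from gusmap.sequence_io import ProteinRecord
from gusmap.ssn import (
    build_ssn,
    components_and_summary,
    cross_set_shared,
    export_graphml,
    export_tables,
)

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def _mutant(rng, base: str, n_sub: int, pid: str) -> ProteinRecord:
    seq = list(base)
    for p in rng.choice(len(base), size=n_sub, replace=False):
        seq[p] = rng.choice([a for a in AMINO if a != seq[p]])
    return ProteinRecord(id=pid, sequence="".join(seq))


@pytest.fixture(scope="module")
def two_blobs():
    """Two families of near-identical members built on unrelated scaffolds."""
    rng = np.random.default_rng(21)
    blob_a = synth.make_scaffold(0)
    blob_b = synth.make_scaffold(1)
    records, attrs = [], {}
    for i in range(4):
        rec = _mutant(rng, blob_a, 15, f"a{i}")  # ~97.5% intra-blob identity
        records.append(rec)
        attrs[rec.id] = {"source": "mouse", "loop_category": "NL"}
    for i in range(3):
        rec = _mutant(rng, blob_b, 15, f"b{i}")
        records.append(rec)
        attrs[rec.id] = {"source": "human", "loop_category": "L2"}
    return records, attrs


class TestBuildSSN:
    def test_single_record_single_node_no_edges(self):
        rec = ProteinRecord(id="only", sequence=synth.make_scaffold(0))
        graph = build_ssn([rec])
        assert graph.number_of_nodes() == 1
        assert graph.number_of_edges() == 0

    def test_identical_sequences_are_connected(self):
        seq = synth.make_scaffold(0)
        a = ProteinRecord(id="a", sequence=seq)
        b = ProteinRecord(id="b", sequence=seq)
        graph = build_ssn([a, b])
        assert graph.has_edge("a", "b")

    def test_unrelated_sequences_not_connected(self):
        rng = np.random.default_rng(4)
        a = ProteinRecord(id="a", sequence="".join(rng.choice(list(AMINO), size=600)))
        b = ProteinRecord(id="b", sequence="".join(rng.choice(list(AMINO), size=600)))
        graph = build_ssn([a, b])
        assert graph.number_of_edges() == 0

    def test_duplicate_ids_rejected(self):
        rec = ProteinRecord(id="a", sequence="MKLW")
        with pytest.raises(ValueError):
            build_ssn([rec, rec])

    def test_edges_monotone_in_threshold(self, two_blobs):
        records, attrs = two_blobs
        tight = build_ssn(records, attrs, evalue_threshold=1e-250)
        loose = build_ssn(records, attrs, evalue_threshold=1e-150)
        assert set(tight.edges) <= set(loose.edges)


class TestComponents:
    def test_edgeless_graph_gives_singletons(self):
        import networkx as nx
        graph = nx.Graph()
        graph.add_nodes_from(f"n{i}" for i in range(5))
        clusters, overview = components_and_summary(graph)
        assert overview["n_clusters"] == 5
        assert overview["n_singletons"] == 5

    def test_two_blob_fixture_resolves_into_two_clusters(self, two_blobs):
        records, attrs = two_blobs
        graph = build_ssn(records, attrs)
        clusters, overview = components_and_summary(graph)
        assert overview["n_clusters"] == 2
        memberships = sorted(tuple(c.members) for c in clusters)
        assert memberships == [("a0", "a1", "a2", "a3"), ("b0", "b1", "b2")]
        assert overview["n_single_source"] == 2
        assert overview["n_mixed_source"] == 0

    def test_tallies_sum_to_cluster_size(self, two_blobs):
        records, attrs = two_blobs
        graph = build_ssn(records, attrs)
        clusters, _ = components_and_summary(graph)
        for c in clusters:
            assert sum(c.by_source.values()) == c.size
            assert sum(c.by_loop_category.values()) == c.size


class TestCrossSetShared:
    def test_identical_sequence_is_shared(self):
        seq = synth.make_scaffold(0)
        pairs, shared_a, shared_b = cross_set_shared(
            [ProteinRecord(id="a", sequence=seq)],
            [ProteinRecord(id="b", sequence=seq)],
        )
        assert shared_a == {"a"} and shared_b == {"b"}

    def test_97_percent_pair_not_shared(self):
        # 600-mer differing at 18 positions: identity 582/600 = 97.0 < 98
        rng = np.random.default_rng(17)
        base = "".join(rng.choice(list(AMINO), size=600))
        other = _mutant(rng, base, 18, "b")
        pairs, shared_a, _ = cross_set_shared(
            [ProteinRecord(id="a", sequence=base)], [other]
        )
        assert pairs == [] and shared_a == set()

    def test_sharing_relation_is_symmetric(self, two_blobs):
        records, _ = two_blobs
        set_a, set_b = records[:4], records[4:]
        pairs_ab, sa, sb = cross_set_shared(set_a, set_b, identity_threshold_pct=90)
        pairs_ba, sb2, sa2 = cross_set_shared(set_b, set_a, identity_threshold_pct=90)
        assert {(p.id_a, p.id_b) for p in pairs_ab} == {
            (p.id_b, p.id_a) for p in pairs_ba
        }
        assert sa == sa2 and sb == sb2


def test_exports_write_plain_text_tables(tmp_path, two_blobs):
    records, attrs = two_blobs
    graph = build_ssn(records, attrs)
    export_tables(graph, tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
    export_graphml(graph, tmp_path / "ssn.graphml")
    nodes = (tmp_path / "nodes.tsv").read_text().splitlines()
    assert len(nodes) == 1 + len(records)
    assert (tmp_path / "ssn.graphml").read_text().startswith("<?xml")
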
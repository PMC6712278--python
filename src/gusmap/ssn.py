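"""Sequence similarity networks and cross-catalog shared-protein analysis.

An SSN places one node per (deduplicated) protein and an undirected edge
between two proteins when their pairwise alignment E-value beats a fixed
threshold — stringent thresholds (default 1e-220) resolve a family into
clusters of near-identical members while keeping distinct subfamilies
apart.  Edges carry the symmetrized E-value (minimum of the two
directional Karlin–Altschul estimates, which differ only through the
query-length term).

Cross-catalog sharing is a different notion: two catalogs "share" a
protein when some pair exceeds an identity threshold (default >98%,
strict) under END-TO-END global alignment with the full alignment length
as denominator — near-identity of whole proteins, not local similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .alignment import ScoringScheme, estimate_evalue, global_align, local_align
from .sequence_io import ProteinRecord


def build_ssn(
    records: Sequence[ProteinRecord],
    attributes: Optional[dict[str, dict]] = None,
    evalue_threshold: float = 1e-220,
    scheme: ScoringScheme = ScoringScheme(),
) -> nx.Graph:
    """All-vs-all SSN over deduplicated records.

    ``attributes`` maps protein id -> node attribute dict (source catalog,
    loop category, phylum, ...).  Node count is always len(records); the
    edge set grows monotonically with ``evalue_threshold``.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("records must be deduplicated by id")
    total = sum(len(r) for r in records)
    graph = nx.Graph(evalue_threshold=evalue_threshold)
    for rec in records:
        attrs = (attributes or {}).get(rec.id, {})
        graph.add_node(rec.id, length=len(rec), **attrs)
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            aln = local_align(a.sequence, b.sequence, scheme, a.id, b.id)
            e_ab = estimate_evalue(aln.score, len(a), total, scheme.karlin_k, scheme.karlin_lambda)
            e_ba = estimate_evalue(aln.score, len(b), total, scheme.karlin_k, scheme.karlin_lambda)
            evalue = min(e_ab, e_ba)
            if evalue <= evalue_threshold:
                graph.add_edge(a.id, b.id, evalue=evalue, score=aln.score)
    return graph


@dataclass
class ClusterSummary:
    members: list[str]
    by_source: dict[str, int]
    by_loop_category: dict[str, int]
    by_phylum: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.members)


def components_and_summary(graph: nx.Graph) -> tuple[list[ClusterSummary], dict]:
    """Connected components with per-cluster attribute tallies.

    Returns (clusters sorted by size descending, overview dict counting
    singleton clusters and single-source vs mixed-source clusters).
    """
    clusters: list[ClusterSummary] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        tallies = {"source": {}, "loop_category": {}, "phylum": {}}
        for m in members:
            node = graph.nodes[m]
            for key, bucket in tallies.items():
                val = node.get(key)
                if val is not None:
                    bucket[val] = bucket.get(val, 0) + 1
        clusters.append(
            ClusterSummary(
                members=members,
                by_source=tallies["source"],
                by_loop_category=tallies["loop_category"],
                by_phylum=tallies["phylum"],
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.members[0]))
    overview = {
        "n_clusters": len(clusters),
        "n_singletons": sum(1 for c in clusters if c.size == 1),
        "n_single_source": sum(1 for c in clusters if len(c.by_source) == 1),
        "n_mixed_source": sum(1 for c in clusters if len(c.by_source) > 1),
    }
    return clusters, overview


@dataclass
class SharedPair:
    id_a: str
    id_b: str
    identity_pct: float


def cross_set_shared(
    set_a: Sequence[ProteinRecord],
    set_b: Sequence[ProteinRecord],
    identity_threshold_pct: float = 98.0,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[list[SharedPair], set[str], set[str]]:
    """Find proteins shared across two catalogs by near-identity.

    A protein is shared when some counterpart exceeds the identity
    threshold (strict >) under end-to-end global alignment.  Returns
    (pairs, shared ids in A, shared ids in B); the relation is symmetric.
    """
    pairs: list[SharedPair] = []
    shared_a: set[str] = set()
    shared_b: set[str] = set()
    for a in set_a:
        for b in set_b:
            aln = global_align(a.sequence, b.sequence, scheme, a.id, b.id)
            if aln.identity_pct > identity_threshold_pct:
                pairs.append(SharedPair(a.id, b.id, aln.identity_pct))
                shared_a.add(a.id)
                shared_b.add(b.id)
    return pairs, shared_a, shared_b


def export_tables(graph: nx.Graph, nodes_path, edges_path) -> None:
    """Write node and edge attribute tables as TSV."""
    node_rows = [{"id": n, **graph.nodes[n]} for n in sorted(graph.nodes)]
    pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
    edge_rows = [
        {"source": min(u, v), "target": max(u, v), **d}
        for u, v, d in graph.edges(data=True)
    ]
    edge_rows.sort(key=lambda r: (r["source"], r["target"]))
    pd.DataFrame(edge_rows, columns=["source", "target", "evalue", "score"]).to_csv(
        edges_path, sep="\t", index=False
    )


def export_graphml(graph: nx.Graph, path) -> None:
    """Write the SSN in GraphML for network-visualization tools."""
    nx.write_graphml(graph, path)
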
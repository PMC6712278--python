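"""End-to-end orchestration: screen -> gate -> iterate -> classify ->
annotate -> taxonomy -> SSN -> stats.

`run_gusome_pipeline` executes the stages in order over in-memory
objects, honouring per-stage toggles, and returns a result bundle with
per-stage counts (the containment chain catalog ⊇ screened ⊇ gated is a
structural invariant), the annotated catalog entries, the iterative-search
round log, the SSN and its cluster summaries, and the composition
statistics.  `write_outputs` serialises everything as plain-text tables,
and the run report records every threshold so a run is self-describing.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .active_site import apply_active_site_gate
from .alignment import ScoringScheme
from .annotate import SignalCall, length_status, predict_signal
from .iterative import ExpansionResult, RoundLog, expand_to_convergence
from .loops import LoopReferenceSet, LoopThresholds, classify_protein
from .screen import ScreenHit, SeedEnzyme, screen_candidates
from .sequence_io import CatalogEntry, ProteinRecord, catalog_to_frame
from .ssn import build_ssn, components_and_summary, export_graphml, export_tables
from .stats import anova_with_bh, composition_by_sample
from .taxonomy import TaxonomyAssignment, assign_all


@dataclass
class PipelineConfig:
    """Thresholds, toggles and the random seed of one pipeline run."""

    min_identity_pct: float = 25.0
    max_evalue: float = 0.05
    loop_thresholds: LoopThresholds = field(default_factory=LoopThresholds)
    ssn_evalue_threshold: float = 1e-220
    sharing_identity_pct: float = 98.0
    fdr: float = 0.05
    max_rounds: int = 10
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    rng_seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "iterate": True, "classify": True, "annotate": True,
            "taxonomy": True, "ssn": True, "stats": True,
        }
    )


@dataclass
class PipelineResult:
    stage_counts: dict
    hits: list[ScreenHit]
    retained: list[ScreenHit]
    expansion: Optional[ExpansionResult]
    entries: list[CatalogEntry]
    graph: Optional[object]
    clusters: Optional[list]
    cluster_overview: Optional[dict]
    composition: Optional[pd.DataFrame]
    anova: Optional[pd.DataFrame]
    report: str


def run_gusome_pipeline(
    catalog: Sequence[ProteinRecord],
    seeds: Sequence[SeedEnzyme],
    refs: Optional[LoopReferenceSet] = None,
    config: Optional[PipelineConfig] = None,
    hit_table: Optional[dict] = None,
    metadata: Optional[pd.DataFrame] = None,
    completeness: Optional[dict] = None,
    signal_calls: Optional[dict[str, SignalCall]] = None,
) -> PipelineResult:
    """Run the mining pipeline over an in-memory catalog.

    Optional inputs: ``hit_table`` (per-query ranked homology hits for
    taxonomy), ``metadata`` (per-sample factor table for the composition
    ANOVA, requires records to carry ``sample_id``), ``completeness``
    (per-protein gene-call completeness flags; missing ids default to
    complete), ``signal_calls`` (external predictor output overriding the
    built-in heuristic).  Stages toggled off are skipped and their outputs
    left ``None``.  An empty catalog yields empty outputs and zero counts.
    """
    cfg = config or PipelineConfig()
    t0 = time.time()
    lines = [f"gusmap {__version__} pipeline run", ""]
    counts: dict[str, int] = {"catalog": len(catalog)}
    lines.append(
        f"thresholds: identity>{cfg.min_identity_pct}%, E<{cfg.max_evalue}, "
        f"loops {cfg.loop_thresholds}, SSN E<={cfg.ssn_evalue_threshold}, "
        f"sharing>{cfg.sharing_identity_pct}%, FDR={cfg.fdr}, "
        f"max_rounds={cfg.max_rounds}, scoring={cfg.scheme}, seed={cfg.rng_seed}"
    )

    hits = screen_candidates(
        catalog, seeds, cfg.min_identity_pct, cfg.max_evalue, cfg.scheme
    ) if catalog else []
    counts["screened"] = len(hits)
    retained = apply_active_site_gate(hits, seeds, cfg.scheme)
    counts["gated"] = len(retained)
    lines.append(
        f"screen: {counts['catalog']} -> {counts['screened']} -> {counts['gated']}"
    )

    expansion = None
    if cfg.stages.get("iterate", True) and catalog:
        expansion = expand_to_convergence(
            catalog, retained, seeds, cfg.min_identity_pct, cfg.max_evalue,
            cfg.scheme, cfg.max_rounds,
        )
        counts["expansion_new"] = expansion.log.total_new
        lines.append(
            f"iterative search: {expansion.log.total_new} expansion member(s), "
            f"converged={expansion.log.converged} "
            f"after {len(expansion.log.rounds)} round(s)"
        )

    entries: list[CatalogEntry] = []
    member_records = [h.record for h in retained]
    tax: dict[str, TaxonomyAssignment] = {}
    if cfg.stages.get("taxonomy", True) and hit_table is not None:
        tax = assign_all(hit_table, [r.id for r in member_records])
    for hit in retained:
        rec = hit.record
        entry = CatalogEntry(record=rec)
        if cfg.stages.get("classify", True) and refs is not None:
            call = classify_protein(rec, refs, cfg.loop_thresholds, cfg.scheme)
            entry.loop_category = call.category
            entry.loop1_seq = call.loop1_seq
            entry.loop2_seq = call.loop2_seq
        if cfg.stages.get("annotate", True):
            flag = True if completeness is None else completeness.get(rec.id, True)
            entry.length_status = length_status(rec, flag).status
            call = (signal_calls or {}).get(rec.id) or predict_signal(rec)
            entry.signal_call = call.call
        assignment = tax.get(rec.id)
        if assignment is not None and assignment.assigned_rank != "unclear":
            entry.taxonomy = str(assignment)
        entries.append(entry)
    if entries:
        counts["classified"] = sum(1 for e in entries if e.loop_category)

    graph = clusters = overview = None
    if cfg.stages.get("ssn", True) and member_records:
        attributes = {}
        for e in entries:
            attrs: dict = {"source": "run"}
            if e.loop_category:
                attrs["loop_category"] = e.loop_category
            assignment = tax.get(e.record.id)
            if assignment is not None and assignment.phylum:
                attrs["phylum"] = assignment.phylum
            attributes[e.record.id] = attrs
        graph = build_ssn(member_records, attributes,
                          cfg.ssn_evalue_threshold, cfg.scheme)
        clusters, overview = components_and_summary(graph)
        counts["ssn_clusters"] = overview["n_clusters"]
        lines.append(f"ssn: {overview}")

    composition = anova = None
    if cfg.stages.get("stats", True) and metadata is not None and entries:
        rows = [
            {"protein_id": e.record.id, "sample_id": e.record.sample_id,
             "category": e.loop_category}
            for e in entries if e.record.sample_id
        ]
        if rows:
            composition = composition_by_sample(pd.DataFrame(rows))
            anova = anova_with_bh(composition, metadata, cfg.fdr)
            counts["anova_tests"] = len(anova)
            lines.append(
                f"stats: {len(anova)} tests, "
                f"{int(anova['significant'].sum())} BH-significant"
            )

    lines.append("")
    lines.append(f"stage counts: {counts}")
    lines.append(f"elapsed: {time.time() - t0:.1f} s")
    return PipelineResult(
        stage_counts=counts, hits=hits, retained=retained, expansion=expansion,
        entries=entries, graph=graph, clusters=clusters,
        cluster_overview=overview, composition=composition, anova=anova,
        report="\n".join(lines),
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Serialise a pipeline result as plain-text tables under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    catalog_to_frame(result.entries).to_csv(out / "catalog.tsv", sep="\t", index=False)
    if result.expansion is not None:
        result.expansion.log.to_frame().to_csv(
            out / "round_log.tsv", sep="\t", index=False
        )
    if result.graph is not None:
        export_tables(result.graph, out / "ssn_nodes.tsv", out / "ssn_edges.tsv")
        export_graphml(result.graph, out / "ssn.graphml")
    if result.composition is not None:
        result.composition.to_csv(out / "composition.tsv", sep="\t", index=False)
    if result.anova is not None:
        result.anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    (out / "report.txt").write_text(result.report + "\n")
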
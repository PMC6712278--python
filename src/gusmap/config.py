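"""YAML run configuration: seeds, active-site specs, loop references, thresholds.

Active-site residue requirements are data, not code: each seed carries its
own named (position, residue) lists in its own numbering, set by the
deployer from the seed's experimental structure.  A minimal config:

.. code-block:: yaml

    seeds:
      - id: ecoli_gus
        pdb_code: 3K46
        fasta: seeds/ecoli.fasta
        loop_anchor_1: 356
        loop_anchor_2: 416
        active_site:
          NxKG: [[581, N], [582, x], [583, K], [584, G]]
          catalytic_E_1: [[413, E]]
    loop_references:
      loop1: {fasta: refs/loop1.fasta, window: [357, 373]}
      loop2: {fasta: refs/loop2.fasta, window: [417, 430]}
    thresholds:
      min_identity_pct: 25
      max_evalue: 0.05
      ssn_evalue_threshold: 1.0e-220
      sharing_identity_pct: 98
      fdr: 0.05
      max_rounds: 10
    loop_thresholds: {mini_min: 4, mini_max: 9, full_min: 10}
    rng_seed: 0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .active_site import ActiveSiteSpec
from .loops import LoopReference, LoopReferenceSet, LoopThresholds
from .pipeline import PipelineConfig
from .screen import SeedEnzyme
from .sequence_io import read_protein_fasta


def _read_single_fasta(path):
    records = read_protein_fasta(path)
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one sequence, got {len(records)}")
    return records[0]


def load_seeds(doc: dict, base: Path) -> list[SeedEnzyme]:
    seeds = []
    for item in doc.get("seeds", []):
        if "sequence" in item:
            seq = item["sequence"]
        else:
            seq = _read_single_fasta(base / item["fasta"]).sequence
        spec = None
        if "active_site" in item:
            spec = ActiveSiteSpec(
                motifs={
                    name: [(int(p), str(r)) for p, r in sites]
                    for name, sites in item["active_site"].items()
                }
            )
        seeds.append(
            SeedEnzyme(
                id=item["id"],
                sequence=seq,
                pdb_code=item.get("pdb_code", ""),
                active_site_spec=spec,
                loop_anchor_1=item.get("loop_anchor_1"),
                loop_anchor_2=item.get("loop_anchor_2"),
            )
        )
    return seeds


def load_loop_references(doc: dict, base: Path) -> LoopReferenceSet | None:
    section = doc.get("loop_references")
    if not section:
        return None
    refs = {}
    for key in ("loop1", "loop2"):
        item = section[key]
        rec = _read_single_fasta(base / item["fasta"])
        start, end = item["window"]
        refs[key] = LoopReference(record=rec, window_start=int(start), window_end=int(end))
    return LoopReferenceSet(loop1_reference=refs["loop1"], loop2_reference=refs["loop2"])


def load_config(path) -> tuple[list[SeedEnzyme], LoopReferenceSet | None, PipelineConfig]:
    """Load (seeds, loop references, pipeline config) from a YAML file."""
    p = Path(path)
    with open(p) as fh:
        doc = yaml.safe_load(fh) or {}
    base = p.parent
    seeds = load_seeds(doc, base)
    refs = load_loop_references(doc, base)
    thresholds = doc.get("thresholds", {})
    cfg = PipelineConfig(
        min_identity_pct=float(thresholds.get("min_identity_pct", 25.0)),
        max_evalue=float(thresholds.get("max_evalue", 0.05)),
        ssn_evalue_threshold=float(thresholds.get("ssn_evalue_threshold", 1e-220)),
        sharing_identity_pct=float(thresholds.get("sharing_identity_pct", 98.0)),
        fdr=float(thresholds.get("fdr", 0.05)),
        max_rounds=int(thresholds.get("max_rounds", 10)),
        loop_thresholds=LoopThresholds(**doc.get("loop_thresholds", {})),
        rng_seed=int(doc.get("rng_seed", 0)),
        stages={**PipelineConfig().stages, **doc.get("stages", {})},
    )
    return seeds, refs, cfg
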
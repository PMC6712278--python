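"""Identity/E-value candidate screen against structure-anchored seed enzymes.

The first tier of structure-guided family mining: every catalog protein is
locally aligned against each seed enzyme of known structure, and passes
when ANY seed alignment clears both cutoffs — identity strictly above
``min_identity_pct`` and E-value strictly below ``max_evalue`` (boundary
values fail, matching the printed ``>25%`` / ``<0.05`` criteria).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .active_site import ActiveSiteSpec
from .alignment import AlignmentResult, ScoringScheme, estimate_evalue, local_align
from .sequence_io import ProteinRecord


@dataclass
class SeedEnzyme:
    """A structure-anchored reference enzyme.

    ``active_site_spec`` lists the residues the family definition demands,
    in the seed's own 1-based numbering; ``loop_anchor_1``/``loop_anchor_2``
    are the residues after which active-site loop insertions occur.
    """

    id: str
    sequence: str
    pdb_code: str = ""
    active_site_spec: Optional[ActiveSiteSpec] = None
    loop_anchor_1: Optional[int] = None
    loop_anchor_2: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for anchor in (self.loop_anchor_1, self.loop_anchor_2):
            if anchor is not None and not (1 <= anchor <= n):
                raise ValueError(f"{self.id}: loop anchor {anchor} outside sequence")
        if self.active_site_spec is not None:
            for name, sites in self.active_site_spec.motifs.items():
                for pos, _ in sites:
                    if not (1 <= pos <= n):
                        raise ValueError(
                            f"{self.id}: motif {name} position {pos} outside sequence"
                        )


@dataclass
class ScreenHit:
    """A catalog protein together with its best qualifying seed alignment."""

    record: ProteinRecord
    alignment: AlignmentResult  # query = candidate, target = seed
    seed_id: str


def screen_candidates(
    catalog: Sequence[ProteinRecord],
    seeds: Sequence[SeedEnzyme],
    min_identity_pct: float = 25.0,
    max_evalue: float = 0.05,
    scheme: ScoringScheme = ScoringScheme(),
    search_space_len: Optional[int] = None,
) -> list[ScreenHit]:
    """Screen a catalog against seed enzymes.

    The E-value search space defaults to the total residue count of the
    screened catalog.  Returns one :class:`ScreenHit` per passing protein
    (catalog order preserved), recording the best-scoring qualifying seed.
    """
    if not seeds:
        raise ValueError("seed set must be nonempty")
    if search_space_len is None:
        search_space_len = sum(len(r) for r in catalog)
    hits: list[ScreenHit] = []
    for rec in catalog:
        best: Optional[tuple[AlignmentResult, str]] = None
        for seed in seeds:
            aln = local_align(
                rec.sequence,
                seed.sequence,
                scheme,
                query_id=rec.id,
                target_id=seed.id,
            )
            aln.evalue = estimate_evalue(
                aln.score,
                len(rec),
                max(search_space_len, 1),
                scheme.karlin_k,
                scheme.karlin_lambda,
            )
            if aln.identity_pct > min_identity_pct and aln.evalue < max_evalue:
                if best is None or aln.score > best[0].score:
                    best = (aln, seed.id)
        if best is not None:
            hits.append(ScreenHit(record=rec, alignment=best[0], seed_id=best[1]))
    return hits
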
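"""Iterative homology seed expansion to a fixed point.

After the first structure-seeded pass, newly found family members are
themselves used as seeds for further rounds over the remaining catalog,
until a round finds nothing new (or ``max_rounds`` is hit).  Each round
applies the same two criteria as the first pass — the identity/E-value
screen and the active-site gate — with one twist: expansion seeds carry no
curated active-site annotation, so each new seed inherits its discovering
seed's requirements translated through the discovering alignment
(seed -> member position transfer).  Expansion hits are reported in a
separate tier from first-pass members, since their seeding sequences are
not structurally confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .active_site import ActiveSiteSpec, check_active_site, map_seed_positions
from .alignment import ScoringScheme
from .screen import ScreenHit, SeedEnzyme, screen_candidates
from .sequence_io import ProteinRecord


@dataclass
class RoundLog:
    """Per-round new-member ids for an iterative expansion run."""

    rounds: list[tuple[int, list[str]]] = field(default_factory=list)
    converged: bool = False

    @property
    def total_new(self) -> int:
        return sum(len(ids) for _, ids in self.rounds)

    def to_frame(self) -> pd.DataFrame:
        rows, cum = [], 0
        for idx, ids in self.rounds:
            cum += len(ids)
            rows.append({"round": idx, "new_count": len(ids), "cumulative_count": cum})
        return pd.DataFrame(rows, columns=["round", "new_count", "cumulative_count"])


@dataclass
class ExpansionResult:
    log: RoundLog
    members: list[ProteinRecord]          # initial + expansion, discovery order
    expansion_members: list[ProteinRecord]  # the separately-tiered new hits


def _member_as_seed(hit: ScreenHit, parent: SeedEnzyme) -> Optional[SeedEnzyme]:
    """Turn a newly found member into a seed, transferring the parent spec.

    The parent's active-site positions are re-expressed in the member's
    numbering through the discovering alignment (query = member,
    target = parent seed).  Members whose alignment leaves any required
    position unmapped cannot seed further rounds.
    """
    if parent.active_site_spec is None:
        return None
    mapping = map_seed_positions(hit.alignment, parent.active_site_spec.positions())
    try:
        spec = parent.active_site_spec.translate(mapping)
    except ValueError:
        return None
    return SeedEnzyme(id=hit.record.id, sequence=hit.record.sequence,
                      active_site_spec=spec)


def expand_to_convergence(
    catalog: Sequence[ProteinRecord],
    initial_members: Sequence[ScreenHit],
    seeds: Sequence[SeedEnzyme],
    min_identity_pct: float = 25.0,
    max_evalue: float = 0.05,
    scheme: ScoringScheme = ScoringScheme(),
    max_rounds: int = 10,
) -> ExpansionResult:
    """Expand the member set by re-seeding the screen until a fixed point.

    ``initial_members`` are the first-pass hits (with their seed
    alignments); ``seeds`` the structure-anchored seeds they were found
    with.  Each round screens the not-yet-member remainder of the catalog
    using all current members as seeds, gates candidates on active-site
    conservation at transferred positions, and stops at the first empty
    round.  If ``max_rounds`` is exhausted first, the partial result is
    returned with ``converged=False``.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    by_seed_id = {s.id: s for s in seeds}
    member_ids = {h.record.id for h in initial_members}
    # seeds for expansion: the members themselves, specs transferred
    current_seeds: list[SeedEnzyme] = []
    for hit in initial_members:
        parent = by_seed_id.get(hit.seed_id)
        if parent is not None:
            s = _member_as_seed(hit, parent)
            if s is not None:
                current_seeds.append(s)
    search_space = sum(len(r) for r in catalog)
    members: list[ProteinRecord] = [h.record for h in initial_members]
    expansion: list[ProteinRecord] = []
    log = RoundLog()
    for round_idx in range(1, max_rounds + 1):
        remainder = [r for r in catalog if r.id not in member_ids]
        if not remainder or not current_seeds:
            log.rounds.append((round_idx, []))
            log.converged = True
            break
        hits = screen_candidates(
            remainder, current_seeds, min_identity_pct, max_evalue,
            scheme, search_space_len=search_space,
        )
        new_seeds: list[SeedEnzyme] = []
        new_ids: list[str] = []
        seed_lut = {s.id: s for s in current_seeds}
        for hit in hits:
            parent = seed_lut[hit.seed_id]
            ok, _ = check_active_site(hit.record, hit.alignment, parent.active_site_spec)
            if not ok:
                continue
            new_ids.append(hit.record.id)
            member_ids.add(hit.record.id)
            members.append(hit.record)
            expansion.append(hit.record)
            s = _member_as_seed(hit, parent)
            if s is not None:
                new_seeds.append(s)
        log.rounds.append((round_idx, sorted(new_ids)))
        if not new_ids:
            log.converged = True
            break
        current_seeds = current_seeds + new_seeds
    return ExpansionResult(log=log, members=members, expansion_members=expansion)
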
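"""Active-site residue verification by alignment position mapping.

The second tier of structure-guided mining: a candidate that clears the
identity/E-value screen is kept only if its alignment to a seed enzyme
conserves every family-defining active-site residue — for GUS, the NxKG
motif whose asparagine/lysine pair coordinates the glucuronate
carboxylate, the two catalytic glutamates, and the N and Y motifs.  Each
requirement is a named list of (seed position, required residue) pairs;
a wildcard residue (``x`` / ``*``) only requires the position be aligned.
Residue match is exact — no conservative-substitution tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, TYPE_CHECKING

from .alignment import AlignmentResult
from .sequence_io import AMINO_ALPHABET, ProteinRecord

if TYPE_CHECKING:  # pragma: no cover
    from .screen import ScreenHit, SeedEnzyme

WILDCARDS = {"x", "X", "*", "."}


@dataclass
class ActiveSiteSpec:
    """Named active-site requirements in a seed's own 1-based numbering."""

    motifs: dict[str, list[tuple[int, str]]]

    def __post_init__(self) -> None:
        for name, sites in self.motifs.items():
            positions = [p for p, _ in sites]
            if positions != sorted(positions) or len(set(positions)) != len(positions):
                raise ValueError(f"motif {name}: positions must be strictly increasing")
            for pos, res in sites:
                if pos < 1:
                    raise ValueError(f"motif {name}: positions are 1-based")
                if res not in WILDCARDS and res not in AMINO_ALPHABET:
                    raise ValueError(f"motif {name}: illegal residue {res!r}")

    def positions(self) -> list[int]:
        return sorted({p for sites in self.motifs.values() for p, _ in sites})

    def translate(self, mapping: dict[int, Optional[int]]) -> "ActiveSiteSpec":
        """Re-express the spec in another sequence's numbering via ``mapping``.

        Used by the iterative search to transfer a seed's requirements onto
        a newly discovered member through their alignment; raises if any
        required position is unmapped.
        """
        motifs: dict[str, list[tuple[int, str]]] = {}
        for name, sites in self.motifs.items():
            new_sites = []
            for pos, res in sites:
                new = mapping.get(pos)
                if new is None:
                    raise ValueError(f"motif {name}: position {pos} unmapped")
                new_sites.append((new, res))
            motifs[name] = new_sites
        return ActiveSiteSpec(motifs=motifs)


def map_seed_positions(
    aln: AlignmentResult, positions: Sequence[int], seed_side: str = "target"
) -> dict[int, Optional[int]]:
    """Map seed positions to candidate positions through the alignment.

    A seed position paired with a gap, or outside the local alignment
    span, maps to ``None``.
    """
    return aln.map_positions(positions, side=seed_side)


def check_active_site(
    candidate: ProteinRecord,
    aln: AlignmentResult,
    spec: ActiveSiteSpec,
    seed_side: str = "target",
) -> tuple[bool, list[str]]:
    """Verify every spec requirement through the candidate/seed alignment.

    Passes iff every non-wildcard required residue maps to an aligned
    candidate position carrying exactly that residue; wildcard positions
    need only be aligned.  Returns (pass, names of failed motifs).
    """
    mapping = map_seed_positions(aln, spec.positions(), seed_side=seed_side)
    failed: list[str] = []
    for name, sites in spec.motifs.items():
        ok = True
        for pos, res in sites:
            cand_pos = mapping.get(pos)
            if cand_pos is None:
                ok = False
                break
            if res not in WILDCARDS and candidate.sequence[cand_pos - 1] != res:
                ok = False
                break
        if not ok:
            failed.append(name)
    return (not failed, failed)


def apply_active_site_gate(
    hits: Sequence["ScreenHit"],
    seeds: Sequence["SeedEnzyme"],
    scheme=None,
) -> list["ScreenHit"]:
    """Retain candidates conserving the active site of at least one seed.

    Each candidate is first checked against its recorded best seed's
    alignment; if that fails, the remaining seeds are tried (fresh local
    alignments).  The gate is idempotent and only ever shrinks the set.
    """
    from .alignment import ScoringScheme, local_align  # local import: cycle

    if scheme is None:
        scheme = ScoringScheme()
    by_id = {s.id: s for s in seeds}
    retained: list["ScreenHit"] = []
    for hit in hits:
        order = [by_id[hit.seed_id]] if hit.seed_id in by_id else []
        order += [s for s in seeds if s.id != hit.seed_id]
        for seed in order:
            if seed.active_site_spec is None:
                continue
            if seed.id == hit.seed_id:
                aln = hit.alignment
            else:
                aln = local_align(
                    hit.record.sequence, seed.sequence, scheme,
                    query_id=hit.record.id, target_id=seed.id,
                )
            ok, _ = check_active_site(hit.record, aln, seed.active_site_spec)
            if ok:
                retained.append(hit)
                break
    return retained
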
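"""Two-tier consensus taxonomy from precomputed ranked homology hits.

Taxonomy is assigned from a user-supplied, ranked hit table (BLASTP-style
tabular output against a comprehensive protein database, with lineages
attached) — never from live database queries.

Tier 1: when the top-scoring hit is >= 95% identical, the query is
assigned the lowest common ancestor (LCA) of the lineages of ALL hits at
>= 95% identity.  Tier 2: otherwise the top five hits are compared and
the query is assigned the deepest rank on which all of them agree.  A
query with no usable hits, or whose tier-2 hits disagree at every rank
down to phylum, is "unclear".

Lineages are ordered root -> species on a fixed rank ladder
(superkingdom, phylum, class, order, family, genus, species) and may be
truncated.  Ranks are compared by name at each depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

TIER1_IDENTITY = 95.0
TIER2_TOP_N = 5


@dataclass
class HitRecord:
    subject_id: str
    identity_pct: float
    score: float
    lineage: list[str]  # root -> species, possibly truncated


@dataclass
class TaxonomyAssignment:
    lineage: list[str]
    assigned_rank: str  # rank name of the deepest element, or "unclear"

    @property
    def phylum(self) -> Optional[str]:
        return self.lineage[1] if len(self.lineage) >= 2 else None

    def __str__(self) -> str:
        return ";".join(self.lineage) if self.lineage else "unclear"


UNCLEAR = TaxonomyAssignment(lineage=[], assigned_rank="unclear")


def lineage_lca(lineages: Sequence[Sequence[str]]) -> list[str]:
    """Longest common prefix of the lineages (position-wise name equality)."""
    if not lineages:
        return []
    out: list[str] = []
    for depth in range(min(len(l) for l in lineages)):
        names = {l[depth] for l in lineages}
        if len(names) != 1:
            break
        out.append(next(iter(names)))
    return out


def _finish(lineage: list[str]) -> TaxonomyAssignment:
    # agreement must reach at least the phylum rank — similarity to more
    # than one phylum is the definition of unclear phylogeny
    if len(lineage) < 2:
        return UNCLEAR
    depth = min(len(lineage), len(RANKS))
    return TaxonomyAssignment(lineage=lineage[:depth], assigned_rank=RANKS[depth - 1])


def assign_taxonomy(hits: Sequence[HitRecord]) -> TaxonomyAssignment:
    """Assign a lineage to one query from its ranked hit list.

    Hits are (re-)sorted by score descending with subject id as a
    deterministic tie-break, so the result is invariant under permutation
    of equally scored hits.  Hits with empty lineages are skipped with a
    warning.
    """
    usable = []
    for h in hits:
        if not h.lineage:
            warnings.warn(f"hit {h.subject_id}: empty lineage skipped")
            continue
        usable.append(h)
    if not usable:
        return UNCLEAR
    ranked = sorted(usable, key=lambda h: (-h.score, h.subject_id))
    if ranked[0].identity_pct >= TIER1_IDENTITY:
        strong = [h.lineage for h in ranked if h.identity_pct >= TIER1_IDENTITY]
        return _finish(lineage_lca(strong))
    top = ranked[:TIER2_TOP_N]
    if len(top) < 2:
        return UNCLEAR  # a lone sub-95% hit cannot form a consensus
    return _finish(lineage_lca([h.lineage for h in top]))


def read_hit_table(path) -> dict[str, list[HitRecord]]:
    """Read a delimited hit table into per-query ranked hit lists.

    Tab-separated columns: query_id, subject_id, identity_pct, score,
    semicolon-delimited lineage (root -> species).
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["query_id", "subject_id", "identity_pct", "score", "lineage"],
        comment="#", dtype=str,
    )
    out: dict[str, list[HitRecord]] = {}
    for row in df.itertuples(index=False):
        lineage = [t for t in str(row.lineage).split(";") if t and t != "nan"]
        out.setdefault(str(row.query_id), []).append(
            HitRecord(
                subject_id=str(row.subject_id),
                identity_pct=float(row.identity_pct),
                score=float(row.score),
                lineage=lineage,
            )
        )
    return out


def assign_all(hit_table: dict[str, list[HitRecord]], query_ids: Sequence[str]) -> dict[str, TaxonomyAssignment]:
    """Assign every query; queries missing from the table are unclear."""
    return {q: assign_taxonomy(hit_table.get(q, [])) for q in query_ids}
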
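"""Active-site loop extraction and seven-category architecture classification.

Glycoside hydrolase family 2 β-glucuronidases differ functionally in two
highly variable loops at the active site, corresponding to insertions
after E. coli GUS residues 356 (loop 1) and 416 (loop 2).  Each candidate
is aligned against two annotated reference enzymes — one carrying a
canonical loop 1, one a canonical loop 2 — and the residues falling
between the reference residues flanking the annotated loop window are
counted as that candidate's insertion.

Categories (closed set of seven):

====== =================================================
L1     full insertion at loop 1
L2     full insertion at loop 2
mL1    mini insertion at loop 1 only
mL2    mini insertion at loop 2 only
mL1_2  mini insertions at both
NL     no insertion at either
NC     no alignment coverage at one or both loop windows
====== =================================================

Default thresholds (configurable, per loop): no-loop ≤ 3 residues, mini
4–9, full ≥ 10.  An 8-residue loop-2 insertion therefore classifies as
mini-loop 2 — the borderline case between mini-loop 2 and no-loop.  A
full loop at either position dominates a mini at the other; should both
positions carry full loops, the longer insertion wins (loop 1 on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import ScoringScheme, global_align
from .sequence_io import ProteinRecord


@dataclass(frozen=True)
class LoopThresholds:
    """Per-loop residue-count bounds for the category table."""

    mini_min: int = 4
    mini_max: int = 9
    full_min: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.mini_min <= self.mini_max < self.full_min):
            raise ValueError(
                "thresholds must satisfy 0 < mini_min <= mini_max < full_min"
            )


@dataclass
class LoopReference:
    """A reference enzyme with an annotated loop window (1-based, inclusive).

    The window is the reference's own loop; the residues at
    ``window_start - 1`` and ``window_end + 1`` are the flanks between
    which candidate insertions are measured.
    """

    record: ProteinRecord
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        n = len(self.record.sequence)
        if not (2 <= self.window_start <= self.window_end <= n - 1):
            raise ValueError(
                f"{self.record.id}: loop window [{self.window_start}, "
                f"{self.window_end}] must leave flanking residues within 1..{n}"
            )

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start + 1


@dataclass
class LoopReferenceSet:
    loop1_reference: LoopReference
    loop2_reference: LoopReference


@dataclass
class LoopCall:
    """Insertion lengths/sequences at the two anchors plus the category."""

    loop1_len: Optional[int]
    loop2_len: Optional[int]
    loop1_seq: Optional[str]
    loop2_seq: Optional[str]
    category: str


_MAX_FLANK_SLIDE = 25


def _measure_window(
    protein: ProteinRecord, ref: LoopReference, scheme: ScoringScheme
) -> tuple[Optional[int], Optional[str]]:
    """Count candidate residues between the reference loop flanks.

    Overlap (free-end-gap) alignment lets fragments align where they can.
    Optimal alignments can place an insertion gap so that a flank residue
    itself slides into the window; when a flank pairs with a gap the
    nearest aligned reference position outside the window is used instead
    and the count corrected by the slide distance.  Coverage requires
    aligned reference positions within ``_MAX_FLANK_SLIDE`` residues on
    both sides of the window.
    """
    aln = global_align(
        protein.sequence,
        ref.record.sequence,
        scheme,
        query_id=protein.id,
        target_id=ref.record.id,
        free_end_gaps=True,
    )
    left, right = ref.window_start - 1, ref.window_end + 1
    lut = {t: q for q, t in aln.pairs}
    slid_left = max((t for t in lut if t <= left), default=None)
    slid_right = min((t for t in lut if t >= right), default=None)
    if (
        slid_left is None
        or slid_right is None
        or left - slid_left > _MAX_FLANK_SLIDE
        or slid_right - right > _MAX_FLANK_SLIDE
    ):
        return None, None
    ql, qr = lut[slid_left], lut[slid_right]
    if qr <= ql:
        return None, None
    seq = protein.sequence[ql : qr - 1]  # residues strictly between brackets
    # trim residues belonging to reference positions outside the window
    trim_l = min(left - slid_left, len(seq))
    seq = seq[trim_l:]
    trim_r = min(slid_right - right, len(seq))
    seq = seq[: len(seq) - trim_r] if trim_r else seq
    return len(seq), seq


def extract_loop_windows(
    protein: ProteinRecord,
    refs: LoopReferenceSet,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[Optional[int], Optional[str], Optional[int], Optional[str]]:
    """Measure loop-1 and loop-2 insertions for one protein.

    Returns ``(loop1_len, loop1_seq, loop2_len, loop2_seq)``; a loop is
    ``None`` when the candidate's alignment does not cover both flanks of
    that reference window.
    """
    l1, s1 = _measure_window(protein, refs.loop1_reference, scheme)
    l2, s2 = _measure_window(protein, refs.loop2_reference, scheme)
    return l1, s1, l2, s2


def classify(
    loop1_len: Optional[int],
    loop2_len: Optional[int],
    thresholds: LoopThresholds = LoopThresholds(),
) -> str:
    """Assign one of the seven categories from the two insertion lengths.

    ``None`` lengths mean missing coverage.  Total and deterministic; the
    categories are mutually exclusive and exhaustive.
    """
    t = thresholds
    if loop1_len is None or loop2_len is None:
        return "NC"
    full1 = loop1_len >= t.full_min
    full2 = loop2_len >= t.full_min
    mini1 = t.mini_min <= loop1_len <= t.mini_max
    mini2 = t.mini_min <= loop2_len <= t.mini_max
    if full1 and full2:
        return "L2" if loop2_len > loop1_len else "L1"
    if full1:
        return "L1"
    if full2:
        return "L2"
    if mini1 and mini2:
        return "mL1_2"
    if mini1:
        return "mL1"
    if mini2:
        return "mL2"
    return "NL"


def classify_protein(
    protein: ProteinRecord,
    refs: LoopReferenceSet,
    thresholds: LoopThresholds = LoopThresholds(),
    scheme: ScoringScheme = ScoringScheme(),
) -> LoopCall:
    """Extract loop windows and classify one protein."""
    l1, s1, l2, s2 = extract_loop_windows(protein, refs, scheme)
    return LoopCall(
        loop1_len=l1, loop2_len=l2, loop1_seq=s1, loop2_seq=s2,
        category=classify(l1, l2, thresholds),
    )
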
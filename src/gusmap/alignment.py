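"""Pairwise alignment kernel and Karlin–Altschul E-value model.

Local (Smith–Waterman) alignment with BLOSUM62 and affine gaps is the
workhorse of the homology screen; global and overlap (free-end-gap) modes
serve the cross-catalog sharing test and loop-window extraction.  The
kernel is Biopython's :class:`Bio.Align.PairwiseAligner`; any backend that
returns :class:`AlignmentResult` objects (including the reader for
12-column tabular search output below) can substitute for it.

Gap convention: a gap of length *k* costs ``gap_open + k * gap_extend``
(the BLAST "existence 11, extension 1" convention).

E-values follow the Karlin–Altschul form ``E = K * m * n * exp(-lambda*S)``
with *m* the query length and *n* the residues in the searched space.  The
default gapped-BLOSUM62 parameters (K = 0.041, lambda = 0.267) are
configuration, not dogma — override them in :class:`ScoringScheme` to match
an external engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and E-value parameters."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0  # cost of the first residue of a gap, minus extend
    gap_extend: float = 1.0
    karlin_k: float = 0.041
    karlin_lambda: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.karlin_k <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be positive")


@dataclass
class AlignmentResult:
    """One pairwise alignment with identity over its aligned columns.

    ``pairs`` holds the 1-based aligned residue pairs (query_pos,
    target_pos), strictly increasing in both coordinates.  ``columns`` is
    the number of alignment columns within the aligned span, gaps
    included — the denominator of ``identity_pct``.
    """

    query_id: str
    target_id: str
    score: float
    identity_pct: float
    columns: int
    pairs: list[tuple[int, int]]
    evalue: Optional[float] = None

    def map_positions(self, positions: Sequence[int], side: str = "target") -> dict[int, Optional[int]]:
        """Map 1-based positions on one sequence to the other through the alignment.

        ``side`` names the sequence the input positions live on; a position
        paired with a gap, or outside the aligned span, maps to ``None``.
        """
        if side == "target":
            lut = {t: q for q, t in self.pairs}
        elif side == "query":
            lut = {q: t for q, t in self.pairs}
        else:
            raise ValueError("side must be 'query' or 'target'")
        return {p: lut.get(p) for p in positions}


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    # Biopython charges open_gap_score on the first gap residue; our
    # convention charges open + extend for it.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    if mode == "overlap":
        aligner.mode = "global"
        try:  # attribute names changed across Biopython releases
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # pragma: no cover
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    else:
        aligner.mode = mode
    return aligner


def _result_from_biopython(aln, query: str, target: str, query_id: str, target_id: str) -> AlignmentResult:
    qblocks, tblocks = aln.aligned
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        for off in range(qe - qs):
            qi, ti = qs + off, ts + off
            pairs.append((qi + 1, ti + 1))
            if query[qi] == target[ti]:
                matches += 1
    if pairs:
        qspan = pairs[-1][0] - pairs[0][0] + 1
        tspan = pairs[-1][1] - pairs[0][1] + 1
        # columns in the aligned span: matched pairs plus interior gaps
        columns = len(pairs) + (qspan - len(pairs)) + (tspan - len(pairs))
        identity = 100.0 * matches / columns
    else:
        columns = 0
        identity = 0.0
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        score=float(aln.score),
        identity_pct=identity,
        columns=columns,
        pairs=pairs,
    )


def local_align(
    query: str,
    target: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentResult:
    """Optimal local alignment under the scheme's scoring.

    Ties among co-optimal alignments are broken by the kernel's canonical
    first traceback, which is deterministic for fixed inputs.
    """
    if not query or not target:
        raise ValueError("both sequences must be nonempty")
    aligner = _make_aligner(scheme, "local")
    alns = aligner.align(query, target)
    try:
        best = alns[0]
    except IndexError:
        # no pair scores positively: the optimal local alignment is empty
        return AlignmentResult(query_id=query_id, target_id=target_id,
                               score=0.0, identity_pct=0.0, columns=0, pairs=[])
    return _result_from_biopython(best, query, target, query_id, target_id)


def global_align(
    query: str,
    target: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    target_id: str = "target",
    free_end_gaps: bool = False,
) -> AlignmentResult:
    """End-to-end (or, with ``free_end_gaps``, overlap) alignment.

    For the strict global mode ``columns`` counts the full alignment
    length including end gaps, so ``identity_pct`` is identity over the
    whole alignment — the denominator used by the >98% sharing test.
    """
    if not query or not target:
        raise ValueError("both sequences must be nonempty")
    aligner = _make_aligner(scheme, "overlap" if free_end_gaps else "global")
    res = _result_from_biopython(
        aligner.align(query, target)[0], query, target, query_id, target_id
    )
    if not free_end_gaps and res.pairs:
        # extend the denominator to the full alignment, end gaps included
        lead = max(res.pairs[0][0] - 1, res.pairs[0][1] - 1)
        trail = max(len(query) - res.pairs[-1][0], len(target) - res.pairs[-1][1])
        matches = round(res.identity_pct * res.columns / 100.0)
        res.columns += lead + trail
        res.identity_pct = 100.0 * matches / res.columns if res.columns else 0.0
    return res


def estimate_evalue(
    score: float,
    query_len: int,
    search_space_len: int,
    K: float = 0.041,
    lam: float = 0.267,
) -> float:
    """Karlin–Altschul expected hit count: ``K * m * n * exp(-lambda * S)``.

    Underflows to 0.0 for very high scores, which is the correct limit.
    """
    if query_len < 1 or search_space_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    try:
        return K * query_len * search_space_len * math.exp(-lam * score)
    except OverflowError:
        return math.inf


#: Column names of the conventional 12-column tabular search output.
TABULAR_COLUMNS = [
    "query_id",
    "subject_id",
    "identity_pct",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_tabular_hits(path) -> pd.DataFrame:
    """Read 12-column tabular homology-search output (BLAST outfmt-6 style).

    Returns a DataFrame with canonical column names and numeric dtypes;
    rows can be adapted into :class:`AlignmentResult` objects (without
    residue-level pairs) for use as an external screening backend.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=TABULAR_COLUMNS, comment="#")
    for col in TABULAR_COLUMNS[2:]:
        df[col] = pd.to_numeric(df[col])
    return df


def tabular_row_to_result(row) -> AlignmentResult:
    """Adapt one tabular hit row into an AlignmentResult (no residue pairs)."""
    qs, qe = int(row["qstart"]), int(row["qend"])
    ts, te = int(row["sstart"]), int(row["send"])
    return AlignmentResult(
        query_id=str(row["query_id"]),
        target_id=str(row["subject_id"]),
        score=float(row["bitscore"]),
        identity_pct=float(row["identity_pct"]),
        columns=int(row["length"]),
        pairs=[(qs, ts), (qe, te)] if qe >= qs else [],
        evalue=float(row["evalue"]),
    )
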
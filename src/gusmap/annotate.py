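"""Protein length-status and rule-based signal-peptide annotation.

Metagenome gene calls frequently truncate the 5' end, so a protein's
printed length is only trusted when its sequence begins with methionine
AND the upstream gene call is flagged complete; everything else is
"unclear".

The signal-peptide caller is a deliberately simple, fully documented
rule-based predictor of Sec/peptidase-I export signals (n-region,
h-region, cleavage motif), designed so annotation runs offline and
deterministically.  Users who run a dedicated external predictor can feed
its tabular output through :func:`parse_external_signal_table` instead —
the two paths produce the same :class:`SignalCall` surface.

Rules, fixed and versioned with the package:

1. no starting methionine -> ``uncertain`` (length/start cannot be trusted);
2. ``present`` requires, within the first 40 residues, all of:
   an n-region (>= 1 K/R among residues 1-7), an h-region (a 7-residue
   window with >= 6 residues from {A,I,L,M,F,V,W,C}), and a peptidase-I
   cleavage motif (small residues from {A,G,S,T,C} at the -3 and -1
   positions of a cleavage site located between residues 15 and 40,
   after the h-region);
3. a cysteine immediately following the predicted cleavage site
   downgrades ``present`` to ``uncertain`` (possible lipoprotein,
   ambiguous peptidase class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .sequence_io import ProteinRecord

HYDROPHOBIC = frozenset("AILMFVWC")
SMALL = frozenset("AGSTC")
BASIC = frozenset("KR")

_N_REGION_SPAN = 7      # residues scanned for K/R
_H_WINDOW = 7           # h-region window length
_H_MIN_HYDRO = 6        # hydrophobic residues required in the window
_CLEAVE_MIN = 15        # earliest cleavage position (1-based)
_CLEAVE_MAX = 40        # latest cleavage position


@dataclass
class LengthStatus:
    status: str  # "confirmed" | "unclear"
    length: int


@dataclass
class SignalCall:
    call: str  # "present" | "absent" | "uncertain"
    cleavage_site: Optional[int] = None  # 1-based last residue of the signal
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.call == "present") != (self.cleavage_site is not None):
            raise ValueError("cleavage_site present iff call is present")


def length_status(record: ProteinRecord, completeness_flag: bool = True) -> LengthStatus:
    """Confirmed iff the sequence starts with M and the gene call is complete."""
    ok = record.sequence.startswith("M") and completeness_flag
    return LengthStatus(status="confirmed" if ok else "unclear", length=len(record))


def predict_signal(record: ProteinRecord) -> SignalCall:
    """Rule-based Sec/peptidase-I signal-peptide call (see module docstring)."""
    seq = record.sequence
    if not seq.startswith("M"):
        return SignalCall(call="uncertain", reason="no starting methionine")
    head = seq[: _CLEAVE_MAX]
    if not (BASIC & set(head[:_N_REGION_SPAN])):
        return SignalCall(call="absent", reason="no n-region (K/R in first 7)")
    h_start = None  # 0-based start of the first qualifying h-window
    for i in range(0, len(head) - _H_WINDOW + 1):
        window = head[i : i + _H_WINDOW]
        if sum(r in HYDROPHOBIC for r in window) >= _H_MIN_HYDRO:
            h_start = i
            break
    if h_start is None:
        return SignalCall(call="absent", reason="no h-region")
    for c in range(max(_CLEAVE_MIN, h_start + _H_WINDOW + 1), _CLEAVE_MAX + 1):
        # cleavage after residue c; -1 residue at c, -3 residue at c-2 (1-based)
        if c > len(seq) - 1 or c - 3 < 0:
            continue
        if seq[c - 1] in SMALL and seq[c - 3] in SMALL:
            if c < len(seq) and seq[c] == "C":
                return SignalCall(
                    call="uncertain",
                    reason="cysteine immediately after predicted peptidase I site",
                )
            return SignalCall(call="present", cleavage_site=c, reason="n/h/c regions found")
    return SignalCall(call="absent", reason="no peptidase I cleavage motif")


def parse_external_signal_table(path) -> dict[str, SignalCall]:
    """Parse an external signal-peptide predictor's tabular output.

    Expected tab-separated columns: protein id, best class (SpI, SpII,
    TMH, CYT), optional cleavage site as ``start-end`` (cut between the
    two).  Signal-peptidase classes with a cleavage site map to
    ``present``; membrane/cytoplasmic classes map to ``absent``.
    Unparseable rows are skipped with a warning and counted.
    """
    calls: dict[str, SignalCall] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                pid, klass = parts[0], parts[1]
                if klass in ("SpI", "SpII"):
                    if len(parts) < 3 or "-" not in parts[2]:
                        raise ValueError("signal class without cleavage site")
                    site = int(parts[2].split("-")[0])
                    calls[pid] = SignalCall(call="present", cleavage_site=site,
                                            reason=f"external: {klass}")
                elif klass in ("TMH", "CYT"):
                    calls[pid] = SignalCall(call="absent", reason=f"external: {klass}")
                else:
                    raise ValueError(f"unknown class {klass!r}")
            except (IndexError, ValueError) as exc:
                skipped += 1
                warnings.warn(f"signal table line {lineno} skipped: {exc}")
    if skipped:
        warnings.warn(f"signal table: {skipped} row(s) skipped")
    return calls
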
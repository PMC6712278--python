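"""Protein FASTA and catalog-table I/O.

A *catalog* is an ordered collection of predicted proteins from an assembled
metagenome.  This module reads and writes the two plain-text surfaces the
rest of the package works from: multi-record protein FASTA files and
delimited/spreadsheet catalog tables carrying per-protein annotations
(loop category, loop-region sequences, taxonomy, length status, signal
call).  Exact-string deduplication lives here; near-duplicate collapsing at
an identity threshold is a network-analysis concern (see
:mod:`gusmap.ssn`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

# 20 standard residues plus X for ambiguity.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: The seven loop-architecture categories (see :mod:`gusmap.loops`).
LOOP_CATEGORIES = ("L1", "L2", "mL1", "mL2", "mL1_2", "NL", "NC")

# Normalisation map for the category strings found in the wild.
_CATEGORY_ALIASES = {
    "l1": "L1",
    "loop 1": "L1",
    "loop1": "L1",
    "l2": "L2",
    "loop 2": "L2",
    "loop2": "L2",
    "ml1": "mL1",
    "mini-loop 1": "mL1",
    "mini loop 1": "mL1",
    "mini-loop1": "mL1",
    "ml2": "mL2",
    "mini-loop 2": "mL2",
    "mini loop 2": "mL2",
    "mini-loop2": "mL2",
    "ml1_2": "mL1_2",
    "ml1,2": "mL1_2",
    "mini-loop 1,2": "mL1_2",
    "mini loop 1,2": "mL1_2",
    "nl": "NL",
    "no loop": "NL",
    "no-loop": "NL",
    "noloop": "NL",
    "nc": "NC",
    "no coverage": "NC",
    "no-coverage": "NC",
}


class FastaFormatError(ValueError):
    """Malformed FASTA input (carries the offending line number)."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class CatalogValidationError(ValueError):
    """A catalog table row violates the schema."""


@dataclass
class ProteinRecord:
    """One catalog protein.

    ``id`` is the first whitespace-delimited header token; the full header
    is retained as ``description``.  ``sample_id`` identifies the
    metagenome sample of origin when known (parsed from a ``sample=``
    token in the header, if present).
    """

    id: str
    sequence: str
    sample_id: Optional[str] = None
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be nonempty")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CatalogEntry:
    """One annotated catalog row (the Table-S2-style layout)."""

    record: ProteinRecord
    loop_category: Optional[str] = None
    loop1_seq: Optional[str] = None
    loop2_seq: Optional[str] = None
    taxonomy: Optional[str] = None
    length_status: str = "unclear"
    signal_call: Optional[str] = None

    def __post_init__(self) -> None:
        if self.loop_category is not None:
            self.loop_category = normalize_category(self.loop_category)
        if self.length_status not in ("confirmed", "unclear"):
            raise CatalogValidationError(
                f"{self.record.id}: length_status must be confirmed/unclear, "
                f"got {self.length_status!r}"
            )
        if self.loop_category == "NC" and (self.loop1_seq and self.loop2_seq):
            raise CatalogValidationError(
                f"{self.record.id}: 'no coverage' entries cannot carry both "
                "loop sequences"
            )


def normalize_category(value: str) -> str:
    """Map a free-form loop-category string onto the seven-value enum."""
    key = value.strip()
    if key in LOOP_CATEGORIES:
        return key
    canon = _CATEGORY_ALIASES.get(key.lower())
    if canon is None:
        raise CatalogValidationError(f"unknown loop category {value!r}")
    return canon


_SAMPLE_RE = re.compile(r"\bsample=(\S+)")


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into an ordered list of records.

    Sequences are uppercased; a single terminal ``*`` (stop symbol) is
    stripped.  Internal ``*`` or residues outside the 20-letter alphabet
    (plus X) raise :class:`FastaFormatError` naming the line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []
    seq_lines: list[tuple[int, str]] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        star = seq.find("*")
        if star != -1 and star != len(seq) - 1:
            off = 0
            for ln, part in seq_lines:
                if star < off + len(part):
                    raise FastaFormatError("internal '*' in sequence", ln)
                off += len(part)
        if seq.endswith("*"):
            seq = seq[:-1]
        tokens = header.split(None, 1)
        if not tokens:
            raise FastaFormatError("empty FASTA header", header_line)
        rid = tokens[0]
        if rid in seen:
            raise FastaFormatError(f"duplicate id {rid!r}", header_line)
        seen.add(rid)
        m = _SAMPLE_RE.search(header)
        try:
            rec = ProteinRecord(
                id=rid,
                sequence=seq,
                sample_id=m.group(1) if m else None,
                description=header,
            )
        except ValueError as exc:
            raise FastaFormatError(str(exc), header_line) from exc
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                seq_lines = []
                if not header:
                    raise FastaFormatError("empty FASTA header", lineno)
            else:
                if header is None:
                    raise FastaFormatError(
                        "sequence data before first header", lineno
                    )
                up = line.upper()
                bad = set(up) - AMINO_ALPHABET - {"*"}
                if bad:
                    raise FastaFormatError(
                        f"illegal residue character(s) {sorted(bad)}", lineno
                    )
                chunks.append(up)
                seq_lines.append((lineno, up))
        flush()
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as multi-line FASTA (ids only; description if set)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def dedup_exact(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the first occurrence of each exact sequence string.

    Input order is otherwise preserved; the operation is idempotent.
    """
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


_CATALOG_COLUMNS = [
    "id",
    "sequence",
    "sample_id",
    "loop_category",
    "loop1_seq",
    "loop2_seq",
    "taxonomy",
    "length_status",
    "signal_call",
]


def _read_table(path, dialect: Optional[str]) -> pd.DataFrame:
    p = Path(path)
    kind = dialect or p.suffix.lstrip(".").lower()
    if kind in ("xlsx", "xls"):
        return pd.read_excel(p, dtype=str)
    sep = {"csv": ",", "tsv": "\t"}.get(kind, "\t")
    return pd.read_csv(p, sep=sep, dtype=str)


def read_catalog_table(path, dialect: Optional[str] = None) -> list[CatalogEntry]:
    """Read an annotated catalog table (TSV/CSV/XLSX by extension or ``dialect``).

    Missing cells map to absent fields; category strings are normalised to
    the seven-value enum; an unknown category raises
    :class:`CatalogValidationError` naming the offending row.
    """
    df = _read_table(path, dialect)
    df.columns = [str(c).strip().lower() for c in df.columns]
    entries: list[CatalogEntry] = []
    for i, row in df.iterrows():
        def cell(name: str) -> Optional[str]:
            v = row.get(name)
            if v is None or (isinstance(v, float) and pd.isna(v)) or pd.isna(v):
                return None
            v = str(v).strip()
            return v or None

        try:
            rec = ProteinRecord(
                id=cell("id") or "",
                sequence=(cell("sequence") or "").upper().rstrip("*"),
                sample_id=cell("sample_id"),
            )
            entry = CatalogEntry(
                record=rec,
                loop_category=cell("loop_category"),
                loop1_seq=cell("loop1_seq"),
                loop2_seq=cell("loop2_seq"),
                taxonomy=cell("taxonomy"),
                length_status=cell("length_status") or "unclear",
                signal_call=cell("signal_call"),
            )
        except (ValueError, CatalogValidationError) as exc:
            raise CatalogValidationError(f"row {i + 2}: {exc}") from exc
        entries.append(entry)
    return entries


def catalog_to_frame(entries: Sequence[CatalogEntry]) -> pd.DataFrame:
    """Flatten catalog entries into a DataFrame with the canonical columns."""
    rows = []
    for e in entries:
        rows.append(
            {
                "id": e.record.id,
                "sequence": e.record.sequence,
                "sample_id": e.record.sample_id,
                "loop_category": e.loop_category,
                "loop1_seq": e.loop1_seq,
                "loop2_seq": e.loop2_seq,
                "taxonomy": e.taxonomy,
                "length_status": e.length_status,
                "signal_call": e.signal_call,
            }
        )
    return pd.DataFrame(rows, columns=_CATALOG_COLUMNS)


def write_catalog_table(entries: Sequence[CatalogEntry], path, dialect: Optional[str] = None) -> None:
    """Write catalog entries as TSV/CSV/XLSX (chosen by extension or ``dialect``)."""
    df = catalog_to_frame(entries)
    p = Path(path)
    kind = dialect or p.suffix.lstrip(".").lower()
    if kind in ("xlsx", "xls"):
        df.to_excel(p, index=False)
    else:
        df.to_csv(p, sep="," if kind == "csv" else "\t", index=False)
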
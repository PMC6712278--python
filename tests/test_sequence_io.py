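"""FASTA/catalog I/O: parsing contracts, round-trips, deduplication."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gusmap.sequence_io import (
    CatalogEntry,
    CatalogValidationError,
    FastaFormatError,
    ProteinRecord,
    dedup_exact,
    normalize_category,
    read_catalog_table,
    read_protein_fasta,
    write_catalog_table,
    write_protein_fasta,
)

AMINO = "ACDEFGHIKLMNPQRSTWYV"

seq_strategy = st.text(alphabet=AMINO + "X", min_size=1, max_size=40)


def test_empty_file_gives_empty_collection(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_protein_fasta(p) == []


def test_single_record_parsed(tmp_path):
    p = tmp_path / "one.fasta"
    p.write_text(">p1 some description sample=S7\nMKL\n")
    (rec,) = read_protein_fasta(p)
    assert rec.id == "p1"
    assert len(rec) == 3
    assert rec.sample_id == "S7"
    assert rec.description.startswith("p1 some")


def test_terminal_stop_stripped_internal_stop_rejected(tmp_path):
    p = tmp_path / "stop.fasta"
    p.write_text(">p1\nMKL*\n")
    assert read_protein_fasta(p)[0].sequence == "MKL"
    p.write_text(">p1\nMK*L\n")
    with pytest.raises(FastaFormatError, match="line 2"):
        read_protein_fasta(p)


def test_illegal_residue_names_line(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">p1\nMKL\n>p2\nMK1\n")
    with pytest.raises(FastaFormatError, match="line 4"):
        read_protein_fasta(p)


def test_lowercase_uppercased_and_multiline_joined(tmp_path):
    p = tmp_path / "lc.fasta"
    p.write_text(">p1\nmkl\nacd\n")
    assert read_protein_fasta(p)[0].sequence == "MKLACD"


@given(
    st.lists(seq_strategy, min_size=0, max_size=20).map(
        lambda seqs: [
            ProteinRecord(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)
        ]
    )
)
def test_fasta_round_trip_is_identity(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("rt") / "rt.fasta"
    write_protein_fasta(records, path)
    back = read_protein_fasta(path)
    assert [(r.id, r.sequence) for r in back] == [
        (r.id, r.sequence) for r in records
    ]


def test_round_trip_100_random_records(tmp_path):
    rng = np.random.default_rng(42)
    records = [
        ProteinRecord(
            id=f"rand{i}",
            sequence="".join(rng.choice(list(AMINO), size=rng.integers(5, 80))),
        )
        for i in range(100)
    ]
    path = tmp_path / "rand.fasta"
    write_protein_fasta(records, path)
    back = read_protein_fasta(path)
    assert [(r.id, r.sequence) for r in back] == [
        (r.id, r.sequence) for r in records
    ]


class TestDedup:
    def test_all_distinct_unchanged(self):
        recs = [ProteinRecord(id=f"r{i}", sequence=s) for i, s in enumerate(["MK", "ML", "MN"])]
        assert dedup_exact(recs) == recs

    def test_first_occurrence_kept(self):
        a = ProteinRecord(id="a", sequence="MKL")
        b = ProteinRecord(id="b", sequence="MKL")
        assert dedup_exact([a, b]) == [a]

    @given(st.lists(seq_strategy, max_size=30))
    def test_idempotent_and_order_stable(self, seqs):
        recs = [ProteinRecord(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)]
        once = dedup_exact(recs)
        assert dedup_exact(once) == once
        ids = [r.id for r in recs]
        assert [r.id for r in once] == sorted(
            (r.id for r in once), key=ids.index
        )


class TestCatalogTable:
    def test_header_only_gives_zero_entries(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("id\tsequence\tloop_category\n")
        assert read_catalog_table(p) == []

    def test_unknown_category_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\tsequence\tloop_category\np1\tMKL\tbogus\n")
        with pytest.raises(CatalogValidationError, match="row 2"):
            read_catalog_table(p)

    @pytest.mark.parametrize("raw,canon", [
        ("loop 1", "L1"), ("Mini-Loop 2", "mL2"), ("mini-loop 1,2", "mL1_2"),
        ("No Loop", "NL"), ("no coverage", "NC"), ("L2", "L2"),
    ])
    def test_category_normalization(self, raw, canon):
        assert normalize_category(raw) == canon

    @pytest.mark.parametrize("ext", ["tsv", "csv", "xlsx"])
    def test_round_trip_synthetic_catalog(self, tmp_path, ext):
        rng = np.random.default_rng(3)
        entries = [
            CatalogEntry(
                record=ProteinRecord(
                    id=f"e{i}",
                    sequence="".join(rng.choice(list(AMINO), size=30)),
                    sample_id=f"S{i % 3}",
                ),
                loop_category=["L1", "NL", "mL2", None, "NC"][i % 5],
                loop1_seq="AAPW" if i % 5 == 0 else None,
                taxonomy="Bacteria;Firmicutes" if i % 2 else None,
                length_status="confirmed" if i % 2 else "unclear",
                signal_call=["present", "absent", "uncertain"][i % 3],
            )
            for i in range(10)
        ]
        path = tmp_path / f"cat.{ext}"
        write_catalog_table(entries, path)
        back = read_catalog_table(path)
        assert len(back) == 10
        for orig, rt in zip(entries, back):
            assert rt.record.id == orig.record.id
            assert rt.record.sequence == orig.record.sequence
            assert rt.loop_category == orig.loop_category
            assert rt.loop1_seq == orig.loop1_seq
            assert rt.taxonomy == orig.taxonomy
            assert rt.length_status == orig.length_status
            assert rt.signal_call == orig.signal_call
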
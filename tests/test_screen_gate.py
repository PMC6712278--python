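"""Homology screen and active-site gate on planted-truth fixtures."""

import pytest

from gusmap import synth
from gusmap.active_site import (
    ActiveSiteSpec,
    apply_active_site_gate,
    check_active_site,
    map_seed_positions,
)
from gusmap.alignment import local_align
from gusmap.screen import SeedEnzyme, screen_candidates
from gusmap.sequence_io import ProteinRecord


def as_record(seed):
    return ProteinRecord(id=seed.id, sequence=seed.sequence)


class TestScreen:
    def test_seed_passes_via_itself(self, seed_enzyme):
        hits = screen_candidates([as_record(seed_enzyme)], [seed_enzyme])
        assert len(hits) == 1
        assert hits[0].alignment.identity_pct == 100.0

    def test_empty_catalog_gives_empty_result(self, seed_enzyme):
        assert screen_candidates([], [seed_enzyme]) == []

    def test_empty_seed_set_rejected(self, seed_enzyme):
        with pytest.raises(ValueError):
            screen_candidates([as_record(seed_enzyme)], [])

    def test_true_members_pass_and_shuffled_decoys_fail(self, small_fixture, seed_enzyme):
        records, truth = small_fixture
        hits = {h.record.id for h in screen_candidates(records, [seed_enzyme])}
        for _, row in truth.iterrows():
            if row.is_true:
                assert row.id in hits, f"true member {row.id} missed by screen"
            elif row.kind == "decoy_shuffled":
                assert row.id not in hits, f"shuffled decoy {row.id} passed screen"

    def test_output_invariant_under_catalog_reordering(self, small_fixture, seed_enzyme):
        records, _ = small_fixture
        fwd = {h.record.id for h in screen_candidates(records, [seed_enzyme])}
        rev = {h.record.id for h in screen_candidates(records[::-1], [seed_enzyme])}
        assert fwd == rev

    def test_output_is_subset_of_catalog(self, small_fixture, seed_enzyme):
        records, _ = small_fixture
        hits = screen_candidates(records, [seed_enzyme])
        assert {h.record.id for h in hits} <= {r.id for r in records}


class TestPositionMapping:
    def test_self_alignment_maps_identically(self, seed_enzyme):
        aln = local_align(seed_enzyme.sequence, seed_enzyme.sequence)
        mapping = map_seed_positions(aln, [1, 100, 450, 603])
        assert mapping == {1: 1, 100: 100, 450: 450, 603: 603}

    def test_insertion_shifts_mapping(self, scaffold):
        # 5 residues inserted at position 100 shift all later positions by +5
        candidate = scaffold[:100] + "WWWWW" + scaffold[100:]
        aln = local_align(candidate, scaffold)
        mapping = map_seed_positions(aln, [50, 450])
        assert mapping[50] == 50
        assert mapping[450] == 455

    def test_position_beyond_alignment_is_absent(self, scaffold):
        fragment = scaffold[:200]  # candidate covers seed 1..200 only
        aln = local_align(fragment, scaffold)
        mapping = map_seed_positions(aln, [450])
        assert mapping[450] is None


class TestActiveSiteCheck:
    def test_seed_passes_its_own_spec(self, seed_enzyme):
        rec = as_record(seed_enzyme)
        aln = local_align(rec.sequence, seed_enzyme.sequence)
        ok, failed = check_active_site(rec, aln, seed_enzyme.active_site_spec)
        assert ok and failed == []

    def test_intact_planted_motifs_pass(self, small_fixture, small_retained, seed_enzyme):
        _, truth = small_fixture
        hits, _ = small_retained
        true_full = set(truth[truth.is_true].id)
        for hit in hits:
            if hit.record.id in true_full:
                ok, _ = check_active_site(
                    hit.record, hit.alignment, seed_enzyme.active_site_spec
                )
                assert ok, hit.record.id

    def test_mutated_motif_fails_naming_it(self, scaffold, seed_enzyme):
        # break the NxKG asparagine (position 560 -> A)
        broken = scaffold[:559] + "A" + scaffold[560:]
        rec = ProteinRecord(id="broken", sequence=broken)
        aln = local_align(broken, scaffold)
        ok, failed = check_active_site(rec, aln, seed_enzyme.active_site_spec)
        assert not ok
        assert failed == ["NxKG"]

    def test_unaligned_spec_position_fails(self, scaffold, seed_enzyme):
        truncated = scaffold[:500]  # ends before the NxKG motif
        rec = ProteinRecord(id="trunc", sequence=truncated)
        aln = local_align(truncated, scaffold)
        ok, failed = check_active_site(rec, aln, seed_enzyme.active_site_spec)
        assert not ok
        assert "NxKG" in failed


class TestGate:
    def test_empty_input_gives_empty_output(self, seed_enzyme):
        assert apply_active_site_gate([], [seed_enzyme]) == []

    def test_planted_truth_separation(self, small_fixture, small_retained):
        _, truth = small_fixture
        _, retained = small_retained
        got = {h.record.id for h in retained}
        assert got == set(truth[truth.is_true].id)

    def test_gate_is_idempotent(self, small_retained, seed_enzyme):
        _, retained = small_retained
        again = apply_active_site_gate(retained, [seed_enzyme])
        assert [h.record.id for h in again] == [h.record.id for h in retained]

    def test_containment_chain(self, small_fixture, small_retained):
        records, _ = small_fixture
        hits, retained = small_retained
        catalog_ids = {r.id for r in records}
        screened_ids = {h.record.id for h in hits}
        retained_ids = {h.record.id for h in retained}
        assert retained_ids <= screened_ids <= catalog_ids


def test_spec_validation_rejects_bad_positions():
    with pytest.raises(ValueError):
        ActiveSiteSpec(motifs={"m": [(5, "N"), (3, "K")]})
    with pytest.raises(ValueError):
        ActiveSiteSpec(motifs={"m": [(1, "B")]})
    with pytest.raises(ValueError):
        SeedEnzyme(id="s", sequence="MKL", loop_anchor_1=7)
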
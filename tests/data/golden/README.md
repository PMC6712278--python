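# Golden reference catalogs (not bundled)

Two acceptance checks tally published third-party catalogs that cannot be
redistributed with this repository. To run them, place here:

- `mouse_catalog_s1.xlsx` — the published mouse GUSome catalog (444
  entries) with at least `id` and `sequence` columns.
- `mouse_catalog_s2.xlsx` — the annotated version with the canonical
  columns (`id`, `sequence`, `loop_category`, `loop1_seq`, `loop2_seq`,
  `taxonomy` as a semicolon lineage, `length_status`, `signal_call`).
- `human_gusome.fasta` — the 279-member human GUSome protein set.

Without these files `tests/test_acceptance.py::
test_supplementary_catalog_tallies_match_published_counts` and
`test_cross_catalog_sharing_matches_published_count` fail with a message
pointing here; all other tests are self-contained.
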
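"""Mine a GUS-like family from a synthetic catalog with planted truth.

Generates 40 true family members (mutated copies of the seed scaffold
with intact active sites) plus 40 decoys, then applies the two-tier
rubric: local-homology screen (>25% identity, E < 0.05) followed by the
active-site residue gate.
"""

from gusmap import synth
from gusmap.active_site import apply_active_site_gate
from gusmap.screen import screen_candidates

spec = synth.SyntheticSpec(rng_seed=1, n_true=40, n_decoys=40)
records, truth = synth.make_gus_like(spec)
seed = synth.make_seed()

hits = screen_candidates(records, [seed])
retained = apply_active_site_gate(hits, [seed])

true_ids = set(truth[truth.is_true].id)
print(f"catalog proteins:        {len(records)}")
print(f"pass homology screen:    {len(hits)}")
print(f"pass active-site gate:   {len(retained)}")
print(f"planted true members:    {len(true_ids)}")
print(f"exact recovery:          {true_ids == {h.record.id for h in retained}}")
# The screen admits motif-broken decoys (homologous but catalytically
# dead); the active-site gate removes them, leaving exactly the planted
# family — the containment chain catalog > screened > gated.
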
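import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gusmap import synth
from gusmap.active_site import apply_active_site_gate
from gusmap.screen import screen_candidates

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO), size=length))


@pytest.fixture(scope="session")
def scaffold() -> str:
    return synth.make_scaffold(0)


@pytest.fixture(scope="session")
def seed_enzyme():
    return synth.make_seed()


@pytest.fixture(scope="session")
def loop_refs():
    return synth.make_loop_references()


@pytest.fixture(scope="session")
def small_fixture():
    """10 true + 10 decoy synthetic catalog with truth table."""
    spec = synth.SyntheticSpec(rng_seed=11, n_true=10, n_decoys=10)
    records, truth = synth.make_gus_like(spec)
    return records, truth


@pytest.fixture(scope="session")
def small_retained(small_fixture, seed_enzyme):
    """Screen+gate output on the small fixture (shared across tests)."""
    records, _ = small_fixture
    hits = screen_candidates(records, [seed_enzyme])
    return hits, apply_active_site_gate(hits, [seed_enzyme])


@pytest.fixture(scope="session")
def planted_fixture():
    """40 true + 40 decoy catalog used by the full-recovery checks."""
    spec = synth.SyntheticSpec(rng_seed=5, n_true=40, n_decoys=40)
    records, truth = synth.make_gus_like(spec)
    return spec, records, truth
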
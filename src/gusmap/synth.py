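"""Synthetic GUS-like catalogs, hit tables and sample designs with known truth.

Every stage of the mining pipeline is testable offline against fixtures
generated here: family members are built on a shared enzyme scaffold and
mutated to a controlled percent identity with the family-defining
active-site residues protected; loop insertions of chosen lengths are
planted at the two anchor positions; decoys are composition-matched
shuffles or motif-broken variants; sample designs carry planted
composition effects.  All outputs are deterministic functions of
``rng_seed``.

The scaffold is a SYNTHETIC stand-in for a real GUS sequence: a 603-residue
protein drawn from globular amino-acid background frequencies with the
family's motif architecture (two catalytic glutamates, N and Y motifs,
and the NxKG glucuronate-coordinating motif) planted at fixed positions,
and both loop anchors placed N-terminal of every motif so that truncated
"no coverage" fragments can still carry a complete active site.  Its
numbering is its own; nothing downstream assumes the scaffold matches any
database sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .active_site import ActiveSiteSpec
from .alignment import ScoringScheme, estimate_evalue, local_align
from .loops import LoopReference, LoopReferenceSet
from .screen import SeedEnzyme
from .sequence_io import ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Approximate globular-protein background frequencies (order as AMINO_ACIDS).
BACKGROUND = np.array(
    [0.078, 0.019, 0.053, 0.063, 0.039, 0.072, 0.022, 0.051, 0.057, 0.090,
     0.022, 0.045, 0.052, 0.042, 0.051, 0.071, 0.058, 0.064, 0.013, 0.032]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: Polar/charged alphabet used for the controlled N-terminal region — no
#: residue from the signal-peptide hydrophobic set, no cysteine.
POLAR_ALPHABET = "DENQKRHSTGP"

SCAFFOLD_LENGTH = 603
LOOP_ANCHOR_1 = 356
LOOP_ANCHOR_2 = 416
NTERM_CONTROLLED = 40  # residues 1..40 carry the non-signal N-terminal truth
_FLANK = 5

#: Family-defining active-site requirements in scaffold numbering.
SCAFFOLD_MOTIFS = {
    "catalytic_E_1": [(450, "E")],
    "catalytic_E_2": [(504, "E")],
    "N_motif": [(530, "N")],
    "Y_motif": [(545, "Y")],
    "NxKG": [(560, "N"), (561, "x"), (562, "K"), (563, "G")],
}

LOOP_CLASSES = ("L1", "L2", "mL1", "mL2", "mL1_2", "NL", "NC")

#: Loop-length draw ranges per class: (loop1 range, loop2 range), inclusive.
_CLASS_LENGTH_RANGES = {
    "L1": ((12, 25), (0, 3)),
    "L2": ((0, 3), (12, 25)),
    "mL1": ((4, 9), (0, 3)),
    "mL2": ((0, 3), (4, 9)),
    "mL1_2": ((4, 9), (4, 9)),
    "NL": ((0, 3), (0, 3)),
    "NC": ((0, 3), (0, 3)),  # generated full-architecture, then truncated
}


def scaffold_positions() -> dict:
    """Protected coordinate sets of the canonical scaffold (1-based)."""
    motif_pos = {p for sites in SCAFFOLD_MOTIFS.values() for p, _ in sites}
    flank = set()
    for anchor in (LOOP_ANCHOR_1, LOOP_ANCHOR_2):
        flank.update(range(anchor - _FLANK, anchor + _FLANK + 1))
    return {"motifs": motif_pos, "anchor_flanks": flank}


def make_scaffold(variant_seed: int = 0) -> str:
    """Generate a scaffold sequence (synthetic; deterministic per seed).

    ``variant_seed`` 0 is the canonical scaffold; other values give
    unrelated scaffolds with the same motif architecture (useful for
    multi-family network fixtures).
    """
    rng = np.random.default_rng(20250 + variant_seed)
    seq = list(rng.choice(list(AMINO_ACIDS), size=SCAFFOLD_LENGTH, p=BACKGROUND))
    seq[0] = "M"
    polar = list(POLAR_ALPHABET)
    for i in range(1, NTERM_CONTROLLED):
        seq[i] = polar[rng.integers(len(polar))]
    for sites in SCAFFOLD_MOTIFS.values():
        for pos, res in sites:
            if res != "x":
                seq[pos - 1] = res
    return "".join(seq)


def scaffold_spec() -> ActiveSiteSpec:
    return ActiveSiteSpec(motifs={k: list(v) for k, v in SCAFFOLD_MOTIFS.items()})


def make_seed(variant_seed: int = 0, seed_id: str = "seed_scaffold") -> SeedEnzyme:
    """The scaffold packaged as a structure-anchored seed enzyme."""
    return SeedEnzyme(
        id=seed_id,
        sequence=make_scaffold(variant_seed),
        pdb_code="SYNTHETIC",
        active_site_spec=scaffold_spec(),
        loop_anchor_1=LOOP_ANCHOR_1,
        loop_anchor_2=LOOP_ANCHOR_2,
    )


def make_loop_references(variant_seed: int = 0) -> LoopReferenceSet:
    """Reference enzymes with annotated canonical loop windows.

    Loop-1 reference carries a 17-residue insertion after anchor 1;
    loop-2 reference a 14-residue insertion after anchor 2.
    """
    scaffold = make_scaffold(variant_seed)
    rng = np.random.default_rng(40250 + variant_seed)
    ins1 = "".join(rng.choice(list(AMINO_ACIDS), size=17, p=BACKGROUND))
    ins2 = "".join(rng.choice(list(AMINO_ACIDS), size=14, p=BACKGROUND))
    ref1 = ProteinRecord(
        id="ref_loop1_synthetic",
        sequence=scaffold[:LOOP_ANCHOR_1] + ins1 + scaffold[LOOP_ANCHOR_1:],
        description="ref_loop1_synthetic canonical loop-1 reference (synthetic)",
    )
    ref2 = ProteinRecord(
        id="ref_loop2_synthetic",
        sequence=scaffold[:LOOP_ANCHOR_2] + ins2 + scaffold[LOOP_ANCHOR_2:],
        description="ref_loop2_synthetic canonical loop-2 reference (synthetic)",
    )
    return LoopReferenceSet(
        loop1_reference=LoopReference(
            record=ref1, window_start=LOOP_ANCHOR_1 + 1,
            window_end=LOOP_ANCHOR_1 + len(ins1),
        ),
        loop2_reference=LoopReference(
            record=ref2, window_start=LOOP_ANCHOR_2 + 1,
            window_end=LOOP_ANCHOR_2 + len(ins2),
        ),
    )


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic catalog with known ground truth."""

    rng_seed: int = 0
    n_true: int = 40
    n_decoys: int = 40
    identity_band: tuple[float, float] = (45.0, 80.0)  # percent vs scaffold
    loop_class_distribution: dict = field(
        default_factory=lambda: {
            "NL": 0.40, "L1": 0.12, "L2": 0.12, "mL1": 0.08,
            "mL2": 0.15, "mL1_2": 0.06, "NC": 0.07,
        }
    )
    signal_fraction: float = 0.3
    scaffold_variant: int = 0

    def __post_init__(self) -> None:
        if self.n_true < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        total = sum(self.loop_class_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("loop class probabilities must sum to 1")
        lo, hi = self.identity_band
        if not (0 < lo <= hi <= 100):
            raise ValueError("identity band must satisfy 0 < low <= high <= 100")


def _mutable_positions(n: int) -> tuple[list[int], set[int]]:
    """(mutable 0-based positions, positions restricted to the polar alphabet)."""
    protected = scaffold_positions()
    hard = {p - 1 for p in protected["motifs"] | protected["anchor_flanks"]}
    hard.add(0)  # the starting methionine
    nterm = set(range(1, NTERM_CONTROLLED))
    mutable = [i for i in range(n) if i not in hard]
    return mutable, nterm


def _substitute(rng: np.random.Generator, seq: list[str], pos: int, nterm: set[int]) -> None:
    alphabet = POLAR_ALPHABET if pos in nterm else AMINO_ACIDS
    choices = [a for a in alphabet if a != seq[pos]]
    seq[pos] = choices[rng.integers(len(choices))]


def _mutate_to_band(
    rng: np.random.Generator, scaffold: str, identity_band: tuple[float, float]
) -> list[str]:
    """Substitute residues outside protected positions to hit the identity band."""
    target = rng.uniform(identity_band[0], identity_band[1])
    n = len(scaffold)
    k = int(round(n * (1.0 - target / 100.0)))
    mutable, nterm = _mutable_positions(n)
    if k > len(mutable):
        raise ValueError(
            f"identity band {identity_band} unreachable: needs {k} substitutions "
            f"but only {len(mutable)} unprotected positions exist"
        )
    seq = list(scaffold)
    for pos in rng.choice(len(mutable), size=k, replace=False):
        _substitute(rng, seq, mutable[pos], nterm)
    return seq


def _random_insert(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND))


def _plant_signal(rng: np.random.Generator, seq: list[str]) -> tuple[list[str], int]:
    """Replace the N-terminus with a constructed Sec signal peptide.

    Returns (sequence, cleavage site 1-based).  The signal satisfies the
    n/h/c-region rules of :func:`gusmap.annotate.predict_signal` by
    construction.
    """
    total = int(rng.integers(18, 25))  # cleavage site position
    h_len = total - 3 - 3  # M + 2 basic, then h-region, then 3-residue c-region
    h = "".join(np.random.default_rng(rng.integers(2**31)).choice(
        list("LAIVF"), size=h_len, p=[0.5, 0.2, 0.15, 0.1, 0.05]))
    x = "QHE"[rng.integers(3)]
    signal = "M" + "KK" + h + "A" + x + "A"
    assert len(signal) == total
    return list(signal) + seq[total:], total


def make_gus_like(spec: SyntheticSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a catalog of true family members plus decoys, with truth.

    True proteins: scaffold mutated into the identity band outside
    protected positions, loop insertions drawn per the class
    distribution, optional planted signal peptide; "NC" proteins are
    C-terminal fragments starting past both loop anchors.  Decoys:
    half residue-shuffled (fail the homology screen), half motif-broken
    (pass the screen, fail the active-site gate).

    Returns (records, truth table) in bijection by id.
    """
    rng = np.random.default_rng(spec.rng_seed)
    scaffold = make_scaffold(spec.scaffold_variant)
    classes = list(spec.loop_class_distribution)
    probs = np.array([spec.loop_class_distribution[c] for c in classes])
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []

    for i in range(spec.n_true):
        cls = classes[rng.choice(len(classes), p=probs)]
        seq = _mutate_to_band(rng, scaffold, spec.identity_band)
        (lo1, hi1), (lo2, hi2) = _CLASS_LENGTH_RANGES[cls]
        l1 = int(rng.integers(lo1, hi1 + 1))
        l2 = int(rng.integers(lo2, hi2 + 1))
        has_signal = False
        cleavage = None
        if cls == "NC":
            seq = seq[LOOP_ANCHOR_2 + _FLANK + 5 :]
            l1 = l2 = None
        else:
            if rng.uniform() < spec.signal_fraction:
                seq, cleavage = _plant_signal(rng, seq)
                has_signal = True
            # insertion coordinates: the anchors are scaffold positions;
            # signal planting replaces residues 1..c without changing length
            s = "".join(seq)
            s = s[:LOOP_ANCHOR_1] + _random_insert(rng, l1) + s[LOOP_ANCHOR_1:]
            s = (
                s[: LOOP_ANCHOR_2 + l1]
                + _random_insert(rng, l2)
                + s[LOOP_ANCHOR_2 + l1 :]
            )
            seq = list(s)
        pid = f"gus_t{i + 1:03d}"
        records.append(ProteinRecord(id=pid, sequence="".join(seq),
                                     description=f"{pid} synthetic true member"))
        truth_rows.append(
            {"id": pid, "kind": "true", "is_true": True, "loop_category": cls,
             "loop1_len": l1, "loop2_len": l2, "active_site_intact": True,
             "signal": has_signal, "cleavage_site": cleavage}
        )

    n_shuffled = spec.n_decoys // 2
    for i in range(spec.n_decoys):
        if i < n_shuffled:
            base = _mutate_to_band(rng, scaffold, spec.identity_band)
            seq = [base[j] for j in rng.permutation(len(base))]
            pid = f"dec_s{i + 1:03d}"
            kind = "decoy_shuffled"
        else:
            seq = _mutate_to_band(rng, scaffold, spec.identity_band)
            for sites in SCAFFOLD_MOTIFS.values():
                for pos, res in sites:
                    if res != "x":
                        seq[pos - 1] = "A" if res != "A" else "G"
            pid = f"dec_m{i - n_shuffled + 1:03d}"
            kind = "decoy_motif_broken"
        records.append(ProteinRecord(id=pid, sequence="".join(seq),
                                     description=f"{pid} synthetic decoy"))
        truth_rows.append(
            {"id": pid, "kind": kind, "is_true": False, "loop_category": None,
             "loop1_len": None, "loop2_len": None,
             "active_site_intact": False, "signal": False, "cleavage_site": None}
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["id", "kind", "is_true", "loop_category", "loop1_len",
                 "loop2_len", "active_site_intact", "signal", "cleavage_site"],
    )
    return records, truth


def plant_chain(
    rng_seed: int = 0,
    mutation_fraction: float = 0.72,
    scheme: ScoringScheme = ScoringScheme(),
    min_identity_pct: float = 25.0,
    max_evalue: float = 0.05,
    search_space_len: int = 50_000,
    max_attempts: int = 50,
) -> tuple[ProteinRecord, ProteinRecord]:
    """Plant a two-hop homology chain scaffold -> A -> B.

    A is within screen range of the scaffold seed; B is within range of A
    but OUTSIDE screen range of the scaffold, so an iterative search must
    find B through A.  Only the motif positions (±1) are conserved along
    the chain, keeping scaffold↔B identity near the two-hop product of
    the per-hop identities.  Because local-alignment statistics jitter
    around the cutoffs, candidate chains are drawn deterministically (one
    sub-seed per attempt) and verified with the package aligner until the
    planted relations hold; raises after ``max_attempts`` failures.
    """
    scaffold = make_scaffold(0)
    motif_pos = {p for sites in SCAFFOLD_MOTIFS.values() for p, _ in sites}
    hard = set()
    for p in motif_pos:
        hard.update({p - 2, p - 1, p})  # 0-based position ±1
    mutable = [i for i in range(len(scaffold)) if i not in hard]

    def passes(query: str, target: str) -> bool:
        aln = local_align(query, target, scheme)
        ev = estimate_evalue(aln.score, len(query), search_space_len,
                             scheme.karlin_k, scheme.karlin_lambda)
        return aln.identity_pct > min_identity_pct and ev < max_evalue

    master = np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        rng = np.random.default_rng(master.integers(2**31))

        def hop(seq: str) -> str:
            out = list(seq)
            k = int(round(mutation_fraction * len(mutable)))
            for pos in rng.choice(len(mutable), size=k, replace=False):
                i = mutable[pos]
                choices = [a for a in AMINO_ACIDS if a != out[i]]
                out[i] = choices[rng.integers(len(choices))]
            return "".join(out)

        a_seq = hop(scaffold)
        b_seq = hop(a_seq)
        if passes(a_seq, scaffold) and passes(b_seq, a_seq) and not passes(b_seq, scaffold):
            return (
                ProteinRecord(id="chain_A", sequence=a_seq,
                              description="chain_A planted first-shell homolog"),
                ProteinRecord(id="chain_B", sequence=b_seq,
                              description="chain_B planted second-shell homolog"),
            )
    raise ValueError(
        "could not plant a chain satisfying the screen-range constraints; "
        "adjust mutation_fraction or thresholds"
    )


# ---------------------------------------------------------------------------
# Sample designs with planted composition effects


@dataclass
class CompositionDesign:
    """A sample design with optional planted per-factor composition effects.

    ``effects`` maps factor -> level -> {category: delta}; deltas within
    one level must sum to zero (proportions must stay a distribution) and
    shifted probabilities must stay within [0, 1].
    """

    n_samples: int = 48
    proteins_per_sample: int = 100
    factor_levels: dict = field(
        default_factory=lambda: {
            "strain": ["B6", "BALBc", "CD1", "DBA2"],
            "provider": ["provA", "provB", "provC"],
            "location": ["loc1", "loc2", "loc3"],
            "sex": ["F", "M"],
            "diet": ["LF", "HF"],
        }
    )
    baseline: dict = field(
        default_factory=lambda: {
            "NL": 0.40, "L1": 0.10, "L2": 0.15, "mL1": 0.08,
            "mL2": 0.15, "mL1_2": 0.05, "NC": 0.07,
        }
    )
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.baseline.values()) - 1.0) > 1e-9:
            raise ValueError("baseline probabilities must sum to 1")
        for factor, levels in self.effects.items():
            if factor not in self.factor_levels:
                raise ValueError(f"effect on unknown factor {factor!r}")
            for level, deltas in levels.items():
                if level not in self.factor_levels[factor]:
                    raise ValueError(f"effect on unknown level {factor}={level}")
                if abs(sum(deltas.values())) > 1e-9:
                    raise ValueError(
                        f"effect deltas for {factor}={level} must sum to 0"
                    )
                for cat, d in deltas.items():
                    p = self.baseline.get(cat, 0.0) + d
                    if not (0.0 <= p <= 1.0):
                        raise ValueError(
                            f"shifted probability for {cat} outside [0, 1]"
                        )


def make_metadata_and_assignments(
    design: CompositionDesign, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate sample metadata and per-protein category assignments.

    Factor levels are tiled across samples and permuted independently, so
    every factor shows every level (near-balanced, unconfounded in
    expectation).  Per-sample category counts are multinomial draws from
    the baseline shifted by any planted effects.  Deterministic given
    ``rng_seed``.

    Returns (metadata, assignments) where metadata has one row per sample
    keyed by ``sample_id`` and assignments has columns protein_id,
    sample_id, category.
    """
    rng = np.random.default_rng(rng_seed)
    n = design.n_samples
    meta = {"sample_id": [f"S{i + 1:03d}" for i in range(n)]}
    for factor, levels in design.factor_levels.items():
        tiled = np.array((levels * (n // len(levels) + 1))[:n])
        meta[factor] = tiled[rng.permutation(n)]
    metadata = pd.DataFrame(meta)

    categories = list(design.baseline)
    base = np.array([design.baseline[c] for c in categories])
    rows = []
    counter = 0
    for _, sample in metadata.iterrows():
        probs = base.copy()
        for factor, levels in design.effects.items():
            deltas = levels.get(sample[factor])
            if deltas:
                for cat, d in deltas.items():
                    probs[categories.index(cat)] += d
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        counts = rng.multinomial(design.proteins_per_sample, probs)
        for cat, k in zip(categories, counts):
            for _ in range(int(k)):
                counter += 1
                rows.append(
                    {"protein_id": f"p{counter:06d}",
                     "sample_id": sample["sample_id"], "category": cat}
                )
    assignments = pd.DataFrame(rows, columns=["protein_id", "sample_id", "category"])
    return metadata, assignments
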
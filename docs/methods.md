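# Methods

## The mining model

`gusmap` treats enzyme-family identification as a two-tier decision per
catalog protein. Tier one is sequence-level: the optimal Smith–Waterman
local alignment against each structure-anchored seed under BLOSUM62 with
affine gaps (a gap of length k costs `gap_open + k·gap_extend`, defaults
11 + k·1, the standard protein-search convention). Significance follows
the Karlin–Altschul form E = K·m·n·e^(−λS) with m the query length and n
the total residue count of the screened catalog; K = 0.041 and λ = 0.267
(gapped BLOSUM62 defaults) are configuration constants so that a
different search engine's statistics can be substituted. A candidate
passes with identity strictly above 25% and E strictly below 0.05 against
at least one seed; boundary values fail. Identity is counted over the
aligned columns of the local alignment, gaps included, tails excluded —
the denominator must be pinned for a percent-identity cutoff to be
reproducible.

Tier two is structural: each seed carries named active-site requirements
as (position, residue) lists in its own numbering — for GUS the NxKG
motif, two catalytic glutamates, and the N and Y motifs. Positions are
mapped through the candidate/seed alignment; a candidate is retained only
when every non-wildcard residue is conserved *exactly* (no
conservative-substitution credit — the residues must be maintained, not
merely similar) and every position is aligned. Requirements are data in
the run configuration, not code, because they come from each seed's
experimental structure.

The alignment kernel is Biopython's `PairwiseAligner`; tests verify its
scores against an independent hand-written Gotoh dynamic program. Ties
among co-optimal alignments are broken by the kernel's canonical first
traceback, which is deterministic for fixed inputs; tie-break order can
shift which of several equal-scoring tracebacks is reported but never the
score, identity or E-value. Any backend producing `AlignmentResult`
objects (including the reader for 12-column tabular search output) can
stand in for the built-in kernel.

## Iterative expansion

Newly discovered members re-seed the screen over the remaining catalog
until a round finds nothing new (default cap 10 rounds). Expansion seeds
have no curated active-site annotation, so each inherits its discovering
seed's requirements translated through the discovering alignment — the
minimal rule consistent with applying "the same two criteria" at every
round. A member whose alignment leaves any required position unmapped
cannot seed further rounds. Expansion hits are reported in a separate
tier from first-pass members because their seeding sequences are not
structurally confirmed enzymes. Whether expansion should instead recheck
candidates against the original structural seeds is a genuinely open
design point; the transfer rule was chosen because it lets the search
reach family members outside direct seed range, which is the purpose of
iterating.

## Loop classification

GH2 β-glucuronidases differ functionally through insertions at two
active-site loop anchors (E. coli GUS numbering 356 and 416). Each
candidate is aligned (global with free end gaps, so fragments align where
they can) against two reference enzymes carrying annotated canonical
loop-1 and loop-2 windows; the candidate residues falling between the
reference residues flanking a window are that candidate's insertion.
Optimal alignments sometimes slide a flank residue into the window when
gap placement is degenerate; if a flank pairs with a gap, the nearest
aligned reference position outside the window (within 25 residues) is
used and the count corrected by the slide distance. Both flanks
unreachable means no coverage.

Default category bounds per loop — no-loop ≤ 3 residues, mini 4–9, full
≥ 10 — are configuration with documented defaults; the borderline case is
the 8-residue loop-2 insertion, which classifies as mini-loop 2. The
seven categories are closed: a full loop at either anchor dominates a
mini at the other, and in the (synthetically possible) both-full case the
longer insertion wins with loop 1 on ties. Alignment-based measurement
carries an inherent ±1-residue ambiguity when inserted residues happen to
match flank residues; category calls are robust to this, exact lengths
near category boundaries are not.

## Annotation

Length status is `confirmed` only when the sequence begins with
methionine *and* the gene call is flagged complete (missing flags default
to complete; the CLI can invert that). The signal-peptide caller is a
deliberately simple rule-based predictor of Sec/peptidase-I signals so
annotation runs offline and deterministically: within the first 40
residues it requires an n-region (≥ 1 K/R among residues 1–7), an
h-region (a 7-residue window with ≥ 6 of A/I/L/M/F/V/W/C), and a cleavage
motif (A/G/S/T/C at the −3 and −1 positions of a site between residues 15
and 40, after the h-region). No starting methionine gives `uncertain`,
and a cysteine immediately after the predicted cleavage site downgrades
`present` to `uncertain` (possible lipoprotein; the peptidase class is
ambiguous). Users running a dedicated predictor feed its tabular output
through `parse_external_signal_table` instead; both paths produce the
same `SignalCall` surface. Only the missing-methionine start rule is
encoded for "uncertain N-terminus"; miscalled-but-present methionines are
not detectable from sequence alone.

## Taxonomy

Assignment consumes a user-supplied ranked hit table (BLASTP-style, with
semicolon lineages) — never live database queries. Tier 1: top hit ≥ 95%
identity → the lowest common ancestor of *all* hits ≥ 95%. "Most specific
taxonomy among the strong hits" is interpreted as their LCA rather than
the single deepest lineage, because the notion of an unclear phylogeny
hinges on conflict between hits; the LCA reading covers both
interpretations conservatively. Tier 2: consensus (LCA) of the top 5 hits
by score, over however many exist down to a minimum of 2; a lone sub-95%
hit is unclear. Agreement must reach at least the phylum rank — high
similarity to more than one phylum is the definition of unclear. Ranks
are compared by name on a fixed ladder
(superkingdom→phylum→class→order→family→genus→species); equal scores are
tie-broken by subject id so assignment is permutation-invariant.

## Networks and sharing

The SSN places an undirected edge between two proteins when the
symmetrized E-value (minimum of the two directional estimates, which
differ only through the query-length term) is ≤ 1e-220 — a threshold
stringent enough to resolve subfamilies while keeping near-identical
members together. The same K/λ model as the screen makes edges
reproducible without any external service. Cross-catalog sharing is
deliberately a different comparison: identity > 98% (strict) under
end-to-end global alignment with the full alignment length, end gaps
included, as denominator — near-identity of whole proteins, not local
similarity.

## Composition statistics

Per-sample category proportions (counts over classified proteins; raw
proportions, no transform) are the response of a five-way main-effects
ANOVA over strain, provider, location, sex and diet, with Type II sums of
squares — appropriate for the unbalanced designs real cohorts produce —
and no interaction terms. Factors with one observed level are dropped
with a warning; aliased designs raise an error naming the offending
factors; a constant response returns F = 0, p = 1. Significance is
decided only by Benjamini–Hochberg at FDR 0.05 over the whole
(category × factor) family of one analysis; loop-category and phylum
analyses form separate families. The fitting goes through statsmodels
OLS/`anova_lm`; tests verify F and p against an explicit
dummy-matrix/residual-sum-of-squares computation, and BH flags against an
exhaustive step-up enumeration.

## Synthetic study data

The generator emulates the statistical structure the pipeline assumes,
with every ground truth recorded. The scaffold is a synthetic 603-residue
stand-in for a real GUS sequence: globular background amino-acid
frequencies with the family motif architecture planted at fixed
positions, and — unlike the real E. coli enzyme, where a catalytic
glutamate sits between the two loop anchors — all gate motifs placed
C-terminal of both anchors, so that no-coverage fragments (truncated
before the loop windows) can still carry a complete active site, as NC
proteins do in real catalogs.

True members are substitution-only mutants of the scaffold within a
target identity band (default 45–80%, family-level divergence), with
motif positions and anchor flanks (± 5) protected and insertions drawn
only at the two anchors, so planted loop lengths are exactly recoverable.
The N-terminal 40 residues are drawn from a polar alphabet so non-signal
N-termini are non-signal by construction; signal-positive members replace
the N-terminus with a constructed n/h/c-region peptide (cleavage site
18–24). Decoys are composition-matched shuffles (fail the screen) or
motif-broken homologs (pass the screen, fail the gate). The two-hop chain
fixture conserves only motif positions ± 1 and mutates 72% of the rest
per hop; because local-alignment statistics jitter around the cutoffs,
chains are drawn deterministically and verified with the package aligner
until A is in seed range, B in A's range, and B outside seed range.

Sample designs tile factor levels across samples and permute them
independently (near-balanced, unconfounded in expectation); per-sample
category counts are multinomial (default 100 proteins/sample) from a
baseline distribution shifted by planted zero-sum effects — the default
planted effect moves no-loop up and loop 2 down under the high-fat diet.

What the synthetic data does *not* emulate: assembly and gene-calling
errors, insertions outside the loop anchors, compositional biases between
lineages, phylogenetic correlation between samples, and overdispersion
beyond multinomial sampling. Passing the planted-truth suites shows the
machinery is correct under the stated model, not that real-catalog calls
are error-free — alignment-based loop classification in particular has
acknowledged edge-case ambiguity.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen as the smallest
sizes at which each property is meaningfully exercised: 40 + 40 proteins
for recovery, a 10-protein catalog plus the chain for iteration, 9
near-identical proteins in two families for the SSN, 500 null and 200
planted-effect replicates (40 samples each) for calibration. Alignment
oracle comparisons run at lengths 30–50 where the quadratic DP is cheap.
E-values may underflow to exactly 0 for very high scores, which is the
correct limit and compares safely against any threshold. Proportions are
validated to sum to 1 within 1e-9; BH input p-values must lie in [0, 1].
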
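# Methods

## Formalism

A logical network is a set of nodes, each with a level cap L_i (1 for
Boolean nodes, 2 for nodes with a distinct phosphorylated/active form),
one total update function per node, and optional clamps. Update functions
are stored as ordered lists of threshold-condition cases
("`CtrA==2 & CcrM>=1 & !GcrA & !DnaA -> 1`") with an explicit default;
the first matching case wins. This representation encodes AND/OR/NOT
logic and multi-valued semantics ("kinase at level 2, phosphatase at
level 1") compactly while staying total by construction; a truth-table
expansion (`truth_table`) exists so any rule can be cross-checked against
an explicit enumeration. Updating is synchronous only: the dynamics is a
deterministic map on the mixed-radix state space (size ∏(L_i+1)), and all
analyses are exhaustive. A hard state-space cap (default 10^7) raises an
error rather than silently sampling.

Level 0 uniformly means absent/knocked out. A clamp pins a node to a
fixed level inside the successor map (rule evaluation itself is
unaffected); knockout = clamp to 0, constitutive expression = clamp to
the node's cap. Exhaustive analyses of a clamped network enumerate the
clamp-consistent subspace (clamp-inconsistent states are garden-of-Eden
states that enter the subspace in one step and add nothing).

Attractors are found by functional-graph traversal (color each state,
follow successor chains, detect cycle closure within the current chain),
which visits every state once. Cycles are rotated to start at their
lexicographically smallest encoded state and attractors ordered by that
index, so reports are reproducible. A deliberately naive oracle
(`brute_force_attractors`: simulate a full trajectory from every start
state) is kept as an independent cross-check and agrees on every tested
network.

## The Caulobacter models

The interaction catalogue (13 regulators, 27 signed directed
interactions, each with a PubMed ID) is shipped as a TSV. The reduction
that produced this core from the full literature network — iteratively
deleting nodes that regulate nothing (out-degree 0, self-loops count) —
is implemented and verified on synthetic graphs; the full 153-node /
212-edge literature table is not redistributable here, so the reduction
is additionally checked only for closure on the packaged core.

The update rules are *reconstructions*: the primary literature fixes the
interaction signs and mechanisms and one function explicitly (DnaA' =
CtrA AND CcrM AND NOT GcrA AND NOT DnaA), but not every Boolean form.
Where a form was open we chose the simplest rule consistent with the
catalogue that reproduces the published attractor landscapes, and note
the deviations:

- **CtrA (transcription)**: `GcrA OR (NOT CcrM AND NOT SciP)` —
  constitutive-unless-repressed, OR-gated with GcrA activation. Taking
  positive autoregulation as a literal conjunct would create a spurious
  all-zero fixed point, contradicting the observation that every initial
  state reaches the cycle.
- **GcrA**: `DnaA AND NOT CtrA`. GcrA's documented positive
  autoregulation is omitted: including it prevents GcrA from switching
  off when CtrA rises while DnaA is absent, breaking the published
  stage progression.
- **DivK**: transcriptional activation by CtrA is present in the
  interaction graph but not in DivK's update rule (DivK protein is
  treated as persistent); otherwise the stalked fixed point (CtrA absent,
  DivK phosphorylated) could not exist.
- **PleC levels**: 2 = active phosphatase, 1 = inactivated by DivK~P.
  This is the only assignment that stabilises both polar fixed points and
  lets the PleC→DivJ replacement protocol work.
- **Phosphatase precedence**: in the DivK and DivJ rules the PleC==2
  case is listed first, so the phosphatase dominates the kinase —
  required for the stability of the swarmer fixed point.

The combined 13-node model merges the two CtrA views into one ternary
node: transcriptional targets respond to fully active CtrA (level 2),
and CtrA's own rule composes proteolysis (ClpXP assembled → 0), the
transcriptional gate, and the phosphorelay (ChpT~P → 2, else 1). A
projection test verifies that under a charged relay and no proteolysis
the combined model's transcriptional coordinates move exactly like the
Boolean subnetwork.

Known tensions with the published mutant tables, recorded rather than
resolved: the claim that deleting ctrA leaves DnaA/GcrA oscillating is
incompatible with any rule set containing the published DnaA function
(which requires CtrA), and the claim that deleting the signalling-side
ctrA yields a single attractor conflicts with the stalked fixed point
having CtrA absent. The perturbation reports flag these rows as
inconsistent instead of grading them. Two further model-level findings:
deleting pleC preserves both cell-fate fixed points but also creates a
small out-of-phase 2-cycle in the DivK/DivJ kinase pair (there is no
phosphatase left to break the symmetry), and clamping DivK to its
phosphorylated level alone is sufficient to commit the swarmer→stalked
switch (DivK~P inactivates PleC, after which DivJ~P sustains DivK~P
without the clamp) — the PleC→DivJ replacement is sufficient but not
uniquely necessary in this rule set.

The combined model's own landscape: one stalked fixed point (basin
10,368) plus a 4-state limit cycle (basin 129,600) carrying the
swarmer-side oscillation.

## Perturbation scans and the switch protocol

Knockout/overexpression scans clamp each node in turn for the whole run
(steady-state semantics, not an initial-condition change) and recompute
the full attractor report; every entry is diffed against the unperturbed
baseline. The switch protocol is: rest at a fixed point, apply transient
clamps, iterate the clamped map to convergence, release, iterate again;
the default clamps {PleC = 0, DivJ = 2} model the polar replacement of
the phosphatase by the kinase.

## Derrida analysis

The Hamming distance between multi-valued states counts differing nodes
(not summed level gaps) — the standard generalization; with levels in
{0,1,2} a level-difference metric would conflate "one node changed a
lot" with "two nodes changed".

M(h) is sampled as: draw a background state uniformly over the
(clamp-consistent) state space, redraw h distinct uniformly chosen nodes
to uniformly chosen *different* levels (so the initial distance is
exactly h), advance both states one synchronous step, record the
distance. The slope at the origin is estimated from the h = 1 class
alone, m = M(1)/1, because M(0) = 0 exactly and h is discrete; this
equals the network's average single-perturbation sensitivity. A
through-origin linear fit over h ≤ 3 is available (`method="linear3"`)
as a sensitivity check. Backgrounds are uniform over the state space,
not attractor-restricted (an attractor-restricted mode exists but is not
the default).

For knocked-out networks the clamped map is applied verbatim: the
perturbed node is still drawn uniformly over all n nodes; a perturbation
landing on the clamped node is erased by the clamp after one step
(though it can propagate through the node's readers during that step),
so clamped coordinates never count as differing in M. Under this
convention, clamping a node that neither reads nor is read leaves m
exactly unchanged; clamping a node with inputs generally lowers m by
removing that node's own susceptibility.

An exact enumerator (`exact_derrida_slope`) averages the one-step
distance over every (state, node, replacement-level) triple and serves
as the oracle for the sampled estimator; the two agree within three
standard errors on every tested network, and exactly on the calibration
fixtures (identity network m = 1, constant network m = 0, 3-node
negation ring m = 1). For the combined 13-node model the exact slope is
m = 0.7404; at 20,000 samples the sampled estimate's standard error is
≈ 0.005. Deletions of gcrA (0.664), divJ (0.664) and sciP (0.728) move
the network deeper into the ordered regime than the wild type; under the
reconstructed rules most other deletions do too (only the protease
deletion raises m, to 0.753). The regime label uses a critical band of
|m − 1| ≤ 0.05.

## Synthetic ensembles

The random-network generator draws, per node, exactly k distinct inputs
(self-inputs allowed — the real circuit has autoregulation) and a full
random truth table with i.i.d. outputs from a bias distribution
(uniform by default), using numpy's PCG64 generator so identical seeds
give identical networks. Defaults (Boolean nodes, unbiased tables)
target the classical calibration point: for k = 2, p = 0.5 the expected
sensitivity is k·2p(1−p) = 1, and the exact per-network slope averaged
over 100 generated 8-node networks sits within a few percent of 1.
These ensembles emulate only the combinatorial structure assumed by the
criticality analysis — they have no biology (no signed mechanisms, no
level semantics), so passing ensemble tests validates the engine and the
estimators, not the Caulobacter rule reconstruction.

## Problem sizes and numerical choices

All exhaustive analyses are exact integer computations; the only
randomness is in Derrida sampling and ensemble generation, always behind
an explicit integer seed. Default Derrida sampling uses 20,000 samples
per h (standard error of M(1) well under 0.01 for the 13-node model);
the ensemble calibration uses 100 networks of 8 nodes; oracle
equivalence is checked on 200 random networks with up to 8 nodes. The
combined model's 139,968-state successor table is built vectorized
(numpy) and enumerated in well under a second.

## Limitations

Synchronous updating only; no asynchronous or stochastic semantics, no
kinetic rates, no spatial micro-domain modelling (the two poles appear
only as the two fixed points and the clamp protocol). The rule sets are
reconstructions constrained by the published attractor landscapes; a
different reconstruction consistent with the same interaction catalogue
could shift the Derrida slope within the ordered regime. The full
153-node literature network is handled only at the graph/reduction
level — no dynamics exist for it.
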
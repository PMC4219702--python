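# caulocycle

Discrete logical modeling of the *Caulobacter crescentus* cell-cycle and
cell-fate network: a generic synchronous multi-valued logical-network
engine, the reconstructed core regulatory models, exhaustive attractor and
basin analysis, in-silico knockout/overexpression scans, the
swarmer-to-stalked differentiation switch, and Derrida-map criticality
analysis.

## The problem

*C. crescentus* divides asymmetrically into two cell types: a motile,
replication-inert **swarmer** cell and a surface-attached,
replication-competent **stalked** cell. The decision is made by a small
regulatory core: a transcriptional oscillator (CtrA, GcrA, DnaA, CcrM,
SciP) that paces the cell cycle, coupled through CtrA to a
phospho-proteolytic cascade (DivK, DivJ, PleC, DivL, CckA, ChpT, CpdR and
the ClpXP-RcdA protease) that sets CtrA's phosphorylation and degradation
state in each polar micro-domain.

This package asks the qualitative-dynamics questions: does the wiring
alone, under the simplest discrete kinetics, reproduce the cell-cycle
oscillation, the two cell fates, the known mutant phenotypes, and a
perturbation-robust ("ordered, near-critical") dynamical regime?

## The model

Each node *i* carries a discrete level σ_i ∈ {0, …, L_i} (0 = absent,
1 = present/unphosphorylated, 2 = phosphorylated/active; L_i ≤ 2). All
nodes update simultaneously:

    σ_i(t+1) = f_i(σ_{i1}(t), …, σ_{ik}(t))

where f_i is a logical function of node *i*'s regulators, written as
ordered threshold-condition cases (first match wins, explicit default).
The synchronous map on the finite mixed-radix state space is enumerated
exhaustively: every trajectory ends in a **fixed point** or a **limit
cycle**, and every attractor's **basin** is counted exactly.

Perturbation robustness is quantified by the Derrida map M(h): the mean
Hamming distance (number of differing nodes) between two trajectories one
step after starting at distance h. Its slope at the origin,
m = dM/dh |_{h=0} = M(1), classifies the regime: ordered (m < 1),
critical (m = 1), chaotic (m > 1).

## Worked example

```python
from caulocycle import build_g2b, enumerate_attractors, switch_experiment

net = build_g2b()                      # 9-node phospho-proteolytic cascade
rep = enumerate_attractors(net)        # all 8,748 states
for att, basin in zip(rep.attractors, rep.basin_sizes):
    print(att.kind, len(att), basin)
trace = switch_experiment(net)         # transient {PleC=0, DivJ=2} at the swarmer point
print(net.as_dict(trace.final_rest))
```

prints

```
fixed_point 1 648
fixed_point 1 8100
{'CtrA': 0, 'DivK': 2, 'DivJ': 2, 'PleC': 1, 'DivL': 0, 'CckA': 1,
 'ChpT': 1, 'CpdR': 1, 'ClpXP_RcdA': 1}
```

i.e. the cascade is bistable — a swarmer-pole fixed point (CtrA
phosphorylated, basin 8,100) and a stalked-pole fixed point (CtrA degraded,
protease assembled, basin 648) — and transiently replacing the PleC
phosphatase by the DivJ kinase at the swarmer point flips the system
permanently into the stalked state.

The same API drives the transcriptional oscillator (`build_g2a`, one
4-state limit cycle draining all 32 states) and the combined 13-node
network (`build_g2_combined`, 139,968 states), whose sampled Derrida slope
is m ≈ 0.74 ± 0.01 (exact enumeration: 0.7404) — the ordered regime, near
criticality.

## Command line and analysis scripts

```bash
caulocycle attractors --model g2a
caulocycle perturb --model g2b --mode knockout --report scans.csv
caulocycle derrida --model g2 --samples 20000 --seed 1
caulocycle synth --n 8 --k 2 --seed 7 --out random.yaml
caulocycle pipeline --outdir results/pipeline
```

The numbered scripts under `analysis/` run the individual studies
(network bookkeeping, attractor landscapes, mutant scans, the
differentiation switch, Derrida criticality) and write their tables under
`results/`.

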
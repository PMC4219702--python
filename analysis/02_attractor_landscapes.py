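#!/usr/bin/env python
"""Exhaustive attractor landscapes of the two core subnetworks.

The Boolean transcriptional subnetwork (CtrA, GcrA, DnaA, CcrM, SciP) has a
single 4-state limit cycle draining all 32 states: the cell-cycle
oscillation (replication initiation -> elongation -> division -> full
methylation).  The ternary phospho-proteolytic subnetwork (DivK/DivJ/PleC
switch, DivL-CckA-ChpT-CpdR relay, ClpXP-RcdA protease) is bistable over
its 8,748 states: one fixed point per polar micro-domain (swarmer-like,
CtrA phosphorylated; stalked-like, CtrA degraded).

Writes results/g2a_attractors.csv, results/g2b_attractors.csv (one row per
attractor state) and JSON mirrors.
"""

from pathlib import Path

from caulocycle.engine import enumerate_attractors
from caulocycle.modelio import save_attractor_report, write_attractor_csv
from caulocycle.models import build_g2a, build_g2b

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for builder, label in ((build_g2a, "g2a"), (build_g2b, "g2b")):
        net = builder()
        rep = enumerate_attractors(net)
        print(f"{label}: {rep.state_space_size} states")
        for i, (att, basin) in enumerate(zip(rep.attractors, rep.basin_sizes)):
            print(f"  attractor {i}: {att.kind}, length {len(att)}, basin {basin}")
            for s in att.states:
                print("    " + " ".join(f"{n}={v}" for n, v in zip(net.names, s)))
        write_attractor_csv(net, rep, OUT / f"{label}_attractors.csv")
        save_attractor_report(net, rep, OUT / f"{label}_attractors.json")
    print(f"wrote attractor tables under {OUT}")


if __name__ == "__main__":
    main()
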
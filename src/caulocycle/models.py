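"""The *Caulobacter crescentus* core cell-cycle networks.

Contents:

* an interaction catalogue (13 regulators, 27 signed directed interactions,
  shipped as a packaged TSV) and a generic regulatory-graph container;
* the reduction that strips non-regulatory nodes (out-degree 0) from a
  large literature network down to its regulatory core;
* reference logical rule sets for the two core subnetworks and their
  13-node combination:

  - **G2a** — the Boolean transcriptional oscillator on CtrA, GcrA, DnaA,
    CcrM and SciP.  Its unique attractor is a 4-state limit cycle that
    tracks the cell-cycle stages.
  - **G2b** — the ternary phospho-proteolytic signalling cascade on CtrA,
    DivK, DivJ, PleC, DivL, CckA, ChpT, CpdR and the ClpXP-RcdA protease
    complex.  Levels mean 0 = absent, 1 = present/unphosphorylated,
    2 = phosphorylated (for PleC, 2 = active phosphatase, 1 = inactivated;
    for CpdR, 1 = complex-promoting, 2 = phosphorylated/inactive).  It is
    bistable: one fixed point per daughter-cell micro-domain (swarmer vs
    stalked).
  - **G2** — the combined 13-node network obtained by merging the two
    CtrA views into one ternary node: transcriptional targets respond to
    fully active (phosphorylated, level 2) CtrA, while proteolysis and
    phosphotransfer set CtrA's own level.

The rule sets are reconstructions from the interaction catalogue and the
functional descriptions; where the literature leaves the Boolean form
open, the choices and their rationale are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .engine import LogicalNetwork, NetworkError, NodeDecl, UpdateRule, parse_case

__all__ = [
    "SIGNS",
    "MECHANISMS",
    "InteractionRecord",
    "RegulatoryGraph",
    "load_interactions",
    "packaged_interaction_table",
    "reduce_to_core",
    "build_g2a",
    "build_g2b",
    "build_g2_combined",
    "packaged_model_path",
    "G2A_NODES",
    "G2B_NODES",
    "G2_NODES",
]

SIGNS = frozenset({"positive", "negative", "dual"})
MECHANISMS = frozenset(
    {
        "transcription",
        "methylation",
        "phosphorylation",
        "dephosphorylation",
        "proteolysis",
        "complex_assembly",
        "binding",
    }
)


@dataclass(frozen=True)
class InteractionRecord:
    """One directed signed regulatory interaction with literature evidence."""

    regulator: str
    target: str
    sign: str
    mechanism: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise NetworkError("regulator and target must be nonempty")
        if self.sign not in SIGNS:
            raise NetworkError(f"unknown sign {self.sign!r} (expected one of {sorted(SIGNS)})")
        if self.mechanism not in MECHANISMS:
            raise NetworkError(
                f"unknown mechanism {self.mechanism!r} (expected one of {sorted(MECHANISMS)})"
            )


@dataclass(frozen=True)
class RegulatoryGraph:
    """A static interaction graph (nodes + signed edges), pre-dynamics."""

    nodes: tuple[str, ...]
    edges: tuple[InteractionRecord, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.regulator, e.target, sign=e.sign, mechanism=e.mechanism)
        return g


def load_interactions(table: str | Path | pd.DataFrame) -> RegulatoryGraph:
    """Load an interaction table (TSV or DataFrame) into a RegulatoryGraph.

    Required columns: regulator, target, sign, mechanism, evidence.  The
    node set is the union of endpoints, in first-appearance order.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, comment="#")
    required = ["regulator", "target", "sign", "mechanism", "evidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NetworkError(f"interaction table lacks columns {missing}")
    records = []
    seen: dict[str, None] = {}
    for row in df.itertuples(index=False):
        if pd.isna(row.regulator) or pd.isna(row.target):
            raise NetworkError("empty regulator/target field")
        rec = InteractionRecord(
            regulator=str(row.regulator),
            target=str(row.target),
            sign=str(row.sign),
            mechanism=str(row.mechanism),
            evidence="" if pd.isna(row.evidence) else str(row.evidence),
        )
        records.append(rec)
        seen.setdefault(rec.regulator)
        seen.setdefault(rec.target)
    return RegulatoryGraph(nodes=tuple(seen), edges=tuple(records))


def packaged_interaction_table() -> Path:
    """Path to the packaged 13-node / 27-edge core interaction table."""
    return Path(resources.files("caulocycle").joinpath("data/table1_g2.tsv"))


def packaged_model_path(which: str) -> Path:
    """Path to a packaged reference model file ('g2a', 'g2b' or 'g2')."""
    if which not in {"g2a", "g2b", "g2"}:
        raise ValueError(f"unknown packaged model {which!r}")
    return Path(resources.files("caulocycle").joinpath(f"data/{which}.yaml"))


def reduce_to_core(graph: RegulatoryGraph) -> RegulatoryGraph:
    """Iteratively delete non-regulatory nodes (out-degree 0).

    A node with no outgoing interactions cannot influence the dynamics, so
    it is removed together with its incident edges; removal can expose new
    leaves, so the deletion cascades until a fixed point.  Self-loops count
    as out-edges.  The result is order-independent.
    """
    nodes = set(graph.nodes)
    edges = list(graph.edges)
    while True:
        regulators = {e.regulator for e in edges}
        dead = nodes - regulators
        if not dead:
            break
        nodes -= dead
        edges = [e for e in edges if e.regulator in nodes and e.target in nodes]
    keep = tuple(n for n in graph.nodes if n in nodes)
    return RegulatoryGraph(nodes=keep, edges=tuple(edges))


# ---------------------------------------------------------------------------
# reference rule sets
# ---------------------------------------------------------------------------

G2A_NODES = ("CtrA", "GcrA", "DnaA", "CcrM", "SciP")
G2B_NODES = (
    "CtrA",
    "DivK",
    "DivJ",
    "PleC",
    "DivL",
    "CckA",
    "ChpT",
    "CpdR",
    "ClpXP_RcdA",
)
G2_NODES = (
    "CtrA",
    "GcrA",
    "DnaA",
    "CcrM",
    "SciP",
    "DivK",
    "DivJ",
    "PleC",
    "DivL",
    "CckA",
    "ChpT",
    "CpdR",
    "ClpXP_RcdA",
)


def _rule(target: str, cases: Iterable[str], default: int) -> UpdateRule:
    return UpdateRule(target=target, cases=tuple(parse_case(c) for c in cases), default=default)


def build_g2a() -> LogicalNetwork:
    """Boolean transcriptional oscillator on {CtrA, GcrA, DnaA, CcrM, SciP}.

    CtrA transcribes unless repressed by promoter methylation (CcrM) or
    SciP, and is additionally driven by GcrA; GcrA needs DnaA and is shut
    off by CtrA; DnaA needs CtrA-activated transcription of its methylated
    promoter, is repressed by GcrA and by itself; CcrM needs CtrA and is
    repressed by SciP and by its own promoter methylation; SciP needs CtrA
    and is repressed by DnaA.
    """
    nodes = [NodeDecl(n, 1) for n in G2A_NODES]
    rules = [
        _rule("CtrA", ["GcrA>=1 -> 1", "CcrM==0 & SciP==0 -> 1"], 0),
        _rule("GcrA", ["DnaA>=1 & CtrA==0 -> 1"], 0),
        _rule("DnaA", ["CtrA>=1 & CcrM>=1 & GcrA==0 & DnaA==0 -> 1"], 0),
        _rule("CcrM", ["CtrA>=1 & SciP==0 & CcrM==0 -> 1"], 0),
        _rule("SciP", ["CtrA>=1 & DnaA==0 -> 1"], 0),
    ]
    return LogicalNetwork(nodes, rules, name="g2a")


def build_g2b() -> LogicalNetwork:
    """Ternary phospho-proteolytic cascade deciding the two cell fates.

    The PleC phosphatase (level 2) keeps DivK and DivJ unphosphorylated;
    otherwise the DivJ kinase phosphorylates DivK and DivK~P in turn keeps
    DivJ phosphorylated and inactivates PleC.  DivK~P sequesters DivL, so
    CckA stops autophosphorylating, the CckA->ChpT->CpdR phosphorelay
    drains, unphosphorylated CpdR assembles the ClpXP-RcdA protease, and
    CtrA is degraded.  With PleC active the relay stays charged and ChpT~P
    keeps CtrA phosphorylated instead.  Phosphatase cases are listed first:
    when PleC is active it wins over the kinases.
    """
    caps = {n: 2 for n in G2B_NODES}
    caps["DivL"] = 1
    caps["ClpXP_RcdA"] = 1
    nodes = [NodeDecl(n, caps[n]) for n in G2B_NODES]
    rules = _signalling_rules(ctra_cases=["ClpXP_RcdA==1 -> 0", "ChpT==2 -> 2"], ctra_default=1)
    return LogicalNetwork(nodes, rules, name="g2b")


def _signalling_rules(ctra_cases: list[str], ctra_default: int) -> list[UpdateRule]:
    return [
        _rule("CtrA", ctra_cases, ctra_default),
        _rule("DivK", ["PleC==2 -> 1", "DivJ==2 -> 2"], 1),
        _rule("DivJ", ["PleC==2 -> 1", "DivK==2 -> 2"], 1),
        _rule("PleC", ["DivK==2 -> 1"], 2),
        _rule("DivL", ["DivK==2 -> 0"], 1),
        _rule("CckA", ["DivL==1 -> 2"], 1),
        _rule("ChpT", ["CckA==2 -> 2"], 1),
        _rule("CpdR", ["ChpT==2 -> 2"], 1),
        _rule("ClpXP_RcdA", ["CpdR==1 -> 1"], 0),
    ]


def build_g2_combined() -> LogicalNetwork:
    """The full 13-node core network with a single ternary CtrA.

    Transcriptional targets respond to fully active CtrA (level 2, the
    phosphorylated form); CtrA's own level is set by proteolysis (ClpXP
    assembled -> 0), by its transcriptional gate T = GcrA OR (not CcrM and
    not SciP) (gate closed -> 0), and by the phosphorelay (ChpT~P -> 2,
    else 1).  All other rules are exactly the G2a/G2b reference rules.
    """
    caps = {n: 1 for n in G2_NODES}
    for n in ("CtrA", "DivK", "DivJ", "PleC", "CckA", "ChpT", "CpdR"):
        caps[n] = 2
    nodes = [NodeDecl(n, caps[n]) for n in G2_NODES]
    ctra_cases = [
        "ClpXP_RcdA==1 -> 0",
        "GcrA>=1 & ChpT==2 -> 2",
        "GcrA>=1 -> 1",
        "CcrM==0 & SciP==0 & ChpT==2 -> 2",
        "CcrM==0 & SciP==0 -> 1",
    ]
    transcriptional = [
        _rule("GcrA", ["DnaA>=1 & CtrA<=1 -> 1"], 0),
        _rule("DnaA", ["CtrA==2 & CcrM>=1 & GcrA==0 & DnaA==0 -> 1"], 0),
        _rule("CcrM", ["CtrA==2 & SciP==0 & CcrM==0 -> 1"], 0),
        _rule("SciP", ["CtrA==2 & DnaA==0 -> 1"], 0),
    ]
    signalling = _signalling_rules(ctra_cases=ctra_cases, ctra_default=0)
    rules = {r.target: r for r in transcriptional + signalling}
    return LogicalNetwork(nodes, rules, name="g2")
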
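"""Reading and writing logical-network model files and analysis reports.

Model files are declarative YAML: node declarations with level caps, one
ordered-case rule per node written in the condition-string dialect of
:mod:`caulocycle.engine` (``"CtrA==2 & CcrM>=1 & !GcrA -> 1"``), and
optional clamps.  Reading a file written by :func:`save_model` reproduces
the in-memory network exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any

import yaml

from .engine import (
    AttractorReport,
    LogicalNetwork,
    NetworkError,
    NodeDecl,
    TransitionGraph,
    UpdateRule,
    format_case,
    parse_case,
)

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "attractor_report_to_dict",
    "save_attractor_report",
    "write_attractor_csv",
    "export_transition_graph",
]

FORMAT_TAG = "caulocycle-model/1"


def model_to_dict(network: LogicalNetwork) -> dict[str, Any]:
    return {
        "format": FORMAT_TAG,
        "name": network.name,
        "nodes": [{"name": n.name, "max_level": n.max_level} for n in network.nodes],
        "rules": {
            name: {
                "cases": [format_case(c) for c in rule.cases],
                "default": rule.default,
            }
            for name, rule in network.rules.items()
        },
        "clamps": dict(network.clamps),
    }


def model_from_dict(data: dict[str, Any]) -> LogicalNetwork:
    if data.get("format", FORMAT_TAG) != FORMAT_TAG:
        raise NetworkError(f"unsupported model format {data.get('format')!r}")
    nodes = [NodeDecl(d["name"], int(d.get("max_level", 1))) for d in data["nodes"]]
    rules = {}
    for name, spec in data["rules"].items():
        cases = tuple(parse_case(c) for c in spec.get("cases", []))
        rules[name] = UpdateRule(target=name, cases=cases, default=int(spec.get("default", 0)))
    return LogicalNetwork(
        nodes, rules, clamps=data.get("clamps") or {}, name=data.get("name", "")
    )


def save_model(network: LogicalNetwork, path: str | Path) -> None:
    path = Path(path)
    data = model_to_dict(network)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_model(path: str | Path) -> LogicalNetwork:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(data)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def attractor_report_to_dict(
    network: LogicalNetwork, report: AttractorReport
) -> dict[str, Any]:
    return {
        "format": "caulocycle-attractors/1",
        "model": network.name,
        "node_names": list(network.names),
        "state_space_size": report.state_space_size,
        "attractors": [
            {
                "kind": a.kind,
                "length": len(a),
                "basin_size": b,
                "states": [list(s) for s in a.states],
            }
            for a, b in zip(report.attractors, report.basin_sizes)
        ],
    }


def save_attractor_report(
    network: LogicalNetwork, report: AttractorReport, path: str | Path
) -> None:
    Path(path).write_text(json.dumps(attractor_report_to_dict(network, report), indent=2) + "\n")


def write_attractor_csv(
    network: LogicalNetwork, report: AttractorReport, path: str | Path
) -> None:
    """One row per attractor state, with attractor id, kind and basin size."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["attractor", "kind", "length", "basin_size", "step", *network.names]
        )
        for i, (att, basin) in enumerate(zip(report.attractors, report.basin_sizes)):
            for step, state in enumerate(att.states):
                writer.writerow([i, att.kind, len(att), basin, step, *state])


def export_transition_graph(
    graph: TransitionGraph, path: str | Path, fmt: str | None = None
) -> None:
    """Write a transition graph as DOT or GraphML, states labeled by levels."""
    import networkx as nx

    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "dot"
    g = graph.to_networkx()
    if fmt == "dot":
        lines = ["digraph transitions {"]
        for i, s in enumerate(graph.states):
            label = ",".join(str(v) for v in s)
            lines.append(f'  s{i} [label="{label}"];')
        for i, j in enumerate(graph.edges):
            lines.append(f"  s{i} -> s{j};")
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
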
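"""In-silico genetics: knockouts, constitutive expression, and the
swarmer-to-stalked switch protocol.

A knockout clamps a node to 0 for the whole simulation; constitutive
(over-)expression clamps it to its maximal level.  Scans recompute the
full attractor landscape under each single-node perturbation and diff it
against the unperturbed baseline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .engine import (
    AttractorReport,
    LogicalNetwork,
    NetworkError,
    enumerate_attractors,
    successor,
    trajectory,
)

__all__ = [
    "PerturbationSpec",
    "PerturbationResult",
    "ScanResult",
    "apply_perturbation",
    "knockout_scan",
    "overexpression_scan",
    "write_scan_csv",
    "SwitchTrace",
    "switch_experiment",
]

MODES = ("knockout", "overexpression")


@dataclass(frozen=True)
class PerturbationSpec:
    """A single-node perturbation: Δ (clamp to 0) or + (clamp to max)."""

    node: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise NetworkError(f"mode must be one of {MODES}, got {self.mode!r}")

    def clamp_level(self, network: LogicalNetwork) -> int:
        if self.node not in network.index:
            raise NetworkError(f"unknown node {self.node!r}")
        if self.mode == "knockout":
            return 0
        return network.nodes[network.index[self.node]].max_level


def apply_perturbation(network: LogicalNetwork, spec: PerturbationSpec) -> LogicalNetwork:
    """Return a perturbed copy of the network; the original is unchanged.

    Clamping a node that is already clamped (even to the same level) is a
    conflict and raises.
    """
    level = spec.clamp_level(network)
    tag = "d" if spec.mode == "knockout" else "+"
    return network.with_clamps(
        {spec.node: level}, name=f"{network.name}_{tag}{spec.node}"
    )


@dataclass(frozen=True)
class PerturbationResult:
    """Attractor landscape under one perturbation, diffed vs baseline."""

    spec: PerturbationSpec
    report: AttractorReport
    diff: dict

    @property
    def n_attractors(self) -> int:
        return len(self.report.attractors)


@dataclass(frozen=True)
class ScanResult:
    """One perturbation per node, plus the unperturbed baseline."""

    mode: str
    baseline: AttractorReport
    results: tuple[PerturbationResult, ...]

    def by_node(self, node: str) -> PerturbationResult:
        for r in self.results:
            if r.spec.node == node:
                return r
        raise KeyError(node)


def _summarize(network: LogicalNetwork, report: AttractorReport) -> dict:
    levels = {}
    for name in network.names:
        i = network.index[name]
        vals = sorted({s[i] for a in report.attractors for s in a.states})
        levels[name] = vals
    return {
        "n_attractors": len(report.attractors),
        "n_fixed_points": len(report.fixed_points),
        "n_cycles": len(report.limit_cycles),
        "attractor_lengths": sorted(len(a) for a in report.attractors),
        "levels_seen": levels,
    }


def _scan(network: LogicalNetwork, mode: str, cap: int) -> ScanResult:
    baseline = enumerate_attractors(network, cap=cap)
    base_summary = _summarize(network, baseline)
    results = []
    for node in network.names:
        if node in network.clamps:
            continue
        spec = PerturbationSpec(node=node, mode=mode)
        perturbed = apply_perturbation(network, spec)
        report = enumerate_attractors(perturbed, cap=cap)
        summary = _summarize(network, report)
        diff = {
            "summary": summary,
            "delta_attractors": summary["n_attractors"] - base_summary["n_attractors"],
            "delta_fixed_points": summary["n_fixed_points"] - base_summary["n_fixed_points"],
            "delta_cycles": summary["n_cycles"] - base_summary["n_cycles"],
        }
        results.append(PerturbationResult(spec=spec, report=report, diff=diff))
    return ScanResult(mode=mode, baseline=baseline, results=tuple(results))


def knockout_scan(network: LogicalNetwork, cap: int = 10**7) -> ScanResult:
    """Attractor landscape under Δ(node) for every unclamped node."""
    return _scan(network, "knockout", cap)


def overexpression_scan(network: LogicalNetwork, cap: int = 10**7) -> ScanResult:
    """Attractor landscape under (node)+ for every unclamped node."""
    return _scan(network, "overexpression", cap)


def write_scan_csv(network: LogicalNetwork, scan: ScanResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["node", "mode", "n_attractors", "n_fixed_points", "n_cycles", "attractor_lengths", "levels_seen"]
        )
        base = _summarize(network, scan.baseline)
        w.writerow(
            [
                "(baseline)",
                "none",
                base["n_attractors"],
                base["n_fixed_points"],
                base["n_cycles"],
                ";".join(map(str, base["attractor_lengths"])),
                _fmt_levels(base["levels_seen"]),
            ]
        )
        for r in scan.results:
            s = r.diff["summary"]
            w.writerow(
                [
                    r.spec.node,
                    r.spec.mode,
                    s["n_attractors"],
                    s["n_fixed_points"],
                    s["n_cycles"],
                    ";".join(map(str, s["attractor_lengths"])),
                    _fmt_levels(s["levels_seen"]),
                ]
            )


def _fmt_levels(levels: Mapping[str, Sequence[int]]) -> str:
    return " ".join(f"{k}:{'/'.join(map(str, v))}" for k, v in levels.items())


# ---------------------------------------------------------------------------
# swarmer -> stalked switch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchTrace:
    """Record of a transient-clamp protocol.

    The protocol: rest at ``start``; apply the transient clamps and iterate
    the clamped map to convergence; release the clamps and iterate again.
    ``clamped_rest`` and ``final_rest`` are the two resting states;
    ``trajectory`` is the concatenated state sequence (clamped phase then
    release phase).
    """

    start: tuple[int, ...]
    clamps: dict
    clamped_rest: tuple[int, ...]
    final_rest: tuple[int, ...]
    clamped_phase: tuple[tuple[int, ...], ...]
    release_phase: tuple[tuple[int, ...], ...]

    @property
    def trajectory(self) -> tuple[tuple[int, ...], ...]:
        return self.clamped_phase + self.release_phase

    @property
    def switched(self) -> bool:
        return self.final_rest != self.start


def _run_to_rest(network: LogicalNetwork, state: tuple[int, ...]):
    """Iterate to the first revisited state; require it to be a fixed point."""
    path = trajectory(network, state)
    rest = path[-1]
    if successor(network, rest) != rest:
        raise RuntimeError(
            "protocol phase converged to a limit cycle, not a fixed point; "
            f"cycle entry {rest}"
        )
    # drop the closing duplicate
    return tuple(path[:-1]), rest


def switch_experiment(
    network: LogicalNetwork,
    start: Sequence[int] | None = None,
    transient_clamps: Mapping[str, int] | None = None,
) -> SwitchTrace:
    """Transient-clamp protocol modelling the polar PleC->DivJ replacement.

    By default the protocol starts at the swarmer fixed point (the fixed
    point with the highest CtrA level) and transiently imposes
    {PleC = 0, DivJ = 2}: the swarmer-pole phosphatase is removed and the
    stalked-pole kinase installed, as happens at the differentiating pole.
    After the clamped phase converges, the clamps are released and the
    system relaxes to its final resting state.
    """
    if transient_clamps is None:
        transient_clamps = {"PleC": 0, "DivJ": 2}
    if start is None:
        report = enumerate_attractors(network)
        fps = report.fixed_points
        if not fps:
            raise NetworkError("network has no fixed point to start from")
        i_ctra = network.index["CtrA"]
        start = max((fp.states[0] for fp in fps), key=lambda s: s[i_ctra])
    start = network.validate_state(start)

    clamped_net = network.with_clamps(transient_clamps)
    clamped_phase, clamped_rest = _run_to_rest(clamped_net, start)
    release_phase, final_rest = _run_to_rest(network, clamped_rest)
    return SwitchTrace(
        start=start,
        clamps=dict(transient_clamps),
        clamped_rest=clamped_rest,
        final_rest=final_rest,
        clamped_phase=clamped_phase,
        release_phase=release_phase,
    )
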
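"""Random multi-valued logical networks and brute-force oracles.

The ensemble generator emulates the classical NK-style random ensembles
used to study the ordered/critical/chaotic trichotomy: n nodes, exactly k
distinct inputs per node (self-inputs allowed, as in real circuits with
autoregulation), per-node level caps, and i.i.d. random truth-table
outputs drawn from a tunable bias distribution.  For Boolean k = 2
unbiased tables the ensemble-average Derrida slope is k·2p(1-p) = 1, the
textbook criticality point, which makes the ensemble a calibration
standard for the engine and the slope estimators.

Also here: a deliberately naive attractor finder (simulate a trajectory
from every start state) used as the independent oracle for the engine's
functional-graph enumeration, and a small menagerie of fixed fixtures
with known-by-hand attractor structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import (
    Attractor,
    AttractorReport,
    ConditionLiteral,
    LogicalNetwork,
    NetworkError,
    NodeDecl,
    RuleCase,
    StateSpaceCapExceeded,
    UpdateRule,
    canonicalize_cycle,
    successor,
)
from .models import build_g2a, build_g2b, build_g2_combined

__all__ = [
    "EnsembleSpec",
    "random_network",
    "brute_force_attractors",
    "builtin_fixtures",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a random-network ensemble draw.

    ``max_level`` may be an int (uniform cap) or a per-node sequence;
    ``bias`` is a probability distribution over output levels 0..max_level
    (None = uniform).  With heterogeneous caps, ``bias`` must be None.
    """

    n_nodes: int
    k_inputs: int
    max_level: int | Sequence[int] = 1
    bias: Sequence[float] | None = None
    seed: int = 0

    def caps(self) -> tuple[int, ...]:
        if isinstance(self.max_level, int):
            return (self.max_level,) * self.n_nodes
        caps = tuple(int(c) for c in self.max_level)
        if len(caps) != self.n_nodes:
            raise NetworkError("per-node max_level length must equal n_nodes")
        return caps

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise NetworkError("n_nodes must be >= 1")
        if not 0 <= self.k_inputs < self.n_nodes:
            raise NetworkError("require 0 <= k_inputs < n_nodes")
        if any(c < 1 for c in self.caps()):
            raise NetworkError("max_level must be >= 1 everywhere")
        if self.bias is not None:
            if not isinstance(self.max_level, int):
                raise NetworkError("bias requires a uniform max_level")
            b = np.asarray(self.bias, dtype=float)
            if len(b) != self.max_level + 1 or b.min() < 0 or not np.isclose(b.sum(), 1.0):
                raise NetworkError(
                    f"bias must be a distribution over 0..{self.max_level}"
                )


def random_network(spec: EnsembleSpec) -> LogicalNetwork:
    """Draw one network from the ensemble, reproducibly by seed.

    Each node receives ``k_inputs`` distinct inputs drawn uniformly (self
    allowed) and a full random truth table encoded as one exact-match case
    per input combination (so the engine's case representation is itself
    exercised).  The RNG is numpy's PCG64.
    """
    rng = np.random.default_rng(spec.seed)
    caps = spec.caps()
    names = tuple(f"n{i}" for i in range(spec.n_nodes))
    nodes = [NodeDecl(name, cap) for name, cap in zip(names, caps)]
    rules = {}
    for j, name in enumerate(names):
        inputs = sorted(rng.choice(spec.n_nodes, size=spec.k_inputs, replace=False))
        ranges = [range(caps[i] + 1) for i in inputs]
        cases = []
        last_output = 0
        for combo in itertools.product(*ranges):
            if spec.bias is None:
                out = int(rng.integers(0, caps[j] + 1))
            else:
                out = int(rng.choice(caps[j] + 1, p=np.asarray(spec.bias, dtype=float)))
            conds = tuple(
                ConditionLiteral(names[i], "==", v) for i, v in zip(inputs, combo)
            )
            cases.append(RuleCase(conditions=conds, output=out))
            last_output = out
        if spec.k_inputs == 0:
            # constant node: the single sampled output becomes the default
            rules[name] = UpdateRule(target=name, cases=(), default=last_output)
        else:
            rules[name] = UpdateRule(target=name, cases=tuple(cases), default=0)
    return LogicalNetwork(
        nodes, rules, name=f"random_n{spec.n_nodes}_k{spec.k_inputs}_s{spec.seed}"
    )


def brute_force_attractors(network: LogicalNetwork, cap: int = 10**5) -> AttractorReport:
    """Naive attractor finder: simulate from every clamp-consistent state.

    Independent of the engine's functional-graph traversal (plain per-state
    trajectory simulation with a visited dict); canonicalised identically so
    reports are directly comparable.
    """
    if network.enumerable_size > cap:
        raise StateSpaceCapExceeded(
            f"{network.enumerable_size} states exceed brute-force cap {cap}"
        )
    axes = []
    for node in network.nodes:
        clamp = network.clamps.get(node.name)
        axes.append([clamp] if clamp is not None else list(range(node.max_level + 1)))
    all_states = list(itertools.product(*axes))
    label: dict[tuple[int, ...], int] = {}
    cycles: list[list[tuple[int, ...]]] = []
    for s0 in all_states:
        if s0 in label:
            continue
        path = []
        pos: dict[tuple[int, ...], int] = {}
        s = s0
        while s not in label and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = successor(network, s)
        if s in label:
            lab = label[s]
        else:
            lab = len(cycles)
            cycles.append(path[pos[s]:])
        for p in path:
            label[p] = lab
    basins = [0] * len(cycles)
    for s in all_states:
        basins[label[s]] += 1
    entries = []
    for cyc, basin in zip(cycles, basins):
        rotated, key = canonicalize_cycle(network, cyc)
        entries.append((key, Attractor(rotated), basin))
    entries.sort(key=lambda e: e[0])
    return AttractorReport(
        attractors=tuple(e[1] for e in entries),
        basin_sizes=tuple(e[2] for e in entries),
        state_space_size=len(all_states),
    )


def _boolean_net(names, rule_strings, name):
    from .engine import parse_case

    nodes = [NodeDecl(n, 1) for n in names]
    rules = {
        n: UpdateRule(target=n, cases=tuple(parse_case(c) for c in cases), default=default)
        for n, (cases, default) in rule_strings.items()
    }
    return LogicalNetwork(nodes, rules, name=name)


def builtin_fixtures() -> dict[str, LogicalNetwork]:
    """Named fixture networks with hand-checkable dynamics.

    identity5: every node copies itself (all 32 states fixed, m = 1).
    constant5: every rule outputs 0 (single fixed point, m = 0).
    negation_ring3: x1' = not x3, x2' = not x1, x3' = not x2
        (one 2-cycle {000, 111}, one 6-cycle; m = 1).
    toggle2: x' = not y, y' = not x (fixed points (0,1), (1,0); 2-cycle
        (0,0) <-> (1,1)).
    g2a / g2b / g2: the reference biological models.
    """
    identity5 = _boolean_net(
        [f"x{i}" for i in range(1, 6)],
        {f"x{i}": ([f"x{i}>=1 -> 1"], 0) for i in range(1, 6)},
        "identity5",
    )
    constant5 = _boolean_net(
        [f"x{i}" for i in range(1, 6)],
        {f"x{i}": ([], 0) for i in range(1, 6)},
        "constant5",
    )
    ring = _boolean_net(
        ["x1", "x2", "x3"],
        {
            "x1": (["x3==0 -> 1"], 0),
            "x2": (["x1==0 -> 1"], 0),
            "x3": (["x2==0 -> 1"], 0),
        },
        "negation_ring3",
    )
    toggle = _boolean_net(
        ["x", "y"],
        {"x": (["y==0 -> 1"], 0), "y": (["x==0 -> 1"], 0)},
        "toggle2",
    )
    return {
        "identity5": identity5,
        "constant5": constant5,
        "negation_ring3": ring,
        "toggle2": toggle,
        "g2a": build_g2a(),
        "g2b": build_g2b(),
        "g2": build_g2_combined(),
    }
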
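"""Synchronous multi-valued logical-network dynamics.

A logical network in the Thomas tradition assigns each node a small integer
activity level (0 = absent/knocked out, 1 = present, optionally 2 =
phosphorylated/high).  Every node carries one update rule; all nodes are
updated simultaneously, so the dynamics is a deterministic map on a finite
mixed-radix state space.  This module provides the state representation,
rule evaluation, successor/trajectory computation, exhaustive attractor and
basin enumeration, and transition-graph construction and export.

States are plain tuples of ints, ordered as the network's node list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NodeDecl",
    "ConditionLiteral",
    "RuleCase",
    "UpdateRule",
    "LogicalNetwork",
    "Attractor",
    "AttractorReport",
    "TransitionGraph",
    "NetworkError",
    "StateSpaceCapExceeded",
    "parse_condition",
    "parse_case",
    "format_case",
    "encode_state",
    "decode_state",
    "evaluate_rule",
    "successor",
    "trajectory",
    "successor_table",
    "enumerate_attractors",
    "transition_graph",
    "truth_table",
    "DEFAULT_STATE_SPACE_CAP",
]

DEFAULT_STATE_SPACE_CAP = 10**7

_RELATIONS = ("==", ">=", "<=")


class NetworkError(ValueError):
    """Invalid network, rule, or state."""


class StateSpaceCapExceeded(RuntimeError):
    """The exhaustive analysis was refused because the state space is too large."""


@dataclass(frozen=True)
class NodeDecl:
    """A node and its maximal activity level (levels run 0..max_level)."""

    name: str
    max_level: int = 1

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise NetworkError("node name must be a nonempty string")
        if self.max_level < 1:
            raise NetworkError(f"{self.name}: max_level must be >= 1")


@dataclass(frozen=True)
class ConditionLiteral:
    """An atomic threshold test on one node's level: node <relation> level."""

    node: str
    relation: str
    level: int

    def __post_init__(self) -> None:
        if self.relation not in _RELATIONS:
            raise NetworkError(f"unknown relation {self.relation!r}")

    def holds(self, level: int) -> bool:
        if self.relation == "==":
            return level == self.level
        if self.relation == ">=":
            return level >= self.level
        return level <= self.level


@dataclass(frozen=True)
class RuleCase:
    """A conjunction of literals mapping to an output level."""

    conditions: tuple[ConditionLiteral, ...]
    output: int


@dataclass(frozen=True)
class UpdateRule:
    """Ordered-case update function for one node.

    Cases are tried in order; the first case whose conjunction holds wins,
    otherwise ``default`` applies, so the rule is total by construction.
    """

    target: str
    cases: tuple[RuleCase, ...]
    default: int

    def inputs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for case in self.cases:
            for lit in case.conditions:
                if lit.node not in seen:
                    seen.append(lit.node)
        return tuple(seen)


_LIT_RE = re.compile(r"^\s*(!?)\s*([A-Za-z_]\w*)\s*(?:(==|>=|<=)\s*(\d+))?\s*$")


def parse_condition(text: str) -> tuple[ConditionLiteral, ...]:
    """Parse a conjunction like ``"CtrA==2 & CcrM>=1 & !GcrA"``.

    Shorthand: a bare name means ``name>=1``; ``!name`` means ``name==0``.
    ``"*"`` or the empty string is the always-true conjunction.
    """
    text = text.strip()
    if text in ("", "*", "true"):
        return ()
    literals = []
    for part in text.split("&"):
        m = _LIT_RE.match(part)
        if not m:
            raise NetworkError(f"cannot parse condition literal {part!r}")
        neg, name, rel, level = m.groups()
        if rel is None:
            lit = (
                ConditionLiteral(name, "==", 0)
                if neg
                else ConditionLiteral(name, ">=", 1)
            )
        else:
            if neg:
                raise NetworkError(f"cannot negate an explicit relation: {part!r}")
            lit = ConditionLiteral(name, rel, int(level))
        literals.append(lit)
    return tuple(literals)


def parse_case(text: str) -> RuleCase:
    """Parse a rule case like ``"CtrA==2 & !GcrA -> 1"``."""
    if "->" not in text:
        raise NetworkError(f"rule case {text!r} lacks '-> level'")
    cond, _, out = text.rpartition("->")
    return RuleCase(parse_condition(cond), int(out))


def format_case(case: RuleCase) -> str:
    if not case.conditions:
        parts = "*"
    else:
        parts = " & ".join(
            f"{lit.node}{lit.relation}{lit.level}" for lit in case.conditions
        )
    return f"{parts} -> {case.output}"


class LogicalNetwork:
    """Node declarations, one update rule per node, and optional clamps.

    Clamps pin a node to a fixed level for the whole simulation (knockout =
    clamp to 0, constitutive expression = clamp to max_level); they override
    the node's rule inside :func:`successor`, never inside
    :func:`evaluate_rule`.
    """

    def __init__(
        self,
        nodes: Sequence[NodeDecl],
        rules: Mapping[str, UpdateRule] | Sequence[UpdateRule],
        clamps: Mapping[str, int] | None = None,
        name: str = "",
    ) -> None:
        self.nodes: tuple[NodeDecl, ...] = tuple(nodes)
        self.name = name
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate node names")
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        if not isinstance(rules, Mapping):
            rules = {r.target: r for r in rules}
        if set(rules) != set(names):
            missing = set(names) - set(rules)
            extra = set(rules) - set(names)
            raise NetworkError(f"rules must cover every node (missing={sorted(missing)}, extra={sorted(extra)})")
        self.rules: dict[str, UpdateRule] = {n: rules[n] for n in names}
        self.clamps: dict[str, int] = dict(clamps or {})
        self._validate()
        self._compiled = self._compile()

    # -- validation / derived structure ---------------------------------

    def _validate(self) -> None:
        for node in self.nodes:
            rule = self.rules[node.name]
            outs = [c.output for c in rule.cases] + [rule.default]
            for o in outs:
                if not 0 <= o <= node.max_level:
                    raise NetworkError(
                        f"{node.name}: rule output {o} outside 0..{node.max_level}"
                    )
            for case in rule.cases:
                for lit in case.conditions:
                    if lit.node not in self.index:
                        raise NetworkError(
                            f"{node.name}: rule references undeclared node {lit.node!r}"
                        )
                    cap = self.nodes[self.index[lit.node]].max_level
                    if not 0 <= lit.level <= cap:
                        raise NetworkError(
                            f"{node.name}: literal level {lit.level} outside "
                            f"0..{cap} for {lit.node}"
                        )
        for cname, clevel in self.clamps.items():
            if cname not in self.index:
                raise NetworkError(f"clamp on undeclared node {cname!r}")
            cap = self.nodes[self.index[cname]].max_level
            if not 0 <= clevel <= cap:
                raise NetworkError(f"clamp {cname}={clevel} outside 0..{cap}")

    def _compile(self):
        compiled = []
        for node in self.nodes:
            rule = self.rules[node.name]
            cases = [
                (
                    tuple(
                        (self.index[lit.node], lit.relation, lit.level)
                        for lit in case.conditions
                    ),
                    case.output,
                )
                for case in rule.cases
            ]
            compiled.append((cases, rule.default))
        return compiled

    # -- basic properties ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def radices(self) -> tuple[int, ...]:
        """Number of levels per node (max_level + 1)."""
        return tuple(n.max_level + 1 for n in self.nodes)

    @property
    def state_space_size(self) -> int:
        """Size of the full (unclamped) state space."""
        size = 1
        for r in self.radices:
            size *= r
        return size

    @property
    def enumerable_size(self) -> int:
        """Size of the clamp-consistent state space (what exhaustive runs cover)."""
        size = 1
        for node, r in zip(self.nodes, self.radices):
            size *= 1 if node.name in self.clamps else r
        return size

    # -- state helpers ----------------------------------------------------

    def state(self, mapping: Mapping[str, int] | None = None, **levels: int) -> tuple[int, ...]:
        """Build a state tuple from node-name keyword levels (others default to 0)."""
        values = dict(mapping or {})
        values.update(levels)
        unknown = set(values) - set(self.index)
        if unknown:
            raise NetworkError(f"unknown nodes {sorted(unknown)}")
        return tuple(values.get(n, 0) for n in self.names)

    def as_dict(self, state: Sequence[int]) -> dict[str, int]:
        return dict(zip(self.names, state))

    def validate_state(self, state: Sequence[int]) -> tuple[int, ...]:
        state = tuple(int(v) for v in state)
        if len(state) != self.n_nodes:
            raise NetworkError(
                f"state has {len(state)} entries, network has {self.n_nodes} nodes"
            )
        for v, node in zip(state, self.nodes):
            if not 0 <= v <= node.max_level:
                raise NetworkError(f"level {v} outside 0..{node.max_level} for {node.name}")
        return state

    def with_clamps(self, clamps: Mapping[str, int], name: str | None = None) -> "LogicalNetwork":
        """Return a copy with additional clamps; conflicts with existing clamps raise."""
        merged = dict(self.clamps)
        for k, v in clamps.items():
            if k in merged:
                raise NetworkError(f"node {k!r} is already clamped (to {merged[k]})")
            merged[k] = v
        return LogicalNetwork(self.nodes, self.rules, merged, name=name or self.name)

    def without_clamps(self) -> "LogicalNetwork":
        return LogicalNetwork(self.nodes, self.rules, {}, name=self.name)

    # -- equality (used for model-file round trips) -----------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicalNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.rules == other.rules
            and self.clamps == other.clamps
        )

    def __repr__(self) -> str:
        label = self.name or "LogicalNetwork"
        return f"<{label}: {self.n_nodes} nodes, |S|={self.state_space_size}, clamps={self.clamps}>"


# ---------------------------------------------------------------------------
# mixed-radix state encoding (first node most significant; all-zero -> 0)
# ---------------------------------------------------------------------------

def _weights(network: LogicalNetwork) -> tuple[int, ...]:
    radices = network.radices
    w = [1] * len(radices)
    for i in range(len(radices) - 2, -1, -1):
        w[i] = w[i + 1] * radices[i + 1]
    return tuple(w)


def encode_state(network: LogicalNetwork, state: Sequence[int]) -> int:
    """Mixed-radix index of a state in [0, state_space_size)."""
    state = network.validate_state(state)
    return sum(v * w for v, w in zip(state, _weights(network)))


def decode_state(network: LogicalNetwork, index: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state`."""
    if not 0 <= index < network.state_space_size:
        raise NetworkError(
            f"index {index} outside [0, {network.state_space_size})"
        )
    out = []
    for w, r in zip(_weights(network), network.radices):
        v, index = divmod(index, w)
        out.append(v)
    return tuple(out)


# ---------------------------------------------------------------------------
# rule evaluation and the synchronous map
# ---------------------------------------------------------------------------

def evaluate_rule(network: LogicalNetwork, rule: UpdateRule, state: Sequence[int]) -> int:
    """First matching case's output, else the default.

    Clamps are deliberately ignored here: clamping is a property of the
    *map* (applied in :func:`successor`), not of the rule.
    """
    if rule.target not in network.index:
        raise NetworkError(f"rule targets undeclared node {rule.target!r}")
    state = network.validate_state(state)
    for case in rule.cases:
        ok = True
        for lit in case.conditions:
            if lit.node not in network.index:
                raise NetworkError(f"undeclared node {lit.node!r} in rule for {rule.target}")
            if not lit.holds(state[network.index[lit.node]]):
                ok = False
                break
        if ok:
            return case.output
    return rule.default


def _holds(rel: str, level: int, threshold: int) -> bool:
    if rel == "==":
        return level == threshold
    if rel == ">=":
        return level >= threshold
    return level <= threshold


def successor(network: LogicalNetwork, state: Sequence[int]) -> tuple[int, ...]:
    """One synchronous step: every node updated from the current state."""
    state = network.validate_state(state)
    out = []
    for node, (cases, default) in zip(network.nodes, network._compiled):
        clamp = network.clamps.get(node.name)
        if clamp is not None:
            out.append(clamp)
            continue
        value = default
        for conds, output in cases:
            if all(_holds(rel, state[i], lv) for i, rel, lv in conds):
                value = output
                break
        out.append(value)
    return tuple(out)


def trajectory(
    network: LogicalNetwork, state: Sequence[int], max_steps: int | None = None
) -> list[tuple[int, ...]]:
    """States visited from ``state`` up to and including the first revisit.

    The closing revisited state is included, so a fixed point yields
    ``[s, s]`` and the tail of the list identifies the reached attractor.
    """
    if max_steps is None:
        max_steps = network.state_space_size + 1
    if max_steps < 1:
        raise NetworkError("max_steps must be >= 1")
    state = network.validate_state(state)
    seen = {state}
    path = [state]
    for _ in range(max_steps):
        state = successor(network, state)
        path.append(state)
        if state in seen:
            return path
        seen.add(state)
    raise RuntimeError(
        "trajectory did not revisit a state within max_steps; "
        "increase max_steps to at least the state-space size"
    )


# ---------------------------------------------------------------------------
# exhaustive analysis (vectorized successor table + functional-graph traversal)
# ---------------------------------------------------------------------------

def _enumeration_axes(network: LogicalNetwork) -> list[range]:
    """Per-node level ranges of the clamp-consistent subspace."""
    axes = []
    for node in network.nodes:
        clamp = network.clamps.get(node.name)
        axes.append(range(clamp, clamp + 1) if clamp is not None else range(node.max_level + 1))
    return axes


def enumerate_states(network: LogicalNetwork) -> np.ndarray:
    """(N, n) matrix of every clamp-consistent state, in subspace order."""
    axes = _enumeration_axes(network)
    grids = np.meshgrid(*[np.array(a, dtype=np.int8) for a in axes], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def apply_rules_vectorized(network: LogicalNetwork, levels: np.ndarray) -> np.ndarray:
    """Synchronous step applied to every row of an (N, n) level matrix."""
    out = np.empty_like(levels)
    for j, (node, (cases, default)) in enumerate(zip(network.nodes, network._compiled)):
        clamp = network.clamps.get(node.name)
        if clamp is not None:
            out[:, j] = clamp
            continue
        col = np.full(levels.shape[0], default, dtype=levels.dtype)
        # later cases first so earlier (higher-priority) cases overwrite
        for conds, output in reversed(cases):
            mask = np.ones(levels.shape[0], dtype=bool)
            for i, rel, lv in conds:
                x = levels[:, i]
                mask &= x == lv if rel == "==" else (x >= lv if rel == ">=" else x <= lv)
            col[mask] = output
        out[:, j] = col
    return out


def successor_table(network: LogicalNetwork, cap: int = DEFAULT_STATE_SPACE_CAP):
    """Successor map over the clamp-consistent subspace.

    Returns ``(states, succ_idx)`` where ``states`` is the (N, n) state
    matrix in subspace order and ``succ_idx[i]`` is the subspace index of
    the successor of ``states[i]``.
    """
    n_states = network.enumerable_size
    if n_states > cap:
        raise StateSpaceCapExceeded(
            f"{n_states} states exceed the cap of {cap}; exhaustive analysis refused"
        )
    states = enumerate_states(network)
    nxt = apply_rules_vectorized(network, states)
    # subspace mixed-radix weights (clamped nodes contribute radix 1)
    axes = _enumeration_axes(network)
    radices = [len(a) for a in axes]
    offsets = np.array([a.start for a in axes], dtype=np.int64)
    w = np.ones(len(radices), dtype=np.int64)
    for i in range(len(radices) - 2, -1, -1):
        w[i] = w[i + 1] * radices[i + 1]
    succ_idx = (nxt.astype(np.int64) - offsets) @ w
    return states, succ_idx


@dataclass(frozen=True)
class Attractor:
    """A fixed point (length 1) or limit cycle (length >= 2).

    ``states[i+1]`` is the successor of ``states[i]``, cyclically; the cycle
    is rotated so the lexicographically smallest encoded state comes first.
    """

    states: tuple[tuple[int, ...], ...]

    @property
    def kind(self) -> str:
        return "fixed_point" if len(self.states) == 1 else "limit_cycle"

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class AttractorReport:
    """All attractors of a network with their basin sizes."""

    attractors: tuple[Attractor, ...]
    basin_sizes: tuple[int, ...]
    state_space_size: int

    @property
    def fixed_points(self) -> tuple[Attractor, ...]:
        return tuple(a for a in self.attractors if a.kind == "fixed_point")

    @property
    def limit_cycles(self) -> tuple[Attractor, ...]:
        return tuple(a for a in self.attractors if a.kind == "limit_cycle")


def canonicalize_cycle(
    network: LogicalNetwork, cycle: Sequence[tuple[int, ...]]
) -> tuple[tuple[tuple[int, ...], ...], int]:
    """Rotate a cycle to start at its smallest encoded state.

    Returns the rotated cycle and that smallest index (used to order
    attractors reproducibly).
    """
    codes = [encode_state(network, s) for s in cycle]
    k = codes.index(min(codes))
    rotated = tuple(cycle[k:]) + tuple(cycle[:k])
    return rotated, codes[k]


def enumerate_attractors(
    network: LogicalNetwork, cap: int = DEFAULT_STATE_SPACE_CAP
) -> AttractorReport:
    """Find ALL attractors and basin sizes by exhaustive traversal.

    Every clamp-consistent state is colored by following successor chains;
    a chain either hits an already-resolved state (joining its attractor's
    basin) or closes a new cycle.  Attractors are canonically rotated and
    ordered by their smallest encoded state.
    """
    states, succ_idx = successor_table(network, cap=cap)
    n_states = len(states)
    labels = np.full(n_states, -1, dtype=np.int64)
    raw_cycles: list[list[int]] = []
    for s0 in range(n_states):
        if labels[s0] >= 0:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        x = s0
        while labels[x] < 0 and x not in pos:
            pos[x] = len(path)
            path.append(x)
            x = int(succ_idx[x])
        if labels[x] >= 0:
            lab = int(labels[x])
        else:
            lab = len(raw_cycles)
            raw_cycles.append(path[pos[x]:])
        labels[path] = lab
    basins = np.bincount(labels, minlength=len(raw_cycles))
    # canonical order
    entries = []
    for lab, cyc in enumerate(raw_cycles):
        cycle_states = [tuple(int(v) for v in states[i]) for i in cyc]
        rotated, key = canonicalize_cycle(network, cycle_states)
        entries.append((key, Attractor(rotated), int(basins[lab])))
    entries.sort(key=lambda e: e[0])
    return AttractorReport(
        attractors=tuple(e[1] for e in entries),
        basin_sizes=tuple(e[2] for e in entries),
        state_space_size=n_states,
    )


@dataclass(frozen=True)
class TransitionGraph:
    """The deterministic transition graph over the enumerated state space.

    ``edges[i]`` is the subspace index of the successor of state ``i``;
    ``states`` holds the level vectors in the same order.
    """

    states: tuple[tuple[int, ...], ...]
    edges: tuple[int, ...]
    node_names: tuple[str, ...]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i, s in enumerate(self.states):
            g.add_node(i, levels=",".join(str(v) for v in s))
        for i, j in enumerate(self.edges):
            g.add_edge(i, j)
        return g


def transition_graph(
    network: LogicalNetwork, cap: int = DEFAULT_STATE_SPACE_CAP
) -> TransitionGraph:
    """Full synchronous transition graph (out-degree exactly 1)."""
    states, succ_idx = successor_table(network, cap=cap)
    return TransitionGraph(
        states=tuple(tuple(int(v) for v in s) for s in states),
        edges=tuple(int(i) for i in succ_idx),
        node_names=network.names,
    )


# ---------------------------------------------------------------------------
# truth-table expansion (oracle view of a rule)
# ---------------------------------------------------------------------------

def truth_table(
    network: LogicalNetwork, node: str
) -> dict[tuple[int, ...], int]:
    """Expand a node's rule into an explicit truth table over its inputs.

    Keys are level tuples over ``rule.inputs()`` (in that order); values are
    the rule's output.  Rules with no inputs map the empty tuple to the
    constant output.
    """
    import itertools

    if node not in network.index:
        raise NetworkError(f"unknown node {node!r}")
    rule = network.rules[node]
    input_names = rule.inputs()
    ranges = [range(network.nodes[network.index[n]].max_level + 1) for n in input_names]
    table: dict[tuple[int, ...], int] = {}
    for combo in itertools.product(*ranges):
        probe = list(network.state())
        for n, v in zip(input_names, combo):
            probe[network.index[n]] = v
        table[tuple(combo)] = evaluate_rule(network, rule, probe)
    return table
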
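"""Derrida-map analysis: perturbation propagation and dynamical regime.

The Derrida map M(h) is the mean Hamming distance between two synchronous
trajectories one step after they start at distance h.  Its slope at the
origin, m = dM/dh at h = 0, classifies the regime: perturbations are
absorbed when m < 1 (ordered), amplified when m > 1 (chaotic), and
marginally propagated at m = 1 (critical).

For multi-valued networks the Hamming distance counts differing nodes
(not summed level gaps).  Since h is discrete and M(0) = 0 exactly, the
slope is estimated through the origin from the h = 1 class: the average
number of nodes that change after one step following a single-node
perturbation, averaged over background states, perturbed node, and
replacement level.  A short linear fit over h <= 3 is available as a
sensitivity check.

Clamped (knocked-out) networks are handled by applying the clamped map
verbatim: backgrounds are drawn clamp-consistently, the perturbed node is
drawn uniformly over ALL nodes, and a perturbation landing on a clamped
node is erased by the clamp after one step (though it may propagate
through the node's readers during that step).  Consequently clamped
coordinates never count as differing in M.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import (
    LogicalNetwork,
    NetworkError,
    StateSpaceCapExceeded,
    apply_rules_vectorized,
    enumerate_states,
    successor,
)

__all__ = [
    "hamming_distance",
    "random_state",
    "perturb_state",
    "DerridaMap",
    "derrida_map",
    "RegimeEstimate",
    "derrida_slope",
    "exact_derrida_slope",
    "knockout_derrida_scan",
    "classify_regime",
    "plot_derrida_map",
    "CRITICAL_BAND",
]

CRITICAL_BAND = 0.05


def hamming_distance(s1: Sequence[int], s2: Sequence[int]) -> int:
    """Number of nodes at which two states differ."""
    if len(s1) != len(s2):
        raise NetworkError("states have different lengths")
    return sum(a != b for a, b in zip(s1, s2))


def random_state(network: LogicalNetwork, rng: np.random.Generator) -> tuple[int, ...]:
    """Uniform draw over the clamp-consistent state space."""
    out = []
    for node in network.nodes:
        clamp = network.clamps.get(node.name)
        out.append(clamp if clamp is not None else int(rng.integers(0, node.max_level + 1)))
    return tuple(out)


def perturb_state(
    network: LogicalNetwork,
    state: Sequence[int],
    h: int,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Flip exactly h distinct nodes to new uniformly chosen levels.

    Each perturbed node is reassigned a level drawn uniformly from its
    allowed levels excluding the current one, so the Hamming distance to
    the input is exactly h.
    """
    state = network.validate_state(state)
    n = network.n_nodes
    if not 1 <= h <= n:
        raise NetworkError(f"h={h} outside 1..{n}")
    picked = rng.choice(n, size=h, replace=False)
    out = list(state)
    for i in picked:
        cap = network.nodes[i].max_level
        draw = int(rng.integers(0, cap))
        # skip over the current level: uniform over the cap alternatives
        out[i] = draw if draw < state[i] else draw + 1
    return tuple(out)


@dataclass(frozen=True)
class DerridaMap:
    """Sampled one-step Derrida map M(h) for h = 1..n (M(0) = 0 exactly)."""

    h_values: tuple[int, ...]
    m_values: tuple[float, ...]
    stderr: tuple[float, ...]
    sample_counts: tuple[int, ...]
    n_nodes: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.h_values,
                "h_normalized": [h / self.n_nodes for h in self.h_values],
                "M": self.m_values,
                "M_normalized": [m / self.n_nodes for m in self.m_values],
                "n_samples": self.sample_counts,
                "stderr": self.stderr,
            }
        )


def derrida_map(
    network: LogicalNetwork,
    samples_per_h: int = 20_000,
    seed: int = 0,
    h_values: Sequence[int] | None = None,
) -> DerridaMap:
    """Sample the one-step Derrida map.

    For each h: draw a clamp-consistent background S1, perturb h nodes to
    get S2, advance both one synchronous step, and record the Hamming
    distance.  Reproducible for a fixed seed.
    """
    if samples_per_h < 1:
        raise NetworkError("samples_per_h must be >= 1")
    rng = np.random.default_rng(seed)
    n = network.n_nodes
    if h_values is None:
        h_values = range(1, n + 1)
    ms, ses, counts = [], [], []
    for h in h_values:
        dists = np.empty(samples_per_h)
        for k in range(samples_per_h):
            s1 = random_state(network, rng)
            s2 = perturb_state(network, s1, h, rng)
            dists[k] = hamming_distance(successor(network, s1), successor(network, s2))
        ms.append(float(dists.mean()))
        ses.append(float(dists.std(ddof=1) / np.sqrt(samples_per_h)) if samples_per_h > 1 else 0.0)
        counts.append(samples_per_h)
    return DerridaMap(
        h_values=tuple(int(h) for h in h_values),
        m_values=tuple(ms),
        stderr=tuple(ses),
        sample_counts=tuple(counts),
        n_nodes=n,
        seed=seed,
    )


@dataclass(frozen=True)
class RegimeEstimate:
    """Slope of the Derrida map at the origin and the implied regime."""

    slope_m: float
    standard_error: float
    regime: str
    n_samples: int
    method: str = "h1"


def classify_regime(m: float, critical_band: float = CRITICAL_BAND) -> str:
    if abs(m - 1.0) <= critical_band:
        return "critical"
    return "ordered" if m < 1.0 else "chaotic"


def derrida_slope(
    network: LogicalNetwork,
    samples: int = 20_000,
    seed: int = 0,
    method: str = "h1",
    critical_band: float = CRITICAL_BAND,
) -> RegimeEstimate:
    """Estimate m = dM/dh at h = 0 by sampling.

    ``method='h1'`` (default): m = M(1), the finite difference through the
    origin.  ``method='linear3'``: slope of an unweighted least-squares
    line through the origin over the classes h = 1..3, as a sensitivity
    check on the h-grid choice.
    """
    if method == "h1":
        dm = derrida_map(network, samples_per_h=samples, seed=seed, h_values=[1])
        m, se = dm.m_values[0], dm.stderr[0]
    elif method == "linear3":
        hmax = min(3, network.n_nodes)
        dm = derrida_map(
            network, samples_per_h=samples, seed=seed, h_values=range(1, hmax + 1)
        )
        h = np.array(dm.h_values, dtype=float)
        M = np.array(dm.m_values)
        m = float((h @ M) / (h @ h))  # through-origin least squares
        se = float(np.sqrt(np.array(dm.stderr) ** 2 @ (h / (h @ h)) ** 2))
    else:
        raise NetworkError(f"unknown slope method {method!r}")
    return RegimeEstimate(
        slope_m=m,
        standard_error=se,
        regime=classify_regime(m, critical_band),
        n_samples=samples,
        method=method,
    )


def exact_derrida_slope(network: LogicalNetwork, cap: int = 10**6) -> float:
    """Exhaustively enumerated m = M(1): the oracle for the sampled slope.

    Averages the one-step Hamming distance over every clamp-consistent
    background state, every perturbed node (uniform over all n nodes), and
    every replacement level (uniform over the node's alternatives).
    """
    n_states = network.enumerable_size
    n = network.n_nodes
    # pairs evaluated: n_states * sum(caps); guard on the dominant factor
    if n_states * n > cap * 4:
        raise StateSpaceCapExceeded(
            f"{n_states} states x {n} nodes too large for exact enumeration (cap {cap})"
        )
    states = enumerate_states(network)
    base_next = apply_rules_vectorized(network, states)
    total = 0.0
    for i, node in enumerate(network.nodes):
        cap_i = node.max_level
        per_state = np.zeros(len(states))
        for v in range(cap_i + 1):
            cur = states[:, i]
            mask = cur != v
            if not mask.any():
                continue
            perturbed = states.copy()
            perturbed[:, i] = v
            dist = (apply_rules_vectorized(network, perturbed) != base_next).sum(axis=1)
            per_state += np.where(mask, dist, 0) / cap_i
        total += per_state.sum()
    return float(total / (len(states) * n))


def knockout_derrida_scan(
    network: LogicalNetwork,
    samples: int = 5_000,
    seed: int = 0,
    exact: bool = False,
    critical_band: float = CRITICAL_BAND,
) -> pd.DataFrame:
    """Slope under each single-node knockout, plus the wild type.

    Returns a DataFrame with columns node, m, stderr, regime, sorted by m
    ascending (the wild-type row is labeled ``(wild_type)``).  With
    ``exact=True`` the exhaustive enumerator is used and stderr is 0.
    """
    rows = []

    def estimate(net: LogicalNetwork, label: str) -> dict:
        if exact:
            m = exact_derrida_slope(net)
            return {"node": label, "m": m, "stderr": 0.0, "regime": classify_regime(m, critical_band)}
        est = derrida_slope(net, samples=samples, seed=seed)
        return {"node": label, "m": est.slope_m, "stderr": est.standard_error, "regime": est.regime}

    rows.append(estimate(network, "(wild_type)"))
    for name in network.names:
        if name in network.clamps:
            continue
        ko = network.with_clamps({name: 0}, name=f"{network.name}_d{name}")
        rows.append(estimate(ko, name))
    df = pd.DataFrame(rows).sort_values("m", kind="stable").reset_index(drop=True)
    return df


def plot_derrida_map(dmap: DerridaMap, path=None, normalized: bool = True):
    """Plot M(h) with the diagonal reference line; save to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = dmap.as_frame()
    x = frame["h_normalized"] if normalized else frame["h"]
    y = frame["M_normalized"] if normalized else frame["M"]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lim = 1.0 if normalized else dmap.n_nodes
    ax.plot([0, lim], [0, lim], "--", color="grey", lw=1, label="M(h) = h")
    ax.plot(np.concatenate([[0], x]), np.concatenate([[0], y]), "o-", label="M(h)")
    ax.set_xlabel("h(t)" + (" / n" if normalized else ""))
    ax.set_ylabel("M(h) = h(t+1)" + (" / n" if normalized else ""))
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
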
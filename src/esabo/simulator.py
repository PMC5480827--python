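"""Signed Boolean network dynamics for synthetic microbiome compositions.

A community of ``N`` microbial species is modelled as an undirected graph
whose edges carry a sign: ``+1`` for synergistic (mutualistic) and ``-1``
for competitive interactions.  The binary state vector ``s`` records which
species are present.  All species are updated synchronously by a
majority-of-inputs rule:

    s_i(t+1) = 1        if sum_j G_ij s_j(t) > 0
    s_i(t+1) = s_i(t)   if sum_j G_ij s_j(t) = 0
    s_i(t+1) = 0        if sum_j G_ij s_j(t) < 0

where ``G`` is the signed adjacency matrix.  Because the state space is
finite every trajectory ends in a fixed point or a cycle; those attractors
are interpreted as steady-state community compositions and collected into a
samples x species presence/absence table.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "AttractorRecord",
    "generate_random_signed_network",
    "update_state",
    "run_to_attractor",
    "enumerate_attractors",
    "sample_attractor_table",
    "add_binary_noise",
]


def default_labels(n_nodes: int) -> tuple[str, ...]:
    """Species labels: single letters A, B, ... for up to 26 nodes, else sp001, ..."""
    if n_nodes <= 26:
        return tuple(string.ascii_uppercase[:n_nodes])
    return tuple(f"sp{i + 1:03d}" for i in range(n_nodes))


@dataclass(frozen=True)
class InteractionNetwork:
    """Signed, undirected, simple interaction graph over ``n_nodes`` species.

    ``adjacency`` is the symmetric generalized adjacency matrix with entries
    in {-1, 0, +1} and zero diagonal; entry ``(i, j)`` is the sign of the
    interaction between species ``i`` and ``j``.
    """

    adjacency: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.int8)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-interactions are not allowed (diagonal must be 0)")
        if not np.isin(adj, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        object.__setattr__(self, "adjacency", adj)
        labels = tuple(self.labels) or default_labels(adj.shape[0])
        if len(labels) != adj.shape[0]:
            raise ValueError("number of labels must match number of nodes")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_positive(self) -> int:
        return int(np.sum(np.triu(self.adjacency) == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(np.triu(self.adjacency) == -1))

    def edges(self) -> list[tuple[str, str, int]]:
        """All edges as (label_a, label_b, sign), upper-triangle order."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return [
            (self.labels[i], self.labels[j], int(self.adjacency[i, j]))
            for i, j in zip(ii, jj)
        ]

    def non_edges(self) -> list[tuple[str, str]]:
        """Unordered node pairs with no interaction."""
        out = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if self.adjacency[i, j] == 0:
                    out.append((self.labels[i], self.labels[j]))
        return out

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency))))
        return nx.is_connected(g)

    @classmethod
    def from_edges(
        cls,
        labels: Sequence[str],
        positive: Iterable[tuple[str, str]],
        negative: Iterable[tuple[str, str]],
    ) -> "InteractionNetwork":
        """Build a network from explicit signed edge lists over labelled nodes."""
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
        for sign, pairs in ((1, positive), (-1, negative)):
            for a, b in pairs:
                i, j = index[a], index[b]
                if i == j:
                    raise ValueError(f"self-loop on node {a!r}")
                if adj[i, j] != 0:
                    raise ValueError(f"duplicate edge {a!r}-{b!r}")
                adj[i, j] = adj[j, i] = sign
        return cls(adj, labels)


@dataclass(frozen=True)
class AttractorRecord:
    """An attractor of the synchronous dynamics.

    ``representative`` is the canonical state: the fixed point itself, or the
    lexicographically smallest state of a cycle.  ``basin_hits`` counts how
    many sampled initial conditions reached this attractor (1 for a single
    :func:`run_to_attractor` call).
    """

    kind: str  # "fixed_point" or "cycle"
    representative: np.ndarray
    cycle_length: int
    basin_hits: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_point", "cycle"):
            raise ValueError("kind must be 'fixed_point' or 'cycle'")
        if (self.kind == "fixed_point") != (self.cycle_length == 1):
            raise ValueError("fixed_point if and only if cycle_length == 1")


def generate_random_signed_network(
    n_nodes: int,
    n_positive: int,
    n_negative: int,
    seed: int | np.random.Generator,
    max_retries: int = 10_000,
) -> InteractionNetwork:
    """Draw a connected random graph with signed edges, uniform given connectivity.

    Edge positions are sampled uniformly among all simple graphs with
    ``n_positive + n_negative`` edges; draws whose underlying graph is
    disconnected are rejected and redrawn (up to ``max_retries``), so the
    result is uniform over *connected* configurations.  Signs are then
    assigned by a uniform random partition of the accepted edge set.
    """
    m = n_positive + n_negative
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_positive < 0 or n_negative < 0:
        raise ValueError("edge counts must be non-negative")
    if m > max_edges:
        raise ValueError(
            f"{m} edges requested but a simple graph on {n_nodes} nodes "
            f"holds at most {max_edges}"
        )
    if m < n_nodes - 1:
        raise ValueError(
            f"{m} edges cannot connect {n_nodes} nodes (need at least {n_nodes - 1})"
        )
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    for _ in range(max_retries):
        chosen = rng.choice(len(pairs), size=m, replace=False)
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(pairs[k] for k in chosen)
        if not nx.is_connected(g):
            continue
        adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        signs = rng.permutation([1] * n_positive + [-1] * n_negative)
        for k, sign in zip(chosen, signs):
            i, j = pairs[k]
            adj[i, j] = adj[j, i] = sign
        return InteractionNetwork(adj)
    raise RuntimeError(
        f"no connected graph found in {max_retries} draws "
        f"(n_nodes={n_nodes}, edges={m}); increase max_retries or edge count"
    )


def update_state(network: InteractionNetwork, state: np.ndarray) -> np.ndarray:
    """One synchronous step of the threshold dynamics."""
    state = np.asarray(state, dtype=np.int8)
    if state.shape != (network.n_nodes,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({network.n_nodes},)"
        )
    drive = network.adjacency @ state
    return np.where(drive > 0, 1, np.where(drive < 0, 0, state)).astype(np.int8)


def _default_max_steps(n_nodes: int) -> int:
    if n_nodes > 20:
        raise ValueError(
            "for networks with more than 20 nodes pass max_steps explicitly "
            "(the default 2**N + 1 would be astronomically large)"
        )
    return 2**n_nodes + 1


def run_to_attractor(
    network: InteractionNetwork,
    initial: np.ndarray,
    max_steps: int | None = None,
) -> AttractorRecord:
    """Iterate the dynamics until a state repeats; return the attractor.

    The trajectory is followed with exact state hashing; the first revisited
    state closes either a fixed point or a cycle.  Since the state space has
    2^N elements a revisit is guaranteed within 2^N + 1 steps.
    """
    if max_steps is None:
        max_steps = _default_max_steps(network.n_nodes)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = np.asarray(initial, dtype=np.int8)
    seen: dict[bytes, int] = {}
    trajectory: list[np.ndarray] = []
    for _ in range(max_steps + 1):
        key = state.tobytes()
        if key in seen:
            cycle = trajectory[seen[key]:]
            rep = min(cycle, key=lambda s: tuple(s))
            length = len(cycle)
            return AttractorRecord(
                kind="fixed_point" if length == 1 else "cycle",
                representative=rep.copy(),
                cycle_length=length,
            )
        seen[key] = len(trajectory)
        trajectory.append(state)
        state = update_state(network, state)
    raise RuntimeError(
        f"no state revisited within max_steps={max_steps}; "
        "increase max_steps (2**N + 1 always suffices)"
    )


def enumerate_attractors(
    network: InteractionNetwork, max_nodes: int = 20
) -> list[AttractorRecord]:
    """Exhaustive attractor enumeration over all 2^N initial states.

    Brute-force ground truth for small networks; ``basin_hits`` holds exact
    basin sizes.  Attractors are returned sorted by representative.
    """
    n = network.n_nodes
    if n > max_nodes:
        raise ValueError(f"exhaustive sweep over 2^{n} states refused (> 2^{max_nodes})")
    found: dict[bytes, AttractorRecord] = {}
    for code in range(2**n):
        state = np.array([(code >> k) & 1 for k in range(n)], dtype=np.int8)
        rec = run_to_attractor(network, state)
        key = rec.representative.tobytes()
        if key in found:
            prev = found[key]
            found[key] = AttractorRecord(
                prev.kind, prev.representative, prev.cycle_length, prev.basin_hits + 1
            )
        else:
            found[key] = rec
    return sorted(found.values(), key=lambda r: tuple(r.representative))


def sample_attractor_table(
    network: InteractionNetwork,
    n_initial: int,
    seed: int | np.random.Generator,
    weighting: str = "distinct",
    max_steps: int | None = None,
) -> pd.DataFrame:
    """Sample attractors from random initial compositions into a binary table.

    Initial states are i.i.d. Bernoulli(1/2) per species.  In ``distinct``
    mode the table has one row per distinct attractor representative (the
    default, which samples the steady-state repertoire homogeneously); in
    ``basin_weighted`` mode one row per initial condition, so attractors
    appear in proportion to their basin sizes.

    Returns a samples x species DataFrame of 0/1 with species labels as
    columns.
    """
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")
    if weighting not in ("distinct", "basin_weighted"):
        raise ValueError("weighting must be 'distinct' or 'basin_weighted'")
    rng = np.random.default_rng(seed)
    n = network.n_nodes
    cache: dict[bytes, np.ndarray] = {}  # any visited state -> its attractor rep
    rows: list[np.ndarray] = []
    for _ in range(n_initial):
        state = rng.integers(0, 2, size=n).astype(np.int8)
        path: list[bytes] = []
        probe = state
        while probe.tobytes() not in cache and probe.tobytes() not in path:
            path.append(probe.tobytes())
            probe = update_state(network, probe)
        if probe.tobytes() in cache:
            rep = cache[probe.tobytes()]
        else:
            rep = run_to_attractor(network, probe, max_steps=max_steps).representative
        for key in path:
            cache[key] = rep
        rows.append(rep)
    if weighting == "distinct":
        uniq = sorted({r.tobytes() for r in rows})
        data = np.array([np.frombuffer(b, dtype=np.int8) for b in uniq])
        index = [f"attractor_{k + 1:03d}" for k in range(len(uniq))]
    else:
        data = np.array(rows)
        index = [f"sample_{k + 1:04d}" for k in range(len(rows))]
    return pd.DataFrame(data, index=index, columns=list(network.labels), dtype=np.int8)


def add_binary_noise(
    table: pd.DataFrame,
    noise_level: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Substitute a fraction of entries by a fair coin flip.

    Each entry is independently selected with probability ``noise_level``;
    selected entries are replaced by a uniform draw from {0, 1} (so the
    expected fraction of entries actually changed is ``noise_level / 2``).
    """
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError("noise_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = table.to_numpy(dtype=np.int8, copy=True)
    mask = rng.random(values.shape) < noise_level
    values[mask] = rng.integers(0, 2, size=int(mask.sum()), dtype=np.int8)
    return pd.DataFrame(values, index=table.index, columns=table.columns, dtype=np.int8)
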
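"""Erdős–Rényi network container with in-place node removal.

The simulator spends almost all of its time deleting nodes one at a time
from a large sparse graph and re-evaluating connectivity statistics, so the
container is deliberately minimal: static adjacency lists plus an
``alive`` mask and a cached array of *alive-subgraph* degrees.  Removing a
node never rewrites adjacency; it flips the mask and decrements the cached
degrees of the surviving neighbours.  Links to removed nodes therefore do
not count towards any degree, moment, or component statistic.

Node ids are ``0..N-1`` and stable for the lifetime of a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "Network",
    "DegreeDistribution",
    "UndefinedKappaError",
    "generate_er",
    "kappa",
    "cluster_sizes",
    "largest_cluster_fraction",
    "read_edge_list",
    "write_edge_list",
]


class UndefinedKappaError(RuntimeError):
    """All alive nodes have degree zero, so κ = ⟨k²⟩/⟨k⟩ is 0/0.

    Callers treat this as "the network has already broken down": with no
    surviving edge there cannot be a spanning cluster.
    """


@dataclass
class Network:
    """Simple undirected graph with a node-removal mask.

    Attributes
    ----------
    n_nodes:
        Number of nodes ``N``; ids are ``0..N-1``.
    adjacency:
        Per-node neighbour-id lists (symmetric, no self-loops, no
        parallel edges).  Never mutated by node removal.
    alive:
        Per-node flag; ``True`` means the node has not been removed.
    degrees:
        Degree of each node *within the alive subgraph*.  Entries of
        removed nodes are zero.
    """

    n_nodes: int
    adjacency: list[list[int]]
    alive: list[bool] = field(default=None)  # type: ignore[assignment]
    degrees: list[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alive is None:
            self.alive = [True] * self.n_nodes
        if self.degrees is None:
            self.degrees = [len(nbrs) for nbrs in self.adjacency]

    # -- basic queries -------------------------------------------------

    @property
    def n_alive(self) -> int:
        return sum(self.alive)

    @property
    def n_edges(self) -> int:
        """Number of edges between alive nodes."""
        return sum(d for d, a in zip(self.degrees, self.alive) if a) // 2

    def alive_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.alive[v]]

    def alive_degrees(self) -> np.ndarray:
        """Degrees of the alive nodes (alive-subgraph convention)."""
        return np.array(
            [d for d, a in zip(self.degrees, self.alive) if a], dtype=np.int64
        )

    # -- mutation ------------------------------------------------------

    def remove_node(self, v: int) -> None:
        """Remove node ``v`` and all of its links."""
        if not self.alive[v]:
            raise ValueError(f"node {v} is already removed")
        alive = self.alive
        degrees = self.degrees
        for u in self.adjacency[v]:
            if alive[u]:
                degrees[u] -= 1
        degrees[v] = 0
        alive[v] = False

    def copy(self) -> "Network":
        return Network(
            n_nodes=self.n_nodes,
            adjacency=[list(nbrs) for nbrs in self.adjacency],
            alive=list(self.alive),
            degrees=list(self.degrees),
        )

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "Network":
        """Build a network from an iterable of undirected edges.

        Rejects self-loops and parallel edges (the graph must be simple).
        """
        adjacency: list[list[int]] = [[] for _ in range(n_nodes)]
        seen: set[tuple[int, int]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop at node {a}")
            if not (0 <= a < n_nodes and 0 <= b < n_nodes):
                raise ValueError(f"edge ({a}, {b}) outside node range 0..{n_nodes - 1}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                raise ValueError(f"parallel edge ({a}, {b})")
            seen.add(key)
            adjacency[a].append(b)
            adjacency[b].append(a)
        return cls(n_nodes=n_nodes, adjacency=adjacency)

    def edges(self) -> list[tuple[int, int]]:
        """Edges of the alive subgraph, each as ``(min, max)``, sorted."""
        out = []
        for v in range(self.n_nodes):
            if not self.alive[v]:
                continue
            for u in self.adjacency[v]:
                if u > v and self.alive[u]:
                    out.append((v, u))
        out.sort()
        return out


@dataclass(frozen=True)
class DegreeDistribution:
    """Degree distribution P(k) with its mean ⟨k⟩ = Σ k·P(k).

    ``probabilities`` maps degree k to P(k); entries must be nonnegative
    and sum to one (tolerance 1e-12), and ``mean`` must be consistent with
    the probabilities to the same tolerance.
    """

    probabilities: Mapping[int, float]
    mean: float

    def __post_init__(self) -> None:
        total = math.fsum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("negative probability")
        mean = math.fsum(k * p for k, p in self.probabilities.items())
        if abs(mean - self.mean) > 1e-12:
            raise ValueError(f"stated mean {self.mean} != Σ k·P(k) = {mean}")

    @classmethod
    def from_probabilities(cls, probabilities: Mapping[int, float]) -> "DegreeDistribution":
        mean = math.fsum(k * p for k, p in probabilities.items())
        return cls(probabilities=dict(probabilities), mean=mean)

    @classmethod
    def from_degrees(cls, degrees: Sequence[int]) -> "DegreeDistribution":
        """Empirical degree distribution of a degree sequence."""
        degrees = np.asarray(degrees, dtype=np.int64)
        if degrees.size == 0:
            raise ValueError("empty degree sequence")
        values, counts = np.unique(degrees, return_counts=True)
        probs = {int(k): c / degrees.size for k, c in zip(values, counts)}
        return cls.from_probabilities(probs)

    @classmethod
    def from_network(cls, network: Network) -> "DegreeDistribution":
        return cls.from_degrees(network.alive_degrees())

    @classmethod
    def poisson(cls, mean: float, k_max: int | None = None) -> "DegreeDistribution":
        """Truncated, renormalised Poisson(mean).

        The series is cut at ``k_max = ⌈mean + 12·√mean⌉`` by default,
        where the discarded tail mass is below 1e-12, and renormalised so
        the distribution is exactly stochastic.
        """
        if mean < 0:
            raise ValueError("mean must be nonnegative")
        if mean == 0:
            return cls(probabilities={0: 1.0}, mean=0.0)
        if k_max is None:
            k_max = math.ceil(mean + 12.0 * math.sqrt(mean))
        ks = np.arange(k_max + 1)
        pmf = stats.poisson.pmf(ks, mean)
        pmf = pmf / pmf.sum()
        return cls.from_probabilities({int(k): float(p) for k, p in zip(ks, pmf)})


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_er(n_nodes: int, mean_degree: float, seed: int) -> Network:
    """Generate a G(N, p) Erdős–Rényi network.

    Every unordered node pair is connected independently with
    ``p = mean_degree / (n_nodes - 1)``, so the realised mean degree is a
    random variable centred on ``mean_degree``.  Sampling uses the
    geometric skip method (O(E), not O(N²)).  The same seed reproduces the
    identical graph.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if not 0 <= mean_degree <= n_nodes - 1:
        raise ValueError(
            f"mean_degree must lie in [0, n_nodes-1] = [0, {n_nodes - 1}]; "
            f"got {mean_degree}"
        )
    p = mean_degree / (n_nodes - 1)
    g = nx.fast_gnp_random_graph(n_nodes, p, seed=int(seed))
    adjacency: list[list[int]] = [[] for _ in range(n_nodes)]
    for a, b in g.edges():
        adjacency[a].append(b)
        adjacency[b].append(a)
    return Network(n_nodes=n_nodes, adjacency=adjacency)


# ---------------------------------------------------------------------------
# Connectivity statistics
# ---------------------------------------------------------------------------


def kappa(network: Network) -> float:
    """Molloy–Reed ratio κ = ⟨k²⟩/⟨k⟩ over the alive subgraph.

    Degrees are counted within the alive subgraph, so links to removed
    nodes contribute nothing.  Isolated alive nodes contribute k = 0 to
    both moments.  A giant component can exist only while κ > 2; the
    breakdown criterion of the removal process is the first crossing of
    κ = 2.

    Raises
    ------
    UndefinedKappaError
        If every alive node has degree zero (κ is 0/0); callers treat
        this as an already-broken network.
    """
    degs = network.alive_degrees()
    if degs.size == 0:
        raise UndefinedKappaError("no alive nodes")
    sum_k = int(degs.sum())
    if sum_k == 0:
        raise UndefinedKappaError("all alive degrees are zero")
    sum_k2 = int((degs.astype(np.int64) ** 2).sum())
    return sum_k2 / sum_k


def _component_sizes(network: Network) -> list[int]:
    """Connected-component sizes of the alive subgraph (iterative BFS)."""
    alive = network.alive
    adjacency = network.adjacency
    seen = [False] * network.n_nodes
    sizes: list[int] = []
    for start in range(network.n_nodes):
        if not alive[start] or seen[start]:
            continue
        seen[start] = True
        size = 1
        stack = [start]
        while stack:
            v = stack.pop()
            for u in adjacency[v]:
                if alive[u] and not seen[u]:
                    seen[u] = True
                    size += 1
                    stack.append(u)
        sizes.append(size)
    return sizes


def cluster_sizes(network: Network) -> list[int]:
    """Sizes of the connected components of the alive subgraph, descending.

    The sizes sum to the number of alive nodes; an empty graph yields an
    empty list.
    """
    return sorted(_component_sizes(network), reverse=True)


def largest_cluster_fraction(network: Network) -> float:
    """Relative size S of the largest cluster.

    S divides the largest component size by the number of nodes still
    present (the alive count), not by the initial N.
    """
    n_alive = network.n_alive
    if n_alive == 0:
        raise ValueError("no alive nodes")
    return max(_component_sizes(network)) / n_alive


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

_NODES_COMMENT = "# n_nodes ="


def write_edge_list(network: Network, path: str | Path) -> None:
    """Write the alive subgraph as a plain two-column undirected edge list.

    A ``# n_nodes = N`` header records the node count so that trailing
    isolated nodes survive a round trip.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_NODES_COMMENT} {network.n_nodes}\n")
        for a, b in network.edges():
            fh.write(f"{a} {b}\n")


def read_edge_list(path: str | Path, dedupe: bool = False) -> Network:
    """Read a plain-text undirected edge list.

    Each non-comment line holds two whitespace-separated nonnegative
    integer node ids.  Lines starting with ``#`` are ignored, except for
    an optional ``# n_nodes = N`` header.  Self-loops are always an
    error.  Duplicate edges are an error in the default strict mode, or
    silently collapsed when ``dedupe=True``.
    """
    path = Path(path)
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    declared_n: int | None = None
    max_id = -1
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith(_NODES_COMMENT):
                    declared_n = int(line[len(_NODES_COMMENT) :])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {parts!r}")
            try:
                a, b = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node id") from exc
            if a < 0 or b < 0:
                raise ValueError(f"{path}:{lineno}: negative node id")
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop at node {a}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                if dedupe:
                    continue
                raise ValueError(f"{path}:{lineno}: duplicate edge ({a}, {b})")
            seen.add(key)
            edges.append(key)
            max_id = max(max_id, a, b)
    n_nodes = declared_n if declared_n is not None else max_id + 1
    if n_nodes < max_id + 1:
        raise ValueError(f"declared n_nodes {declared_n} smaller than max id {max_id}")
    if n_nodes < 1:
        raise ValueError("empty edge list with no node-count header")
    return Network.from_edges(n_nodes, edges)
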
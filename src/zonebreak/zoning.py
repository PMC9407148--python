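"""Inner/outer zone partitions of a network.

Three schemes are provided, mirroring how a tumour's hypoxic centre can be
distinguished from its well-oxygenated periphery in the network picture:

* ``k_sorted`` — rank nodes by degree and split at the median degree; the
  high-degree half is the inner zone.
* ``k_shell`` — peel the network by k-shell decomposition; the nucleus
  (the last, innermost shell) is the inner zone.
* ``random`` — a structure-blind half/half split, used as a negative
  control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "INNER",
    "OUTER",
    "TieRule",
    "ZoneAssignment",
    "ShellIndex",
    "zone_by_sorted_degree",
    "kshell_decomposition",
    "zone_by_kshell",
    "zone_random",
]

INNER = "inner"
OUTER = "outer"

TieRule = Literal["ties_inner", "ties_outer"]


@dataclass(frozen=True)
class ZoneAssignment:
    """A two-zone partition of the alive nodes.

    ``is_inner[v]`` is True when node v belongs to the inner zone.
    ``threshold_info`` records the median degree (k_sorted) or the
    nucleus shell index (k_shell).  ``degenerate`` flags the pathological
    case of a single-zone partition (e.g. a single-shell network).
    """

    is_inner: tuple[bool, ...]
    method: Literal["k_sorted", "k_shell", "random"]
    threshold_info: float | int | None = None
    tie_rule: TieRule | None = None
    degenerate: bool = False

    def zone_of(self, v: int) -> str:
        return INNER if self.is_inner[v] else OUTER

    def inner_nodes(self) -> list[int]:
        return [v for v, flag in enumerate(self.is_inner) if flag]

    def outer_nodes(self) -> list[int]:
        return [v for v, flag in enumerate(self.is_inner) if not flag]

    def inner_fraction(self, network: Network | None = None) -> float:
        """Fraction of (alive) nodes in the inner zone."""
        if network is None:
            return sum(self.is_inner) / len(self.is_inner)
        alive_inner = sum(
            1 for v, a in enumerate(network.alive) if a and self.is_inner[v]
        )
        n_alive = network.n_alive
        if n_alive == 0:
            raise ValueError("no alive nodes")
        return alive_inner / n_alive

    def to_frame(self, network: Network, shells: "ShellIndex | None" = None) -> pd.DataFrame:
        """Tabulate node_id, degree, shell and zone for CSV export."""
        records = []
        for v in range(network.n_nodes):
            if not network.alive[v]:
                continue
            records.append(
                {
                    "node_id": v,
                    "degree": network.degrees[v],
                    "shell": shells.shell_of[v] if shells is not None else pd.NA,
                    "zone": self.zone_of(v),
                }
            )
        return pd.DataFrame.from_records(
            records, columns=["node_id", "degree", "shell", "zone"]
        )


@dataclass(frozen=True)
class ShellIndex:
    """Per-node k-shell index: the peeling round each node was removed in.

    ``shell_of[v]`` equals the core number of v — the largest k such that
    v belongs to a subgraph of minimum degree ≥ k.  Entries of removed
    nodes are -1.
    """

    shell_of: tuple[int, ...]

    def max_shell(self) -> int:
        m = max(self.shell_of)
        if m < 0:
            raise ValueError("no alive nodes")
        return m


def _require_nonempty(network: Network) -> list[int]:
    alive = network.alive_nodes()
    if not alive:
        raise ValueError("network has no alive nodes")
    return alive


def zone_by_sorted_degree(
    network: Network, tie_rule: TieRule = "ties_inner"
) -> ZoneAssignment:
    """Median-degree split: high-degree nodes form the inner zone.

    The threshold is the lower median of the alive-node degree multiset.
    Nodes with degree strictly above it go inner and strictly below go
    outer; nodes exactly at the median go to the side named by
    ``tie_rule``.  Alternating the tie rule across realisations divides
    the nodes roughly equally between the zones on average.
    """
    if tie_rule not in ("ties_inner", "ties_outer"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    alive = _require_nonempty(network)
    degs = sorted(network.degrees[v] for v in alive)
    median = degs[(len(degs) - 1) // 2]  # lower median
    is_inner = [False] * network.n_nodes
    for v in alive:
        d = network.degrees[v]
        if d > median or (d == median and tie_rule == "ties_inner"):
            is_inner[v] = True
    return ZoneAssignment(
        is_inner=tuple(is_inner),
        method="k_sorted",
        threshold_info=median,
        tie_rule=tie_rule,
    )


def kshell_decomposition(network: Network) -> ShellIndex:
    """k-shell decomposition of the alive subgraph by recursive peeling.

    For k = 1, 2, ... all nodes of current degree ≤ k are repeatedly
    deleted until none remain; nodes deleted during round k form shell k.
    Isolated nodes are peeled before the k = 1 round and get shell 0.
    The resulting shell index of every node equals its core number.
    """
    _require_nonempty(network)
    n = network.n_nodes
    deg = list(network.degrees)
    remaining = [bool(a) for a in network.alive]
    shell = [-1] * n
    n_left = sum(remaining)
    adjacency = network.adjacency
    k = 0
    while n_left:
        stack = [v for v in range(n) if remaining[v] and deg[v] <= k]
        if not stack:
            k += 1
            continue
        # cascade: deletions may drag further nodes to degree <= k
        while stack:
            v = stack.pop()
            if not remaining[v]:
                continue
            remaining[v] = False
            shell[v] = k
            n_left -= 1
            for u in adjacency[v]:
                if remaining[u]:
                    deg[u] -= 1
                    if deg[u] <= k:
                        stack.append(u)
        k += 1
    return ShellIndex(shell_of=tuple(shell))


def zone_by_kshell(
    network: Network, shells: ShellIndex | None = None
) -> ZoneAssignment:
    """Nucleus split: the last (maximum) k-shell is the inner zone.

    All nodes whose shell index equals the maximum shell form the inner
    zone; every other shell is outer.  A single-shell network yields a
    degenerate all-inner partition, flagged and warned about.
    """
    _require_nonempty(network)
    if shells is None:
        shells = kshell_decomposition(network)
    nucleus = shells.max_shell()
    is_inner = [s == nucleus for s in shells.shell_of]
    degenerate = all(
        is_inner[v] for v in range(network.n_nodes) if network.alive[v]
    )
    if degenerate:
        warnings.warn(
            "single-shell network: k-shell zoning puts every node in the "
            "inner zone",
            stacklevel=2,
        )
    return ZoneAssignment(
        is_inner=tuple(is_inner),
        method="k_shell",
        threshold_info=nucleus,
        degenerate=degenerate,
    )


def zone_random(network: Network, seed: int | np.random.Generator) -> ZoneAssignment:
    """Structure-blind half/half partition (negative control).

    ⌊m/2⌋ of the m alive nodes are drawn uniformly at random into the
    inner zone; the same seed reproduces the same partition.
    """
    alive = _require_nonempty(network)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(alive))
    n_inner = len(alive) // 2
    is_inner = [False] * network.n_nodes
    for idx in order[:n_inner]:
        is_inner[alive[idx]] = True
    return ZoneAssignment(is_inner=tuple(is_inner), method="random")
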
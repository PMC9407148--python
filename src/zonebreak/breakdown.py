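"""Two-zone stochastic node removal to the κ = 2 breakdown point.

The process draws a node uniformly at random among the survivors.  A node
picked from the outer zone is removed outright (p_ext = 1); a node picked
from the inner zone is removed with the reduced probability (1−r)·p_ext
and otherwise survives the pick, staying eligible for future draws.  Every
removal deletes the node together with all of its links.  After each
successful removal the Molloy–Reed ratio κ = ⟨k²⟩/⟨k⟩ of the surviving
subgraph is updated incrementally; the process stops at the first crossing
of κ ≤ 2, the point where the spanning cluster ceases to exist.

The reduction rate r plays the role of the centre-vs-periphery difference
in kill probability: r = 0 is spatially uniform therapy, r → 1 a fully
protected inner zone.  r = 1 is rejected outright because the inner zone
then can never be depleted and the breakdown point need not be reachable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Network, cluster_sizes, generate_er
from .zoning import (
    ZoneAssignment,
    kshell_decomposition,
    zone_by_kshell,
    zone_by_sorted_degree,
    zone_random,
)

__all__ = [
    "RemovalConfig",
    "Trajectory",
    "BreakdownResult",
    "EnsembleSummary",
    "run_breakdown",
    "run_ensemble",
    "ZONING_METHODS",
]

logger = logging.getLogger(__name__)

ZONING_METHODS = ("k_sorted", "k_shell", "random")

_RNG_BLOCK = 1 << 14


@dataclass(frozen=True)
class RemovalConfig:
    """Parameters of one removal run.

    Attributes
    ----------
    r:
        Reduction rate of the inner-zone removal probability, in [0, 1).
        The inner-zone probability is ``(1 - r) * p_ext``.
    seed:
        Seed for the removal randomness (node draws and inner-zone coins).
    p_ext:
        Outer-zone removal probability; the model fixes it at 1.
    kappa_stop:
        Breakdown threshold on κ; the model fixes it at 2.
    record_trajectory:
        If True, record (f, S, κ) after every successful removal.
    f_stop:
        Optional removed fraction up to which removal continues even after
        the κ crossing, so that late-time trajectories are available.
    max_attempts:
        Safety cap on the number of draws (defaults to 1000·N).
    """

    r: float
    seed: int | np.random.SeedSequence
    p_ext: float = 1.0
    kappa_stop: float = 2.0
    record_trajectory: bool = False
    f_stop: float | None = None
    max_attempts: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r < 1.0:
            raise ValueError(
                f"r must lie in [0, 1); got {self.r} (r = 1 makes the inner "
                "zone irremovable and the process need not terminate)"
            )
        if not 0.0 < self.p_ext <= 1.0:
            raise ValueError(f"p_ext must lie in (0, 1]; got {self.p_ext}")
        if self.kappa_stop <= 0:
            raise ValueError("kappa_stop must be positive")
        if self.f_stop is not None and not 0.0 <= self.f_stop < 1.0:
            raise ValueError(f"f_stop must lie in [0, 1); got {self.f_stop}")


@dataclass(frozen=True)
class Trajectory:
    """(f, S, κ) after each successful removal, in removal order.

    ``f[t]`` increases by exactly 1/N per removal; ``S`` is the largest
    cluster over the surviving node count; ``kappa`` is NaN once no alive
    edge remains.
    """

    f: np.ndarray
    S: np.ndarray
    kappa: np.ndarray

    def s_at(self, f_value: float, n_nodes: int) -> float:
        """S after ``round(f_value * N)`` removals (NaN if not reached)."""
        step = int(round(f_value * n_nodes))
        if step <= 0 or step > self.f.size:
            return float("nan")
        return float(self.S[step - 1])


@dataclass(frozen=True)
class BreakdownResult:
    """Outcome of one removal run.

    ``n_removed``, ``f_c`` and ``final_cluster_sizes`` describe the state
    at the breakdown crossing (first removal with κ ≤ kappa_stop), even
    when ``f_stop`` made the run continue past it; ``removal_order`` and
    ``trajectory`` cover the full run.
    """

    n_nodes: int
    removal_order: tuple[int, ...]
    n_removed: int
    f_c: float
    final_cluster_sizes: tuple[int, ...]
    kappa_final: float
    terminated: bool
    trajectory: Trajectory | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.final_cluster_sizes)

    @property
    def largest_cluster(self) -> int:
        return self.final_cluster_sizes[0] if self.final_cluster_sizes else 0


class NonTerminationError(RuntimeError):
    """The draw loop hit its safety cap before reaching the stop state."""


def _kappa_sums(network: Network) -> tuple[int, int]:
    degs = network.alive_degrees()
    return int(degs.sum()), int((degs**2).sum())


def _largest_cluster_history(
    network: Network, order: Sequence[int]
) -> np.ndarray:
    """Largest-cluster size after each removal step, via reverse union-find.

    Starting from the final alive set, removed nodes are re-activated in
    reverse removal order while a disjoint-set forest tracks component
    sizes; sizes only merge during the replay, so the running maximum at
    reverse step t is the largest cluster of the forward state after t
    removals.
    """
    n = network.n_nodes
    parent = list(range(n))
    size = [1] * n
    active = list(network.alive)
    adjacency = network.adjacency

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]  # path halving
            v = parent[v]
        return v

    def union(a: int, b: int) -> int:
        ra, rb = find(a), find(b)
        if ra == rb:
            return size[ra]
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        parent[rb] = ra
        size[ra] += size[rb]
        return size[ra]

    largest = 1 if any(active) else 0
    for v in range(n):
        if active[v]:
            for u in adjacency[v]:
                if u > v and active[u]:
                    largest = max(largest, union(v, u))

    history = np.empty(len(order), dtype=np.int64)
    for t in range(len(order) - 1, -1, -1):
        history[t] = largest
        v = order[t]
        active[v] = True
        largest = max(largest, 1)
        for u in adjacency[v]:
            if active[u]:
                largest = max(largest, union(v, u))
    return history


def run_breakdown(
    network: Network, zones: ZoneAssignment, config: RemovalConfig
) -> BreakdownResult:
    """Run the two-zone removal process on ``network`` (mutated in place).

    Returns an already-broken result (``n_removed = 0``) when the initial
    κ is at or below the threshold.  Raises :class:`NonTerminationError`
    if ``max_attempts`` draws do not reach the stop state.
    """
    n = network.n_nodes
    sum_k, sum_k2 = _kappa_sums(network)
    kappa_now = sum_k2 / sum_k if sum_k > 0 else float("nan")
    if sum_k == 0 or kappa_now <= config.kappa_stop:
        return BreakdownResult(
            n_nodes=n,
            removal_order=(),
            n_removed=0,
            f_c=0.0,
            final_cluster_sizes=tuple(cluster_sizes(network)),
            kappa_final=kappa_now,
            terminated=True,
            trajectory=Trajectory(
                f=np.empty(0), S=np.empty(0), kappa=np.empty(0)
            )
            if config.record_trajectory
            else None,
        )

    rng = np.random.default_rng(config.seed)
    max_attempts = config.max_attempts or 1000 * n
    r = config.r
    p_inner = (1.0 - r) * config.p_ext
    p_outer = config.p_ext
    needs_coin = p_inner < 1.0 or p_outer < 1.0

    alive = network.alive
    degrees = network.degrees
    adjacency = network.adjacency
    is_inner = zones.is_inner

    alive_list = network.alive_nodes()
    n_alive = len(alive_list)
    pos = [-1] * n
    for i, v in enumerate(alive_list):
        pos[v] = i

    removal_order: list[int] = []
    kappa_trace: list[float] = [] if config.record_trajectory else None  # type: ignore[assignment]

    crossed = False
    n_removed_at_cross = 0
    kappa_at_cross = kappa_now
    sizes_at_cross: tuple[int, ...] = ()
    f_stop_steps = (
        int(round(config.f_stop * n)) if config.f_stop is not None else 0
    )

    # block-refilled uniforms: one per draw for the index, one per coin
    u_block = rng.random(_RNG_BLOCK)
    u_i = 0
    attempts = 0
    while True:
        attempts += 1
        if attempts > max_attempts:
            raise NonTerminationError(
                f"no stop state after {max_attempts} draws "
                f"(r={r}, {n_alive} nodes alive, kappa={kappa_now:.3f})"
            )
        if u_i >= _RNG_BLOCK - 1:
            u_block = rng.random(_RNG_BLOCK)
            u_i = 0
        v = alive_list[int(u_block[u_i] * n_alive)]
        u_i += 1
        if needs_coin:
            p_remove = p_inner if is_inner[v] else p_outer
            if p_remove < 1.0:
                if u_block[u_i] >= p_remove:
                    u_i += 1
                    continue  # the pick failed; the node stays eligible
                u_i += 1

        # successful removal: drop v and its links, update moment sums
        d = degrees[v]
        sum_k -= 2 * d
        sum_k2 -= d * d
        for u in adjacency[v]:
            if alive[u]:
                ku = degrees[u]
                sum_k2 -= 2 * ku - 1
                degrees[u] = ku - 1
        degrees[v] = 0
        alive[v] = False
        i = pos[v]
        last = alive_list[n_alive - 1]
        alive_list[i] = last
        pos[last] = i
        n_alive -= 1
        removal_order.append(v)

        kappa_now = sum_k2 / sum_k if sum_k > 0 else float("nan")
        if kappa_trace is not None:
            kappa_trace.append(kappa_now)
        if not crossed and (sum_k == 0 or kappa_now <= config.kappa_stop):
            crossed = True
            n_removed_at_cross = len(removal_order)
            kappa_at_cross = kappa_now
            sizes_at_cross = tuple(cluster_sizes(network))
        if crossed and len(removal_order) >= f_stop_steps:
            break
        if n_alive == 0:
            break

    trajectory = None
    if config.record_trajectory:
        history = _largest_cluster_history(network, removal_order)
        steps = np.arange(1, len(removal_order) + 1)
        trajectory = Trajectory(
            f=steps / n,
            S=history / (n - steps),
            kappa=np.asarray(kappa_trace, dtype=float),
        )

    return BreakdownResult(
        n_nodes=n,
        removal_order=tuple(removal_order),
        n_removed=n_removed_at_cross,
        f_c=n_removed_at_cross / n,
        final_cluster_sizes=sizes_at_cross,
        kappa_final=kappa_at_cross,
        terminated=crossed,
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-replicate records and per-r aggregates of an ensemble.

    Attributes
    ----------
    runs:
        One row per replicate: replicate, r, model, n_removed, f_c,
        n_clusters, largest_cluster, kappa_final, inner_fraction, seed,
        n_nodes, mean_degree.
    per_r:
        Mean and standard error of the mean (SEM) of n_clusters and f_c
        per r, plus the cluster count normalised by its r = 0 mean when
        r = 0 is part of the grid.
    curves:
        Ensemble-mean S on the fixed f grid, per r (empty when
        trajectories were not recorded).
    cluster_sizes:
        r → list (one entry per replicate) of final cluster-size tuples
        at the breakdown crossing.
    trajectories:
        (r, replicate) → :class:`Trajectory`, kept only when requested
        via ``keep_trajectories``.
    """

    runs: pd.DataFrame
    per_r: pd.DataFrame
    curves: pd.DataFrame
    cluster_sizes: dict[float, list[tuple[int, ...]]] = field(repr=False, default_factory=dict)
    trajectories: dict[tuple[float, int], Trajectory] = field(repr=False, default_factory=dict)


DEFAULT_F_GRID = tuple(np.round(np.arange(1, 20) * 0.05, 2))


def _zone_for(
    method: str,
    network: Network,
    replicate: int,
    zone_seed: np.random.SeedSequence,
) -> ZoneAssignment:
    if method == "k_sorted":
        tie = "ties_inner" if replicate % 2 == 0 else "ties_outer"
        return zone_by_sorted_degree(network, tie_rule=tie)
    if method == "k_shell":
        return zone_by_kshell(network, kshell_decomposition(network))
    if method == "random":
        return zone_random(network, np.random.default_rng(zone_seed))
    raise ValueError(f"unknown zoning method {method!r}; expected one of {ZONING_METHODS}")


def run_ensemble(
    n_nodes: int,
    mean_degree: float,
    zoning_method: str,
    r_values: Sequence[float],
    n_reps: int,
    master_seed: int,
    *,
    record_trajectory: bool = False,
    f_stop: float | None = None,
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    keep_trajectories: bool = False,
) -> EnsembleSummary:
    """Run ``n_reps`` seeded replicates for every r in ``r_values``.

    Each replicate draws a fresh ER network, zones it (k_sorted tie rule
    alternating with replicate parity) and runs the removal process.  All
    randomness derives from ``master_seed``, so identical arguments give
    bitwise-identical summaries.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if zoning_method not in ZONING_METHODS:
        raise ValueError(
            f"unknown zoning method {zoning_method!r}; expected one of {ZONING_METHODS}"
        )
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(len(r_values) * n_reps)

    records = []
    curve_rows = []
    sizes_by_r: dict[float, list[tuple[int, ...]]] = {float(r): [] for r in r_values}
    trajectories: dict[tuple[float, int], Trajectory] = {}
    record_trajectory = record_trajectory or keep_trajectories
    for ri, r in enumerate(r_values):
        for rep in range(n_reps):
            child = children[ri * n_reps + rep]
            gen_ss, removal_ss, zone_ss = child.spawn(3)
            gen_seed = int(gen_ss.generate_state(1)[0] % (2**31))
            network = generate_er(n_nodes, mean_degree, seed=gen_seed)
            zones = _zone_for(zoning_method, network, rep, zone_ss)
            config = RemovalConfig(
                r=float(r),
                seed=removal_ss,
                record_trajectory=record_trajectory,
                f_stop=f_stop,
            )
            try:
                result = run_breakdown(network, zones, config)
            except NonTerminationError as exc:
                raise NonTerminationError(
                    f"replicate {rep} (r={r}, method={zoning_method}): {exc}"
                ) from exc
            logger.info(
                "r=%.2f rep=%d: f_c=%.4f clusters=%d",
                r,
                rep,
                result.f_c,
                result.n_clusters,
            )
            records.append(
                {
                    "replicate": rep,
                    "r": float(r),
                    "model": zoning_method,
                    "n_removed": result.n_removed,
                    "f_c": result.f_c,
                    "n_clusters": result.n_clusters,
                    "largest_cluster": result.largest_cluster,
                    "kappa_final": result.kappa_final,
                    "inner_fraction": zones.inner_fraction(),
                    "seed": gen_seed,
                    "n_nodes": n_nodes,
                    "mean_degree": mean_degree,
                }
            )
            sizes_by_r[float(r)].append(result.final_cluster_sizes)
            if keep_trajectories and result.trajectory is not None:
                trajectories[(float(r), rep)] = result.trajectory
            if record_trajectory and result.trajectory is not None:
                for f_value in f_grid:
                    curve_rows.append(
                        {
                            "replicate": rep,
                            "r": float(r),
                            "model": zoning_method,
                            "f": float(f_value),
                            "S": result.trajectory.s_at(float(f_value), n_nodes),
                        }
                    )

    runs = pd.DataFrame.from_records(records)
    per_r = (
        runs.groupby("r", as_index=False)
        .agg(
            n_reps=("replicate", "size"),
            n_clusters_mean=("n_clusters", "mean"),
            n_clusters_sem=("n_clusters", "sem"),
            f_c_mean=("f_c", "mean"),
            f_c_sem=("f_c", "sem"),
            inner_fraction_mean=("inner_fraction", "mean"),
        )
        .sort_values("r", ignore_index=True)
    )
    if (per_r["r"] == 0.0).any():
        ref = per_r.loc[per_r["r"] == 0.0, "n_clusters_mean"].iloc[0]
        per_r["n_clusters_norm"] = per_r["n_clusters_mean"] / ref
    else:
        per_r["n_clusters_norm"] = np.nan

    if curve_rows:
        curve_df = pd.DataFrame.from_records(curve_rows)
        curves = (
            curve_df.groupby(["model", "r", "f"], as_index=False)
            .agg(S_mean=("S", "mean"), S_sem=("S", "sem"), n=("S", "size"))
            .sort_values(["model", "r", "f"], ignore_index=True)
        )
    else:
        curves = pd.DataFrame(columns=["model", "r", "f", "S_mean", "S_sem", "n"])

    return EnsembleSummary(
        runs=runs,
        per_r=per_r,
        curves=curves,
        cluster_sizes=sizes_by_r,
        trajectories=trajectories,
    )
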
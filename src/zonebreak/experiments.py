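"""Experiment orchestration: configs, figure-style sweeps, summaries.

The canonical study conditions are ER networks with N = 10,000 and
⟨k⟩ = 20, an r grid of {0, 0.1, ..., 0.8}, and ensembles of seeded
replicates; :func:`reproduce_figure` regenerates the data tables behind
the standard observables (cluster counts vs r, removed fraction vs r,
cluster-size distributions, simulated-vs-analytic S(f), and S(f)
trajectories), each fully determined by the master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .analytics import aggregate_cluster_distribution, analytic_largest_cluster
from .breakdown import ZONING_METHODS, EnsembleSummary, run_ensemble

__all__ = [
    "ExperimentConfig",
    "DEFAULT_R_GRID",
    "FIGURE_IDS",
    "reproduce_figure",
    "summarize",
]

logger = logging.getLogger(__name__)

DEFAULT_R_GRID = tuple(np.round(np.arange(0, 9) * 0.1, 1))
FIGURE_IDS = ("fig2", "fig3", "fig4", "fig5", "fig6")

RUNS_COLUMNS = [
    "replicate",
    "r",
    "model",
    "n_removed",
    "f_c",
    "n_clusters",
    "largest_cluster",
    "kappa_final",
    "seed",
    "n_nodes",
    "mean_degree",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one ensemble experiment.

    Serialises losslessly to and from YAML.  ``zoning_method`` may be any
    of ``k_sorted``, ``k_shell`` or ``random``; figures that compare the
    two structural zonings ignore it and run both.
    """

    n_nodes: int = 10_000
    mean_degree: float = 20.0
    zoning_method: str = "k_sorted"
    r_values: tuple[float, ...] = DEFAULT_R_GRID
    n_reps: int = 100
    master_seed: int = 0
    output_dir: str = "."
    trajectory_stride: int = 1
    fit_min_count: int = 5

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.zoning_method not in ZONING_METHODS:
            raise ValueError(
                f"unknown zoning_method {self.zoning_method!r}; "
                f"expected one of {ZONING_METHODS}"
            )
        if any(not 0.0 <= r < 1.0 for r in self.r_values):
            raise ValueError("every r must lie in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["r_values"] = [float(r) for r in self.r_values]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["r_values"] = tuple(float(r) for r in data["r_values"])
        return cls(**data)


def _seed_for(master_seed: int, label: str) -> int:
    """Stable per-purpose child seed below 2**31."""
    entropy = [master_seed] + [ord(c) for c in label]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _both_models(
    config: ExperimentConfig,
    r_values: Sequence[float],
    **kwargs,
) -> dict[str, EnsembleSummary]:
    out = {}
    for method in ("k_sorted", "k_shell"):
        out[method] = run_ensemble(
            config.n_nodes,
            config.mean_degree,
            method,
            r_values,
            config.n_reps,
            _seed_for(config.master_seed, method),
            **kwargs,
        )
    return out


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    df.to_csv(path, index=False)
    logger.info("wrote %s (%d rows)", path, len(df))
    return path


def _plot_xy(df, x, y, by, path, xlabel, ylabel) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for key, grp in df.groupby(by):
        ax.plot(grp[x], grp[y], "o-", label=str(key))
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def reproduce_figure(
    figure_id: str, config: ExperimentConfig, plot: bool = False
) -> pd.DataFrame:
    """Recompute the data table behind one of the standard observables.

    figure ids:
      * ``fig2`` — normalised number of clusters at breakdown vs r.
      * ``fig3`` — removed fraction f_c at breakdown vs r.
      * ``fig4`` — pooled cluster-size distributions at r = 0 and 0.8.
      * ``fig5`` — simulated vs analytic S(f) at r = 0.
      * ``fig6`` — S(f) trajectories at r = 0 and r = 0.8.

    Writes ``<figure_id>.csv`` (and ``<figure_id>.png`` when ``plot``)
    under ``config.output_dir`` and returns the table.
    """
    if figure_id not in FIGURE_IDS:
        raise ValueError(f"unknown figure id {figure_id!r}; expected one of {FIGURE_IDS}")
    out_dir = Path(config.output_dir)

    if figure_id in ("fig2", "fig3"):
        summaries = _both_models(config, config.r_values)
        frames = []
        for method, summary in summaries.items():
            per_r = summary.per_r.copy()
            per_r.insert(0, "model", method)
            frames.append(per_r)
        table = pd.concat(frames, ignore_index=True)
        if figure_id == "fig2":
            cols = ["model", "r", "n_clusters_mean", "n_clusters_sem", "n_clusters_norm"]
            ylab = "normalised cluster count"
            ycol = "n_clusters_norm"
        else:
            cols = ["model", "r", "f_c_mean", "f_c_sem"]
            ylab = "removed fraction f_c"
            ycol = "f_c_mean"
        table = table[cols]
        _write(table, out_dir, f"{figure_id}.csv")
        if plot:
            _plot_xy(table, "r", ycol, "model", out_dir / f"{figure_id}.png", "r", ylab)
        return table

    if figure_id == "fig4":
        summaries = _both_models(config, (0.0, 0.8))
        rows = []
        for method, summary in summaries.items():
            for r, size_lists in summary.cluster_sizes.items():
                dist = aggregate_cluster_distribution(size_lists)
                for s, c in zip(dist.sizes, dist.counts):
                    rows.append(
                        {
                            "model": method,
                            "r": r,
                            "size": s,
                            "count": c,
                            "n_realizations": dist.n_realizations,
                        }
                    )
        table = pd.DataFrame.from_records(rows)
        _write(table, out_dir, "fig4.csv")
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            for (method, r), grp in table.groupby(["model", "r"]):
                ax.loglog(grp["size"], grp["count"], "o", ms=3, label=f"{method}, r={r}")
            ax.set_xlabel("cluster size s")
            ax.set_ylabel("count n(s)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out_dir / "fig4.png", dpi=150)
            plt.close(fig)
        return table

    if figure_id == "fig5":
        summary = run_ensemble(
            config.n_nodes,
            config.mean_degree,
            "k_shell",
            (0.0,),
            config.n_reps,
            _seed_for(config.master_seed, "fig5"),
            record_trajectory=True,
            f_stop=0.95,
        )
        curves = summary.curves
        rows = []
        for _, row in curves.iterrows():
            rows.append(
                {
                    "f": row["f"],
                    "S_sim_mean": row["S_mean"],
                    "S_sim_sem": row["S_sem"],
                    "S_analytic": analytic_largest_cluster(config.mean_degree, row["f"]),
                }
            )
        table = pd.DataFrame.from_records(rows).sort_values("f", ignore_index=True)
        _write(table, out_dir, "fig5.csv")
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            ax.plot(table["f"], table["S_analytic"], "-", label="analytic")
            ax.plot(table["f"], table["S_sim_mean"], "o", ms=4, label="simulation")
            ax.set_xlabel("removed fraction f")
            ax.set_ylabel("largest cluster S")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out_dir / "fig5.png", dpi=150)
            plt.close(fig)
        return table

    # fig6: S(f) trajectories for r = 0 (models coincide) and r = 0.8
    summaries = _both_models(
        config, (0.0, 0.8), record_trajectory=True, f_stop=0.95
    )
    frames = []
    for method, summary in summaries.items():
        curves = summary.curves.copy()
        frames.append(curves)
    table = pd.concat(frames, ignore_index=True)[
        ["model", "r", "f", "S_mean", "S_sem"]
    ]
    _write(table, out_dir, "fig6.csv")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for (method, r), grp in table.groupby(["model", "r"]):
            ax.plot(grp["f"], grp["S_mean"], "o-", ms=3, label=f"{method}, r={r}")
        ax.set_xlabel("removed fraction f")
        ax.set_ylabel("largest cluster S")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "fig6.png", dpi=150)
        plt.close(fig)
    return table


def summarize(runs: Iterable[pd.DataFrame | str | Path]) -> pd.DataFrame:
    """Aggregate per-replicate run tables into per-(model, r) statistics.

    All inputs must come from the same study conditions (one N and one
    ⟨k⟩).  Means and SEMs are reported per (model, r); the cluster count
    is additionally normalised by the same model's r = 0 mean when an
    r = 0 arm is present.  A single replicate yields an NaN SEM.
    """
    frames = []
    for item in runs:
        df = item if isinstance(item, pd.DataFrame) else pd.read_csv(item)
        missing = set(RUNS_COLUMNS) - {"seed", "n_nodes", "mean_degree"} - set(df.columns)
        if missing:
            raise ValueError(f"run table is missing columns {sorted(missing)}")
        frames.append(df)
    if not frames:
        raise ValueError("no run tables given")
    runs_df = pd.concat(frames, ignore_index=True)
    for col in ("n_nodes", "mean_degree"):
        if col in runs_df.columns and runs_df[col].nunique() > 1:
            raise ValueError(
                f"incompatible run tables: multiple values of {col}: "
                f"{sorted(runs_df[col].unique())}"
            )
    summary = (
        runs_df.groupby(["model", "r"], as_index=False)
        .agg(
            n_reps=("f_c", "size"),
            f_c_mean=("f_c", "mean"),
            f_c_sem=("f_c", "sem"),
            n_clusters_mean=("n_clusters", "mean"),
            n_clusters_sem=("n_clusters", "sem"),
        )
        .sort_values(["model", "r"], ignore_index=True)
    )
    norm = []
    for _, row in summary.iterrows():
        ref_rows = summary[(summary["model"] == row["model"]) & (summary["r"] == 0.0)]
        norm.append(
            row["n_clusters_mean"] / ref_rows["n_clusters_mean"].iloc[0]
            if len(ref_rows)
            else np.nan
        )
    summary["n_clusters_norm"] = norm
    return summary
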
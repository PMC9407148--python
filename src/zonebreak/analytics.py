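"""Generating-function analytics and cluster-size statistics.

For uniform removal (no zones) the relative size of the largest cluster
has a closed form.  With G0 the probability generating function of the
degree distribution and G1 that of the excess degree,

    S = 1 - G0(u),      u = G1(u)  (smallest nonnegative root),

    G0(x) = Σ_k P(k) x^k,      G1(x) = G0'(x) / ⟨k⟩.

Removing a fraction f of the nodes of an ER network uniformly at random
leaves another ER network whose degree distribution is Poisson with mean
⟨k⟩(1 - f); evaluating S on that residual distribution gives the largest
cluster normalised per *surviving* node, the same normalisation the
simulator reports.

The module also pools cluster-size histograms at the breakdown point and
fits their power-law exponent by ordinary least squares in log-log space,
mirroring the straight-line fits conventional for near-critical cluster
statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .breakdown import BreakdownResult
from .network import DegreeDistribution

__all__ = [
    "GeneratingFunctionModel",
    "ClusterSizeDistribution",
    "PowerLawFit",
    "InsufficientDataError",
    "g0",
    "g1",
    "solve_u",
    "analytic_largest_cluster",
    "aggregate_cluster_distribution",
    "fit_power_law",
]

_U_TOL = 1e-12


def _as_arrays(dist: DegreeDistribution) -> tuple[np.ndarray, np.ndarray]:
    ks = np.fromiter(dist.probabilities.keys(), dtype=np.int64)
    ps = np.fromiter(dist.probabilities.values(), dtype=float)
    return ks, ps


def g0(x: float, dist: DegreeDistribution) -> float:
    """Degree generating function G0(x) = Σ P(k) x^k for x in [0, 1]."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1]; got {x}")
    ks, ps = _as_arrays(dist)
    return float(np.sum(ps * np.power(float(x), ks)))


def g1(x: float, dist: DegreeDistribution) -> float:
    """Excess-degree generating function G1(x) = G0'(x) / ⟨k⟩."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1]; got {x}")
    if dist.mean <= 0:
        raise ValueError("G1 requires a positive mean degree")
    ks, ps = _as_arrays(dist)
    mask = ks >= 1
    ks, ps = ks[mask], ps[mask]
    return float(np.sum(ks * ps * np.power(float(x), ks - 1)) / dist.mean)


def solve_u(dist: DegreeDistribution) -> float:
    """Smallest nonnegative root of u = G1(u) on [0, 1].

    u is the probability that following a random edge leads to a finite
    branch.  Subcritical distributions have no interior root and return
    u = 1 (no giant component).  The interior root, when present, is
    bracketed on [0, 1 - ε] and polished with Brent's method.
    """
    def h(u: float) -> float:
        return u - g1(u, dist)

    h0 = h(0.0)
    if h0 >= 0.0:
        # h(0) = -P(1)/<k> <= 0 always; equality means u = 0 is the root
        return 0.0
    upper = 1.0 - 1e-9
    if h(upper) <= 0.0:
        return 1.0  # no interior root: only the trivial fixed point u = 1
    return float(optimize.brentq(h, 0.0, upper, xtol=_U_TOL, rtol=8.9e-16))


@dataclass(frozen=True)
class GeneratingFunctionModel:
    """A degree distribution together with its solved fixed point u."""

    degree_dist: DegreeDistribution
    u: float

    @classmethod
    def from_distribution(cls, dist: DegreeDistribution) -> "GeneratingFunctionModel":
        return cls(degree_dist=dist, u=solve_u(dist))

    @property
    def mean_degree(self) -> float:
        return self.degree_dist.mean

    def largest_cluster(self) -> float:
        """Relative giant-component size S = 1 - G0(u)."""
        return 1.0 - g0(self.u, self.degree_dist)


def analytic_largest_cluster(mean_degree: float, f: float) -> float:
    """Closed-form S after uniform random removal of a fraction f.

    The residual network of an ER graph under uniform removal is again
    ER, with Poisson degree distribution of mean ⟨k⟩(1 - f); S is
    normalised to the surviving node count.  Returns 0 at and below the
    critical point ⟨k⟩(1 - f) = 1 (i.e. for f ≥ 1 - 1/⟨k⟩).
    """
    if mean_degree <= 0:
        raise ValueError("mean_degree must be positive")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1]; got {f}")
    effective_mean = mean_degree * (1.0 - f)
    if effective_mean <= 1.0:
        return 0.0
    model = GeneratingFunctionModel.from_distribution(
        DegreeDistribution.poisson(effective_mean)
    )
    return model.largest_cluster()


# ---------------------------------------------------------------------------
# Cluster-size distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """Pooled histogram of cluster sizes over an ensemble at breakdown."""

    sizes: tuple[int, ...]
    counts: tuple[int, ...]
    n_realizations: int

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes) or any(c < 1 for c in self.counts):
            raise ValueError("sizes and counts must be positive")
        if len(self.sizes) != len(self.counts):
            raise ValueError("sizes and counts must be parallel")

    def total_nodes(self) -> int:
        """Σ s·n(s): alive nodes summed over all pooled realisations."""
        return sum(s * c for s, c in zip(self.sizes, self.counts))

    def samples(self) -> np.ndarray:
        """Expand the histogram back into one size sample per cluster."""
        return np.repeat(self.sizes, self.counts)


def aggregate_cluster_distribution(
    results: Iterable[BreakdownResult | Sequence[int]],
    drop_largest: bool = False,
) -> ClusterSizeDistribution:
    """Pool final cluster sizes of many runs into one histogram.

    Accepts either :class:`BreakdownResult` objects (all of which must
    have terminated) or bare cluster-size sequences.  With
    ``drop_largest`` each realisation's largest cluster — the remnant of
    the main body, whose size scales differently from the broken-off
    fragments at the critical point — is left out, so the histogram
    describes the fragment-size distribution proper.
    """
    counter: Counter[int] = Counter()
    n_real = 0
    for item in results:
        if isinstance(item, BreakdownResult):
            if not item.terminated:
                raise ValueError("cannot pool a run that did not terminate")
            sizes = item.final_cluster_sizes
        else:
            sizes = tuple(item)
        if drop_largest and sizes:
            sizes = list(sizes)
            sizes.remove(max(sizes))  # one largest cluster per realisation
        counter.update(sizes)
        n_real += 1
    if n_real == 0:
        raise ValueError("no results to aggregate")
    pairs = sorted(counter.items())
    return ClusterSizeDistribution(
        sizes=tuple(s for s, _ in pairs),
        counts=tuple(c for _, c in pairs),
        n_realizations=n_real,
    )


# ---------------------------------------------------------------------------
# Power-law fits
# ---------------------------------------------------------------------------


class InsufficientDataError(ValueError):
    """Fewer than three qualifying (size, count) points for the fit."""


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10 n(s) on log10 s; ``slope`` is the exponent."""

    slope: float
    intercept: float
    fit_range: tuple[int, int]
    n_points: int
    r_squared: float


def fit_power_law(
    dist: ClusterSizeDistribution,
    min_count: int = 5,
    min_size: int = 2,
    size_range: tuple[int, int] | None = None,
) -> PowerLawFit:
    """Fit the power-law exponent of a cluster-size histogram.

    Ordinary least squares of log10 counts on log10 sizes, restricted to
    sizes ≥ ``min_size`` with pooled count ≥ ``min_count`` (and inside
    ``size_range`` when given).  The singleton bin and sparsely populated
    large-size bins are thereby excluded, where finite-size effects bend
    the distribution away from the critical power law.
    """
    sizes = np.asarray(dist.sizes, dtype=float)
    counts = np.asarray(dist.counts, dtype=float)
    mask = (sizes >= min_size) & (counts >= min_count)
    if size_range is not None:
        mask &= (sizes >= size_range[0]) & (sizes <= size_range[1])
    sizes, counts = sizes[mask], counts[mask]
    if sizes.size < 3:
        raise InsufficientDataError(
            f"only {sizes.size} qualifying points (need >= 3); relax "
            "min_count/min_size or pool more realisations"
        )
    fit = stats.linregress(np.log10(sizes), np.log10(counts))
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_range=(int(sizes.min()), int(sizes.max())),
        n_points=int(sizes.size),
        r_squared=float(fit.rvalue**2),
    )
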
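"""Adjacency spectra, kernel-smoothed spectral densities, and divergences.

A graph's signature here is the distribution of its adjacency eigenvalues:
the full (exact) spectrum is smoothed with a Gaussian kernel at the Silverman
plug-in bandwidth and evaluated on a grid shared by every graph in a
comparison, so that Kullback-Leibler and Jensen-Shannon divergences between
graphs are well defined.  Divergences are reported in nats by default
(``base=2`` gives bits); the JS *distance* is the square root of the JS
divergence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import rel_entr

__all__ = [
    "SpectralDensity",
    "DiscreteDistribution",
    "adjacency_spectrum",
    "silverman_bandwidth",
    "shared_grid",
    "spectral_density",
    "density_matrix",
    "mean_density",
    "density_to_masses",
    "kl_divergence",
    "js_divergence",
    "js_distance",
]

#: Bandwidth used when every eigenvalue coincides and the plug-in rule is zero.
FALLBACK_BANDWIDTH = 1e-3

#: Probability floor applied to gridded densities before log-ratio divergences.
DENSITY_FLOOR = 1e-12

DEFAULT_GRID_POINTS = 512


@dataclass
class SpectralDensity:
    """A normalized, discretized eigenvalue density on a shared grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_eigenvalues: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have the same length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        area = np.trapezoid(self.density, self.grid)
        if not math.isclose(area, 1.0, abs_tol=1e-9):
            raise ValueError(f"density integrates to {area}, not 1")


@dataclass
class DiscreteDistribution:
    """A probability mass function on an ordered support."""

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.support) != len(self.probabilities):
            raise ValueError("support and probabilities must have the same length")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


def _as_nx(graph) -> nx.Graph:
    return graph.graph if hasattr(graph, "graph") and isinstance(
        getattr(graph, "graph"), nx.Graph
    ) else graph


def adjacency_spectrum(graph, scale: bool = False) -> np.ndarray:
    """Exact adjacency spectrum, ascending.

    ``scale=True`` divides eigenvalues by sqrt(n); off by default since graphs
    in one comparison are of comparable size and no normalization is assumed.
    """
    g = _as_nx(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph has no spectrum")
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    eig = np.linalg.eigvalsh(a)
    if scale:
        eig = eig / math.sqrt(n)
    return np.sort(eig)


def silverman_bandwidth(values) -> float:
    """Silverman's plug-in bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    The minimum is taken over the positive candidates (the convention of R's
    ``bw.nrd0``), so a zero IQR with positive spread still yields a usable
    bandwidth.  A constant vector falls back to :data:`FALLBACK_BANDWIDTH`
    with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a bandwidth")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    candidates = [c for c in (sd, iqr / 1.34) if c > 0]
    if not candidates:
        warnings.warn(
            f"all values identical; falling back to bandwidth {FALLBACK_BANDWIDTH}"
        )
        return FALLBACK_BANDWIDTH
    return 0.9 * min(candidates) * x.size ** (-1 / 5)


def shared_grid(
    eigenvalue_sets, n_points: int = DEFAULT_GRID_POINTS, pad: float = 3.0
) -> np.ndarray:
    """Common evaluation grid spanning the pooled eigenvalue range.

    The grid covers [min - pad*h_max, max + pad*h_max] where h_max is the
    largest per-graph Silverman bandwidth, so every graph's kernel mass is
    essentially inside the grid.
    """
    eigenvalue_sets = [np.asarray(e, dtype=float) for e in eigenvalue_sets]
    if not eigenvalue_sets:
        raise ValueError("no eigenvalue sets given")
    lo = min(e.min() for e in eigenvalue_sets)
    hi = max(e.max() for e in eigenvalue_sets)
    hmax = max(silverman_bandwidth(e) if e.size > 1 else FALLBACK_BANDWIDTH
               for e in eigenvalue_sets)
    return np.linspace(lo - pad * hmax, hi + pad * hmax, n_points)


def spectral_density(eigenvalues, grid, bandwidth: float | None = None) -> SpectralDensity:
    """Gaussian KDE of the eigenvalues on ``grid``, renormalized to area 1.

    ``bandwidth`` defaults to the Silverman plug-in value of the input.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("no eigenvalues")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(eig) if eig.size > 1 else FALLBACK_BANDWIDTH
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.asarray(grid, dtype=float)
    # a kernel much narrower than the grid spacing would fall between grid
    # points and lose its mass; clamp to half the median spacing
    dx = float(np.median(np.diff(grid)))
    bandwidth = max(float(bandwidth), 0.5 * dx)
    z = (grid[:, None] - eig[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (eig.size * bandwidth * math.sqrt(2 * math.pi))
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("density has zero mass on the grid; widen the grid")
    dens = dens / area
    return SpectralDensity(grid, dens, float(bandwidth), int(eig.size))


def density_matrix(eigenvalue_sets, grid) -> np.ndarray:
    """Per-graph probability-mass rows on ``grid`` (one row per graph).

    Each row is the graph's spectral density converted to grid-cell masses
    summing to 1; this is the workhorse representation for permutation tests
    and distance matrices.
    """
    rows = [
        density_to_masses(spectral_density(e, grid)) for e in eigenvalue_sets
    ]
    return np.vstack(rows)


def mean_density(densities) -> SpectralDensity:
    """Pointwise arithmetic mean of densities on an identical grid."""
    densities = list(densities)
    if not densities:
        raise ValueError("no densities")
    grid = densities[0].grid
    for d in densities[1:]:
        if not np.array_equal(d.grid, grid):
            raise ValueError("densities must share an identical grid")
    mean = np.mean([d.density for d in densities], axis=0)
    mean = mean / np.trapezoid(mean, grid)
    return SpectralDensity(
        grid,
        mean,
        float(np.mean([d.bandwidth for d in densities])),
        int(sum(d.n_eigenvalues for d in densities)),
    )


def density_to_masses(density: SpectralDensity, floor: float = DENSITY_FLOOR) -> np.ndarray:
    """Convert a gridded density to floored, normalized cell masses."""
    m = np.maximum(density.density, floor)
    return m / m.sum()


def _as_probs(p) -> np.ndarray:
    if isinstance(p, SpectralDensity):
        return density_to_masses(p)
    if isinstance(p, DiscreteDistribution):
        return p.probabilities
    return np.asarray(p, dtype=float)


def _check_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, SpectralDensity) and isinstance(q, SpectralDensity):
        if not np.array_equal(p.grid, q.grid):
            raise ValueError("densities must share an identical grid")
    if isinstance(p, DiscreteDistribution) and isinstance(q, DiscreteDistribution):
        if not np.array_equal(p.support, q.support):
            raise ValueError("distributions must share a common support")
    pa, qa = _as_probs(p), _as_probs(q)
    if pa.shape != qa.shape:
        raise ValueError("distributions must have the same length")
    return pa, qa


def kl_divergence(p, q, base: float | None = None) -> float:
    """Kullback-Leibler divergence sum p log(p/q); terms with p=0 contribute 0.

    Raises if q puts zero mass where p does not — smooth q first (the
    prioritization module applies additive smoothing for exactly this reason).
    """
    pa, qa = _check_pair(p, q)
    if np.any((qa == 0) & (pa > 0)):
        raise ValueError(
            "q has zero mass where p > 0; apply smoothing before computing KL"
        )
    val = float(rel_entr(pa, qa).sum())
    if base is not None:
        val /= math.log(base)
    return max(val, 0.0)


def js_divergence(p, q, base: float | None = None) -> float:
    """Jensen-Shannon divergence (symmetric, in [0, ln 2] for natural log)."""
    pa, qa = _check_pair(p, q)
    m = 0.5 * (pa + qa)
    val = 0.5 * float(rel_entr(pa, m).sum()) + 0.5 * float(rel_entr(qa, m).sum())
    if base is not None:
        val /= math.log(base)
    return min(max(val, 0.0), math.log(2) / (math.log(base) if base else 1.0))


def js_distance(p, q, base: float | None = None) -> float:
    """Jensen-Shannon distance: the square root of the JS divergence."""
    return math.sqrt(js_divergence(p, q, base=base))
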
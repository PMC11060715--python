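"""Pairwise functional connectivity with a stationary-bootstrap null.

Zero-lag Pearson correlations between z-scored dF/F traces are tested
against a stationary block bootstrap (geometric block lengths, mean 23
frames = 1.84 s at the 12.5 Hz effective rate, circular wrap-around, 5000
iterations by default).  One member of each pair is resampled — its
autocorrelation survives, the cross-correlation is destroyed — and a pair
is a significant functional connection when its r exceeds the 99th
percentile of its own null distribution.  Graph summaries follow the
field's conventions: significant connections per neuron, strong
connections (r > 0.3), and density as percent of all possible pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import networkx as nx
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "CorrelationMatrix",
    "BootstrapNull",
    "FunctionalGraph",
    "block_duration_s",
    "pairwise_correlation",
    "stationary_bootstrap_indices",
    "stationary_bootstrap_null",
    "build_graph",
    "centroid_distances",
]


def block_duration_s(mean_block_frames: float, frame_rate_hz: float) -> float:
    """Mean bootstrap block duration in seconds (e.g. 23 frames at 12.5 Hz)."""
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    return mean_block_frames / frame_rate_hz


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r matrix; undefined pairs are NaN."""

    r: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("r must be square")


@dataclass
class BootstrapNull:
    """Per-pair null-quantile thresholds from the stationary bootstrap."""

    threshold: np.ndarray  # neurons x neurons, symmetric, NaN diagonal
    n_iterations: int
    mean_block_frames: float
    quantile: float
    seed: int


@dataclass
class FunctionalGraph:
    """Bootstrap-validated functional connectivity graph."""

    graph: nx.Graph
    n_neurons: int
    significant_count: np.ndarray  # per-neuron incident significant edges
    strong_count: np.ndarray  # per-neuron incident edges with r > strong_threshold
    strong_threshold: float
    distances_um: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def connections_per_neuron(self) -> float:
        """Significant connections divided by population size."""
        return self.n_edges / self.n_neurons

    @property
    def density_percent(self) -> float:
        possible = self.n_neurons * (self.n_neurons - 1) / 2
        return 100.0 * self.n_edges / possible if possible else 0.0

    def edge_table(self) -> list[tuple[int, int, float]]:
        return [(i, j, d["r"]) for i, j, d in self.graph.edges(data=True)]


def pairwise_correlation(z: np.ndarray) -> CorrelationMatrix:
    """Exact Pearson r for every neuron pair of a neurons x frames matrix.

    Rows with zero variance (or NaN, e.g. excluded by z-scoring) yield NaN
    for all their pairs.
    """
    z = np.atleast_2d(np.asarray(z, float))
    n, T = z.shape
    if n < 2 or T < 3:
        raise ValueError("need >= 2 neurons and >= 3 frames")
    valid = np.isfinite(z).all(axis=1) & (z.std(axis=1) > 0)
    r = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sub = np.corrcoef(z[valid])
        r[np.ix_(valid, valid)] = sub
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, n_frames=T)


def stationary_bootstrap_indices(
    n_frames: int, mean_block_frames: float, rng: np.random.Generator
) -> np.ndarray:
    """One stationary-bootstrap resampling schedule of length ``n_frames``.

    Blocks start at uniform positions, have geometric lengths with the
    given mean, and wrap around the end of the series.
    """
    p = 1.0 / mean_block_frames
    idx = np.empty(n_frames, dtype=np.intp)
    pos = 0
    while pos < n_frames:
        start = int(rng.integers(n_frames))
        length = int(rng.geometric(p))
        length = min(length, n_frames - pos)
        idx[pos : pos + length] = (start + np.arange(length)) % n_frames
        pos += length
    return idx


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (x - mean) / sd


def stationary_bootstrap_null(
    z: np.ndarray,
    n_iterations: int = 5000,
    mean_block_frames: float = 23.0,
    quantile: float = 0.99,
    seed: int = 0,
) -> BootstrapNull:
    """Null-correlation thresholds for every pair by stationary bootstrap.

    Per iteration one resampling schedule is drawn and applied to the
    matrix; for the pair (i, j), i < j, neuron j's resampled trace is
    correlated with neuron i's original trace.  The per-pair threshold is
    the ``quantile`` of its null distribution.  Sharing one schedule across
    pairs keeps the cost at one matrix product per iteration; the marginal
    null of each pair is unaffected.
    """
    z = np.atleast_2d(np.asarray(z, float))
    n, T = z.shape
    if T <= mean_block_frames:
        raise ValueError("need more frames than the mean block length")
    if n_iterations < 100:
        warnings.warn("fewer than 100 bootstrap iterations: unstable quantile", stacklevel=2)
    rng = np.random.default_rng(seed)
    z0 = _standardize_rows(z)
    iu = np.triu_indices(n, k=1)
    null = np.empty((n_iterations, iu[0].size), dtype=np.float32)
    for b in range(n_iterations):
        idx = stationary_bootstrap_indices(T, mean_block_frames, rng)
        zb = _standardize_rows(z[:, idx])
        c = (z0 @ zb.T) / T  # c[i, j] = corr(original i, resampled j)
        null[b] = c[iu]
    thr_flat = np.nanquantile(null, quantile, axis=0)
    threshold = np.full((n, n), np.nan)
    threshold[iu] = thr_flat
    threshold.T[iu] = thr_flat
    return BootstrapNull(
        threshold=threshold,
        n_iterations=n_iterations,
        mean_block_frames=mean_block_frames,
        quantile=quantile,
        seed=seed,
    )


def centroid_distances(centroids: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between ROI centroids (um)."""
    centroids = np.asarray(centroids, float)
    if centroids.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    return squareform(pdist(centroids))


def build_graph(
    corr: CorrelationMatrix,
    null: BootstrapNull,
    centroids: np.ndarray | None = None,
    strong_threshold: float = 0.3,
) -> FunctionalGraph:
    """Keep pairs whose r exceeds their bootstrap threshold; summarize.

    Undefined pairs (NaN correlation) never become edges but still count
    in the density denominator (percent of the maximum possible
    connections).
    """
    r = corr.r
    n = r.shape[0]
    if null.threshold.shape != r.shape:
        raise ValueError("correlation and null must cover identical pairs")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    dist = centroid_distances(centroids) if centroids is not None else None
    if centroids is not None:
        for i in range(n):
            g.nodes[i]["centroid_um"] = tuple(np.asarray(centroids[i], float))
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore"):
        sig = r[iu] > null.threshold[iu]
    for i, j, keep in zip(iu[0], iu[1], sig):
        if keep:
            attrs = {"r": float(r[i, j]), "threshold": float(null.threshold[i, j])}
            if dist is not None:
                attrs["distance_um"] = float(dist[i, j])
            g.add_edge(int(i), int(j), **attrs)
    sig_count = np.array([g.degree(i) for i in range(n)])
    strong_count = np.zeros(n, dtype=int)
    for i, j, d in g.edges(data=True):
        if d["r"] > strong_threshold:
            strong_count[i] += 1
            strong_count[j] += 1
    return FunctionalGraph(
        graph=g,
        n_neurons=n,
        significant_count=sig_count,
        strong_count=strong_count,
        strong_threshold=strong_threshold,
        distances_um=dist,
    )
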
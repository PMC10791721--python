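"""Integration/segregation metrics on an aligned gradient embedding.

Six families of metrics summarize how compressed or expanded the connectome
hierarchy is for one subject:

* network median distance — |median gradient-1 score of A − median of B|;
* gradient range and SD — global spread of the principal gradient;
* network peak distance — distance between the networks' density peaks;
* eccentricity — mean distance of a network's parcels from the origin of the
  space spanned by the first three gradients;
* within-network dispersion — sum of squared distances from the network
  centroid (coordinate-wise median);
* between-network dispersion — distance between two network centroids, which
  at dims=1 reduces exactly to the network median distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core_io import GradientSet, NetworkPartition, RunConfig

__all__ = [
    "network_median_distance",
    "gradient_range",
    "gradient_sd",
    "network_peak_distance",
    "eccentricity",
    "within_dispersion",
    "between_dispersion",
    "BinnedDistribution",
    "bin_gradient",
    "average_bins",
    "segregation_report",
]

_KDE_GRID = 512


def _scores_1d(gset: GradientSet, component: int) -> np.ndarray:
    if not 0 <= component < gset.n_gradients:
        raise IndexError(f"component {component} out of range")
    return gset.scores[:, component]


def _net_scores(gset: GradientSet, part: NetworkPartition, network: str,
                component: int) -> np.ndarray:
    return _scores_1d(gset, component)[part.indices(network)]


def network_median_distance(gset: GradientSet, part: NetworkPartition,
                            net_a: str, net_b: str, component: int = 0,
                            signed: bool = False) -> float:
    """Distance between two networks' median scores on one gradient.

    Reported as an absolute value by default; ``signed=True`` returns
    median(A) − median(B).
    """
    if net_a == net_b:
        raise ValueError("net_a and net_b must differ")
    diff = float(
        np.median(_net_scores(gset, part, net_a, component))
        - np.median(_net_scores(gset, part, net_b, component))
    )
    return diff if signed else abs(diff)


def gradient_range(gset: GradientSet, component: int = 0) -> float:
    """max − min of the scores on one gradient."""
    s = _scores_1d(gset, component)
    if s.size < 2:
        raise ValueError("need at least 2 parcels")
    return float(s.max() - s.min())


def gradient_sd(gset: GradientSet, component: int = 0) -> float:
    """Sample (n−1) standard deviation of the scores on one gradient."""
    s = _scores_1d(gset, component)
    if s.size < 2:
        raise ValueError("need at least 2 parcels")
    return float(s.std(ddof=1))


def _kde_peak(scores: np.ndarray) -> float:
    """Location of the dominant mode: argmax of a Gaussian KDE.

    Silverman bandwidth, evaluated on a 512-point grid spanning
    [min − 3h, max + 3h]; ties resolve to the lower score (first argmax).
    """
    if scores.size < 5:
        raise ValueError("need at least 5 parcels for density estimation")
    kde = gaussian_kde(scores, bw_method="silverman")
    h = kde.factor * scores.std(ddof=1)
    grid = np.linspace(scores.min() - 3 * h, scores.max() + 3 * h, _KDE_GRID)
    return float(grid[np.argmax(kde(grid))])


def network_peak_distance(gset: GradientSet, part: NetworkPartition,
                          net_a: str, net_b: str, component: int = 0) -> float:
    """|peak(A) − peak(B)| where peaks are KDE density modes on gradient 1."""
    if net_a == net_b:
        raise ValueError("net_a and net_b must differ")
    pa = _kde_peak(_net_scores(gset, part, net_a, component))
    pb = _kde_peak(_net_scores(gset, part, net_b, component))
    return abs(pa - pb)


def _coords(gset: GradientSet, dims: int) -> np.ndarray:
    if dims > gset.n_gradients:
        raise ValueError(f"dims={dims} exceeds {gset.n_gradients} gradients")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    return gset.scores[:, :dims]


def eccentricity(gset: GradientSet, part: NetworkPartition | None = None,
                 network: str | None = None, dims: int = 3,
                 agg: str = "mean") -> float:
    """Distance of a network's parcels from the embedding origin.

    Euclidean norms over the first ``dims`` gradients, aggregated by the mean
    (``agg="mean"``, the default) or by the sum of squares (``agg="sum_sq"``).
    With ``network=None`` the global (all-parcel) value is returned.
    """
    coords = _coords(gset, dims)
    if network is not None:
        if part is None:
            raise ValueError("a partition is required to select a network")
        coords = coords[part.indices(network)]
    norms = np.linalg.norm(coords, axis=1)
    if agg == "mean":
        return float(norms.mean())
    if agg == "sum_sq":
        return float(np.sum(norms**2))
    raise ValueError("agg must be 'mean' or 'sum_sq'")


def _centroid(coords: np.ndarray) -> np.ndarray:
    """Network centroid: coordinate-wise median."""
    return np.median(coords, axis=0)


def within_dispersion(gset: GradientSet, part: NetworkPartition,
                      network: str, dims: int = 3) -> float:
    """Sum of squared distances from the network centroid (median)."""
    coords = _coords(gset, dims)[part.indices(network)]
    if coords.shape[0] < 1:
        raise ValueError(f"network {network!r} is empty")
    return float(np.sum((coords - _centroid(coords)) ** 2))


def between_dispersion(gset: GradientSet, part: NetworkPartition,
                       net_a: str, net_b: str, dims: int = 3) -> float:
    """Euclidean distance between two network centroids.

    At ``dims=1`` this is exactly the network median distance.
    """
    coords = _coords(gset, dims)
    ca = _centroid(coords[part.indices(net_a)])
    cb = _centroid(coords[part.indices(net_b)])
    return float(np.linalg.norm(ca - cb))


@dataclass(frozen=True)
class BinnedDistribution:
    """Histogram of gradient-1 scores (51 edges for 50 bins by default).

    ``counts`` sums to the number of parcels binned; ``per_network`` holds an
    optional stratification whose per-network counts sum to network sizes.
    """

    edges: np.ndarray
    counts: np.ndarray
    per_network: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.size != counts.size + 1:
            raise ValueError("need one more edge than bins")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)


def bin_gradient(gset: GradientSet, n_bins: int = 50,
                 edges: np.ndarray | None = None, component: int = 0,
                 part: NetworkPartition | None = None) -> BinnedDistribution:
    """Bin gradient scores into a histogram (optionally network-stratified).

    Pass explicit ``edges`` to share a common binning across participants.
    """
    scores = _scores_1d(gset, component)
    if edges is None:
        edges = np.histogram_bin_edges(scores, bins=n_bins)
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(scores, bins=edges)
    per_network = None
    if part is not None:
        per_network = {
            net: np.histogram(scores[part.indices(net)], bins=edges)[0].astype(float)
            for net in part.network_order
        }
    return BinnedDistribution(edges=edges, counts=counts.astype(float),
                              per_network=per_network)


def average_bins(dists: Sequence[BinnedDistribution]) -> BinnedDistribution:
    """Average counts per bin across participants (edges must match)."""
    if len(dists) == 0:
        raise ValueError("need at least one distribution")
    edges = dists[0].edges
    for d in dists[1:]:
        if d.edges.shape != edges.shape or not np.allclose(d.edges, edges):
            raise ValueError("bin edges differ across participants")
    counts = np.mean([d.counts for d in dists], axis=0)
    per_network = None
    if all(d.per_network is not None for d in dists):
        nets = dists[0].per_network.keys()
        per_network = {
            net: np.mean([d.per_network[net] for d in dists], axis=0) for net in nets
        }
    return BinnedDistribution(edges=edges.copy(), counts=counts,
                              per_network=per_network)


def segregation_report(gset: GradientSet, part: NetworkPartition,
                       config: RunConfig | None = None,
                       subject_id: str = "s0") -> pd.DataFrame:
    """All metrics for one subject as a tidy DataFrame.

    Columns: subject, metric, network_a, network_b, dims, value. Pairwise
    metrics cover all K·(K−1)/2 pairs; eccentricity additionally has a
    global row (network_a = "Global").
    """
    config = config or RunConfig()
    dims = config.eccentricity_dims
    rows: list[dict] = []

    def add(metric: str, value: float, net_a: str = "", net_b: str = "",
            d: int = 1) -> None:
        rows.append(dict(subject=subject_id, metric=metric, network_a=net_a,
                         network_b=net_b, dims=d, value=value))

    add("gradient_range", gradient_range(gset))
    add("gradient_sd", gradient_sd(gset))
    add("variance_explained", float(gset.explained_variance[0]))
    add("eccentricity", eccentricity(gset, dims=dims, agg=config.eccentricity_agg),
        net_a="Global", d=dims)
    for net in part.network_order:
        add("eccentricity",
            eccentricity(gset, part, net, dims=dims, agg=config.eccentricity_agg),
            net_a=net, d=dims)
        add("within_dispersion", within_dispersion(gset, part, net, dims=dims),
            net_a=net, d=dims)
    sizes = part.sizes()
    for net_a, net_b in part.pairs():
        add("median_distance",
            network_median_distance(gset, part, net_a, net_b,
                                    signed=config.signed_median_distance),
            net_a, net_b)
        if min(sizes[net_a], sizes[net_b]) >= 5:  # KDE needs >= 5 parcels
            add("peak_distance", network_peak_distance(gset, part, net_a, net_b),
                net_a, net_b)
        add("between_dispersion",
            between_dispersion(gset, part, net_a, net_b, dims=dims),
            net_a, net_b, d=dims)
    return pd.DataFrame(rows)
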
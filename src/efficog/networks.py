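"""Weighted structural-connectome graph metrics.

The unit of analysis is a symmetric, nonnegative, zero-diagonal matrix of
fractional-anisotropy (FA) weights between brain regions.  Global efficiency
``E_G`` is the mean over nodes of nodal efficiency ``E_j``, the average
inverse shortest weighted path length from each node to every other node.
Because any single proportional density threshold is arbitrary, metrics are
computed over a sweep of densities and summarized by the trapezoidal area
under the metric-vs-density curve (AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WeightedNetwork",
    "EfficiencyProfile",
    "LENGTH_MAPS",
    "build_network",
    "proportional_threshold",
    "shortest_weighted_paths",
    "global_efficiency",
    "efficiency_auc",
    "default_densities",
    "EfficiencyTransformer",
]

#: weight -> length maps; both are strictly positive and decreasing on (0, 1]
LENGTH_MAPS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "inverse": lambda w: 1.0 / w,
    "neglog": lambda w: -np.log(w),
}


def default_densities(start: float = 0.30, stop: float = 0.90, step: float = 0.05) -> np.ndarray:
    """Proportional-threshold grid, default 0.30 to 0.90 in steps of 0.05."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric FA-weighted network; absent edges are exactly zero."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("edge weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @staticmethod
    def default_labels(n: int) -> tuple[str, ...]:
        return tuple(f"roi_{i + 1:03d}" for i in range(n))

    @classmethod
    def from_array(cls, weights: np.ndarray, labels: Sequence[str] | None = None) -> "WeightedNetwork":
        weights = np.asarray(weights, dtype=float)
        if labels is None:
            labels = cls.default_labels(weights.shape[0])
        return cls(tuple(labels), weights)


@dataclass
class EfficiencyProfile:
    """Per-density global/nodal efficiency plus density-AUC summaries."""

    densities: np.ndarray
    e_global: np.ndarray  # (n_densities,)
    e_nodal: np.ndarray  # (n_densities, n_nodes)
    auc_global: float = field(init=False)
    auc_nodal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.auc_nodal = efficiency_auc(self.densities, self.e_nodal)
        self.auc_global = float(efficiency_auc(self.densities, self.e_global))

    def to_frame(self, labels: Sequence[str]) -> pd.DataFrame:
        """Tidy (long) per-density, per-node table."""
        rows = []
        for di, d in enumerate(self.densities):
            for ni, lab in enumerate(labels):
                rows.append((float(d), lab, self.e_nodal[di, ni], self.e_global[di]))
        return pd.DataFrame(rows, columns=["density", "node", "e_nodal", "e_global"])


def build_network(
    count_matrix: np.ndarray,
    fa_matrix: np.ndarray,
    labels: Sequence[str] | None = None,
) -> WeightedNetwork:
    """Build an FA-weighted network from a streamline-count and a mean-FA matrix.

    Streamline counts may be asymmetric (seeding direction); they are
    symmetrized by averaging, and an edge exists wherever the symmetrized
    count is positive.  The edge weight is the FA value for that pair.
    """
    counts = np.asarray(count_matrix, dtype=float)
    fa = np.asarray(fa_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"count matrix must be square, got shape {counts.shape}")
    if counts.shape != fa.shape:
        raise ValueError(f"count matrix {counts.shape} and FA matrix {fa.shape} differ in shape")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be nonnegative")
    if np.any((fa < 0) | (fa > 1)):
        bad = np.argwhere((fa < 0) | (fa > 1))[0]
        raise ValueError(
            f"FA values must lie in [0, 1]; found {fa[tuple(bad)]} at ({bad[0]}, {bad[1]})"
        )
    sym_counts = (counts + counts.T) / 2.0
    fa_sym = (fa + fa.T) / 2.0
    weights = np.where(sym_counts > 0, fa_sym, 0.0)
    np.fill_diagonal(weights, 0.0)
    return WeightedNetwork.from_array(weights, labels)


def _edge_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by (weight desc, node-pair lexicographic).

    The lexicographic tie-break makes thresholding reproducible when several
    edges share the boundary weight.
    """
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w = weights[iu, ju]
    # lexsort keys: last key is primary; negate weights for descending order
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def proportional_threshold(net: WeightedNetwork, density: float) -> WeightedNetwork:
    """Retain the ``round(density * n(n-1)/2)`` strongest edges, zero the rest."""
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = net.n_nodes
    k = int(np.floor(density * n * (n - 1) / 2 + 0.5))
    iu, ju = _edge_order(net.weights)
    w_sorted = net.weights[iu, ju]
    keep = min(k, int(np.count_nonzero(w_sorted)))
    out = np.zeros_like(net.weights)
    out[iu[:keep], ju[:keep]] = w_sorted[:keep]
    out = out + out.T
    return WeightedNetwork(net.labels, out)


def _lengths(weights: np.ndarray, length_map: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    if np.any(weights < 0):
        raise ValueError("edge weights must be nonnegative")
    lengths = np.zeros_like(weights)
    mask = weights > 0
    lengths[mask] = length_map(weights[mask])
    if np.any(lengths[mask] < 0):
        raise ValueError("length map produced negative lengths")
    return lengths


def shortest_weighted_paths(
    net: WeightedNetwork,
    length_map: str | Callable[[np.ndarray], np.ndarray] = "inverse",
) -> np.ndarray:
    """All-pairs shortest weighted path lengths d_ij.

    Each edge weight w is mapped to a length f(w) (default f(w) = 1/w, so
    stronger connections are shorter); d_ij is the minimal summed length over
    paths.  Unreachable pairs get +inf, the diagonal is 0.
    """
    if isinstance(length_map, str):
        length_map = LENGTH_MAPS[length_map]
    lengths = _lengths(net.weights, length_map)
    return dijkstra(lengths, directed=False, unweighted=False)


def global_efficiency(
    net: WeightedNetwork,
    length_map: str | Callable[[np.ndarray], np.ndarray] = "inverse",
) -> tuple[float, np.ndarray]:
    """Weighted global and nodal efficiency.

    E_j(i) = sum_{j != i} 1/d_ij / (n - 1) with 1/inf := 0, and E_G is the
    mean of E_j over nodes.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    d = shortest_weighted_paths(net, length_map)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    e_nodal = inv.sum(axis=1) / (n - 1)
    return float(e_nodal.mean()), e_nodal


def efficiency_auc(densities: Sequence[float], values: np.ndarray) -> np.ndarray | float:
    """Trapezoidal area under a metric-vs-density curve.

    ``values`` may be a vector (one metric per density) or a matrix with one
    row per density (e.g. nodal efficiencies); integration is along axis 0.
    """
    densities = np.asarray(densities, dtype=float)
    if densities.size < 2:
        raise ValueError("AUC needs at least 2 densities")
    if np.any(np.diff(densities) <= 0):
        raise ValueError("densities must be strictly increasing")
    values = np.asarray(values, dtype=float)
    if values.shape[0] != densities.size:
        raise ValueError("one row of values per density required")
    return np.trapezoid(values, densities, axis=0)


def efficiency_profile(
    net: WeightedNetwork,
    densities: Sequence[float] | None = None,
    length_map: str | Callable[[np.ndarray], np.ndarray] = "inverse",
) -> EfficiencyProfile:
    """Threshold sweep: efficiency at each proportional density, plus AUCs."""
    densities = default_densities() if densities is None else np.asarray(densities, float)
    e_g = np.empty(densities.size)
    e_j = np.empty((densities.size, net.n_nodes))
    for i, d in enumerate(densities):
        thr = proportional_threshold(net, float(d))
        e_g[i], e_j[i] = global_efficiency(thr, length_map)
    return EfficiencyProfile(densities, e_g, e_j)


class EfficiencyTransformer(BaseEstimator, TransformerMixin):
    """Map a list of weighted networks to density-AUC efficiency features.

    Parameters
    ----------
    densities : sequence of float, default 0.30..0.90 step 0.05
        Proportional density thresholds.
    length_map : {"inverse", "neglog"} or callable, default "inverse"
        Weight-to-length map for shortest paths.

    After ``fit``, ``labels_`` holds the node labels and ``transform``
    returns a DataFrame with one row per subject: ``eg_auc`` plus one
    ``ej_auc_<label>`` column per node.
    """

    def __init__(self, densities: Sequence[float] | None = None, length_map: str = "inverse"):
        self.densities = densities
        self.length_map = length_map

    def fit(self, X: Sequence[WeightedNetwork], y=None) -> "EfficiencyTransformer":
        if len(X) == 0:
            raise ValueError("need at least one network")
        self.labels_ = X[0].labels
        self.densities_ = (
            default_densities() if self.densities is None else np.asarray(self.densities, float)
        )
        return self

    def transform(self, X: Sequence[WeightedNetwork]) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "labels_")
        rows = []
        for net in X:
            if net.labels != self.labels_:
                raise ValueError("all networks must share the fitted node labels")
            prof = efficiency_profile(net, self.densities_, self.length_map)
            rows.append(np.concatenate([[prof.auc_global], prof.auc_nodal]))
        cols = ["eg_auc"] + [f"ej_auc_{lab}" for lab in self.labels_]
        return pd.DataFrame(rows, columns=cols)

    def profile(self, net: WeightedNetwork) -> EfficiencyProfile:
        """Full per-density profile for a single network."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "labels_")
        return efficiency_profile(net, self.densities_, self.length_map)
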
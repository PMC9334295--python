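"""Waxman cell-graph construction from nucleus centroids.

The Waxman link function assigns to each node pair a score
``p(u, v) = alpha * exp(-d(u, v) / (beta * L))`` where ``d`` is the Euclidean
distance between the nuclei and ``L`` the largest pairwise distance among the
nodes of the image.  A pair is linked when the score clears a fixed cut-off
``R`` — i.e. the rule degenerates to a deterministic distance-threshold graph
with radius ``d* = beta * L * ln(alpha / R)``.  With the defaults alpha = 1,
beta = 0.025 and R in {0.1, 0.05, 0.02}, R maps to the reporting label
p = 1 - R (0.9, 0.95, 0.98).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "WaxmanParams",
    "CellGraph",
    "waxman_probability",
    "decide_link",
    "threshold_radius",
    "max_pairwise_distance",
    "build_graph",
]


@dataclass(frozen=True)
class WaxmanParams:
    """Waxman rule parameters.

    ``L`` is normally computed per image from the detected centers; set it
    explicitly to pin the length scale across images.
    """

    alpha: float = 1.0
    beta: float = 0.025
    R: float = 0.05
    L: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if not (0 < self.R <= self.alpha):
            raise ValueError("need 0 < R <= alpha")
        if self.L is not None and self.L <= 0:
            raise ValueError("L must be > 0 when given")

    @property
    def p_label(self) -> float:
        """Reporting label p = 1 - R used alongside the cut-off in tables."""
        return 1.0 - self.R

    def replace(self, **kw) -> "WaxmanParams":
        return dataclasses.replace(self, **kw)


@dataclass
class CellGraph:
    """Node coordinates plus the symmetric boolean adjacency they induce."""

    coords: np.ndarray  # (n, 2) float
    adjacency: np.ndarray  # (n, n) bool, zero diagonal

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        A = np.asarray(self.adjacency, dtype=bool)
        if A.shape != (len(self.coords),) * 2:
            raise ValueError("adjacency shape does not match coords")
        if np.any(A != A.T) or np.any(np.diag(A)):
            raise ValueError("adjacency must be symmetric with a zero diagonal")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency.astype(np.uint8))
        for i, (x, y) in enumerate(self.coords):
            g.nodes[i]["pos"] = (float(x), float(y))
        return g


def waxman_probability(d: float | np.ndarray, params: WaxmanParams, L: float | None = None):
    """Waxman link score alpha * exp(-d / (beta * L)); decreasing in d."""
    L = params.L if L is None else L
    if L is None or L <= 0:
        raise ValueError("a positive L is required (give params.L or the L argument)")
    return params.alpha * np.exp(-np.asarray(d, dtype=float) / (params.beta * L))


def decide_link(d: float, params: WaxmanParams, L: float | None = None) -> bool:
    """True iff the Waxman score clears the cut-off: alpha*exp(-d/(beta L)) - R >= 0.

    Equivalent to ``d <= threshold_radius(params, L)`` (ties at the threshold
    are linked).
    """
    return bool(waxman_probability(d, params, L) >= params.R)


def threshold_radius(params: WaxmanParams, L: float | None = None) -> float:
    """Deterministic link radius d* = beta * L * ln(alpha / R)."""
    L = params.L if L is None else L
    if L is None or L <= 0:
        raise ValueError("a positive L is required")
    return params.beta * L * math.log(params.alpha / params.R)


def max_pairwise_distance(coords: np.ndarray) -> float:
    """Largest Euclidean distance over all node pairs (the diameter L).

    Brute force below 1000 nodes; above, the maximum is attained on the
    convex hull, so only hull vertices are compared.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 nodes")
    pts = coords
    if len(pts) > 1000:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear/degenerate input: fall back to brute force
            pass
    return float(pdist(pts).max())


def build_graph(coords: np.ndarray, params: WaxmanParams | None = None) -> CellGraph:
    """Build the undirected Waxman cell graph over ``coords``.

    Edge (i, j) is present iff ``decide_link(d_ij)``; the result equals a
    distance-threshold graph of radius d*.  Duplicate coordinates are allowed
    (distance 0 always links when alpha >= R).  A single node yields a
    0-edge graph without requiring L.
    """
    params = params or WaxmanParams()
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n == 0:
        raise ValueError("coords must be nonempty")
    if n == 1:
        return CellGraph(coords=coords, adjacency=np.zeros((1, 1), dtype=bool))
    L = params.L if params.L is not None else max_pairwise_distance(coords)
    D = squareform(pdist(coords))
    if L <= 0:  # all points coincident: every pair at distance 0
        A = np.full((n, n), params.alpha >= params.R, dtype=bool)
    else:
        A = waxman_probability(D, params, L) >= params.R
    np.fill_diagonal(A, False)
    return CellGraph(coords=coords, adjacency=A)
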
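"""Network statistics of cell graphs and their Erdős–Rényi reference.

Three statistics characterize each graph: the mean degree k, the global
clustering coefficient cc (node average of C_i = 2 E_i / (k_i (k_i - 1)),
with C_i := 0 for degree < 2), and the characteristic path length cpl (mean
breadth-first shortest-path length over reachable unordered node pairs; the
reachable fraction is reported alongside, since fragmented colonies are
common at high dose).

Small-world-ness compares the graph against size-matched G(n, m)
Erdős–Rényi draws:

    SW = (cc / cc_rand) / (cpl / cpl_rand)

SW > 1 marks a graph that clusters more, at similar path length, than random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph import CellGraph

__all__ = [
    "TopologyMetrics",
    "NoConnectedPairsError",
    "local_clustering",
    "global_clustering",
    "characteristic_path_length",
    "sample_er_graph",
    "er_reference",
    "small_worldness",
]


class NoConnectedPairsError(ValueError):
    """Path length requested on a graph in which no pair of nodes is connected."""


@dataclass
class TopologyMetrics:
    """Per-image topology summary plus the E–R reference it was normalized by."""

    n_nodes: int
    n_edges: int
    k_mean: float
    cc: float
    cpl: float
    reachable_fraction: float
    cc_rand: float
    cpl_rand: float
    sw: float
    er_replicates: int
    seed: int


def _adjacency(graph: CellGraph | np.ndarray) -> np.ndarray:
    A = graph.adjacency if isinstance(graph, CellGraph) else np.asarray(graph)
    A = A.astype(bool)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return A


def local_clustering(graph: CellGraph | np.ndarray, i: int) -> float:
    """C_i = 2 E_i / (k (k - 1)) for node i; 0 when the degree is below 2."""
    A = _adjacency(graph)
    if not (0 <= i < len(A)):
        raise IndexError(f"node {i} out of range for {len(A)} nodes")
    nbrs = np.nonzero(A[i])[0]
    k = len(nbrs)
    if k < 2:
        return 0.0
    e_i = int(A[np.ix_(nbrs, nbrs)].sum()) // 2
    return 2.0 * e_i / (k * (k - 1))


def global_clustering(graph: CellGraph | np.ndarray) -> float:
    """Mean of C_i over all nodes (degree < 2 contributing 0)."""
    A = _adjacency(graph).astype(np.float64)
    n = len(A)
    if n < 1:
        raise ValueError("graph must have at least one node")
    deg = A.sum(axis=1)
    # triangles through each node = diag(A^3) / 2 = row-sum of (A^2 ∘ A) / 2
    tri = ((A @ A) * A).sum(axis=1) / 2.0
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * tri / np.where(denom > 0, denom, 1.0), 0.0)
    return float(c.mean())


def characteristic_path_length(graph: CellGraph | np.ndarray) -> tuple[float, float]:
    """(cpl, reachable_fraction): mean BFS shortest-path length over reachable
    unordered pairs, and the fraction of all pairs that are reachable.

    Raises :class:`NoConnectedPairsError` on edgeless graphs.
    """
    A = _adjacency(graph)
    n = len(A)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not A.any():
        raise NoConnectedPairsError("graph has no edges; no connected pairs")
    D = shortest_path(csr_matrix(A), method="D", directed=False, unweighted=True)
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    finite = np.isfinite(d)
    n_pairs = len(d)
    n_reach = int(finite.sum())
    if n_reach == 0:  # unreachable without edges, guarded above
        raise NoConnectedPairsError("no connected pairs")
    return float(d[finite].mean()), n_reach / n_pairs


def sample_er_graph(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Adjacency of one G(n, m) draw: m edges uniform without replacement."""
    total = n * (n - 1) // 2
    if not (0 <= m <= total):
        raise ValueError(f"m must be in [0, {total}]")
    idx = rng.choice(total, size=m, replace=False)
    iu = np.triu_indices(n, k=1)
    A = np.zeros((n, n), dtype=bool)
    A[iu[0][idx], iu[1][idx]] = True
    return A | A.T


def er_reference(
    n: int, m: int, replicates: int = 20, seed: int = 0
) -> tuple[float, float]:
    """Mean (cc_rand, cpl_rand) over ``replicates`` G(n, m) draws.

    Replicates without any connected pair are skipped for cpl (impossible for
    m >= 1); m = 0 raises, since the E–R reference is then degenerate.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if m == 0:
        raise NoConnectedPairsError(
            "m = 0: the E-R reference has no edges and cpl_rand is undefined"
        )
    rng = np.random.default_rng(seed)
    ccs, cpls = [], []
    for _ in range(replicates):
        A = sample_er_graph(n, m, rng)
        ccs.append(global_clustering(A))
        try:
            cpl, _ = characteristic_path_length(A)
        except NoConnectedPairsError:  # pragma: no cover - m >= 1 always has a pair
            continue
        cpls.append(cpl)
    return float(np.mean(ccs)), float(np.mean(cpls))


def small_worldness(
    graph: CellGraph | np.ndarray, replicates: int = 20, seed: int = 0
) -> TopologyMetrics:
    """Full topology record of a graph, normalized by matched G(n, m) draws.

    Raises if the E–R reference clustering is 0 (possible at very small m);
    increase ``replicates`` or report the graph as degenerate.
    """
    A = _adjacency(graph)
    n = len(A)
    m = int(A.sum()) // 2
    if n < 2 or m < 1:
        raise ValueError("need a graph with at least 2 nodes and 1 edge")
    cc = global_clustering(A)
    cpl, reach = characteristic_path_length(A)
    cc_rand, cpl_rand = er_reference(n, m, replicates=replicates, seed=seed)
    if cc_rand <= 0:
        raise ZeroDivisionError(
            "E-R reference clustering is 0 at this (n, m); increase replicates "
            "or treat the graph as too sparse for a small-world comparison"
        )
    sw = (cc / cc_rand) / (cpl / cpl_rand)
    return TopologyMetrics(
        n_nodes=n,
        n_edges=m,
        k_mean=2.0 * m / n,
        cc=cc,
        cpl=cpl,
        reachable_fraction=reach,
        cc_rand=cc_rand,
        cpl_rand=cpl_rand,
        sw=sw,
        er_replicates=replicates,
        seed=seed,
    )
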
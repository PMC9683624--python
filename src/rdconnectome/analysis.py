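"""Time-series and graph-level summaries of network simulations.

Similarity matrices (cross-correlation, co-activation) feed the clustering
stage; the Kuramoto order parameter quantifies phase synchrony across
nodes; the local graph metrics table mirrors the standard connectome
descriptors (degrees, convergence/divergence ratio, out-clustering,
matching indices) with per-metric ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .connectome_model import Connectome
from .dynamics import Trajectory

__all__ = [
    "SimilarityMatrix",
    "cross_correlation_matrix",
    "average_similarity",
    "kuramoto_order",
    "coactivation_matrix",
    "local_graph_metrics",
    "matching_matrix",
    "modularity_partition",
]

#: Fraction of samples discarded as initial transient by default.
DEFAULT_TRANSIENT_FRACTION = 0.1


@dataclass
class SimilarityMatrix:
    """Symmetric node-by-node similarity with provenance."""

    matrix: np.ndarray
    nodes: list
    statistic: str
    transient: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _resolve_transient(n_samples: int, transient: int | None) -> int:
    if transient is None:
        return int(np.floor(n_samples * DEFAULT_TRANSIENT_FRACTION))
    if transient < 0 or transient >= n_samples:
        raise ValueError("transient must be in [0, n_samples)")
    return transient


def cross_correlation_matrix(
    traj: Trajectory, species: str | None = None, transient: int | None = None
) -> SimilarityMatrix:
    """Zero-lag Pearson correlation of all node pairs' post-transient series.

    Zero-variance (constant) series get correlation 0 against everything,
    with a warning; the diagonal is exactly 1.
    """
    X = traj.get(species) if species is not None else traj.states[0]
    species = species or traj.species[0]
    cut = _resolve_transient(X.shape[1], transient)
    X = X[:, cut:]
    if X.shape[1] < 3:
        raise ValueError("need at least 3 post-transient samples")
    sd = X.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant series; their correlations are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C[np.isnan(C)] = 0.0
    C[flat, :] = 0.0
    C[:, flat] = 0.0
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    return SimilarityMatrix(
        matrix=C, nodes=list(traj.nodes), statistic="cross_correlation", transient=cut
    )


def average_similarity(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Entrywise mean of per-combination similarity matrices."""
    if not mats:
        raise ValueError("no matrices to average")
    nodes = mats[0].nodes
    for m in mats:
        if m.nodes != nodes:
            raise ValueError("matrices cover different node sets")
    avg = np.mean([m.matrix for m in mats], axis=0)
    return SimilarityMatrix(
        matrix=avg, nodes=list(nodes), statistic=f"mean_{mats[0].statistic}",
        transient=mats[0].transient, meta={"n_averaged": len(mats)},
    )


def kuramoto_order(
    traj: Trajectory,
    species: str | None = None,
    transient: int | None = None,
    edge_trim: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Kuramoto order parameter r(t) and its time average.

    Phases come from the analytic signal (Hilbert transform of the
    mean-subtracted post-transient series); a fraction ``edge_trim`` of
    samples is dropped at each end where the transform is unreliable.
    Constant series are excluded with a warning.  r(t) is in [0, 1]:
    1 = full synchrony, 0 = incoherence.
    """
    X = traj.get(species) if species is not None else traj.states[0]
    cut = _resolve_transient(X.shape[1], transient)
    X = X[:, cut:]
    if X.shape[0] < 2:
        raise ValueError("kuramoto_order needs at least 2 nodes")
    sd = X.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} constant series excluded from the order parameter",
            stacklevel=2,
        )
    X = X[keep]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant series")
    phases = np.angle(hilbert(X - X.mean(axis=1, keepdims=True), axis=1))
    r_t = np.abs(np.exp(1j * phases).mean(axis=0))
    trim = int(np.floor(edge_trim * r_t.size))
    core = r_t[trim: r_t.size - trim] if trim > 0 else r_t
    return r_t, float(core.mean())


def coactivation_matrix(
    traj: Trajectory,
    species: str | None = None,
    transient: int | None = None,
    threshold_sd: float = 0.5,
) -> SimilarityMatrix:
    """Jaccard-style co-activation of binarized series.

    A node is "active" when above its own mean + ``threshold_sd`` standard
    deviations.  Entry (i, j) = |both active| / |either active| over the
    post-transient samples; pairs never active together or apart get 0.
    """
    X = traj.get(species) if species is not None else traj.states[0]
    cut = _resolve_transient(X.shape[1], transient)
    X = X[:, cut:]
    thr = X.mean(axis=1, keepdims=True) + threshold_sd * X.std(axis=1, keepdims=True)
    A = X > thr
    never = ~A.any(axis=1)
    if np.any(never):
        warnings.warn(
            f"{int(never.sum())} nodes never exceed threshold; their rows are 0",
            stacklevel=2,
        )
    Af = A.astype(float)
    both = Af @ Af.T
    either = A.sum(axis=1)[:, None] + A.sum(axis=1)[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(either > 0, both / np.maximum(either, 1e-300), 0.0)
    M[never, :] = 0.0
    M[:, never] = 0.0
    M = (M + M.T) / 2.0
    return SimilarityMatrix(
        matrix=M, nodes=list(traj.nodes), statistic="coactivation", transient=cut
    )


# -- graph-level metrics ----------------------------------------------

def matching_matrix(c: Connectome, direction: str = "out") -> SimilarityMatrix:
    """Pairwise matching index |N(i) & N(j)| / |N(i) | N(j)|.

    Neighborhoods are out- or in-neighbor sets with i and j themselves
    excluded; empty unions give 0.
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    g = c.graph
    nodes = c.nodes
    nbrs = {
        n: (set(g.successors(n)) if direction == "out" else set(g.predecessors(n)))
        for n in nodes
    }
    n = len(nodes)
    M = np.zeros((n, n))
    for i, a in enumerate(nodes):
        M[i, i] = 1.0
        for j in range(i + 1, n):
            b = nodes[j]
            na = nbrs[a] - {a, b}
            nb = nbrs[b] - {a, b}
            union = na | nb
            M[i, j] = M[j, i] = len(na & nb) / len(union) if union else 0.0
    return SimilarityMatrix(matrix=M, nodes=list(nodes), statistic=f"matching_{direction}")


def _out_clustering(g: nx.DiGraph, node) -> float:
    """Density of directed edges among a node's out-neighbors."""
    nbrs = [v for v in g.successors(node) if v != node]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for a in nbrs for b in nbrs if a != b and g.has_edge(a, b))
    return links / (k * (k - 1))


def local_graph_metrics(c: Connectome) -> pd.DataFrame:
    """Per-node table of local connectome descriptors with ranks.

    Columns: deg_in, deg_out, deg_all, DGinDGall (= deg_in / deg_all, the
    convergence/divergence ratio; 0 for isolated nodes), CluC_out
    (clustering of the out-neighborhood), matching_in / matching_out
    (mean matching index against all other nodes), plus a ``rank_*``
    column per metric (descending, ties get the average rank).
    """
    if c.n_nodes == 0:
        raise ValueError("empty connectome")
    g = c.graph
    nodes = c.nodes
    deg_in = np.array([g.in_degree(n) for n in nodes], dtype=float)
    deg_out = np.array([g.out_degree(n) for n in nodes], dtype=float)
    deg_all = deg_in + deg_out
    with np.errstate(invalid="ignore", divide="ignore"):
        dgin = np.where(deg_all > 0, deg_in / np.maximum(deg_all, 1e-300), 0.0)
    cluc = np.array([_out_clustering(g, n) for n in nodes])
    m_in = matching_matrix(c, "in").matrix
    m_out = matching_matrix(c, "out").matrix
    off = ~np.eye(len(nodes), dtype=bool)
    df = pd.DataFrame(
        {
            "deg_in": deg_in,
            "deg_out": deg_out,
            "deg_all": deg_all,
            "DGinDGall": dgin,
            "CluC_out": cluc,
            "matching_in": np.array([m_in[i, off[i]].mean() for i in range(len(nodes))]),
            "matching_out": np.array([m_out[i, off[i]].mean() for i in range(len(nodes))]),
        },
        index=pd.Index(nodes, name="node"),
    )
    for col in list(df.columns):
        df[f"rank_{col}"] = df[col].rank(ascending=False, method="average")
    return df


def modularity_partition(
    c: Connectome, seed: int = 0, resolution: float = 1.0
) -> tuple[dict, float]:
    """Louvain modularity maximization on the symmetrized weighted graph.

    Returns (node -> module id, Q).  Disconnected components simply end up
    in separate modules.
    """
    if c.n_nodes == 0:
        raise ValueError("empty connectome")
    ug = nx.Graph()
    ug.add_nodes_from(c.nodes)
    for s, t, data in c.edges():
        w = data.get("weight", 1.0)
        if ug.has_edge(s, t):
            ug.edges[s, t]["weight"] += w
        else:
            ug.add_edge(s, t, weight=w)
    comms = nx.community.louvain_communities(ug, weight="weight", seed=seed,
                                             resolution=resolution)
    q = nx.community.modularity(ug, comms, weight="weight", resolution=resolution)
    assignment = {n: i for i, comm in enumerate(comms) for n in comm}
    return assignment, float(q)
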
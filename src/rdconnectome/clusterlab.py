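"""Clustering of similarity matrices and the parameter-sweep driver.

Two clustering routes: spectral clustering (normalized-Laplacian embedding
plus k-means, with an eigengap heuristic for the cluster count) and the
Markov cluster algorithm (MCL: alternating expansion and inflation of a
column-stochastic matrix until the iterates stabilize).

Partitions are compared with the average best-match Jaccard coefficient:
for clusterings A and B,

    ( sum_{X in A} max_{Y in B} J(X, Y)
      + sum_{Y in B} max_{X in A} J(Y, X) ) / (|A| + |B|),

with J(X, Y) = |X & Y| / |X | Y|.  The sweep driver enumerates a Cartesian
parameter grid (inclusive endpoints), simulates each combination, reduces
each run to a similarity matrix and a clustering, and assembles the
averaged matrix plus the pairwise clustering-similarity matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .analysis import SimilarityMatrix, average_similarity, cross_correlation_matrix, \
    coactivation_matrix
from .connectome_model import Connectome
from .dynamics import SolverConfig, integrate

__all__ = [
    "MCLConfig",
    "ClusterAssignment",
    "ParamGrid",
    "SweepResult",
    "correlation_to_affinity",
    "spectral_cluster",
    "mcl",
    "jaccard_clustering_similarity",
    "run_sweep",
    "GRID_PRESETS",
]


@dataclass(frozen=True)
class MCLConfig:
    """Markov-cluster parameters (printed defaults of the toolchain).

    zero_threshold: values at or below it are treated as zero each round;
    equal_threshold: max entrywise difference at which two successive
    iterates count as equal (termination); loop_gain: if > 0, the diagonal
    is set to this value before iteration; inflation: elementwise power.
    """

    zero_threshold: float = 1e-7
    equal_threshold: float = 1e-7
    loop_gain: float = 0.0
    inflation: float = 2.0
    max_iter: int = 200

    def __post_init__(self):
        if self.zero_threshold < 0 or self.equal_threshold < 0 or self.loop_gain < 0:
            raise ValueError("thresholds and loop gain must be >= 0")
        if self.inflation <= 1:
            raise ValueError("inflation exponent must be > 1")


@dataclass
class ClusterAssignment:
    """Partition of nodes into clusters."""

    labels: dict
    method: str = ""
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.labels:
            raise ValueError("empty cluster assignment")

    @property
    def nodes(self) -> set:
        return set(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> list[frozenset]:
        by_id: dict = {}
        for node, cid in self.labels.items():
            by_id.setdefault(cid, set()).add(node)
        return [frozenset(v) for _, v in sorted(by_id.items(), key=lambda kv: str(kv[0]))]

    @classmethod
    def from_clusters(cls, clusters: Sequence[Sequence], method: str = "",
                      parameters: dict | None = None) -> "ClusterAssignment":
        labels: dict = {}
        for cid, cluster in enumerate(clusters):
            for node in cluster:
                if node in labels:
                    raise ValueError(f"node {node} appears in two clusters")
                labels[node] = cid
        return cls(labels=labels, method=method, parameters=parameters or {})


def correlation_to_affinity(matrix: np.ndarray) -> np.ndarray:
    """Map correlations in [-1, 1] to nonnegative affinities via (1 + c) / 2."""
    m = np.asarray(matrix, dtype=float)
    if m.min() >= 0:
        return m.copy()
    return (1.0 + m) / 2.0


def _eigengap_k(affinity: np.ndarray, k_max: int | None = None) -> int:
    """Eigengap heuristic on the normalized Laplacian: k = position of the
    largest gap in the ascending eigenvalue sequence."""
    n = affinity.shape[0]
    d = affinity.sum(axis=1)
    d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    lap = np.eye(n) - d_isqrt[:, None] * affinity * d_isqrt[None, :]
    ev = np.sort(np.linalg.eigvalsh((lap + lap.T) / 2.0))
    k_max = k_max or max(2, n // 2)
    gaps = np.diff(ev[: k_max + 1])
    return int(np.argmax(gaps[1:]) + 2)  # at least 2 clusters


def spectral_cluster(
    sim: SimilarityMatrix, k: int | str = "auto", seed: int = 0
) -> ClusterAssignment:
    """Spectral clustering of a similarity matrix.

    Negative entries (correlations) are shifted to affinities via
    (1 + c) / 2; the normalized-Laplacian embedding is clustered with
    k-means.  ``k="auto"`` picks k by the eigengap heuristic.
    """
    A = correlation_to_affinity(sim.matrix)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    if k == "auto":
        k = _eigengap_k(A)
    k = int(k)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = A.sum(axis=1)
    d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    lap = np.eye(n) - d_isqrt[:, None] * A * d_isqrt[None, :]
    ev, vec = np.linalg.eigh((lap + lap.T) / 2.0)
    emb = vec[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
    return ClusterAssignment(
        labels=dict(zip(sim.nodes, (int(x) for x in labels))),
        method="spectral",
        parameters={"k": k, "seed": seed},
    )


def mcl(sim: SimilarityMatrix | np.ndarray, cfg: MCLConfig = MCLConfig(),
        nodes: Sequence | None = None) -> ClusterAssignment:
    """Markov cluster algorithm on a nonnegative similarity matrix.

    The matrix is normalized to [0, 1], the diagonal set to ``loop_gain``
    when positive, columns made stochastic, then expansion (matrix square)
    and inflation (elementwise power + column renormalization) alternate,
    zeroing entries below ``zero_threshold``, until successive iterates
    differ by less than ``equal_threshold``.  Rows with mass (attractors)
    define the clusters; nodes sharing an attractor share a cluster.
    """
    if isinstance(sim, SimilarityMatrix):
        M = correlation_to_affinity(sim.matrix)
        nodes = list(sim.nodes)
    else:
        M = np.array(sim, dtype=float)
        nodes = list(nodes) if nodes is not None else list(range(M.shape[0]))
    if M.min() < 0:
        raise ValueError("MCL needs a nonnegative matrix")
    peak = M.max()
    if peak > 0:
        M = M / peak
    if cfg.loop_gain > 0:
        np.fill_diagonal(M, cfg.loop_gain)
    M[M <= cfg.zero_threshold] = 0.0
    M = _col_normalize(M)
    for _ in range(cfg.max_iter):
        prev = M
        M = M @ M                       # expansion
        M = np.power(M, cfg.inflation)  # inflation
        M[M <= cfg.zero_threshold] = 0.0
        M = _col_normalize(M)
        if np.max(np.abs(M - prev)) < cfg.equal_threshold:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {cfg.max_iter} iterations "
            f"(last delta {np.max(np.abs(M - prev)):.3e})"
        )
    # attractor rows -> clusters; union nodes that share any attractor
    n = M.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        members = np.nonzero(M[i] > cfg.zero_threshold)[0]
        for j in members[1:]:
            ri, rj = find(int(members[0])), find(int(j))
            if ri != rj:
                parent[rj] = ri
    roots = {}
    labels = {}
    for j in range(n):
        r = find(j)
        labels[nodes[j]] = roots.setdefault(r, len(roots))
    return ClusterAssignment(
        labels=labels, method="mcl",
        parameters={"inflation": cfg.inflation, "loop_gain": cfg.loop_gain},
    )


def _col_normalize(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=0, keepdims=True)
    out = np.divide(M, s, out=np.zeros_like(M), where=s > 0)
    # a column with no mass keeps its node on the diagonal (isolated)
    dead = np.nonzero(s.ravel() == 0)[0]
    out[dead, dead] = 1.0
    return out


def jaccard_clustering_similarity(A: ClusterAssignment, B: ClusterAssignment) -> float:
    """Average best-match Jaccard coefficient between two clusterings.

    1 iff the partitions are identical; symmetric in (A, B).
    """
    if A.nodes != B.nodes:
        raise ValueError("clusterings cover different node sets")
    ca, cb = A.clusters(), B.clusters()

    def best(x, others):
        return max(len(x & y) / len(x | y) for y in others)

    total = sum(best(x, cb) for x in ca) + sum(best(y, ca) for y in cb)
    return total / (len(ca) + len(cb))


# -- parameter sweeps -------------------------------------------------

@dataclass(frozen=True)
class ParamGrid:
    """Cartesian grid over named parameters with inclusive endpoints.

    ``axes`` maps parameter name -> (min, max, step); each axis contributes
    round((max - min) / step) + 1 values.  Combinations are enumerated in
    lexicographic order of the axes as given (last axis fastest).
    """

    axes: tuple = ()

    def __init__(self, axes: Mapping[str, tuple]):
        object.__setattr__(self, "axes", tuple((k, tuple(v)) for k, v in axes.items()))

    def values(self, name: str) -> np.ndarray:
        axes = dict(self.axes)
        lo, hi, step = axes[name]
        n = int(round((hi - lo) / step)) + 1
        return np.round(np.linspace(lo, hi, n), 12)

    @property
    def names(self) -> list[str]:
        return [k for k, _ in self.axes]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.values(k).size for k in self.names)

    @property
    def n_combinations(self) -> int:
        return int(np.prod(self.shape))

    def combination(self, index: int) -> dict:
        """The parameter dict at a flat combination index (row-major)."""
        if not 0 <= index < self.n_combinations:
            raise IndexError(f"combination index {index} out of range")
        idx = np.unravel_index(index, self.shape)
        return {k: float(self.values(k)[i]) for k, i in zip(self.names, idx)}

    def index_of(self, combo: Mapping[str, float]) -> int:
        """Inverse of :meth:`combination` (round-trip bijection)."""
        idx = []
        for k in self.names:
            vals = self.values(k)
            i = int(np.argmin(np.abs(vals - combo[k])))
            if abs(vals[i] - combo[k]) > 1e-9:
                raise ValueError(f"{combo[k]} is not on the {k} axis")
            idx.append(i)
        return int(np.ravel_multi_index(tuple(idx), self.shape))

    def __iter__(self):
        names = self.names
        for values in itertools.product(*(self.values(k) for k in names)):
            yield dict(zip(names, (float(v) for v in values)))


#: Grids reproducing the published sweep sizes (16 / 256 / 540 / 375).
GRID_PRESETS: dict[str, ParamGrid] = {
    "gm_2param": ParamGrid(
        {"rateA": (0.004, 0.016, 0.004), "rateI": (0.004, 0.016, 0.004)}
    ),
    "gm_4param": ParamGrid(
        {
            "rateA": (0.004, 0.016, 0.004),
            "rateI": (0.004, 0.016, 0.004),
            "muA": (0.004, 0.016, 0.004),
            "muI": (0.004, 0.016, 0.004),
        }
    ),
    "mm_540": ParamGrid(
        {"A": (10, 15, 1), "B": (13, 18, 1), "C": (8, 10, 1), "D": (0.2, 0.6, 0.1)}
    ),
    "mm_375": ParamGrid(
        {"A": (14, 18, 1), "B": (14, 18, 1), "C": (14, 18, 1), "D": (0.2, 0.6, 0.2)}
    ),
}


@dataclass
class SweepResult:
    """Everything a parameter sweep produced.

    ``clustering_similarity`` is the combinations-x-combinations matrix of
    pairwise average-Jaccard similarities between the per-combination
    region clusterings.
    """

    grid: ParamGrid
    combinations: list[dict]
    matrices: list[SimilarityMatrix]
    clusterings: list[ClusterAssignment]
    averaged: SimilarityMatrix
    clustering_similarity: np.ndarray
    failed: list[tuple[int, str]] = field(default_factory=list)


def run_sweep(
    grid: ParamGrid,
    model_factory: Callable[[dict], object],
    connectome: Connectome,
    init: np.ndarray,
    solver: SolverConfig,
    mode: str = "out_diffusion",
    statistic: str = "cross_correlation",
    clustering: str = "spectral",
    k: int | str = "auto",
    mcl_config: MCLConfig = MCLConfig(),
    transient: int | None = None,
) -> SweepResult:
    """Simulate every grid combination and compare the region clusterings.

    ``model_factory`` maps a parameter dict to a model parameter object
    (e.g. ``lambda p: replace(get_preset("gm_sweep"), **p)``).  Failed
    simulations (blow-up, domain errors) are recorded and excluded rather
    than fatal.
    """
    if statistic not in ("cross_correlation", "coactivation"):
        raise ValueError("statistic must be 'cross_correlation' or 'coactivation'")
    if clustering not in ("spectral", "mcl"):
        raise ValueError("clustering must be 'spectral' or 'mcl'")
    combos = list(grid)
    matrices: list[SimilarityMatrix] = []
    clusterings: list[ClusterAssignment] = []
    kept: list[dict] = []
    failed: list[tuple[int, str]] = []
    for i, combo in enumerate(combos):
        try:
            model = model_factory(combo)
            traj = integrate(model, connectome, init, solver, mode=mode)
            if statistic == "cross_correlation":
                simmat = cross_correlation_matrix(traj, transient=transient)
            else:
                simmat = coactivation_matrix(traj, transient=transient)
            if clustering == "spectral":
                ca = spectral_cluster(simmat, k=k, seed=solver.seed)
            else:
                ca = mcl(simmat, mcl_config)
        except Exception as exc:
            warnings.warn(f"combination {i} failed and is excluded: {exc}", stacklevel=2)
            failed.append((i, str(exc)))
            continue
        kept.append(combo)
        matrices.append(simmat)
        clusterings.append(ca)
    if not matrices:
        raise RuntimeError("every sweep combination failed")
    m = len(clusterings)
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            S[i, j] = S[j, i] = jaccard_clustering_similarity(clusterings[i], clusterings[j])
    return SweepResult(
        grid=grid,
        combinations=kept,
        matrices=matrices,
        clusterings=clusterings,
        averaged=average_similarity(matrices),
        clustering_similarity=S,
        failed=failed,
    )
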
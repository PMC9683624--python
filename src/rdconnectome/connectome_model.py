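"""Graph representation of a connectome and its diffusion coupling operator.

A connectome is a weighted directed graph whose nodes are brain regions.
Edge weights derive from ordinal tract-tracing categories (0 = absent/very
weak ... 4 = very strong) via an exponential transform, so that the
strongest category maps to weight 1.  The diffusion coupling operator ``L``
turns the graph into a mass-conserving transport operator: ``dU/dt = L @ U``
moves concentration along (or against) edge direction.

Euclidean distance between region centroids can be folded into the dynamics
by inserting relay nodes on edges; a chain of ``k`` relays delays signal
transfer the way a longer fiber tract would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Connectome",
    "CouplingMatrix",
    "DistanceExpansion",
    "COUPLING_MODES",
    "weight_from_category",
    "build_coupling",
    "distance_factor",
    "insert_distance_nodes",
    "contract_distance_nodes",
    "ORDINAL_CATEGORIES",
]

#: Ordinal weight-category vocabulary mapped onto the numeric scale [0, 4].
#: Fractional values ("weak-to-moderate") interpolate between anchors.
ORDINAL_CATEGORIES: dict[str, float] = {
    "absent": 0.0,
    "very weak": 0.5,
    "weak": 1.0,
    "weak to moderate": 1.5,
    "moderate": 2.0,
    "moderate to strong": 2.5,
    "strong": 3.0,
    "very strong": 4.0,
}

COUPLING_MODES = ("out_diffusion", "in_diffusion", "out_transpose", "in_transpose")


class ConnectomeError(ValueError):
    """Raised on invalid connectome structure or parameters."""


@dataclass
class Connectome:
    """A weighted directed graph of brain regions.

    Thin wrapper around :class:`networkx.DiGraph` that fixes a node order
    (needed for a stable adjacency matrix) and enforces the weight
    invariants (weights >= 0, unique node ids, no duplicate edges — the
    DiGraph itself guarantees the latter two).

    Node attributes: ``hemisphere`` ("L"/"R" or absent), ``centroid``
    (3-vector, mm).  Edge attributes: ``weight`` (nonnegative float),
    optional ``category`` (ordinal 0-4) and ``contralateral`` flag.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    name: str = ""
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Sequence[str] | None = None,
        name: str = "",
        allow_self_loops: bool = False,
    ) -> "Connectome":
        """Build from ``(source, target, weight)`` triples.

        ``nodes`` fixes the node order (and may include isolated nodes);
        otherwise nodes appear in edge order.
        """
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for e in edges:
            s, t, w = e[0], e[1], float(e[2])
            if g.has_edge(s, t):
                raise ConnectomeError(f"duplicate directed edge {s}->{t}")
            g.add_edge(s, t, weight=w)
        return cls(graph=g, name=name, allow_self_loops=allow_self_loops)

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        ids = list(self.graph.nodes)
        if len(ids) != len(set(ids)):
            raise ConnectomeError("node identifiers must be unique")
        for s, t, data in self.graph.edges(data=True):
            w = data.get("weight", 1.0)
            if not np.isfinite(w) or w < 0:
                raise ConnectomeError(f"edge {s}->{t} has invalid weight {w}")
            if s == t and not self.allow_self_loops:
                raise ConnectomeError(
                    f"self-loop {s}->{s} present but allow_self_loops is False"
                )

    # -- views --------------------------------------------------------
    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def index_of(self, node) -> int:
        return self.nodes.index(node)

    def adjacency(self) -> np.ndarray:
        """Dense adjacency ``W`` with ``W[i, j]`` = weight of edge i -> j."""
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, weight="weight")

    def edges(self, data: bool = True):
        return self.graph.edges(data=data)

    def copy(self) -> "Connectome":
        return Connectome(
            graph=self.graph.copy(), name=self.name, allow_self_loops=self.allow_self_loops
        )

    def apply_categories(self) -> "Connectome":
        """Set each edge weight from its ordinal ``category`` attribute."""
        c = self.copy()
        for s, t, data in c.graph.edges(data=True):
            if "category" in data:
                data["weight"] = weight_from_category(data["category"])
        return c


@dataclass
class CouplingMatrix:
    """The network diffusion operator L with ``dU/dt = L @ U``.

    In mass-conserving modes every column of L sums to zero, off-diagonal
    entries are nonnegative and diagonal entries nonpositive, so the total
    concentration ``sum(U)`` is invariant under pure diffusion.
    """

    matrix: np.ndarray
    mode: str
    nodes: list
    conserves_mass: bool = True

    def __matmul__(self, other):
        return self.matrix @ other

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def weight_from_category(x: float) -> float:
    """Exponential transform of an ordinal weight category.

    Maps a category ``x`` in [0, 4] to ``10**(-(16/49) * (x - 4)**2)``,
    i.e. into (0, 1] with the strongest category anchored at weight 1.
    Strictly increasing in x; fractional categories are allowed.
    """
    x = float(x)
    if not (0.0 <= x <= 4.0):
        raise ConnectomeError(f"ordinal category {x} outside [0, 4]")
    return float(10.0 ** (-(16.0 / 49.0) * (x - 4.0) ** 2))


def build_coupling(
    c: Connectome,
    mode: str = "out_diffusion",
    normalize: bool = False,
) -> CouplingMatrix:
    """Build the diffusion coupling operator for a connectome.

    Modes
    -----
    out_diffusion
        Flow follows edge direction: ``dU_i = sum_j w_ji U_j - U_i sum_j w_ij``
        (node i receives along its afferents, loses along its efferents).
        The default, matching signal flow along axonal direction.
    in_diffusion
        Flow against edge direction (roles of afferents/efferents swapped).
    out_transpose / in_transpose
        The same two operators built on the transposed adjacency.

    All four modes are mass conserving by construction (columns of L sum
    to zero).  ``normalize=True`` row-normalizes the adjacency first so
    every node has unit total out-rate (in-rate for the in_* modes).

    Self-loops are dropped: diffusion to self is a no-op.
    """
    if mode not in COUPLING_MODES:
        raise ConnectomeError(f"unknown coupling mode {mode!r}; choose from {COUPLING_MODES}")
    if c.n_nodes < 1:
        raise ConnectomeError("connectome has no nodes")
    W = c.adjacency()
    np.fill_diagonal(W, 0.0)
    if mode in ("out_transpose", "in_transpose"):
        W = W.T
    if mode in ("in_diffusion", "in_transpose"):
        W = W.T  # in-diffusion of W == out-diffusion of the reversed graph
    if normalize:
        out = W.sum(axis=1, keepdims=True)
        np.divide(W, out, out=W, where=out > 0)
    L = W.T - np.diag(W.sum(axis=1))
    return CouplingMatrix(matrix=L, mode=mode, nodes=c.nodes, conserves_mass=True)


def distance_factor(d: float, w: float, F1: float = 0.01, F2: float = 0.01, S: float = 1.0) -> float:
    """Distance/weight transform ``F1*d + F2/w + S``.

    ``d`` is the Euclidean centroid distance (mm) and ``w`` the transformed
    connection weight.  The result sets the number of relay nodes inserted
    on an edge (longer or weaker connections get more relays, hence more
    delay).
    """
    if w <= 0:
        raise ConnectomeError("distance_factor requires a positive weight")
    if d < 0:
        raise ConnectomeError("distance must be nonnegative")
    return F1 * d + F2 / w + S


@dataclass
class DistanceExpansion:
    """Bookkeeping for relay-node insertion on edges.

    ``relay_nodes`` maps each original edge to the ordered list of relay
    node ids inserted on it; ``original_edges`` stores the replaced
    ``(source, target, weight)`` triples so the expansion is invertible.
    """

    relay_nodes: dict[tuple, list]
    original_edges: dict[tuple, float]
    D: float
    theta: float

    @property
    def n_relays(self) -> int:
        return sum(len(v) for v in self.relay_nodes.values())


def insert_distance_nodes(
    c: Connectome,
    D: float,
    theta: float = 1.0,
    relay_counts: Mapping[tuple, int] | int = 1,
) -> tuple[Connectome, DistanceExpansion]:
    """Expand edges into relay chains encoding fiber-tract distance.

    An edge ``A -> B`` of weight ``e1`` with ``k >= 1`` relays becomes the
    chain ``A -> E_1 -> ... -> E_k -> B`` with rate ``D * e1`` into the
    first relay and ``theta * D * e1`` out of every relay, so that under
    out-diffusion coupling the chain integrates the three-node relay rate
    equations (dA/dt = -D e1 A, dE/dt = D e1 A - theta D e1 E,
    dB/dt = theta D e1 E) and their k-relay generalization.  ``k = 0``
    leaves the edge unchanged.  Mass on the chain is conserved.
    """
    if D <= 0 or theta <= 0:
        raise ConnectomeError("D and theta must be positive")
    counts: Mapping[tuple, int]
    if isinstance(relay_counts, int):
        counts = {(s, t): relay_counts for s, t, _ in c.edges()}
    else:
        counts = dict(relay_counts)
    g = c.graph.copy()
    relay_nodes: dict[tuple, list] = {}
    originals: dict[tuple, float] = {}
    for (s, t), k in counts.items():
        if k < 0 or k != int(k):
            raise ConnectomeError(f"relay count for edge {s}->{t} must be a nonnegative integer")
        k = int(k)
        if k == 0 or not g.has_edge(s, t):
            continue
        e1 = g.edges[s, t]["weight"]
        originals[(s, t)] = e1
        g.remove_edge(s, t)
        relays = [f"{s}->{t}#relay{i + 1}" for i in range(k)]
        relay_nodes[(s, t)] = relays
        chain = [s, *relays, t]
        g.add_edge(chain[0], chain[1], weight=D * e1, relay=True)
        for a, b in zip(chain[1:-1], chain[2:]):
            g.add_edge(a, b, weight=theta * D * e1, relay=True)
    expanded = Connectome(graph=g, name=c.name, allow_self_loops=c.allow_self_loops)
    return expanded, DistanceExpansion(
        relay_nodes=relay_nodes, original_edges=originals, D=D, theta=theta
    )


def contract_distance_nodes(c: Connectome, exp: DistanceExpansion) -> Connectome:
    """Invert :func:`insert_distance_nodes`, restoring the original edges."""
    g = c.graph.copy()
    for (s, t), relays in exp.relay_nodes.items():
        g.remove_nodes_from(relays)
        g.add_edge(s, t, weight=exp.original_edges[(s, t)])
    return Connectome(graph=g, name=c.name, allow_self_loops=c.allow_self_loops)
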
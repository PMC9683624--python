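"""Synthetic networks: surrogate graphs, 2D lattices, and a bilateral
mechanosensory fixture connectome.

The fixture emulates the bilateral mechanosensory subconnectome (20 named
regions per hemisphere): dorsal root ganglia project ipsilaterally onto the
cuneate nucleus, which relays contralaterally to the ventrolateral /
ventroposterolateral thalamus, which projects on to the ipsilateral primary
somatosensory cortex, all embedded in seeded random cortico-cortical and
thalamo-cortical background connectivity.  Its weights are synthetic
stand-ins (ordinal categories drawn with a fixed seed), not the published
tract-tracing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome_model import Connectome, weight_from_category

__all__ = [
    "LatticeSpec",
    "build_lattice",
    "generate_surrogate",
    "surrogate_like",
    "mechanosensory_fixture",
    "MECHANOSENSORY_REGIONS",
    "SURROGATE_KINDS",
]

#: The 20 region abbreviations of the mechanosensory subconnectome.
MECHANOSENSORY_REGIONS = (
    "AGl",    # lateral agranular prefrontal cortex
    "AGm",    # medial agranular prefrontal cortex
    "CERC",   # cerebellar cortex
    "Cu",     # cuneate nucleus
    "DCeN",   # cerebellar nuclei
    "DRGC1",  # dorsal root ganglion, cervical segment 1
    "DRGC2",
    "DRGC3",
    "Gr",     # gracile nucleus
    "ILN",    # intralaminar nuclei
    "IO",     # inferior olive
    "LTNG",   # lateral thalamic nuclear group
    "mPFC",   # medial prefrontal cortex
    "Pn",     # pontine nuclei
    "PTG",    # posterior group
    "S1",     # primary somatosensory cortex
    "S2",     # secondary somatosensory cortex
    "VL",     # ventrolateral thalamic nucleus
    "VNT",    # ventral thalamus
    "VPL",    # ventral posterolateral thalamic nucleus
)

SURROGATE_KINDS = (
    "erdos_renyi",
    "watts_strogatz",
    "barabasi_albert",
    "rewiring",
    "klemm_eguiluz",
)


@dataclass
class LatticeSpec:
    """Regular 2D lattice: `boundary` is periodic or reflecting; the
    neighborhood is 4 (von Neumann) or 8 (Moore)."""

    width: int
    height: int
    boundary: str = "reflecting"
    neighborhood: int = 4

    def __post_init__(self):
        if self.width < 2 or self.height < 2:
            raise ValueError("lattice must be at least 2x2")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError("boundary must be 'periodic' or 'reflecting'")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")


def build_lattice(spec: LatticeSpec) -> Connectome:
    """Grid graph whose out-diffusion coupling discretizes the 2D Laplacian.

    Edges are bidirectional pairs of weight 1 (lattice diffusion is
    undirected); node ids are ``"x,y"`` strings in row-major order.
    """
    w, h = spec.width, spec.height
    offsets = [(1, 0), (0, 1)]
    if spec.neighborhood == 8:
        offsets += [(1, 1), (1, -1)]
    g = nx.DiGraph()
    for y in range(h):
        for x in range(w):
            g.add_node(f"{x},{y}", x=float(x), y=float(y))
    for y in range(h):
        for x in range(w):
            for dx, dy in offsets:
                nx_, ny_ = x + dx, y + dy
                if spec.boundary == "periodic":
                    nx_, ny_ = nx_ % w, ny_ % h
                elif not (0 <= nx_ < w and 0 <= ny_ < h):
                    continue
                a, b = f"{x},{y}", f"{nx_},{ny_}"
                if a == b:
                    continue
                g.add_edge(a, b, weight=1.0)
                g.add_edge(b, a, weight=1.0)
    return Connectome(graph=g, name=f"lattice_{w}x{h}_{spec.boundary}")


def generate_surrogate(
    kind: str,
    n_nodes: int | None = None,
    n_edges: int | None = None,
    seed: int = 0,
    directed: bool = True,
    template: Connectome | None = None,
    **params,
) -> Connectome:
    """Random surrogate networks with matched node/edge budgets.

    kinds: ``erdos_renyi`` (uniform edges; `p` or `n_edges`),
    ``watts_strogatz`` (small world; `k`, `p`), ``barabasi_albert``
    (scale free; `m`), ``rewiring`` (degree-preserving double-edge swaps
    of `template`; `n_swaps`), ``klemm_eguiluz`` (growing scale free with
    deactivation; `m`, `mu`).

    Undirected generator output (WS, BA, KE) is converted to directed
    bidirectional edge pairs; all edges get weight 1 except rewiring,
    which carries the template weights along with the swapped edges.
    """
    if kind not in SURROGATE_KINDS:
        raise ValueError(f"unknown surrogate kind {kind!r}; choose from {SURROGATE_KINDS}")
    rng = np.random.default_rng(seed)

    if kind == "rewiring":
        if template is None:
            raise ValueError("rewiring needs a template connectome")
        return _rewire(template, rng, n_swaps=params.get("n_swaps", 10 * template.n_edges))

    if n_nodes is None or n_nodes < 2:
        raise ValueError("n_nodes >= 2 required")

    if kind == "erdos_renyi":
        if n_edges is not None:
            g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)),
                                    directed=directed)
        else:
            p = params.get("p")
            if p is None:
                raise ValueError("erdos_renyi needs p or n_edges")
            g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)),
                                    directed=directed)
        g = g.to_directed(as_view=False) if not g.is_directed() else g
    elif kind == "watts_strogatz":
        k = params.get("k", max(2, 2 * ((n_edges or 2 * n_nodes) // (2 * n_nodes))))
        p = params.get("p", 0.1)
        g = nx.watts_strogatz_graph(n_nodes, k, p, seed=int(rng.integers(2**31)))
        g = g.to_directed(as_view=False)
    elif kind == "barabasi_albert":
        m = params.get("m", max(1, (n_edges or 2 * n_nodes) // (2 * n_nodes)))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
        g = g.to_directed(as_view=False)
    else:  # klemm_eguiluz
        m = params.get("m", 3)
        mu = params.get("mu", 0.1)
        g = _klemm_eguiluz(n_nodes, m, mu, rng).to_directed(as_view=False)

    out = nx.DiGraph()
    out.add_nodes_from(range(n_nodes))
    for s, t in g.edges():
        if s != t:
            out.add_edge(s, t, weight=1.0)
    return Connectome(graph=out, name=f"{kind}_n{n_nodes}_seed{seed}")


def surrogate_like(template: Connectome, kind: str, seed: int = 0, **params) -> Connectome:
    """Surrogate with the template's node and (approximate) edge count.

    ``rewiring`` preserves both exactly (and the degree sequences);
    ``erdos_renyi`` matches the edge count exactly; the growth models
    match it as closely as their mechanisms allow.
    """
    if kind == "rewiring":
        return generate_surrogate(kind, seed=seed, template=template, **params)
    return generate_surrogate(
        kind, n_nodes=template.n_nodes, n_edges=template.n_edges, seed=seed, **params
    )


def _rewire(template: Connectome, rng: np.random.Generator, n_swaps: int) -> Connectome:
    """Directed degree-preserving double-edge swaps.

    Picks edge pairs (a->b, c->d) and rewires to (a->d, c->b) when neither
    new edge exists nor creates a self-loop, preserving every node's in-
    and out-degree exactly.  Weights travel with the source endpoint.
    """
    g = template.graph.copy()
    edges = list(g.edges())
    attempts = 0
    swaps = 0
    max_attempts = 50 * n_swaps
    while swaps < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(len(edges)), rng.integers(len(edges))
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if a == d or c == b or g.has_edge(a, d) or g.has_edge(c, b):
            continue
        w_ab = g.edges[a, b]["weight"]
        w_cd = g.edges[c, d]["weight"]
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, weight=w_ab)
        g.add_edge(c, b, weight=w_cd)
        edges[i], edges[j] = (a, d), (c, b)
        swaps += 1
    return Connectome(graph=g, name=f"{template.name}_rewired")


def _klemm_eguiluz(n: int, m: int, mu: float, rng: np.random.Generator) -> nx.Graph:
    """Klemm-Eguiluz growing scale-free network with an active-node list.

    Starts from a complete graph on m active nodes; each new node links to
    the m active nodes (each link redirected to a random node with
    probability mu), becomes active, and deactivates one active node
    chosen with probability inversely proportional to its degree.
    """
    if n <= m:
        raise ValueError("klemm_eguiluz needs n_nodes > m")
    g = nx.complete_graph(m)
    active = list(range(m))
    for new in range(m, n):
        g.add_node(new)
        targets = set()
        for a in active:
            t = a
            if rng.random() < mu:
                others = [v for v in g.nodes if v != new and v not in targets]
                t = others[rng.integers(len(others))]
            if t not in targets and t != new:
                targets.add(t)
        for t in targets:
            g.add_edge(new, t)
        active.append(new)
        inv_deg = np.array([1.0 / max(g.degree(a), 1) for a in active])
        drop = rng.choice(len(active), p=inv_deg / inv_deg.sum())
        active.pop(drop)
    return g


def mechanosensory_fixture(seed: int = 0) -> Connectome:
    """Synthetic bilateral mechanosensory subconnectome (40 nodes).

    The 20 regions x {L, R} carry the mechanosensory chain
    DRGC1-3 -> ipsilateral Cu -> contralateral VL/VPL -> ipsilateral-to-
    thalamus S1, plus seeded random cortico-cortical / thalamo-cortical
    background edges.  DRG nodes have no afferents (pseudounipolar sensory
    origin).  Every edge carries an ordinal weight category (its weight is
    the exponential transform of the category) and a ``contralateral``
    flag; nodes carry hemisphere and a synthetic stereotaxic centroid.
    """
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    for region in MECHANOSENSORY_REGIONS:
        for hemi, sign in (("L", -1.0), ("R", 1.0)):
            # synthetic centroid: mediolateral offset by hemisphere,
            # rostrocaudal/vertical jittered per region for distances
            base = rng.normal(0.0, 3.0, size=2)
            g.add_node(
                f"{region}_{hemi}",
                hemisphere=hemi,
                centroid=(sign * float(rng.uniform(1.0, 4.0)), float(base[0]), float(base[1])),
            )

    def add(s, t, category, contralateral=False):
        if g.has_edge(s, t):
            return
        g.add_edge(
            s, t,
            category=float(category),
            weight=weight_from_category(category),
            contralateral=bool(contralateral),
        )

    # -- the mechanosensory pathway, both hemispheres -----------------
    for side, other in (("L", "R"), ("R", "L")):
        for drg in ("DRGC1", "DRGC2", "DRGC3"):
            add(f"{drg}_{side}", f"Cu_{side}", 4)            # ipsilateral
        for thal in ("VL", "VPL"):
            add(f"Cu_{side}", f"{thal}_{other}", 4, True)    # decussation
            add(f"{thal}_{other}", f"S1_{other}", 4)         # thalamo-cortical

    # -- seeded background connectivity -------------------------------
    cortical = ("AGl", "AGm", "mPFC", "S1", "S2")
    thalamic = ("ILN", "LTNG", "PTG", "VL", "VNT", "VPL")
    precerebellar = ("Pn", "IO", "Gr", "Cu")
    drg = ("DRGC1", "DRGC2", "DRGC3")
    for side in ("L", "R"):
        other = "R" if side == "L" else "L"
        # cortico-cortical (ipsi- and contralateral homotopic)
        for a in cortical:
            for b in cortical:
                if a != b and rng.random() < 0.5:
                    add(f"{a}_{side}", f"{b}_{side}", rng.integers(1, 5))
            add(f"{a}_{side}", f"{a}_{other}", rng.integers(1, 4), True)
        # thalamo-cortical and cortico-thalamic
        for t in thalamic:
            for c in cortical:
                if rng.random() < 0.35:
                    add(f"{t}_{side}", f"{c}_{side}", rng.integers(1, 5))
                if rng.random() < 0.35:
                    add(f"{c}_{side}", f"{t}_{side}", rng.integers(1, 5))
        # precerebellar / cerebellar loop
        add(f"Gr_{side}", f"VPL_{other}", 3, True)
        add(f"Pn_{side}", f"CERC_{other}", 3, True)
        add(f"IO_{side}", f"CERC_{other}", 3, True)
        add(f"CERC_{side}", f"DCeN_{side}", 4)
        add(f"DCeN_{side}", f"VL_{other}", 3, True)
        add(f"Cu_{side}", f"CERC_{side}", 2)
        for a in precerebellar:
            for b in precerebellar:
                if a != b and rng.random() < 0.25:
                    add(f"{a}_{side}", f"{b}_{side}", rng.integers(1, 4))

    # DRG nodes are pure sources: drop any accidental afferent
    for d in drg:
        for side in ("L", "R"):
            g.remove_edges_from(list(g.in_edges(f"{d}_{side}")))

    return Connectome(graph=g, name=f"mechanosensory_fixture_seed{seed}")
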
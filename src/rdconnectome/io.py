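"""Readers and writers for connectomes, trajectories and matrices.

Formats: edge-list CSV (``source,target,weight[,category]``), node CSV
(``id,hemisphere,x,y,z``), adjacency TSV with node-id header row/column,
GraphML, long-format trajectory TSV (``time, node, species, value``) with
a JSON metadata sidecar, and a JSON run manifest for provenance.

CSV dialect: comma-separated, UTF-8, ``#`` comment lines; adjacency and
matrix files are tab-separated.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .analysis import SimilarityMatrix
from .connectome_model import Connectome, ConnectomeError
from .dynamics import Trajectory

__all__ = [
    "read_connectome",
    "write_connectome",
    "read_edgelist_csv",
    "write_edgelist_csv",
    "read_node_csv",
    "write_node_csv",
    "read_adjacency_tsv",
    "write_adjacency_tsv",
    "read_graphml",
    "write_graphml",
    "write_trajectory",
    "read_trajectory",
    "write_matrix",
    "read_matrix",
    "write_manifest",
]

_FORMATS = ("edgelist", "adjacency", "graphml")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".tsv":
        return "adjacency"
    return "edgelist"


def read_connectome(path, fmt: str | None = None, node_csv=None) -> Connectome:
    """Read a connectome; the format is inferred from the suffix unless given."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise ConnectomeError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    if fmt == "graphml":
        c = read_graphml(path)
    elif fmt == "adjacency":
        c = read_adjacency_tsv(path)
    else:
        c = read_edgelist_csv(path)
    if node_csv is not None:
        read_node_csv(node_csv, into=c)
    return c


def write_connectome(c: Connectome, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "graphml":
        write_graphml(c, path)
    elif fmt == "adjacency":
        write_adjacency_tsv(c, path)
    else:
        write_edgelist_csv(c, path)


# -- edge-list CSV ----------------------------------------------------

def read_edgelist_csv(path) -> Connectome:
    """``source,target,weight[,category]`` rows; '#' lines are comments."""
    path = Path(path)
    g = nx.DiGraph()
    problems = []
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "source":
                continue
            if len(row) < 3:
                problems.append(f"line {lineno}: expected >= 3 fields, found {len(row)}")
                continue
            s, t = row[0].strip(), row[1].strip()
            try:
                w = float(row[2])
            except ValueError:
                problems.append(f"line {lineno}: weight {row[2]!r} is not a number")
                continue
            if w < 0:
                problems.append(f"line {lineno}: negative weight {w}")
                continue
            if g.has_edge(s, t):
                problems.append(f"line {lineno}: duplicate edge {s}->{t}")
                continue
            attrs = {"weight": w}
            if len(row) >= 4 and row[3].strip():
                attrs["category"] = float(row[3])
            g.add_edge(s, t, **attrs)
    if problems:
        raise ConnectomeError("invalid edge list:\n  " + "\n  ".join(problems))
    return Connectome(graph=g, name=path.stem)


def write_edgelist_csv(c: Connectome, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(["source", "target", "weight", "category"])
        for s, t, data in c.edges():
            wr.writerow(
                [s, t, repr(data.get("weight", 1.0)), data.get("category", "")]
            )


# -- node metadata CSV ------------------------------------------------

def read_node_csv(path, into: Connectome | None = None) -> Connectome:
    """``id,hemisphere,x,y,z`` rows; attaches attributes to ``into`` if given."""
    path = Path(path)
    g = into.graph if into is not None else nx.DiGraph()
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "id":
                continue
            node = row[0].strip()
            if into is not None and node not in g:
                raise ConnectomeError(f"line {lineno}: unknown node {node!r}")
            attrs = {}
            if len(row) > 1 and row[1].strip():
                attrs["hemisphere"] = row[1].strip()
            if len(row) >= 5 and all(v.strip() for v in row[2:5]):
                attrs["centroid"] = tuple(float(v) for v in row[2:5])
            g.add_node(node, **attrs)
    return into if into is not None else Connectome(graph=g, name=path.stem)


def write_node_csv(c: Connectome, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "hemisphere", "x", "y", "z"])
        for n, data in c.graph.nodes(data=True):
            cen = data.get("centroid", ("", "", ""))
            wr.writerow([n, data.get("hemisphere", ""), *cen])


# -- adjacency TSV ----------------------------------------------------

def read_adjacency_tsv(path) -> Connectome:
    """Tab-separated adjacency with node ids on the header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.columns = [str(col) for col in df.columns]
    df.index = [str(ix) for ix in df.index]
    if list(df.columns) != list(df.index):
        raise ConnectomeError("adjacency header row and column disagree")
    g = nx.DiGraph()
    g.add_nodes_from(df.index)
    W = df.to_numpy(dtype=float)
    if np.any(W < 0):
        raise ConnectomeError("negative weights in adjacency matrix")
    nodes = list(df.index)
    for i, s in enumerate(nodes):
        for j, t in enumerate(nodes):
            if W[i, j] != 0:
                g.add_edge(s, t, weight=float(W[i, j]))
    return Connectome(graph=g, name=Path(path).stem)


def write_adjacency_tsv(c: Connectome, path) -> None:
    W = c.adjacency()
    pd.DataFrame(W, index=c.nodes, columns=c.nodes).to_csv(path, sep="\t")


# -- GraphML ----------------------------------------------------------

def write_graphml(c: Connectome, path) -> None:
    g = c.graph.copy()
    for _, data in g.nodes(data=True):
        cen = data.pop("centroid", None)
        if cen is not None:
            data["x"], data["y"], data["z"] = (float(v) for v in cen)
    nx.write_graphml(g, path)


def read_graphml(path) -> Connectome:
    g = nx.read_graphml(path)
    if not g.is_directed():
        g = g.to_directed(as_view=False)
    out = nx.DiGraph()
    for n, data in g.nodes(data=True):
        attrs = dict(data)
        if all(k in attrs for k in ("x", "y", "z")):
            attrs["centroid"] = (float(attrs.pop("x")), float(attrs.pop("y")),
                                 float(attrs.pop("z")))
        out.add_node(n, **attrs)
    for s, t, data in g.edges(data=True):
        out.add_edge(s, t, **{k: v for k, v in data.items()})
    return Connectome(graph=out, name=Path(path).stem)


# -- trajectories and matrices ----------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Long-format TSV (time, node, species, value) + JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for si, sp in enumerate(traj.species):
        for ni, node in enumerate(traj.nodes):
            rows.append(
                pd.DataFrame(
                    {
                        "time": traj.times,
                        "node": node,
                        "species": sp,
                        "value": traj.states[si, ni],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(traj.metadata, indent=2, default=str))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    species = tuple(dict.fromkeys(df["species"]))
    nodes = list(dict.fromkeys(df["node"]))
    times = np.sort(df["time"].unique())
    states = np.empty((len(species), len(nodes), times.size))
    pivot = df.pivot_table(index=["species", "node"], columns="time", values="value")
    for si, sp in enumerate(species):
        for ni, node in enumerate(nodes):
            states[si, ni] = pivot.loc[(sp, node)].to_numpy()
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trajectory(times=times, states=states, species=species, nodes=nodes,
                      metadata=meta)


def write_matrix(m: SimilarityMatrix, path) -> None:
    pd.DataFrame(m.matrix, index=m.nodes, columns=m.nodes).to_csv(path, sep="\t")


def read_matrix(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(
        matrix=df.to_numpy(dtype=float), nodes=[str(ix) for ix in df.index],
        statistic=Path(path).stem,
    )


def write_manifest(path, config: dict, seed: int | None = None) -> dict:
    """Write a reproducibility manifest (config + hash + version) as JSON."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package": "rdconnectome",
        "version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
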
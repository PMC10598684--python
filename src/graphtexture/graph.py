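"""Node-weighted graph data model, validation, I/O and first-order summaries.

The central object is :class:`NodeWeightedGraph`: a simple (no self-loops,
no duplicate edges), optionally directed graph whose edges are *unweighted*
and whose nodes each carry one scalar weight or ordered categorical code.
Edges may additionally carry a categorical label (e.g. ``"activation"`` /
``"repression"``) so that separate co-occurrence matrices can be built per
interaction type.

First-order summary statistics (node/edge counts, degrees, diameter, path
length, density) depend only on topology; they are deliberately blind to any
permutation of the node weights, which is the motivating contrast with the
texture features built on top of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GraphValidationError",
    "NodeWeightedGraph",
    "GraphSummary",
    "read_edge_list",
    "write_edge_list",
    "read_weight_table",
    "write_weight_table",
    "attach_weights",
    "read_graphml",
    "write_graphml",
    "summary_statistics",
    "grid_graph_from_matrix",
]


class GraphValidationError(ValueError):
    """Raised when a graph violates the node-weighted graph invariants."""


@dataclass(frozen=True)
class NodeWeightedGraph:
    """A simple graph with one scalar weight per node and unweighted edges.

    Parameters
    ----------
    nodes
        Node identifiers (opaque strings).
    edges
        ``(source, target)`` pairs.  For undirected graphs the orientation is
        irrelevant; duplicates (including reversed duplicates) are removed
        with a warning at construction.
    directed
        Whether edges are directed.
    edge_categories
        Optional per-edge categorical labels, aligned with ``edges``.
    weights
        Optional mapping node -> real weight (or ordered level code).  When
        present it must cover every node exactly.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    directed: bool = False
    edge_categories: Optional[tuple[str, ...]] = None
    weights: Optional[Mapping[str, float]] = None

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        directed: bool = False,
        edge_categories: Optional[Sequence[str]] = None,
        weights: Optional[Mapping[str, float]] = None,
    ) -> None:
        nodes = tuple(str(n) for n in nodes)
        raw_edges = [(str(u), str(v)) for u, v in edges]
        cats = list(edge_categories) if edge_categories is not None else None
        if cats is not None and len(cats) != len(raw_edges):
            raise GraphValidationError(
                f"{len(cats)} edge categories for {len(raw_edges)} edges"
            )

        node_set = set(nodes)
        if len(node_set) != len(nodes):
            raise GraphValidationError("duplicate node identifiers")
        for u, v in raw_edges:
            if u not in node_set or v not in node_set:
                raise GraphValidationError(
                    f"edge ({u}, {v}) references an undeclared node"
                )
            if u == v:
                raise GraphValidationError(f"self-loop on node {u!r} is not allowed")

        # Deduplicate; an undirected edge is identified by its unordered pair.
        seen: dict[tuple[str, str], int] = {}
        kept_edges: list[tuple[str, str]] = []
        kept_cats: list[str] = []
        dropped = 0
        for idx, (u, v) in enumerate(raw_edges):
            key = (u, v) if directed else (min(u, v), max(u, v))
            if key in seen:
                dropped += 1
                continue
            seen[key] = idx
            kept_edges.append((u, v))
            if cats is not None:
                kept_cats.append(str(cats[idx]))
        if dropped:
            warnings.warn(
                f"removed {dropped} duplicate edge(s)", UserWarning, stacklevel=2
            )

        if weights is not None:
            weights = {str(k): float(v) for k, v in dict(weights).items()}
            missing = sorted(node_set - weights.keys())
            if missing:
                raise GraphValidationError(
                    "nodes missing a weight: " + ", ".join(missing)
                )
            extra = sorted(weights.keys() - node_set)
            if extra:
                raise GraphValidationError(
                    "weights for undeclared nodes: " + ", ".join(extra)
                )

        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", tuple(kept_edges))
        object.__setattr__(self, "directed", bool(directed))
        object.__setattr__(
            self, "edge_categories", tuple(kept_cats) if cats is not None else None
        )
        object.__setattr__(self, "weights", weights)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def has_weights(self) -> bool:
        return self.weights is not None

    def weight_array(self, nodes: Optional[Sequence[str]] = None) -> np.ndarray:
        """Weights in the order of ``nodes`` (default: declared node order)."""
        if self.weights is None:
            raise GraphValidationError("graph has no node weights attached")
        order = self.nodes if nodes is None else nodes
        return np.asarray([self.weights[n] for n in order], dtype=float)

    def with_weights(self, weights: Mapping[str, float]) -> "NodeWeightedGraph":
        """Return a copy of this graph with ``weights`` as its node weights."""
        return NodeWeightedGraph(
            self.nodes,
            self.edges,
            directed=self.directed,
            edge_categories=self.edge_categories,
            weights=weights,
        )

    def to_networkx(self) -> "nx.Graph | nx.DiGraph":
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for idx, (u, v) in enumerate(self.edges):
            attrs = {}
            if self.edge_categories is not None:
                attrs["category"] = self.edge_categories[idx]
            g.add_edge(u, v, **attrs)
        if self.weights is not None:
            nx.set_node_attributes(g, dict(self.weights), "weight")
        return g

    @classmethod
    def from_networkx(
        cls, g: "nx.Graph | nx.DiGraph", weight_key: Optional[str] = "weight"
    ) -> "NodeWeightedGraph":
        nodes = [str(n) for n in g.nodes]
        edges = [(str(u), str(v)) for u, v in g.edges]
        cats = None
        if any("category" in d for _, _, d in g.edges(data=True)):
            cats = [str(d.get("category", "")) for _, _, d in g.edges(data=True)]
        weights = None
        if weight_key is not None:
            attr = nx.get_node_attributes(g, weight_key)
            if attr:
                missing = [str(n) for n in g.nodes if n not in attr]
                if missing:
                    raise GraphValidationError(
                        f"nodes missing {weight_key!r} attribute: "
                        + ", ".join(sorted(missing))
                    )
                weights = {str(k): float(v) for k, v in attr.items()}
        return cls(
            nodes,
            edges,
            directed=g.is_directed(),
            edge_categories=cats,
            weights=weights,
        )


@dataclass(frozen=True)
class GraphSummary:
    """First-order (weight-blind) summary statistics of a graph.

    ``diameter`` and ``mean_path_length`` are ``None`` on disconnected
    graphs — an explicit undefined marker rather than infinity.
    """

    n_nodes: int
    n_edges: int
    max_degree: int
    min_degree: int
    mean_degree: float
    diameter: Optional[int]
    mean_path_length: Optional[float]
    edge_density: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_nodes": self.n_nodes,
                "n_edges": self.n_edges,
                "max_degree": self.max_degree,
                "min_degree": self.min_degree,
                "mean_degree": self.mean_degree,
                "diameter": np.nan if self.diameter is None else self.diameter,
                "mean_path_length": (
                    np.nan if self.mean_path_length is None else self.mean_path_length
                ),
                "edge_density": self.edge_density,
            }
        )


# ----------------------------------------------------------------------
# I/O


def read_edge_list(path, directed: bool = False) -> NodeWeightedGraph:
    """Read a TSV/CSV edge list with columns source, target[, category].

    A header row is required.  Tab is the default separator; a comma is
    accepted.  Duplicate edges are removed with a warning; self-loops raise
    :class:`GraphValidationError` naming the offending row.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GraphValidationError(f"could not parse edge list {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "source" not in cols or "target" not in cols:
        raise GraphValidationError(
            f"{path}: edge list requires 'source' and 'target' columns, got {cols}"
        )
    bad = df.index[df["source"].isna() | df["target"].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise GraphValidationError(
            f"{path}: malformed row at line {int(bad[0]) + 2} (missing endpoint)"
        )
    loops = df.index[df["source"] == df["target"]]
    if len(loops):
        raise GraphValidationError(
            f"{path}: self-loop at line {int(loops[0]) + 2} "
            f"({df.loc[loops[0], 'source']})"
        )
    edges = list(zip(df["source"], df["target"]))
    cats = list(df["category"]) if "category" in cols else None
    nodes = sorted(set(df["source"]) | set(df["target"]))
    return NodeWeightedGraph(nodes, edges, directed=directed, edge_categories=cats)


def write_edge_list(graph: NodeWeightedGraph, path) -> None:
    """Write the edge list as TSV (inverse of :func:`read_edge_list`)."""
    data = {"source": [u for u, _ in graph.edges], "target": [v for _, v in graph.edges]}
    if graph.edge_categories is not None:
        data["category"] = list(graph.edge_categories)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_weight_table(path) -> dict[str, float]:
    """Read a node-weight CSV with header ``node,weight``."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "node" not in df.columns or "weight" not in df.columns:
        raise GraphValidationError(
            f"{path}: weight table requires 'node' and 'weight' columns"
        )
    return {str(n): float(w) for n, w in zip(df["node"], df["weight"])}


def write_weight_table(graph: NodeWeightedGraph, path) -> None:
    if graph.weights is None:
        raise GraphValidationError("graph has no weights to write")
    pd.DataFrame(
        {"node": list(graph.nodes), "weight": [graph.weights[n] for n in graph.nodes]}
    ).to_csv(path, index=False)


def attach_weights(
    graph: NodeWeightedGraph, table: Mapping[str, float]
) -> NodeWeightedGraph:
    """Attach a node->weight table to a graph.

    Every graph node must appear in the table; nodes present only in the
    table are added as isolated nodes with a warning (they contribute nothing
    to co-occurrence).
    """
    table = {str(k): float(v) for k, v in dict(table).items()}
    missing = sorted(set(graph.nodes) - table.keys())
    if missing:
        raise GraphValidationError(
            "weight table missing node(s): " + ", ".join(missing)
        )
    extra = sorted(table.keys() - set(graph.nodes))
    nodes = list(graph.nodes)
    if extra:
        warnings.warn(
            f"adding {len(extra)} isolated node(s) present only in the weight "
            f"table: {', '.join(extra)}",
            UserWarning,
            stacklevel=2,
        )
        nodes.extend(extra)
    return NodeWeightedGraph(
        nodes,
        graph.edges,
        directed=graph.directed,
        edge_categories=graph.edge_categories,
        weights=table,
    )


def read_graphml(path, weight_key: str = "weight") -> NodeWeightedGraph:
    """Read a GraphML file; node weights come from ``weight_key``.

    Equivalent to :func:`read_edge_list` followed by :func:`attach_weights`.
    Raises if any node lacks the weight attribute (pass ``weight_key=None``
    to read topology only).
    """
    g = nx.read_graphml(path)
    if weight_key is not None:
        attr = nx.get_node_attributes(g, weight_key)
        missing = [str(n) for n in g.nodes if n not in attr]
        if missing:
            raise GraphValidationError(
                f"{path}: node(s) missing weight attribute {weight_key!r}: "
                + ", ".join(sorted(missing))
            )
    return NodeWeightedGraph.from_networkx(g, weight_key=weight_key)


def write_graphml(graph: NodeWeightedGraph, path, weight_key: str = "weight") -> None:
    g = graph.to_networkx()
    if graph.weights is not None and weight_key != "weight":
        nx.set_node_attributes(g, dict(graph.weights), weight_key)
    nx.write_graphml(g, path)


# ----------------------------------------------------------------------
# Summaries and constructors


def summary_statistics(graph: NodeWeightedGraph) -> GraphSummary:
    """First-order topology summary; invariant to any weight permutation."""
    g = graph.to_networkx()
    if graph.directed:
        und = g.to_undirected()
    else:
        und = g
    degrees = np.asarray([d for _, d in und.degree()], dtype=int)
    n, m = graph.n_nodes, graph.n_edges
    if n == 0:
        raise GraphValidationError("empty graph")
    connected = n == 1 or nx.is_connected(und)
    if connected and n > 1:
        diameter: Optional[int] = nx.diameter(und)
        mpl: Optional[float] = nx.average_shortest_path_length(und)
    elif connected:
        diameter, mpl = 0, 0.0
    else:
        diameter, mpl = None, None
    density = 0.0 if n < 2 else m / (n * (n - 1) / 2 if not graph.directed else n * (n - 1))
    return GraphSummary(
        n_nodes=n,
        n_edges=m,
        max_degree=int(degrees.max()) if n else 0,
        min_degree=int(degrees.min()) if n else 0,
        mean_degree=float(degrees.mean()) if n else 0.0,
        diameter=diameter,
        mean_path_length=mpl,
        edge_density=float(density),
    )


def grid_graph_from_matrix(values) -> NodeWeightedGraph:
    """Build the 4-neighbourhood grid graph of a 2D array.

    One node per cell, named ``r{i}c{j}``, weighted by the cell value, with
    undirected edges between horizontally and vertically adjacent cells.
    An r x c matrix yields r*c nodes and r(c-1) + c(r-1) edges.  This is the
    bridge between the graph co-occurrence matrix and the classical image
    GLCM: the grid graph's undirected co-occurrence matrix equals the
    symmetric image GLCM summed over unit offsets (0,1) and (1,0).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise GraphValidationError("grid_graph_from_matrix requires a non-empty 2D array")
    r, c = arr.shape
    name = lambda i, j: f"r{i}c{j}"  # noqa: E731
    nodes = [name(i, j) for i in range(r) for j in range(c)]
    edges = []
    for i in range(r):
        for j in range(c):
            if j + 1 < c:
                edges.append((name(i, j), name(i, j + 1)))
            if i + 1 < r:
                edges.append((name(i, j), name(i + 1, j)))
    weights = {name(i, j): float(arr[i, j]) for i in range(r) for j in range(c)}
    return NodeWeightedGraph(nodes, edges, directed=False, weights=weights)
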
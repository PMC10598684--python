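"""Graph co-occurrence matrices — the GLCM analogue for node-weighted graphs.

For a graph whose nodes carry integer levels ``1..Ng``, the co-occurrence
matrix ``C`` counts how often a node of level ``i`` shares an edge with a
node of level ``j``.  In undirected mode every edge contributes *both*
ordered pairs (i,j) and (j,i), the symmetric-GLCM convention, so the matrix
is symmetric and sums to ``2|E|``; in directed mode each edge contributes a
single source->target pair and the total is ``|E|``.  An optional edge
category restricts counting to matching edges, so e.g. activation and
repression interactions of one regulatory network yield two separate
matrices.

Normalising ``C`` by its total gives the joint probability matrix ``p(i,j)``
with marginals ``px``/``py`` and their moments — the object on which every
texture feature is defined.  Levels absent from the graph still occupy their
row/column (contrast-type features depend on level spacing), and the matrix
is indexed by the integer level values themselves, 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .discretize import DiscretizationScheme, apply_scheme, fit_scheme
from .graph import GraphValidationError, NodeWeightedGraph

__all__ = [
    "CooccurrenceMatrix",
    "ProbabilityMatrix",
    "count_cooccurrence",
    "normalize",
    "cooccurrence_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Ng x Ng integer counts of neighbouring level pairs."""

    levels: tuple[int, ...]
    counts: np.ndarray
    mode: str
    category: Optional[str] = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.levels), columns=list(self.levels))


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Joint probability matrix p(i,j) with marginals and moments.

    ``mu_x``, ``sigma_x`` are the mean and standard deviation of the row
    marginal ``px`` over the integer level values (likewise for columns).
    For a symmetric matrix the x and y moments coincide.
    """

    levels: tuple[int, ...]
    p: np.ndarray
    mode: str = "undirected"
    category: Optional[str] = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def level_values(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=float)

    @property
    def px(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def mu_x(self) -> float:
        return float(np.dot(self.level_values, self.px))

    @property
    def mu_y(self) -> float:
        return float(np.dot(self.level_values, self.py))

    @property
    def sigma_x(self) -> float:
        i = self.level_values
        return float(np.sqrt(np.dot((i - self.mu_x) ** 2, self.px)))

    @property
    def sigma_y(self) -> float:
        j = self.level_values
        return float(np.sqrt(np.dot((j - self.mu_y) ** 2, self.py)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=list(self.levels), columns=list(self.levels))


def _integer_levels(graph: NodeWeightedGraph) -> dict[str, int]:
    if graph.weights is None:
        raise GraphValidationError("graph has no node weights attached")
    out: dict[str, int] = {}
    for node, w in graph.weights.items():
        if not float(w).is_integer() or w < 1:
            raise GraphValidationError(
                f"node {node!r} has non-integer weight {w!r}: discretize the "
                "weights into levels 1..Ng first (see graphtexture.discretize)"
            )
        out[node] = int(w)
    return out


def count_cooccurrence(
    graph: NodeWeightedGraph,
    mode: Optional[str] = None,
    category: Optional[str] = None,
    n_levels: Optional[int] = None,
) -> CooccurrenceMatrix:
    """Count neighbouring level pairs over the edges of a level-coded graph.

    Parameters
    ----------
    graph
        Graph whose weights are integer levels in ``1..Ng``.
    mode
        ``"directed"`` or ``"undirected"``; defaults to the graph's own
        directedness.  Requesting undirected counting on a directed graph
        symmetrises the edges; requesting directed counting on an undirected
        graph is an error (the orientation would be arbitrary).
    category
        Restrict counting to edges carrying this category label.
    n_levels
        Matrix dimension Ng; defaults to the maximum level present.  Levels
        never observed still occupy their row/column.
    """
    levels_by_node = _integer_levels(graph)
    if mode is None:
        mode = "directed" if graph.directed else "undirected"
    if mode not in ("directed", "undirected"):
        raise ValueError("mode must be 'directed' or 'undirected'")
    if mode == "directed" and not graph.directed:
        raise GraphValidationError(
            "directed counting on an undirected graph is ambiguous"
        )

    edges = graph.edges
    if category is not None:
        if graph.edge_categories is None:
            raise GraphValidationError("graph has no edge categories")
        known = sorted(set(graph.edge_categories))
        if category not in known:
            raise GraphValidationError(
                f"unknown edge category {category!r}; known: {', '.join(known)}"
            )
        edges = tuple(
            e for e, c in zip(graph.edges, graph.edge_categories) if c == category
        )

    ng = max(levels_by_node.values()) if n_levels is None else int(n_levels)
    if any(l > ng for l in levels_by_node.values()):
        raise GraphValidationError("a node level exceeds n_levels")
    counts = np.zeros((ng, ng), dtype=np.int64)
    for u, v in edges:
        i, j = levels_by_node[u] - 1, levels_by_node[v] - 1
        counts[i, j] += 1
        if mode == "undirected":
            counts[j, i] += 1
    return CooccurrenceMatrix(
        levels=tuple(range(1, ng + 1)), counts=counts, mode=mode, category=category
    )


def normalize(matrix: CooccurrenceMatrix) -> ProbabilityMatrix:
    """Normalise counts to the joint probability matrix p = C / sum(C)."""
    total = matrix.counts.sum()
    if total == 0:
        raise GraphValidationError("graph has no usable edges")
    return ProbabilityMatrix(
        levels=matrix.levels,
        p=matrix.counts.astype(float) / float(total),
        mode=matrix.mode,
        category=matrix.category,
    )


class PipelineResult(NamedTuple):
    """Discretize -> count -> normalise, with the fitted scheme for provenance."""

    probability: ProbabilityMatrix
    cooccurrence: CooccurrenceMatrix
    scheme: DiscretizationScheme


def cooccurrence_pipeline(
    graph: NodeWeightedGraph,
    n_levels: int = 4,
    method: str = "equal",
    mode: Optional[str] = None,
    category: Optional[str] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Full pipeline from continuous node weights to a probability matrix.

    Fits the discretization scheme on the graph's own weights, applies it,
    counts co-occurrence and normalises.  The default of four levels with
    equal-width binning mirrors common usage on fitness landscapes and
    expression networks.
    """
    if graph.weights is None:
        raise GraphValidationError("graph has no node weights attached")
    values = graph.weight_array()
    scheme = fit_scheme(values, n_levels, method=method, seed=seed)
    codes = apply_scheme(scheme, values)
    coded = graph.with_weights(dict(zip(graph.nodes, (int(c) for c in codes))))
    cm = count_cooccurrence(coded, mode=mode, category=category, n_levels=n_levels)
    return PipelineResult(probability=normalize(cm), cooccurrence=cm, scheme=scheme)
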
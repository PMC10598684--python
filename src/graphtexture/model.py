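"""Model/Results surface tying the pipeline together.

:class:`GraphTexture` is built from a node-weighted graph plus the analysis
choices (number of levels, discretization method, counting mode, optional
edge category); :meth:`GraphTexture.fit` runs discretize -> count ->
normalise -> features and returns a :class:`GraphTextureResults` carrying
the feature estimates, the fitted scheme, both matrices, and diagnostic
baselines (permutation and bootstrap label resampling) that quantify how
far each feature sits from its label-randomised null.

Example
-------
>>> from graphtexture import landscapes
>>> from graphtexture.model import GraphTexture
>>> land = landscapes.make_eggbox(4)
>>> res = GraphTexture(land.to_graph(), n_levels=4, method="equal").fit()
>>> round(res.features["contrast"], 3)
9.0
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .cooccurrence import cooccurrence_pipeline
from .graph import NodeWeightedGraph, attach_weights
from .texture import FEATURE_NAMES, compute_all

__all__ = ["GraphTexture", "GraphTextureResults"]


class GraphTexture:
    """Texture-feature model of one node-weighted graph.

    Parameters
    ----------
    graph
        Graph with node weights attached (continuous or already level-coded;
        continuous weights are discretized at fit time).
    n_levels
        Number of ordered levels Ng (default 4).
    method
        Discretization scheme: ``"equal"``, ``"quantile"`` or ``"kmeans"``.
    mode
        ``"directed"`` / ``"undirected"`` counting; defaults to the graph's
        own directedness.
    category
        Optional edge-category filter (e.g. count only activation edges).
    log_base
        Entropy logarithm base; natural log when None.
    """

    def __init__(
        self,
        graph: NodeWeightedGraph,
        n_levels: int = 4,
        method: str = "equal",
        mode: Optional[str] = None,
        category: Optional[str] = None,
        log_base: Optional[float] = None,
        seed: Optional[int] = None,
    ) -> None:
        if graph.weights is None:
            raise ValueError("GraphTexture requires a graph with node weights")
        self.graph = graph
        self.n_levels = int(n_levels)
        self.method = method
        self.mode = mode
        self.category = category
        self.log_base = log_base
        self.seed = seed

    @classmethod
    def from_dataframes(
        cls,
        edges: pd.DataFrame,
        weights: "pd.DataFrame | Mapping[str, float]",
        directed: bool = False,
        **kwargs,
    ) -> "GraphTexture":
        """Build from an edge table (source, target[, category]) and a weight
        table (node, weight) or mapping."""
        cats = list(edges["category"]) if "category" in edges.columns else None
        graph = NodeWeightedGraph(
            sorted(set(edges["source"].astype(str)) | set(edges["target"].astype(str))),
            list(zip(edges["source"].astype(str), edges["target"].astype(str))),
            directed=directed,
            edge_categories=cats,
        )
        if isinstance(weights, pd.DataFrame):
            weights = {str(n): float(w) for n, w in zip(weights["node"], weights["weight"])}
        graph = attach_weights(graph, weights)
        return cls(graph, **kwargs)

    def fit(self) -> "GraphTextureResults":
        """Run the discretize -> co-occurrence -> texture pipeline."""
        result = cooccurrence_pipeline(
            self.graph,
            n_levels=self.n_levels,
            method=self.method,
            mode=self.mode,
            category=self.category,
            seed=self.seed,
        )
        features = compute_all(
            result.probability, log_base=self.log_base, scheme_method=self.method
        )
        return GraphTextureResults(self, result, features)


class GraphTextureResults:
    """Fitted texture features with provenance and baseline diagnostics."""

    def __init__(self, model, pipeline_result, feature_vector):
        self.model = model
        self.scheme = pipeline_result.scheme
        self.cooccurrence = pipeline_result.cooccurrence
        self.probability = pipeline_result.probability
        self.feature_vector = feature_vector
        self.features = feature_vector.to_series()

    # statsmodels-flavoured alias
    @property
    def params(self) -> pd.Series:
        return self.features

    def _baseline(self, perturb, n_draws: int, seed: Optional[int]) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n_draws):
            g = perturb(self.model.graph, int(rng.integers(2**31 - 1)))
            res = GraphTexture(
                g,
                n_levels=self.model.n_levels,
                method=self.model.method,
                mode=self.model.mode,
                category=self.model.category,
                log_base=self.model.log_base,
            ).fit()
            rows.append(res.features)
        return pd.DataFrame(rows).reset_index(drop=True)

    def permutation_baseline(
        self, n_permutations: int = 100, seed: Optional[int] = None
    ) -> pd.DataFrame:
        """Feature distribution under uniform random label permutation."""
        return self._baseline(synthetic.permute_labels, n_permutations, seed)

    def bootstrap_baseline(
        self, n_resamples: int = 100, seed: Optional[int] = None
    ) -> pd.DataFrame:
        """Feature distribution under with-replacement label resampling."""
        return self._baseline(synthetic.bootstrap_labels, n_resamples, seed)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        g = self.model.graph
        lines = [
            "Graph texture features",
            "=" * 54,
            f"nodes: {g.n_nodes}    edges: {g.n_edges}    "
            f"mode: {self.probability.mode}",
            f"levels: {self.model.n_levels} ({self.model.method})"
            + (f"    category: {self.model.category}" if self.model.category else ""),
            "-" * 54,
        ]
        for name in FEATURE_NAMES:
            val = self.features[name]
            shown = "undefined" if pd.isna(val) else f"{val: .6f}"
            lines.append(f"{name:<26s}{shown:>20s}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<GraphTextureResults: {self.model.graph.n_nodes} nodes, Ng={self.model.n_levels}>"
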
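"""Model fitness landscapes on genotype hypercubes.

A fitness landscape over ``L`` biallelic loci assigns a fitness value to
each of the ``2^L`` genotypes (bitstrings).  Genotypes at Hamming distance 1
are connected — a single mutational step — so the wiring diagram is the
L-dimensional hypercube with ``L * 2^(L-1)`` edges.  Converting a landscape
to a :class:`~graphtexture.graph.NodeWeightedGraph` (fitness as node weight)
feeds it straight into the co-occurrence / texture pipeline.

Generators
----------
additive
    fitness(g) = base + sum_k effects[k] * g_k.  Smooth and monotone; the
    fitness change across any edge equals the effect of the flipped locus.
eggbox
    Two fitness values only (base and base + height) alternating with the
    parity of the number of 1-alleles, so every mutation crosses between
    them and neighbouring genotypes never share a fitness.
house_of_cards (HOC)
    i.i.d. fitness per genotype — the classical random/null landscape.
NK
    Kauffman's tunably rugged model: each locus contributes a uniform(0,1)
    table value indexed by its own allele and those of its K neighbours
    (adjacent loci with wraparound by default); fitness is the mean
    contribution.  K=0 is purely additive; K=N-1 is HOC-like.

:func:`roughness_slope_ratio` is the classical ruggedness baseline: the RMS
residual of the best least-squares additive fit, divided by the mean
absolute fitted locus effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .graph import NodeWeightedGraph

__all__ = [
    "FitnessLandscape",
    "hypercube_graph",
    "make_additive",
    "make_eggbox",
    "make_hoc",
    "make_nk",
    "roughness_slope_ratio",
    "landscape_to_graph",
    "read_landscape_csv",
    "write_landscape_csv",
]

_MAX_LOCI = 20


def _genotypes(L: int) -> list[str]:
    return [format(i, f"0{L}b") for i in range(2**L)]


@dataclass(frozen=True)
class FitnessLandscape:
    """``2^L`` genotypes with one finite fitness value each."""

    n_loci: int
    fitness: Mapping[str, float]

    def __post_init__(self):
        L = self.n_loci
        if not 1 <= L <= _MAX_LOCI:
            raise ValueError(f"n_loci must be in 1..{_MAX_LOCI}")
        expected = _genotypes(L)
        if set(self.fitness.keys()) != set(expected):
            raise ValueError(f"fitness must cover exactly the {2**L} genotypes")
        vals = np.asarray([self.fitness[g] for g in expected], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("fitness values must be finite")

    @property
    def genotypes(self) -> list[str]:
        return _genotypes(self.n_loci)

    def fitness_array(self) -> np.ndarray:
        return np.asarray([self.fitness[g] for g in self.genotypes], dtype=float)

    def to_graph(self) -> NodeWeightedGraph:
        return landscape_to_graph(self)


def hypercube_graph(L: int) -> NodeWeightedGraph:
    """The genotype hypercube: ``2^L`` bitstring nodes, Hamming-1 edges."""
    if not 1 <= L <= _MAX_LOCI:
        raise ValueError(f"L must be in 1..{_MAX_LOCI}")
    nodes = _genotypes(L)
    edges = []
    for i in range(2**L):
        for k in range(L):
            j = i ^ (1 << k)
            if j > i:
                edges.append((format(i, f"0{L}b"), format(j, f"0{L}b")))
    return NodeWeightedGraph(nodes, edges, directed=False)


def make_additive(
    L: int,
    effects: Optional[Sequence[float]] = None,
    base: float = 1.0,
    seed: Optional[int] = None,
) -> FitnessLandscape:
    """Additive landscape: fitness(g) = base + sum_k effects[k] * g_k.

    If ``effects`` is omitted, L effects are drawn with magnitudes
    uniform(0.05, 0.3) and random sign (seeded).
    """
    if effects is None:
        rng = np.random.default_rng(seed)
        mags = rng.uniform(0.05, 0.3, size=L)
        signs = rng.choice([-1.0, 1.0], size=L)
        effects = mags * signs
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (L,):
        raise ValueError(f"effects must have length {L}")
    fit = {}
    for g in _genotypes(L):
        bits = np.frombuffer(g.encode(), dtype=np.uint8) - ord("0")
        fit[g] = float(base + np.dot(effects, bits))
    return FitnessLandscape(n_loci=L, fitness=fit)


def make_eggbox(L: int, base: float = 1.0, height: float = 1.0) -> FitnessLandscape:
    """Eggbox landscape: fitness alternates with the parity of 1-alleles."""
    if height <= 0:
        raise ValueError("height must be positive")
    fit = {g: base + height * (g.count("1") % 2) for g in _genotypes(L)}
    return FitnessLandscape(n_loci=L, fitness=fit)


def make_hoc(
    L: int,
    seed: Optional[int] = None,
    low: float = 0.0,
    high: float = 1.0,
) -> FitnessLandscape:
    """House-of-Cards landscape: i.i.d. uniform(low, high) genotype fitnesses."""
    rng = np.random.default_rng(seed)
    draws = rng.uniform(low, high, size=2**L)
    fit = {g: float(x) for g, x in zip(_genotypes(L), draws)}
    return FitnessLandscape(n_loci=L, fitness=fit)


def make_nk(
    N: int,
    K: int,
    seed: Optional[int] = None,
    neighborhood: str = "adjacent",
) -> FitnessLandscape:
    """Kauffman NK landscape with tunable epistasis.

    Each locus ``k`` has a contribution table of ``2^(K+1)`` i.i.d.
    uniform(0,1) values, indexed by the alleles of the locus and its K
    neighbours; fitness is the arithmetic mean of the N contributions.
    Neighbourhoods are adjacent loci with wraparound by default;
    ``neighborhood="random"`` draws K distinct random partners per locus.
    """
    if not 0 <= K <= N - 1:
        raise ValueError("K must satisfy 0 <= K <= N-1")
    rng = np.random.default_rng(seed)
    tables = rng.uniform(0.0, 1.0, size=(N, 2 ** (K + 1)))
    if neighborhood == "adjacent":
        neigh = [[(k + d) % N for d in range(1, K + 1)] for k in range(N)]
    elif neighborhood == "random":
        neigh = [
            list(rng.choice([x for x in range(N) if x != k], size=K, replace=False))
            for k in range(N)
        ]
    else:
        raise ValueError("neighborhood must be 'adjacent' or 'random'")
    fit = {}
    for g in _genotypes(N):
        bits = [int(b) for b in g]
        total = 0.0
        for k in range(N):
            idx = bits[k]
            for d, nb in enumerate(neigh[k], start=1):
                idx |= bits[nb] << d
            total += tables[k, idx]
        fit[g] = total / N
    return FitnessLandscape(n_loci=N, fitness=fit)


def additive_fit(landscape: FitnessLandscape):
    """Least-squares additive fit: intercept, per-locus effects, residuals."""
    L = landscape.n_loci
    gts = landscape.genotypes
    X = np.ones((2**L, L + 1))
    for r, g in enumerate(gts):
        for k, b in enumerate(g):
            X[r, k + 1] = int(b)
    y = landscape.fitness_array()
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef[0], coef[1:], resid


def roughness_slope_ratio(landscape: FitnessLandscape) -> float:
    """Roughness:slope ruggedness of a landscape.

    Roughness is the RMS residual of the best least-squares additive model;
    slope is the mean absolute fitted locus effect.  Purely additive
    landscapes score 0.  NaN (undefined) is returned when the fitted slope
    is zero — e.g. a constant landscape, or an eggbox, whose parity symmetry
    forces every fitted locus effect to zero.
    """
    _, effects, resid = additive_fit(landscape)
    roughness = float(np.sqrt(np.mean(resid**2)))
    slope = float(np.mean(np.abs(effects)))
    if slope < 1e-12:
        return float("nan")
    return roughness / slope


def landscape_to_graph(landscape: FitnessLandscape) -> NodeWeightedGraph:
    """Hypercube graph with fitness as node weights, pipeline-ready."""
    g = hypercube_graph(landscape.n_loci)
    return g.with_weights(dict(landscape.fitness))


def read_landscape_csv(path) -> FitnessLandscape:
    """Read a landscape CSV with columns ``genotype,fitness``."""
    df = pd.read_csv(path, dtype={"genotype": str})
    df.columns = [c.strip().lower() for c in df.columns]
    if "genotype" not in df.columns or "fitness" not in df.columns:
        raise ValueError(f"{path}: landscape CSV requires 'genotype' and 'fitness'")
    gts = [str(g) for g in df["genotype"]]
    L = len(gts[0])
    fit = {g: float(f) for g, f in zip(gts, df["fitness"])}
    return FitnessLandscape(n_loci=L, fitness=fit)


def write_landscape_csv(landscape: FitnessLandscape, path) -> None:
    pd.DataFrame(
        {
            "genotype": landscape.genotypes,
            "fitness": [landscape.fitness[g] for g in landscape.genotypes],
        }
    ).to_csv(path, index=False)
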
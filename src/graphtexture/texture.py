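"""Haralick-style texture features of a graph co-occurrence matrix.

All features are statistics of the normalised joint probability matrix
``p(i,j)`` over integer level values ``i, j = 1..Ng``:

==========================  ====================================================
energy                      sum p(i,j)^2  (angular second moment)
contrast                    sum (i-j)^2 p(i,j)
correlation                 (sum i*j*p(i,j) - mu_x mu_y) / (sigma_x sigma_y)
variance                    sum (i - mu_x)^2 p(i,j)  ("sum of squares")
inverse_difference_moment   sum p(i,j) / (1 + (i-j)^2)
entropy                     -sum p log p  (natural log by default; 0 log 0 = 0)
max_probability             max p(i,j)
autocorrelation             sum i*j*p(i,j)
homogeneity                 sum p(i,j) / (1 + |i-j|)
dissimilarity               sum |i-j| p(i,j)
cluster_shade               sum (i + j - mu_x - mu_y)^3 p(i,j)
cluster_prominence          sum (i + j - mu_x - mu_y)^4 p(i,j)
==========================  ====================================================

``correlation`` is undefined when either marginal is degenerate
(sigma_x * sigma_y = 0); it is returned as NaN — a flagged value, not an
exception — so group scaling can skip it.

For comparing feature sets across groups of graphs,
:func:`scale_across_group` applies per-feature min-max scaling to [0, 1];
features with zero range across the group map to 0 and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import ProbabilityMatrix

__all__ = [
    "FEATURE_NAMES",
    "TextureFeatureVector",
    "energy",
    "contrast",
    "correlation",
    "entropy",
    "variance",
    "inverse_difference_moment",
    "max_probability",
    "autocorrelation",
    "homogeneity",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "secondary_features",
    "compute_all",
    "scale_across_group",
]

FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "entropy",
    "max_probability",
    "autocorrelation",
    "homogeneity",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
)


def _grids(P: ProbabilityMatrix):
    i = P.level_values
    return np.meshgrid(i, i, indexing="ij")


def energy(P: ProbabilityMatrix) -> float:
    return float(np.sum(P.p**2))


def contrast(P: ProbabilityMatrix) -> float:
    I, J = _grids(P)
    return float(np.sum((I - J) ** 2 * P.p))


def correlation(P: ProbabilityMatrix) -> float:
    """Linear dependence between neighbouring levels; NaN if a marginal is degenerate."""
    sx, sy = P.sigma_x, P.sigma_y
    # tolerance catches marginals degenerate up to floating-point rounding
    if sx < 1e-10 or sy < 1e-10:
        return float("nan")
    I, J = _grids(P)
    return float((np.sum(I * J * P.p) - P.mu_x * P.mu_y) / (sx * sy))


def entropy(P: ProbabilityMatrix, base: Optional[float] = None) -> float:
    """Shannon entropy of p(i,j); natural log unless ``base`` is given."""
    p = P.p[P.p > 0]
    h = float(-np.sum(p * np.log(p)))
    if base is not None:
        h /= math.log(base)
    return h


def variance(P: ProbabilityMatrix) -> float:
    """Sum of squares: variance of levels about mu_x under p(i,j)."""
    I, _ = _grids(P)
    return float(np.sum((I - P.mu_x) ** 2 * P.p))


def inverse_difference_moment(P: ProbabilityMatrix) -> float:
    I, J = _grids(P)
    return float(np.sum(P.p / (1.0 + (I - J) ** 2)))


def max_probability(P: ProbabilityMatrix) -> float:
    return float(P.p.max())


def autocorrelation(P: ProbabilityMatrix) -> float:
    I, J = _grids(P)
    return float(np.sum(I * J * P.p))


def homogeneity(P: ProbabilityMatrix) -> float:
    I, J = _grids(P)
    return float(np.sum(P.p / (1.0 + np.abs(I - J))))


def dissimilarity(P: ProbabilityMatrix) -> float:
    I, J = _grids(P)
    return float(np.sum(np.abs(I - J) * P.p))


def cluster_shade(P: ProbabilityMatrix) -> float:
    I, J = _grids(P)
    return float(np.sum((I + J - P.mu_x - P.mu_y) ** 3 * P.p))


def cluster_prominence(P: ProbabilityMatrix) -> float:
    I, J = _grids(P)
    return float(np.sum((I + J - P.mu_x - P.mu_y) ** 4 * P.p))


def secondary_features(P: ProbabilityMatrix) -> dict[str, float]:
    """The features beyond energy/contrast/correlation/entropy, as a dict."""
    return {
        "variance": variance(P),
        "inverse_difference_moment": inverse_difference_moment(P),
        "max_probability": max_probability(P),
        "autocorrelation": autocorrelation(P),
        "homogeneity": homogeneity(P),
        "dissimilarity": dissimilarity(P),
        "cluster_shade": cluster_shade(P),
        "cluster_prominence": cluster_prominence(P),
    }


@dataclass(frozen=True)
class TextureFeatureVector:
    """All twelve texture features of one probability matrix, with provenance."""

    energy: float
    contrast: float
    correlation: float
    variance: float
    inverse_difference_moment: float
    entropy: float
    max_probability: float
    autocorrelation: float
    homogeneity: float
    dissimilarity: float
    cluster_shade: float
    cluster_prominence: float
    n_levels: Optional[int] = None
    mode: Optional[str] = None
    scheme_method: Optional[str] = None

    def to_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in FEATURE_NAMES})

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def compute_all(
    P: ProbabilityMatrix,
    log_base: Optional[float] = None,
    scheme_method: Optional[str] = None,
) -> TextureFeatureVector:
    """Compute the full texture feature vector of a probability matrix."""
    return TextureFeatureVector(
        energy=energy(P),
        contrast=contrast(P),
        correlation=correlation(P),
        entropy=entropy(P, base=log_base),
        n_levels=P.n_levels,
        mode=P.mode,
        scheme_method=scheme_method,
        **secondary_features(P),
    )


def scale_across_group(
    vectors: "Sequence[TextureFeatureVector] | pd.DataFrame",
    method: str = "minmax",
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each feature across a group of graphs for comparison.

    Min-max scaling to [0, 1] is the default; ``method="zscore"`` centres and
    scales instead.  Features constant across the group map to 0 and are
    flagged; NaN entries (undefined correlations) are excluded from the
    scaling statistics and stay NaN.

    Returns
    -------
    scaled : DataFrame
        One row per input vector, one column per feature.
    zero_range : Series of bool
        Per-feature flag, True where the group had zero range (or zero
        standard deviation for z-scoring).
    """
    if isinstance(vectors, pd.DataFrame):
        df = vectors.loc[:, [c for c in FEATURE_NAMES if c in vectors.columns]].astype(float)
    else:
        vectors = list(vectors)
        if len(vectors) < 2:
            raise ValueError("group scaling requires at least two feature vectors")
        df = pd.DataFrame([v.to_dict() for v in vectors])
    if method == "minmax":
        lo, hi = df.min(skipna=True), df.max(skipna=True)
        rng = hi - lo
        flags = (rng == 0) | rng.isna()
        safe = rng.replace(0, np.nan)
        scaled = (df - lo) / safe
    elif method == "zscore":
        mu, sd = df.mean(skipna=True), df.std(skipna=True, ddof=0)
        flags = (sd == 0) | sd.isna()
        scaled = (df - mu) / sd.replace(0, np.nan)
    else:
        raise ValueError("method must be 'minmax' or 'zscore'")
    # zero-range features: defined entries collapse to 0, NaNs stay NaN
    for col in df.columns[flags]:
        scaled[col] = np.where(df[col].notna(), 0.0, np.nan)
    return scaled, flags
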
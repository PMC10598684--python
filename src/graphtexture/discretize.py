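"""Discretization of continuous node weights into Ng ordered levels.

This is the gray-level reduction step of the image-texture analogy: before a
co-occurrence matrix can be counted, continuous node weights (expression,
fitness, growth rate, ...) are mapped to a small number of ordered integer
levels ``1..Ng``.  Three schemes are provided:

``equal``
    Ng equal-width intervals spanning [min, max] of the fitted values.
    Intervals are left-closed/right-open, except the top interval which is
    closed, so every fitted value maps to a level.
``quantile``
    Ng groups holding (as nearly as possible) equal numbers of values, cut
    at type-7 (linear interpolation) sample quantiles.  All copies of a tied
    value share one level; a value equal to a cut point joins the lower
    level.
``kmeans``
    Exact 1D k-means: the partition of the sorted values into Ng contiguous
    groups minimising within-cluster sum of squares, found by dynamic
    programming rather than a random-restart heuristic, so the result is
    deterministic.  Ties at cluster midpoints break toward the lower level.

All three maps are monotone: v1 <= v2 implies level(v1) <= level(v2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DiscretizationScheme",
    "fit_equal",
    "fit_quantile",
    "fit_kmeans",
    "apply_scheme",
    "fit_scheme",
]

_METHODS = ("equal", "quantile", "kmeans")


@dataclass(frozen=True)
class DiscretizationScheme:
    """A fitted binning of real values into ordered levels ``1..n_levels``.

    ``cuts`` are the interior cut points separating adjacent levels (for
    kmeans they are midpoints between consecutive cluster centers).  ``side``
    records the closure convention: ``"right"`` means a value equal to a cut
    goes to the upper level ([lo, hi) bins, used by ``equal``); ``"left"``
    means it stays in the lower level ((lo, hi] bins, used by ``quantile``
    and ``kmeans``).
    """

    method: str
    n_levels: int
    cuts: tuple[float, ...]
    side: str
    fitted_min: float
    fitted_max: float
    centers: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cut points must be strictly increasing")

    # JSON round-trip for reproducibility manifests -------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "n_levels": self.n_levels,
                "cuts": list(self.cuts),
                "side": self.side,
                "fitted_min": self.fitted_min,
                "fitted_max": self.fitted_max,
                "centers": None if self.centers is None else list(self.centers),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        d = json.loads(text)
        return cls(
            method=d["method"],
            n_levels=int(d["n_levels"]),
            cuts=tuple(d["cuts"]),
            side=d["side"],
            fitted_min=float(d["fitted_min"]),
            fitted_max=float(d["fitted_max"]),
            centers=None if d.get("centers") is None else tuple(d["centers"]),
        )

    def apply(self, values) -> np.ndarray:
        return apply_scheme(self, values)


def _check_values(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("at least one value is required")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be discretized")
    return v


def fit_equal(values, n_levels: int) -> DiscretizationScheme:
    """Fit ``n_levels`` equal-width bins spanning [min, max] of the data."""
    v = _check_values(values)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        if n_levels > 1:
            warnings.warn(
                "constant values: all map to level 1", UserWarning, stacklevel=2
            )
        cuts: tuple[float, ...] = ()
    else:
        cuts = tuple(np.linspace(lo, hi, n_levels + 1)[1:-1])
    return DiscretizationScheme(
        method="equal", n_levels=n_levels, cuts=cuts, side="right",
        fitted_min=lo, fitted_max=hi,
    )


def fit_quantile(values, n_levels: int) -> DiscretizationScheme:
    """Fit ``n_levels`` equal-count bins at type-7 sample quantiles."""
    v = _check_values(values)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo and n_levels > 1:
        warnings.warn("constant values: all map to level 1", UserWarning, stacklevel=2)
        cuts: tuple[float, ...] = ()
    else:
        probs = np.arange(1, n_levels) / n_levels
        q = np.quantile(v, probs)  # linear interpolation = R type 7
        cuts = tuple(np.unique(q))
        if len(cuts) < n_levels - 1:
            warnings.warn(
                "tied quantiles: fewer effective levels than requested",
                UserWarning,
                stacklevel=2,
            )
    return DiscretizationScheme(
        method="quantile", n_levels=n_levels, cuts=cuts, side="left",
        fitted_min=lo, fitted_max=hi,
    )


def _kmeans_1d_exact(u: np.ndarray, w: np.ndarray, k: int):
    """Optimal 1D k-means of unique values ``u`` with counts ``w``.

    Dynamic program over contiguous groups of the sorted values (optimal 1D
    clusters are intervals).  Returns (assignment per unique value, centers).
    O(k * m^2) with prefix sums; m is the number of unique values.
    """
    m = len(u)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwu = np.concatenate([[0.0], np.cumsum(w * u)])
    cwu2 = np.concatenate([[0.0], np.cumsum(w * u * u)])

    def cost(i, j):  # WCSS of u[i:j]
        n = cw[j] - cw[i]
        s = cwu[j] - cwu[i]
        s2 = cwu2[j] - cwu2[i]
        return s2 - s * s / n

    INF = np.inf
    D = np.full((k + 1, m + 1), INF)
    B = np.zeros((k + 1, m + 1), dtype=int)
    D[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, m + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                val = D[c - 1, i] + cost(i, j)
                if val < best - 1e-15:
                    best, arg = val, i
            D[c, j] = best
            B[c, j] = arg
    # backtrack
    bounds = [m]
    j = m
    for c in range(k, 0, -1):
        j = B[c, j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bk = m
    assign = np.empty(m, dtype=int)
    centers = []
    for c in range(k):
        i, j = bounds[c], bounds[c + 1]
        assign[i:j] = c + 1
        centers.append((cwu[j] - cwu[i]) / (cw[j] - cw[i]))
    return assign, np.asarray(centers)


def fit_kmeans(values, n_levels: int, seed: Optional[int] = None) -> DiscretizationScheme:
    """Fit levels by exact 1D k-means (dynamic programming).

    ``seed`` is accepted for interface symmetry with the other stochastic
    operations but the fit is deterministic.  If the data have fewer distinct
    values than ``n_levels`` the fit falls back to one level per distinct
    value with a warning.
    """
    del seed  # exact DP solution; no randomness involved
    v = _check_values(values)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    u, w = np.unique(v, return_counts=True)
    k = n_levels
    if len(u) < k:
        warnings.warn(
            f"only {len(u)} distinct values for k={k}: one level per value",
            UserWarning,
            stacklevel=2,
        )
        k = len(u)
    _, centers = _kmeans_1d_exact(u, w.astype(float), k)
    cuts = tuple((centers[:-1] + centers[1:]) / 2.0)
    return DiscretizationScheme(
        method="kmeans", n_levels=k, cuts=cuts, side="left",
        fitted_min=float(u[0]), fitted_max=float(u[-1]),
        centers=tuple(centers),
    )


def fit_scheme(
    values, n_levels: int, method: str = "equal", seed: Optional[int] = None
) -> DiscretizationScheme:
    """Dispatch to :func:`fit_equal` / :func:`fit_quantile` / :func:`fit_kmeans`."""
    if method == "equal":
        return fit_equal(values, n_levels)
    if method == "quantile":
        return fit_quantile(values, n_levels)
    if method == "kmeans":
        return fit_kmeans(values, n_levels, seed=seed)
    raise ValueError(f"unknown discretization method {method!r}")


def apply_scheme(scheme: DiscretizationScheme, values) -> np.ndarray:
    """Map values to integer levels ``1..n_levels`` under a fitted scheme.

    Values outside the fitted range clamp to level 1 or Ng with a warning.
    """
    v = _check_values(values)
    out_of_range = (v < scheme.fitted_min) | (v > scheme.fitted_max)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} value(s) outside the fitted range "
            "clamped to the boundary level",
            UserWarning,
            stacklevel=2,
        )
    if not scheme.cuts:
        return np.ones(v.shape, dtype=int)
    levels = np.searchsorted(np.asarray(scheme.cuts), v, side=scheme.side) + 1
    return levels.astype(int)
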
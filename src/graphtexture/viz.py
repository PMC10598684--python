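"""Minimal plotting helpers (optional; require matplotlib)."""

from __future__ import annotations

from .cooccurrence import CooccurrenceMatrix, ProbabilityMatrix

__all__ = ["plot_matrix", "plot_feature_groups"]


def plot_matrix(matrix, ax=None, cmap="viridis"):
    """Heatmap of a co-occurrence count or probability matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = matrix.counts if isinstance(matrix, CooccurrenceMatrix) else matrix.p
    im = ax.imshow(data, cmap=cmap, origin="upper")
    ticks = range(len(matrix.levels))
    ax.set_xticks(ticks, labels=[str(l) for l in matrix.levels])
    ax.set_yticks(ticks, labels=[str(l) for l in matrix.levels])
    ax.set_xlabel("level j")
    ax.set_ylabel("level i")
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_feature_groups(scaled_df, groups, ax=None):
    """Strip-plot scaled feature values coloured by group label."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    names = list(scaled_df.columns)
    labels = sorted(set(groups))
    for gi, lab in enumerate(labels):
        sub = scaled_df[[g == lab for g in groups]]
        for xi, name in enumerate(names):
            y = sub[name].dropna()
            x = np.full(len(y), xi) + (gi - (len(labels) - 1) / 2) * 0.2
            ax.plot(x, y, "o", ms=3, alpha=0.6,
                    label=lab if xi == 0 else None)
    ax.set_xticks(range(len(names)), labels=names, rotation=60, ha="right")
    ax.set_ylabel("scaled feature value")
    ax.legend()
    return ax
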
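"""Matplotlib views of a fitted thesaurus.

Thin wrappers: each function takes an optional ``ax`` and returns it, so
figures compose the usual way.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_similarity", "plot_information_curve", "plot_reliability",
           "plot_embedding"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_similarity(sim, labels=None, ax=None, cmap="viridis"):
    """Heat map of the distance matrix, optionally ordered by cluster.

    With ``labels``, rows/columns are grouped by cluster and boundaries
    drawn; otherwise they are ordered by the words' spike counts.
    """
    ax = _get_ax(ax)
    d = sim.d
    if labels is not None:
        order = np.argsort(np.asarray(labels), kind="stable")
        d = d[np.ix_(order, order)]
        bounds = np.flatnonzero(np.diff(np.asarray(labels)[order])) + 0.5
        for b in bounds:
            ax.axhline(b, color="w", lw=0.5)
            ax.axvline(b, color="w", lw=0.5)
    else:
        counts = sim.patterns.sum(axis=1)
        order = np.argsort(counts, kind="stable")
        d = d[np.ix_(order, order)]
    im = ax.imshow(d, cmap=cmap, vmin=0,
                   vmax=1 if sim.metric_kind == "semantic" else None)
    ax.figure.colorbar(im, ax=ax,
                       label="distance (bits)" if sim.metric_kind == "semantic"
                       else "Hamming distance")
    ax.set_xlabel("pattern")
    ax.set_ylabel("pattern")
    return ax


def plot_information_curve(curve, ax=None, **kwargs):
    """Fraction of stimulus information vs number of clusters (log x)."""
    ax = _get_ax(ax)
    ax.semilogx(curve["k"], curve["fraction"], marker="o", **kwargs)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("fraction of I(s;r)")
    ax.set_ylim(0, 1.05)
    ax.axhline(1.0, color="gray", lw=0.5, ls="--")
    return ax


def plot_reliability(reliability, ax=None):
    """Modal-word vs modal-cluster frequency per stimulus, sorted."""
    ax = _get_ax(ax)
    df = reliability.sort_values("p_max_word").reset_index(drop=True)
    ax.plot(df["p_max_word"].to_numpy(), color="gray", label="modal word")
    ax.plot(df["p_max_cluster"].to_numpy(), color="purple",
            label="modal cluster")
    ax.set_xlabel("stimulus (sorted by word reliability)")
    ax.set_ylabel("frequency across repeats")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_embedding(embedding, labels=None, ax=None, **kwargs):
    """2-D scatter of Isomap coordinates, colored by cluster label."""
    ax = _get_ax(ax)
    xy = embedding.coordinates
    c = None if labels is None else np.asarray(labels)[embedding.nodes]
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=c, cmap="tab10", s=14, **kwargs)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    if labels is not None:
        ax.figure.colorbar(sc, ax=ax, label="cluster")
    return ax
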
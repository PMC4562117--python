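"""Geodesic (Isomap) embedding of the codebook.

Semantic distances are bounded above by 1 bit, so long-range
dissimilarities saturate; the embedding therefore trusts only local
distances. Words (or clusters) closer than an epsilon threshold
(default 0.5 bits) are connected in a neighborhood graph, geodesic
distances are all-pairs shortest weighted paths, and classical
(Torgerson) MDS of the geodesic matrix gives coordinates. Fit quality
per dimensionality is the residual variance 1 - r^2(d_G, d_Iso).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "GeodesicGraph",
    "Embedding",
    "inter_cluster_distance",
    "build_geodesic_graph",
    "isomap_embed",
    "cluster_triggered_average",
    "cluster_stimulus_correlation",
]


@dataclass(frozen=True)
class GeodesicGraph:
    """Epsilon-neighborhood graph with all-pairs shortest-path distances.

    ``geodesic[i, j]`` is infinite iff i and j lie in different connected
    components; ``component`` labels components, with the largest first
    (label 0).
    """

    epsilon: float
    adjacency: np.ndarray      # direct distances where < epsilon, else inf
    geodesic: np.ndarray
    component: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.geodesic.shape[0]

    @property
    def largest_component(self) -> np.ndarray:
        return np.flatnonzero(self.component == 0)

    @property
    def n_disconnected(self) -> int:
        return int((self.component != 0).sum())


@dataclass(frozen=True)
class Embedding:
    """MDS coordinates of one connected component.

    ``residual_variance[m-1]`` is 1 - r^2 between geodesic distances and
    embedded Euclidean distances using the first m dimensions.
    """

    nodes: np.ndarray          # indices into the graph's node list
    coordinates: np.ndarray    # (n_nodes, dims)
    residual_variance: np.ndarray

    def distances(self, dims: int | None = None) -> np.ndarray:
        xy = self.coordinates if dims is None else self.coordinates[:, :dims]
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))


def eligible_clusters(labels, min_size: int = 30, max_size: int = 300) -> np.ndarray:
    """Cluster ids sized for response-level embedding (default 30-300 words).

    Very small clusters carry too few points to shape the manifold and
    very large ones dominate it; both bounds are exposed as arguments.
    """
    lab = np.asarray(labels)
    ids, counts = np.unique(lab, return_counts=True)
    return ids[(counts >= min_size) & (counts <= max_size)]


def inter_cluster_distance(sim, labels) -> np.ndarray:
    """Cluster-level distance matrix: mean over cross-cluster word pairs.

    Diagonal entries are mean within-cluster distances (0 for singletons).
    Cluster order follows sorted unique labels.
    """
    d = sim.d if hasattr(sim, "d") else np.asarray(sim)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    k = len(uniq)
    out = np.zeros((k, k))
    members = [np.flatnonzero(lab == u) for u in uniq]
    for a in range(k):
        ia = members[a]
        if len(ia) > 1:
            block = d[np.ix_(ia, ia)]
            out[a, a] = block[np.triu_indices(len(ia), k=1)].mean()
        for b in range(a + 1, k):
            ib = members[b]
            out[a, b] = out[b, a] = d[np.ix_(ia, ib)].mean()
    return out


def build_geodesic_graph(distances: np.ndarray, epsilon: float = 0.5) -> GeodesicGraph:
    """Connect pairs with d < epsilon; geodesics by weighted shortest paths.

    Disconnection is reported through the component labels, not an error.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = np.asarray(distances, dtype=np.float64)
    n = d.shape[0]
    mask = (d < epsilon) & ~np.eye(n, dtype=bool)
    adj = np.where(mask, d, np.inf)
    np.fill_diagonal(adj, 0.0)
    sparse = csr_matrix(np.where(mask, d, 0.0))
    geo = shortest_path(sparse, method="D", directed=False)
    n_comp, raw = connected_components(sparse, directed=False)
    sizes = np.bincount(raw, minlength=n_comp)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(n_comp, dtype=int)
    relabel[order] = np.arange(n_comp)
    return GeodesicGraph(epsilon=float(epsilon), adjacency=adj, geodesic=geo,
                         component=relabel[raw])


def isomap_embed(graph: GeodesicGraph, dims: int = 3) -> Embedding:
    """Classical MDS of the geodesic matrix of the largest component.

    Double-center the squared geodesics, take the top-``dims``
    eigenvectors scaled by sqrt(eigenvalue); eigen-signs are fixed so the
    largest-magnitude coordinate of each axis is positive.
    """
    nodes = graph.largest_component
    m = len(nodes)
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if m < dims + 1:
        raise ValueError(f"largest component has {m} nodes; "
                         f"cannot embed in {dims} dimensions")
    dg = graph.geodesic[np.ix_(nodes, nodes)]
    d2 = dg ** 2
    j = np.eye(m) - np.full((m, m), 1.0 / m)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:dims]
    vals, vecs = vals[idx], vecs[:, idx]
    vals = np.clip(vals, 0.0, None)
    coords = vecs * np.sqrt(vals)[None, :]
    for c in range(coords.shape[1]):   # deterministic sign convention
        j_max = np.argmax(np.abs(coords[:, c]))
        if coords[j_max, c] < 0:
            coords[:, c] = -coords[:, c]
    iu = np.triu_indices(m, k=1)
    geo_flat = dg[iu]
    resid = np.empty(dims)
    for mdim in range(1, dims + 1):
        xy = coords[:, :mdim]
        diff = xy[:, None, :] - xy[None, :, :]
        emb_flat = np.sqrt((diff ** 2).sum(axis=2))[iu]
        if geo_flat.std() == 0 or emb_flat.std() == 0:
            resid[mdim - 1] = 0.0 if np.allclose(geo_flat, emb_flat) else 1.0
        else:
            r = np.corrcoef(geo_flat, emb_flat)[0, 1]
            resid[mdim - 1] = 1.0 - r ** 2
    return Embedding(nodes=nodes, coordinates=coords, residual_variance=resid)


def cluster_triggered_average(waveform: np.ndarray, trial_labels: np.ndarray,
                              bin_width: float, window: float = 0.25):
    """Mean stimulus segment preceding the responses of each cluster.

    ``waveform`` holds one stimulus value per time bin; for each cluster
    the segments of length ``window`` seconds ending at (and including)
    the response bin are averaged over all its trials. Bins with
    insufficient history are dropped. Returns (cluster ids, (k, w) array).
    """
    wave = np.asarray(waveform, dtype=float)
    lab = np.asarray(trial_labels)
    R, T = lab.shape
    if wave.shape[0] < T:
        raise ValueError("waveform must cover all time bins")
    w = int(round(window / bin_width))
    if w < 1 or w > T:
        raise ValueError("window must span between one bin and the recording")
    uniq = np.unique(lab)
    out = np.zeros((len(uniq), w))
    counts = np.zeros(len(uniq), dtype=int)
    # segment ending at bin t covers bins [t-w+1, t]
    segs = np.stack([wave[t - w + 1:t + 1] for t in range(w - 1, T)])
    for ci, c in enumerate(uniq):
        hits = lab[:, w - 1:] == c
        n = int(hits.sum())
        if n:
            out[ci] = (hits.sum(axis=0) @ segs) / n
        counts[ci] = n
    return uniq, out


def cluster_stimulus_correlation(averages: np.ndarray,
                                 cluster_distances: np.ndarray):
    """Waveform correlation vs inter-cluster distance, over cluster pairs.

    Returns a dict with the (distance, correlation) pairs, the Spearman
    rank trend statistic and its p-value; constant-waveform pairs are
    excluded and counted in ``n_excluded``.
    """
    from scipy.stats import spearmanr

    avg = np.asarray(averages, dtype=float)
    dmat = np.asarray(cluster_distances, dtype=float)
    k = avg.shape[0]
    if k < 3:
        raise ValueError("need at least 3 clusters for a trend")
    dists, corrs, excluded = [], [], 0
    for a in range(k):
        for b in range(a + 1, k):
            if avg[a].std() == 0 or avg[b].std() == 0:
                excluded += 1
                continue
            dists.append(dmat[a, b])
            corrs.append(np.corrcoef(avg[a], avg[b])[0, 1])
    dists, corrs = np.asarray(dists), np.asarray(corrs)
    if len(dists) >= 3 and np.std(dists) > 0 and np.std(corrs) > 0:
        rho, p = spearmanr(dists, corrs)
    else:
        rho, p = np.nan, np.nan
    return {"distance": dists, "correlation": corrs,
            "spearman_rho": float(rho) if rho == rho else np.nan,
            "p_value": float(p) if p == p else np.nan,
            "n_excluded": excluded}
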
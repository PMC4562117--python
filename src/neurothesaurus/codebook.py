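"""Clustering the codebook into synonym groups.

The deduplicated test-set words are clustered by average-linkage
hierarchical agglomerative clustering of their semantic (or Hamming)
distance matrix: the distance between two clusters is the average
distance over inter-cluster word pairs. Flat cuts at varying k give the
cluster identity C_k(r) of every word; replacing each trial's word by
its cluster label yields the information curve I(s;C_k(r)) / I(s;r).

Cluster validity is scored by the Hubert-Levin C-Index
(S - S_min)/(S_max - S_min), smaller is better, with significance from
re-clustering symmetric shuffles of the distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .infotools import mutual_information_clusters, \
    mutual_information_stimulus_response
from .thesaurus import SimilarityMatrix, jensen_shannon, posterior_table, \
    unique_patterns

__all__ = [
    "Dendrogram",
    "Clustering",
    "agglomerative_cluster",
    "cut_clusters",
    "information_curve",
    "assign_pattern",
    "cluster_reliability",
    "strong_response_stimuli",
    "shuffle_reliability_null",
    "c_index",
    "clustering_significance",
]


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over the words of a similarity matrix.

    ``merges`` is a scipy linkage matrix: rows (a, b, distance, size).
    """

    merges: np.ndarray
    patterns: np.ndarray
    metric_kind: str

    def __post_init__(self) -> None:
        z = np.asarray(self.merges, dtype=np.float64)
        if z.shape != (self.patterns.shape[0] - 1, 4):
            raise ValueError("merges must be an (n_patterns - 1, 4) linkage matrix")
        if np.any(np.diff(z[:, 2]) < -1e-10):
            warnings.warn("non-monotone merge distances in dendrogram")
        object.__setattr__(self, "merges", z)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.merges, columns=["a", "b", "distance", "size"]) \
            .to_csv(path, index=False)


@dataclass(frozen=True)
class Clustering:
    """A flat k-cluster cut: one label in 1..k per dendrogram leaf."""

    k: int
    labels: np.ndarray
    patterns: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.min() < 1 or lab.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        object.__setattr__(self, "labels", lab)

    def _lookup(self) -> dict[bytes, int]:
        return {row.tobytes(): i
                for i, row in enumerate(np.ascontiguousarray(self.patterns))}

    def trial_labels(self, words: np.ndarray) -> np.ndarray:
        """Cluster label of every word in a (..., N) array of trial words."""
        arr = np.ascontiguousarray(np.asarray(words, dtype=self.patterns.dtype))
        lead = arr.shape[:-1]
        flat = arr.reshape(-1, arr.shape[-1])
        lut = self._lookup()
        out = np.empty(flat.shape[0], dtype=int)
        for i, row in enumerate(flat):
            key = row.tobytes()
            if key not in lut:
                raise KeyError(
                    "word not among the clustered patterns; use assign_pattern "
                    "to map novel words to their semantically nearest cluster")
            out[i] = self.labels[lut[key]]
        return out.reshape(lead)

    def to_csv(self, path) -> None:
        import pandas as pd

        bits = ["".join(str(b) for b in row) for row in self.patterns]
        pd.DataFrame({"pattern": bits, "cluster": self.labels}) \
            .to_csv(path, index=False)


def agglomerative_cluster(sim: SimilarityMatrix | np.ndarray,
                          metric_kind: str = "semantic",
                          patterns: np.ndarray | None = None) -> Dendrogram:
    """Average-linkage agglomerative clustering of a distance matrix."""
    if isinstance(sim, SimilarityMatrix):
        d, patterns, metric_kind = sim.d, sim.patterns, sim.metric_kind
    else:
        d = np.asarray(sim, dtype=np.float64)
        if patterns is None:
            patterns = np.arange(d.shape[0])[:, None]
    if d.shape[0] < 2:
        raise ValueError("need at least 2 patterns to cluster")
    if not np.allclose(d, d.T, atol=1e-12) or np.any(d < 0):
        raise ValueError("distance matrix must be symmetric and nonnegative")
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, np.asarray(patterns), metric_kind)


def cut_clusters(dend: Dendrogram, k: int) -> Clustering:
    """Flat clustering with exactly k clusters (undo the top k-1 merges)."""
    n = dend.n_patterns
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}")
    raw = cut_tree(dend.merges, n_clusters=k).ravel()
    # relabel to 1..k in order of first appearance (deterministic)
    _, labels = np.unique(raw, return_inverse=True)
    first = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in first:
            first[lab] = len(first) + 1
        out[i] = first[lab]
    return Clustering(k=k, labels=out, patterns=dend.patterns)


def information_curve(dend: Dendrogram, test_words: np.ndarray,
                      k_values, extrapolate: bool = True,
                      seed: int = 0):
    """Fraction of stimulus information retained by cluster identity vs k.

    ``test_words`` is the (repeats, time_bins, neurons) test raster whose
    deduplicated words are the dendrogram leaves. Returns a DataFrame with
    columns k, info_bits, fraction (of I(s;r) from the same data).
    """
    import pandas as pd

    from .raster import BinnedRaster

    words = test_words.words if isinstance(test_words, BinnedRaster) \
        else np.asarray(test_words)
    total = mutual_information_stimulus_response(
        BinnedRaster(words, 1.0), extrapolate=extrapolate, seed=seed)
    rows = []
    for k in k_values:
        clustering = cut_clusters(dend, int(k))
        lab = clustering.trial_labels(words)
        info = mutual_information_clusters(lab, k=int(k),
                                           extrapolate=extrapolate,
                                           seed=seed + int(k))
        rows.append((int(k), info, info / total if total > 0 else np.nan))
    return pd.DataFrame(rows, columns=["k", "info_bits", "fraction"])


def assign_pattern(sim: SimilarityMatrix, clustering: Clustering,
                   pattern, models, prior=None) -> tuple[int, float]:
    """Cluster id for a novel word: its semantically nearest leaf's cluster.

    The word's posterior comes from the same train-fitted models; ties in
    distance resolve to the lowest pattern index. Returns (label, distance).
    """
    if sim.posteriors is None:
        raise ValueError("similarity matrix lacks posteriors; build it with "
                         "kind='semantic'")
    post = posterior_table(models, np.asarray(pattern)[None, :],
                           prior=prior).posteriors[0]
    dists = np.array([jensen_shannon(post, q) for q in sim.posteriors])
    idx = int(np.argmin(dists))
    return int(clustering.labels[idx]), float(dists[idx])


def _modal_frequency(labels_2d: np.ndarray) -> np.ndarray:
    """Per-column frequency of the most common value across rows."""
    R, T = labels_2d.shape
    out = np.empty(T)
    for t in range(T):
        _, counts = np.unique(labels_2d[:, t], return_counts=True)
        out[t] = counts.max() / R
    return out


def cluster_reliability(trial_labels: np.ndarray,
                        trial_words: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulus modal-word and modal-cluster frequencies.

    ``trial_labels`` is (repeats, time_bins) cluster ids; ``trial_words``
    the matching (repeats, time_bins, neurons) words. Because clusters
    pool words, p_max_cluster >= p_max_word at every stimulus.
    """
    words = np.asarray(trial_words)
    _, _, inv = unique_patterns(words)
    return _modal_frequency(inv), _modal_frequency(np.asarray(trial_labels))


def strong_response_stimuli(words: np.ndarray, threshold: float = 0.75) -> np.ndarray:
    """Boolean mask of stimuli with >=1 spike in more than ``threshold`` of repeats."""
    arr = np.asarray(words)
    return (arr.any(axis=2).mean(axis=0)) > threshold


def shuffle_reliability_null(trial_labels: np.ndarray, n_shuffles: int,
                             seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Null modal-cluster reliability from label shuffles across all trials.

    Labels are permuted over the flattened (repeat, time_bin) axis —
    preserving overall label counts, destroying stimulus locking — and the
    per-stimulus modal-cluster frequency recomputed. Returns (mean, SD)
    per stimulus over shuffles.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    lab = np.asarray(trial_labels)
    rng = np.random.default_rng(seed)
    R, T = lab.shape
    draws = np.empty((n_shuffles, T))
    flat = lab.ravel()
    for i in range(n_shuffles):
        draws[i] = _modal_frequency(rng.permutation(flat).reshape(R, T))
    return draws.mean(axis=0), draws.std(axis=0)


def c_index(sim: SimilarityMatrix | np.ndarray, labels) -> float:
    """Hubert-Levin C-Index of a flat clustering; smaller is better.

    C = (S - S_min) / (S_max - S_min) where S is the sum of within-cluster
    pair distances, and S_min / S_max sum the l smallest / largest of all
    pair distances, l being the number of within-cluster pairs.
    """
    d = sim.d if isinstance(sim, SimilarityMatrix) else np.asarray(sim)
    lab = np.asarray(labels)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    pair_d = d[iu, ju]
    within = lab[iu] == lab[ju]
    l = int(within.sum())
    if l == 0:
        raise ValueError("no within-cluster pairs (all singletons); "
                         "C-Index is undefined")
    if len(np.unique(lab)) < 2:
        raise ValueError("need at least 2 clusters")
    s = pair_d[within].sum()
    srt = np.sort(pair_d)
    s_min, s_max = srt[:l].sum(), srt[-l:].sum()
    if s_max == s_min:
        return 0.0
    return float((s - s_min) / (s_max - s_min))


def clustering_significance(sim: SimilarityMatrix | np.ndarray, labels,
                            n_shuffles: int = 100, seed: int = 0):
    """Empirical p-value of the clustering's C-Index against matrix shuffles.

    Each shuffle permutes the off-diagonal distance values (jointly for
    (i,j) and (j,i), preserving symmetry), re-clusters with average
    linkage, cuts at the same k, and recomputes the C-Index. p is the
    fraction of shuffles with C <= the observed value.
    """
    if n_shuffles < 20:
        raise ValueError("use at least 20 shuffles")
    d = sim.d if isinstance(sim, SimilarityMatrix) else np.asarray(sim)
    lab = np.asarray(labels)
    k = len(np.unique(lab))
    observed = c_index(d, lab)
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    condensed = squareform(d, checks=False)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuf = squareform(rng.permutation(condensed), checks=False)
        dend = agglomerative_cluster(shuf, metric_kind="shuffled",
                                     patterns=np.arange(n)[:, None])
        null[i] = c_index(shuf, cut_clusters(dend, k).labels)
    p = float((null <= observed).mean())
    return {"c_index": observed, "p_value": p, "null": null,
            "n_shuffles": n_shuffles}
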
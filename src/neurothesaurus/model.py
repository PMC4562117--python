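"""Model/Results facade over the thesaurus pipeline.

``ThesaurusModel`` wraps a binned raster of repeated-stimulus responses;
``fit()`` splits repeats, fits per-stimulus encoding models on the train
half, inverts them to posteriors for the unique test words, builds the
semantic distance matrix and its average-linkage dendrogram, and returns
a ``ThesaurusResults`` carrying all downstream analyses (information
curves, reliability, decoding benchmark, embedding, significance).
"""

from __future__ import annotations

import io

import numpy as np

from . import codebook, decode, embed, infotools
from .encmodels import fit_cond_independent, fit_pairwise_maxent
from .raster import BinnedRaster, bin_spikes, load_spike_times, split_repeats
from .thesaurus import similarity_matrix, unique_patterns

__all__ = ["ThesaurusModel", "ThesaurusResults"]


class ThesaurusModel:
    """Semantic-similarity model of a population's codebook.

    Parameters
    ----------
    raster : BinnedRaster
        Binary words indexed (repeat, time_bin, neuron); the time-bin
        index is the stimulus identity.
    encoding : {"pairwise", "independent"}
        Family of the per-stimulus encoding-noise model.
    pseudocount : float
        Additive smoothing of the per-stimulus moments.
    l2_penalty : float
        Optional ridge on the maxent parameters for undersampled stimuli.
    """

    def __init__(self, raster: BinnedRaster, encoding: str = "pairwise",
                 pseudocount: float = 0.5, l2_penalty: float = 0.0):
        if encoding not in ("pairwise", "independent"):
            raise ValueError("encoding must be 'pairwise' or 'independent'")
        self.raster = raster
        self.encoding = encoding
        self.pseudocount = pseudocount
        self.l2_penalty = l2_penalty

    @classmethod
    def from_spike_times(cls, path, n_repeats: int, n_neurons: int,
                         duration: float, bin_width: float = 0.02,
                         **kwargs) -> "ThesaurusModel":
        spikes = load_spike_times(path, n_repeats, n_neurons, duration)
        return cls(bin_spikes(spikes, bin_width), **kwargs)

    def _fit_encoders(self, raster: BinnedRaster, tol: float, max_iter: int):
        if self.encoding == "independent":
            return fit_cond_independent(raster, pseudocount=self.pseudocount)
        return fit_pairwise_maxent(raster, l2_penalty=self.l2_penalty,
                                   tol=tol, max_iter=max_iter,
                                   pseudocount=self.pseudocount)

    def fit(self, train_fraction: float = 0.5, seed: int = 0,
            tol: float = 1e-4, max_iter: int = 1000) -> "ThesaurusResults":
        """Split repeats, fit encoders on train, build the test thesaurus."""
        train, test = split_repeats(self.raster, train_fraction, seed)
        encoders = self._fit_encoders(train, tol, max_iter)
        sim = similarity_matrix(encoders, test.words, kind="semantic")
        dend = codebook.agglomerative_cluster(sim)
        return ThesaurusResults(self, train, test, encoders, sim, dend,
                                seed=seed, tol=tol, max_iter=max_iter)


class ThesaurusResults:
    """Fitted thesaurus: encoding models, distances, dendrogram, analyses."""

    def __init__(self, model: ThesaurusModel, train: BinnedRaster,
                 test: BinnedRaster, encoders, similarity, dendrogram,
                 seed: int = 0, tol: float = 1e-4, max_iter: int = 1000):
        self.model = model
        self.train = train
        self.test = test
        self.encoders = encoders
        self.similarity = similarity
        self.dendrogram = dendrogram
        self.seed = seed
        self._tol = tol
        self._max_iter = max_iter
        self._hamming = None
        self._truth_encoders = None

    # -- lazy companions ---------------------------------------------------

    @property
    def hamming(self):
        """Hamming-distance matrix over the same unique test words."""
        if self._hamming is None:
            self._hamming = similarity_matrix(self.encoders, self.test.words,
                                              kind="hamming")
        return self._hamming

    def _truth_models(self):
        """Encoding models refitted on the test half (decoding ground truth)."""
        if self._truth_encoders is None:
            self._truth_encoders = self.model._fit_encoders(
                self.test, self._tol, self._max_iter)
        return self._truth_encoders

    # -- analyses ----------------------------------------------------------

    def clustering(self, k: int) -> codebook.Clustering:
        return codebook.cut_clusters(self.dendrogram, k)

    def trial_labels(self, k: int) -> np.ndarray:
        return self.clustering(k).trial_labels(self.test.words)

    def information_curve(self, k_values=None, extrapolate: bool = True):
        if k_values is None:
            n = self.similarity.n_patterns
            k_values = np.unique(np.geomspace(1, n, num=12).astype(int))
        return codebook.information_curve(self.dendrogram, self.test.words,
                                          k_values, extrapolate=extrapolate,
                                          seed=self.seed)

    def reliability(self, k: int):
        """Per-stimulus modal-word vs modal-cluster frequency (DataFrame)."""
        import pandas as pd

        p_word, p_cluster = codebook.cluster_reliability(
            self.trial_labels(k), self.test.words)
        strong = codebook.strong_response_stimuli(self.test.words)
        return pd.DataFrame({"time_bin": np.arange(self.test.n_bins),
                             "p_max_word": p_word,
                             "p_max_cluster": p_cluster,
                             "strong_response": strong})

    def clustering_significance(self, k: int, n_shuffles: int = 100):
        labels = self.clustering(k).labels
        return codebook.clustering_significance(self.similarity, labels,
                                                n_shuffles=n_shuffles,
                                                seed=self.seed)

    def decoding(self, close_neighbor_threshold: float = 0.25,
                 truth: str = "test"):
        """Leave-one-out decoding benchmark (semantic / Hamming / prior).

        ``truth`` picks the models defining the reference posterior:
        "test" refits on the held-out half, "train" reuses the thesaurus
        encoders.
        """
        truth_models = self._truth_models() if truth == "test" else self.encoders
        return decode.evaluate_decoding(
            self.test.words, truth_models, self.encoders,
            close_neighbor_threshold=close_neighbor_threshold)

    def embedding(self, epsilon: float = 0.5, dims: int = 3,
                  level: str = "pattern", k: int | None = None):
        """Isomap embedding of words, or of cluster centroids (level="cluster")."""
        if level == "pattern":
            d = self.similarity.d
        elif level == "cluster":
            if k is None:
                raise ValueError("cluster-level embedding needs k")
            d = embed.inter_cluster_distance(self.similarity,
                                             self.clustering(k).labels)
            d = d - np.diag(np.diag(d))
        else:
            raise ValueError("level must be 'pattern' or 'cluster'")
        graph = embed.build_geodesic_graph(d, epsilon=epsilon)
        return graph, embed.isomap_embed(graph, dims=dims)

    def noise_table(self):
        """Per-stimulus rate / noise-entropy / multi-information table."""
        return infotools.entropy_rate_table(self.test, seed=self.seed)

    # -- presentation ------------------------------------------------------

    def plot_similarity(self, k: int | None = None, ax=None, **kwargs):
        """Distance-matrix heat map; with k, ordered by the k-cut clusters."""
        from . import plotting

        labels = self.clustering(k).labels if k is not None else None
        return plotting.plot_similarity(self.similarity, labels=labels,
                                        ax=ax, **kwargs)

    def plot_information_curve(self, k_values=None, ax=None, **kwargs):
        from . import plotting

        return plotting.plot_information_curve(
            self.information_curve(k_values), ax=ax, **kwargs)

    def plot_reliability(self, k: int, ax=None):
        from . import plotting

        return plotting.plot_reliability(self.reliability(k), ax=ax)

    def summary(self, k: int | None = None) -> str:
        sim = self.similarity
        iu = np.triu_indices(sim.n_patterns, k=1)
        dvals = sim.d[iu]
        uniq, counts, _ = unique_patterns(self.test.words)
        buf = io.StringIO()
        w = buf.write
        w("Neural thesaurus fit\n")
        w("=" * 58 + "\n")
        w(f"Encoding model:        {self.model.encoding} "
          f"(pseudocount {self.model.pseudocount})\n")
        w(f"Neurons:               {self.raster_shape[2]}\n")
        w(f"Stimuli (time bins):   {self.raster_shape[1]}\n")
        w(f"Repeats (train/test):  {self.train.n_repeats}/"
          f"{self.test.n_repeats}\n")
        w(f"Unique test words:     {sim.n_patterns}\n")
        w(f"Semantic distance:     mean {dvals.mean():.3f} bits, "
          f"median {np.median(dvals):.3f} bits\n")
        w(f"Synonym pairs (<0.25): {(dvals < 0.25).mean():.1%}\n")
        if hasattr(self.encoders, "converged") and \
                self.encoders.converged is not None:
            w(f"Maxent fits converged: {int(self.encoders.converged.sum())}"
              f"/{len(self.encoders.converged)}\n")
        if k is not None:
            labels = self.clustering(k).labels
            w(f"C-Index at k={k}:       "
              f"{codebook.c_index(sim, labels):.4f}\n")
        return buf.getvalue()

    @property
    def raster_shape(self):
        return self.model.raster.words.shape
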
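"""Planted-codebook raster generator with exact ground truth.

Emulates the statistical structure of repeated-stimulus population
recordings: per-stimulus firing probabilities with sparse high-rate
"event" epochs, pairwise noise correlations concentrated at event times,
hundreds of repeats, and a planted synonym-cluster organization in which
each cluster has very precise neurons (almost always spiking or almost
always silent) alongside noisy neurons that vary nearly randomly within
the cluster.

Stimuli (time bins) are partitioned into K contiguous blocks; all
stimuli of a block share one generating pairwise maxent model up to a
small rate jitter, so the block IS the planted semantic cluster. Words
are sampled from the exactly enumerated generating distributions, which
makes ground-truth posteriors — and hence the true semantic distance
matrix — exactly computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .encmodels import PairwiseMaxEntModel, _log_weights, _pair_idx, \
    enumerate_distribution, log_likelihood_matrix, sample_patterns
from .raster import BinnedRaster
from .thesaurus import SimilarityMatrix, pairwise_jensen_shannon

__all__ = ["GeneratorConfig", "GroundTruth", "generate_codebook_dataset",
           "ground_truth_similarity"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-codebook generator.

    Defaults describe a small population (10 neurons), a 2 s clip binned
    at 20 ms (100 stimuli), 400 repeats and 8 planted clusters, two of
    which are high-rate, strongly coupled "event" epochs.
    """

    n_neurons: int = 10
    n_stimuli: int = 100
    n_repeats: int = 400
    n_clusters: int = 8
    event_fraction: float = 0.25
    n_precise_on: int = 3
    n_noisy: int = 3
    precise_on_rate: float = 0.985
    precise_off_rate: float = 0.005
    noisy_rate_event: tuple[float, float] = (0.40, 0.60)
    noisy_rate_baseline: tuple[float, float] = (0.10, 0.30)
    coupling_scale: float = 0.3
    min_off_overlap: int = 1
    rate_jitter: float = 0.05  # SD of per-stimulus field jitter, logit scale
    bin_width: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_stimuli:
            raise ValueError("n_clusters cannot exceed n_stimuli")
        if not 0 < self.event_fraction < 1:
            raise ValueError("event_fraction must lie in (0, 1)")
        for r in (self.precise_on_rate, self.precise_off_rate,
                  *self.noisy_rate_event, *self.noisy_rate_baseline):
            if not 0 < r < 1:
                raise ValueError("all rates must lie strictly in (0, 1)")
        if self.n_precise_on + self.n_noisy > self.n_neurons:
            raise ValueError("precise-on plus noisy neurons exceed the population")


@dataclass(frozen=True)
class GroundTruth:
    """The generating structure behind a synthetic raster."""

    models: PairwiseMaxEntModel            # generating model per stimulus
    stimulus_cluster: np.ndarray           # (T,) labels in 1..K
    on_neurons: list[np.ndarray]           # per cluster
    off_neurons: list[np.ndarray]
    noisy_neurons: list[np.ndarray]
    event_cluster: np.ndarray              # (K,) bool
    cluster_rates: np.ndarray = field(repr=False, default=None)  # (K, N)

    @property
    def n_clusters(self) -> int:
        return len(self.on_neurons)

    def word_labels(self, patterns: np.ndarray) -> np.ndarray:
        """Ground-truth cluster of each word: argmax_c of P(word | cluster).

        P(word|cluster) averages the generating P(word|s) over the
        cluster's stimuli.
        """
        ll = log_likelihood_matrix(self.models, np.asarray(patterns))  # log2
        K = self.n_clusters
        out = np.empty((ll.shape[0], K))
        for c in range(K):
            cols = np.flatnonzero(self.stimulus_cluster == c + 1)
            out[:, c] = logsumexp(ll[:, cols] * np.log(2.0), axis=1) - \
                np.log(len(cols))
        return out.argmax(axis=1) + 1


def _smooth_signature(rng: np.random.Generator, length: int) -> np.ndarray:
    """A random smooth waveform segment (random walk, lightly smoothed)."""
    walk = np.cumsum(rng.normal(size=length + 4))
    kernel = np.ones(5) / 5.0
    sig = np.convolve(walk, kernel, mode="valid")
    sig = sig - sig.mean()
    scale = sig.std()
    return sig / scale if scale > 0 else sig


def generate_codebook_dataset(config: GeneratorConfig
                              ) -> tuple[BinnedRaster, GroundTruth, np.ndarray]:
    """Sample a raster with planted synonym clusters.

    Returns ``(raster, ground_truth, waveform)``: the (repeats, bins,
    neurons) binary raster, the generating structure, and a scalar
    stimulus waveform carrying a distinct smooth signature over each
    cluster's block of time bins.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    N, T, K = cfg.n_neurons, cfg.n_stimuli, cfg.n_clusters
    iu, ju = _pair_idx(N)
    n_pairs = len(iu)

    # contiguous blocks of stimuli per cluster
    stimulus_cluster = 1 + (np.arange(T) * K) // T

    n_event = max(1, int(round(K * cfg.event_fraction)))
    event_cluster = np.zeros(K, dtype=bool)
    event_cluster[rng.choice(K, size=n_event, replace=False)] = True

    on_sets, off_sets, noisy_sets = [], [], []
    cluster_rates = np.empty((K, N))
    cluster_beta = np.zeros((K, n_pairs))
    for c in range(K):
        # rejection-sample neuron roles so clusters stay separable: every
        # cluster must keep >= min_off_overlap precise-off neurons inside
        # each other cluster's precise-on set (and vice versa), so no
        # cluster's signature can be mimicked without precise-bit flips
        for _ in range(5000):
            perm = rng.permutation(N)
            on = np.sort(perm[:cfg.n_precise_on])
            noisy = np.sort(perm[cfg.n_precise_on:cfg.n_precise_on + cfg.n_noisy])
            off = np.sort(perm[cfg.n_precise_on + cfg.n_noisy:])
            if all(len(set(o2) & set(off)) >= cfg.min_off_overlap and
                   len(set(on) & set(f2)) >= cfg.min_off_overlap
                   for o2, f2 in zip(on_sets, off_sets)):
                break
        else:
            raise ValueError("could not place separable clusters; relax "
                             "min_off_overlap or enlarge the population")
        lo, hi = (cfg.noisy_rate_event if event_cluster[c]
                  else cfg.noisy_rate_baseline)
        rates = np.empty(N)
        rates[on] = cfg.precise_on_rate
        rates[off] = cfg.precise_off_rate
        rates[noisy] = rng.uniform(lo, hi, size=cfg.n_noisy)
        cluster_rates[c] = rates
        if event_cluster[c] and cfg.coupling_scale != 0 and cfg.n_noisy >= 2:
            noisy_pairs = np.flatnonzero(np.isin(iu, noisy) & np.isin(ju, noisy))
            cluster_beta[c, noisy_pairs] = cfg.coupling_scale
        on_sets.append(on); off_sets.append(off); noisy_sets.append(noisy)

    alpha = np.empty((T, N))
    beta = np.empty((T, n_pairs))
    logZ = np.empty(T)
    for t in range(T):
        c = stimulus_cluster[t] - 1
        p = cluster_rates[c]
        # jitter on the logit scale: proportional perturbation that cannot
        # push precise rates across the on/off boundary
        alpha[t] = np.log(p / (1.0 - p)) + cfg.rate_jitter * rng.normal(size=N)
        beta[t] = cluster_beta[c]
        logZ[t] = logsumexp(_log_weights(alpha[t], beta[t]))
    models = PairwiseMaxEntModel(alpha, beta, logZ)

    # degenerate-distribution guard
    for t in range(T):
        probs = enumerate_distribution(models, t).probs
        if (probs > 1e-12).sum() < 2:
            raise ValueError(f"stimulus {t}: generating distribution is "
                             "degenerate (one pattern carries all mass); "
                             "adjust rates/couplings")

    sample_seeds = rng.integers(0, 2**31 - 1, size=T)
    words = np.empty((cfg.n_repeats, T, N), dtype=np.uint8)
    for t in range(T):
        words[:, t, :] = sample_patterns(models, t, cfg.n_repeats,
                                         seed=int(sample_seeds[t]))
    raster = BinnedRaster(words, cfg.bin_width)

    waveform = np.empty(T)
    for c in range(K):
        blk = np.flatnonzero(stimulus_cluster == c + 1)
        waveform[blk] = _smooth_signature(rng, len(blk))

    truth = GroundTruth(models=models, stimulus_cluster=stimulus_cluster,
                        on_neurons=on_sets, off_neurons=off_sets,
                        noisy_neurons=noisy_sets, event_cluster=event_cluster,
                        cluster_rates=cluster_rates)
    return raster, truth, waveform


def ground_truth_similarity(truth: GroundTruth,
                            min_marginal: float = 1e-4) -> SimilarityMatrix:
    """Exact semantic distance matrix from the generating models.

    Includes every word whose marginal probability under the generating
    models (uniform stimulus prior) exceeds ``min_marginal``; posteriors
    and Jensen-Shannon distances are exact, making this the oracle
    against which an estimated thesaurus is scored.
    """
    models = truth.models
    T = models.n_stimuli
    dist0 = enumerate_distribution(models, 0)
    support = dist0.support
    cond = np.empty((support.shape[0], T))
    cond[:, 0] = dist0.probs
    for t in range(1, T):
        cond[:, t] = enumerate_distribution(models, t).probs
    marginal = cond.mean(axis=1)
    keep = marginal > min_marginal
    if not keep.any():
        raise ValueError("no word exceeds the marginal threshold")
    posts = cond[keep] / (T * marginal[keep][:, None])
    d = pairwise_jensen_shannon(posts)
    return SimilarityMatrix(support[keep], d, "semantic",
                            counts=None, posteriors=posts)
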
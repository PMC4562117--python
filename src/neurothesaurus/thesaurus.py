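"""Semantic similarity between population codewords.

The meaning of a word ``r`` is its posterior over stimuli,
``P(s|r) = P(r|s) P(s) / P(r)``, obtained by inverting the fitted
encoding models over the train-set stimuli. The semantic distance
between two words is the Jensen-Shannon divergence between their
posteriors (base-2 logs, so it lies in [0, 1] bits): 0 for perfect
synonyms, 1 for words with non-overlapping meaning. The syntactic
baseline is the Hamming distance (number of neurons whose spike/silence
state differs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp, xlogy

from .encmodels import log_likelihood_matrix

__all__ = [
    "PosteriorTable",
    "SimilarityMatrix",
    "posterior_over_stimuli",
    "posterior_table",
    "jensen_shannon",
    "pairwise_jensen_shannon",
    "hamming_matrix",
    "similarity_matrix",
    "unique_patterns",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class PosteriorTable:
    """Posteriors over train stimuli for a list of words.

    ``posteriors[p, s]`` is P(s | pattern p); each row sums to 1.
    ``marginal[p]`` is P(r) under the prior.
    """

    patterns: np.ndarray      # (n_patterns, N) uint8
    posteriors: np.ndarray    # (n_patterns, T)
    prior: np.ndarray         # (T,)
    marginal: np.ndarray      # (n_patterns,)

    def __post_init__(self) -> None:
        post = np.asarray(self.posteriors, dtype=np.float64)
        if np.any(np.abs(post.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("each posterior row must sum to 1 within 1e-10")
        object.__setattr__(self, "posteriors", post)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise distances between deduplicated observed words.

    ``metric_kind`` is "semantic" (Jensen-Shannon, bits, in [0,1]) or
    "hamming" (integer bit differences). ``counts`` holds per-word
    multiplicities in the data the matrix was built from.
    """

    patterns: np.ndarray
    d: np.ndarray
    metric_kind: str
    counts: np.ndarray | None = field(default=None)
    posteriors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=np.float64)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("d must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("d must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("d must have a zero diagonal")
        if self.metric_kind not in ("semantic", "hamming"):
            raise ValueError("metric_kind must be 'semantic' or 'hamming'")
        object.__setattr__(self, "d", d)

    @property
    def n_patterns(self) -> int:
        return self.d.shape[0]

    def bitstrings(self) -> list[str]:
        return ["".join(str(b) for b in row) for row in self.patterns]

    def to_csv(self, path) -> None:
        """Square CSV with pattern bitstrings as labels + JSON sidecar."""
        import pandas as pd

        labels = self.bitstrings()
        pd.DataFrame(self.d, index=labels, columns=labels).to_csv(path)
        meta = {"metric_kind": self.metric_kind,
                "units": "bits" if self.metric_kind == "semantic" else "neurons",
                "n_neurons": int(self.patterns.shape[1]),
                "n_patterns": int(self.n_patterns)}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        # column labels survive as strings (the index may lose leading zeros)
        pats = np.array([[int(c) for c in str(s)] for s in df.columns],
                        dtype=np.uint8)
        meta_path = Path(str(path) + ".meta.json")
        kind = "semantic"
        if meta_path.exists():
            kind = json.loads(meta_path.read_text())["metric_kind"]
        return cls(pats, df.to_numpy(), kind)


def unique_patterns(words: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deduplicate words: (unique patterns, counts, inverse index).

    ``words`` is (n_samples, N) or (R, T, N); the inverse index has the
    same leading shape as the input and maps every sample to its row in
    the unique-pattern list.
    """
    arr = np.asarray(words)
    lead = arr.shape[:-1]
    flat = arr.reshape(-1, arr.shape[-1])
    uniq, inv, counts = np.unique(flat, axis=0, return_inverse=True,
                                  return_counts=True)
    return uniq.astype(np.uint8), counts, inv.reshape(lead)


def posterior_over_stimuli(models, pattern, prior=None) -> np.ndarray:
    """P(s|r) for one pattern by Bayes' rule over the fitted models."""
    table = posterior_table(models, np.asarray(pattern)[None, :], prior=prior)
    return table.posteriors[0]


def posterior_table(models, patterns, prior=None) -> PosteriorTable:
    """Posteriors over train stimuli for many patterns at once.

    Likelihoods come from the fitted models, so any binary word — observed
    or novel — gets a strictly positive marginal and a proper posterior.
    """
    pats = np.atleast_2d(np.asarray(patterns))
    T = models.n_stimuli
    if prior is None:
        prior = np.full(T, 1.0 / T)
    prior = np.asarray(prior, dtype=np.float64)
    if prior.shape != (T,) or abs(prior.sum() - 1.0) > 1e-8:
        raise ValueError("prior must be a length-T probability vector")
    loglik = log_likelihood_matrix(models, pats) * LN2   # natural log
    if np.max(loglik) < np.log(1e-300):
        warnings.warn("pattern likelihood maxima below 1e-300; posterior "
                      "computed in log space but may be unreliable")
    logjoint = loglik + np.log(prior)[None, :]
    logmarg = logsumexp(logjoint, axis=1)
    post = np.exp(logjoint - logmarg[:, None])
    post /= post.sum(axis=1, keepdims=True)
    return PosteriorTable(pats.astype(np.uint8), post, prior, np.exp(logmarg))


def _row_entropies(p: np.ndarray) -> np.ndarray:
    return -xlogy(p, p).sum(axis=-1) / LN2


def jensen_shannon(p, q) -> float:
    """Base-2 Jensen-Shannon divergence between two probability vectors.

    D_JS = H[(P+Q)/2] - (H[P] + H[Q]) / 2, symmetric, in [0, 1] bits:
    0 for identical distributions, 1 for non-overlapping support.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    for v in (p, q):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must be probability vectors")
    m = 0.5 * (p + q)
    d = _row_entropies(m) - 0.5 * (_row_entropies(p) + _row_entropies(q))
    return float(np.clip(d, 0.0, 1.0))


def pairwise_jensen_shannon(posteriors: np.ndarray) -> np.ndarray:
    """Symmetric matrix of base-2 JSD between all rows of ``posteriors``."""
    P = np.asarray(posteriors, dtype=np.float64)
    n = P.shape[0]
    h = _row_entropies(P)
    d = np.zeros((n, n))
    for i in range(n - 1):
        mid = 0.5 * (P[i][None, :] + P[i + 1:])
        dij = _row_entropies(mid) - 0.5 * (h[i] + h[i + 1:])
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    return np.clip(d, 0.0, 1.0)


def hamming_matrix(patterns: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances (number of differing neurons)."""
    pats = np.asarray(patterns, dtype=np.int16)
    # (a - b)^2 summed = Hamming for binary vectors
    gram = pats @ pats.T
    sq = np.diag(gram)
    return (sq[:, None] + sq[None, :] - 2 * gram).astype(np.float64)


def similarity_matrix(models, test_words, prior=None,
                      kind: str = "semantic") -> SimilarityMatrix:
    """Distance matrix over the deduplicated words observed in test data.

    ``kind="semantic"``: pairwise Jensen-Shannon divergence between the
    words' posteriors under the train-fitted models. ``kind="hamming"``:
    pairwise bit differences (models unused beyond the neuron count).
    """
    uniq, counts, _ = unique_patterns(np.asarray(test_words))
    if kind == "semantic":
        table = posterior_table(models, uniq, prior=prior)
        d = pairwise_jensen_shannon(table.posteriors)
        return SimilarityMatrix(uniq, d, "semantic", counts=counts,
                                posteriors=table.posteriors)
    if kind == "hamming":
        return SimilarityMatrix(uniq, hamming_matrix(uniq), "hamming",
                                counts=counts)
    raise ValueError("kind must be 'semantic' or 'hamming'")
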
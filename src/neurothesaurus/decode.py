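"""Decoding novel words by semantic nearest neighbor.

A never-before-seen word ``r`` is decoded by borrowing the posterior of
the most similar reference word ``r'``: semantically (minimal
Jensen-Shannon divergence between posteriors under the train-fitted
thesaurus models), syntactically (minimal Hamming distance), or not at
all (the uniform prior). Quality is the divergence between the "true"
posterior of ``r`` and the estimate, averaged over words that have at
least one close semantic neighbor (default < 0.25 bits).
"""

from __future__ import annotations

import numpy as np

from .thesaurus import hamming_matrix, jensen_shannon, \
    pairwise_jensen_shannon, posterior_table, unique_patterns

__all__ = ["nearest_neighbor_decode", "evaluate_decoding"]

MODES = ("semantic", "hamming", "prior")


def nearest_neighbor_decode(query, reference_patterns, reference_posteriors,
                            models=None, mode: str = "semantic",
                            prior=None, exclude=None):
    """Estimate P(s|query) from one reference word.

    Returns ``(posterior_estimate, neighbor_index, distance)``; the
    neighbor index is None for mode="prior". Ties resolve to the lowest
    pattern index. ``exclude`` removes reference indices (e.g. the query
    itself under leave-one-out).
    """
    refs = np.asarray(reference_patterns)
    posts = np.asarray(reference_posteriors)
    if refs.shape[0] == 0:
        raise ValueError("empty reference set")
    T = posts.shape[1]
    if prior is None:
        prior = np.full(T, 1.0 / T)
    if mode == "prior":
        return np.asarray(prior, dtype=float), None, float("nan")
    allowed = np.ones(refs.shape[0], dtype=bool)
    if exclude is not None:
        allowed[np.asarray(exclude, dtype=int)] = False
    if not allowed.any():
        raise ValueError("exclusions leave an empty reference set")
    if mode == "semantic":
        if models is None:
            raise ValueError("semantic mode needs the thesaurus models")
        qpost = posterior_table(models, np.asarray(query)[None, :],
                                prior=prior).posteriors[0]
        dists = np.array([jensen_shannon(qpost, p) for p in posts])
    elif mode == "hamming":
        q = np.asarray(query)
        dists = (refs != q[None, :]).sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dists[~allowed] = np.inf
    idx = int(np.argmin(dists))
    return posts[idx], idx, float(dists[idx])


def evaluate_decoding(test_words, truth_models, thesaurus_models,
                      close_neighbor_threshold: float = 0.25,
                      prior=None, include_self_matches: bool = False):
    """Leave-one-out decoding benchmark over the unique test words.

    For every unique word the "true" posterior comes from ``truth_models``
    and each mode's estimate from the reference set of the *other* words
    (self excluded unless ``include_self_matches``). Averages are over
    words whose nearest semantic neighbor lies within
    ``close_neighbor_threshold`` bits. Returns ``(summary, per_word)``
    DataFrames: summary has mode, mean/SE of the divergence to truth, n.
    """
    import pandas as pd

    if close_neighbor_threshold <= 0:
        raise ValueError("close_neighbor_threshold must be positive")
    words = np.asarray(test_words)
    uniq, _, _ = unique_patterns(words)
    n = uniq.shape[0]
    T = thesaurus_models.n_stimuli
    if prior is None:
        prior = np.full(T, 1.0 / T)
    posts_ref = posterior_table(thesaurus_models, uniq, prior=prior).posteriors
    posts_truth = posterior_table(truth_models, uniq, prior=prior).posteriors

    d_sem = pairwise_jensen_shannon(posts_ref)
    d_ham = hamming_matrix(uniq)
    if not include_self_matches:
        np.fill_diagonal(d_sem, np.inf)
        np.fill_diagonal(d_ham, np.inf)
    nn_sem = d_sem.argmin(axis=1)
    nn_ham = d_ham.argmin(axis=1)
    nn_sem_dist = d_sem[np.arange(n), nn_sem]

    keep = nn_sem_dist < close_neighbor_threshold
    if not keep.any():
        raise ValueError("no word has a semantic neighbor within "
                         f"{close_neighbor_threshold} bits")

    rows = []
    for i in np.flatnonzero(keep):
        truth = posts_truth[i]
        bits = "".join(str(b) for b in uniq[i])
        for mode in MODES:
            if mode == "semantic":
                est, nb, dist = posts_ref[nn_sem[i]], nn_sem[i], nn_sem_dist[i]
            elif mode == "hamming":
                est, nb, dist = posts_ref[nn_ham[i]], nn_ham[i], d_ham[i, nn_ham[i]]
            else:
                est, nb, dist = np.asarray(prior, dtype=float), None, np.nan
            rows.append({
                "pattern": bits, "mode": mode,
                "neighbor": ("" if nb is None else
                             "".join(str(b) for b in uniq[nb])),
                "neighbor_distance": dist,
                "djs_to_truth": jensen_shannon(truth, est),
            })
    per_word = pd.DataFrame(rows)
    summary = (per_word.groupby("mode", sort=False)["djs_to_truth"]
               .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                    n="count")
               .reset_index())
    return summary, per_word
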
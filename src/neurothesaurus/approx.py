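"""Weighted syntactic approximations of the semantic distance.

Can a fixed, stimulus-independent pattern-space formula reproduce the
semantic distances? Two nested linear families are fitted by least
squares to observed d values:

    delta_1(r_i, r_j) = sum_mu  w_mu  (r_i^mu - r_j^mu)^2      (per neuron)
    delta_2(r_i, r_j) = sum_mu sum_nu w_munu (r_i^mu - r_j^nu)^2

delta_1 with unit weights is exactly the Hamming distance. Fits can be
global (one weight set for all pairs) or per cluster (a separate weight
set within each synonym cluster); comparing the two quantifies how
stimulus-dependent the noise structure is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ApproxWeights", "fit_weighted_similarity", "evaluate_similarity_fit"]


def _features(a: np.ndarray, b: np.ndarray, order: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if order == 1:
        return (a - b) ** 2
    if order == 2:
        # symmetrized so delta(i,j) == delta(j,i)
        f1 = (a[:, :, None] - b[:, None, :]) ** 2
        f2 = (b[:, :, None] - a[:, None, :]) ** 2
        return (0.5 * (f1 + f2)).reshape(a.shape[0], -1)
    raise ValueError("order must be 1 or 2")


@dataclass(frozen=True)
class ApproxWeights:
    """Fitted weights of a delta_1 / delta_2 similarity model.

    For scope="global" ``w`` maps None -> weight vector; for
    scope="per_cluster" it maps each cluster label to its own vector.
    Order-1 weights have length N, order-2 length N*N (row-major mu, nu).
    """

    order: int
    scope: str
    w: dict

    def predict(self, patterns_a, patterns_b, labels=None) -> np.ndarray:
        feats = _features(patterns_a, patterns_b, self.order)
        if self.scope == "global":
            return feats @ self.w[None]
        if labels is None:
            raise ValueError("per-cluster weights need pair labels")
        lab = np.asarray(labels)
        out = np.full(feats.shape[0], np.nan)
        for c, wc in self.w.items():
            m = lab == c
            out[m] = feats[m] @ wc
        return out


def _lstsq(feats: np.ndarray, d: np.ndarray, ridge: float):
    n, p = feats.shape
    if ridge > 0:
        a = feats.T @ feats + ridge * np.eye(p)
        return np.linalg.solve(a, feats.T @ d)
    if n < p:
        raise ValueError(f"underdetermined fit: {n} pairs for {p} weights")
    w, _, rank, _ = np.linalg.lstsq(feats, d, rcond=None)
    if rank < p:
        raise ValueError(f"underdetermined fit: design rank {rank} < {p} "
                         "weights; add pairs or use a ridge penalty")
    return w


def fit_weighted_similarity(patterns_a, patterns_b, d, order: int = 2,
                            scope: str = "global", labels=None,
                            ridge: float = 0.0) -> ApproxWeights:
    """Least-squares fit of delta_order to observed distances over pairs.

    ``patterns_a``/``patterns_b`` are the two ends of each training pair,
    ``d`` the corresponding semantic distances. With
    ``scope="per_cluster"``, ``labels`` gives each pair's cluster and a
    separate weight vector is fitted within every cluster.
    """
    d = np.asarray(d, dtype=float)
    feats = _features(patterns_a, patterns_b, order)
    if scope == "global":
        return ApproxWeights(order, "global", {None: _lstsq(feats, d, ridge)})
    if scope == "per_cluster":
        if labels is None:
            raise ValueError("per-cluster scope needs pair labels")
        lab = np.asarray(labels)
        w = {}
        for c in np.unique(lab):
            m = lab == c
            w[c] = _lstsq(feats[m], d[m], ridge)
        return ApproxWeights(order, "per_cluster", w)
    raise ValueError("scope must be 'global' or 'per_cluster'")


def evaluate_similarity_fit(weights: ApproxWeights, patterns_a, patterns_b,
                            d, labels=None, n_bins: int = 20):
    """Out-of-sample R^2 and the column-normalized joint histogram.

    The histogram bins true distances (x) against predictions (y) into
    ``n_bins`` equal-width bins over the observed ranges; each vertical
    slice (fixed true-d bin) is normalized to sum to one. Returns a dict
    with r2, hist, x_edges, y_edges, predictions.
    """
    d = np.asarray(d, dtype=float)
    pred = weights.predict(patterns_a, patterns_b, labels=labels)
    ok = ~np.isnan(pred)
    ss_res = ((d[ok] - pred[ok]) ** 2).sum()
    ss_tot = ((d[ok] - d[ok].mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    hist, x_edges, y_edges = np.histogram2d(d[ok], pred[ok], bins=n_bins)
    col = hist.sum(axis=1, keepdims=True)
    col[col == 0] = 1.0
    return {"r2": float(r2), "hist": hist / col, "x_edges": x_edges,
            "y_edges": y_edges, "predictions": pred}
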
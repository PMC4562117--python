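"""Stimulus-conditional encoding-noise models.

For each stimulus ``s`` (a time bin of the repeated clip) the population's
trial-to-trial variability is modelled either as conditionally independent
neurons,

    P_ind(r|s) = prod_i P(r_i|s),

or as the pairwise maximum-entropy (Ising) distribution

    P2(r|s) = exp( sum_i alpha_i(s) r_i + sum_{i<j} beta_ij(s) r_i r_j ) / Z(s),

the least-structured distribution matching the per-stimulus firing rates
and pairwise co-firing probabilities. The log-likelihood is concave and
its gradient in alpha_i is <r_i>_data - <r_i>_model (and the analogous
pair expression for beta_ij), so the fit is a plain convex optimization
over the exactly enumerated 2^N pattern space.

Empirical moments are smoothed by mixing ``pseudocount`` pseudo-observations
of the all-ones and the all-zeros word into the sample. This keeps every
rate strictly inside (0, 1), and — because it is a mixture of genuine
distributions — the smoothed first and second moments remain jointly
realizable, so the maxent fit always has a solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "CondIndepModel",
    "PairwiseMaxEntModel",
    "PatternDistribution",
    "empirical_moments",
    "smoothed_moments",
    "fit_cond_independent",
    "fit_pairwise_maxent",
    "enumerate_distribution",
    "pattern_log_probability",
    "log_likelihood_matrix",
    "log_likelihood_ratio",
    "sample_patterns",
    "spike_count_distribution",
]

LN2 = np.log(2.0)
#: Largest population size for which 2^N patterns are enumerated exactly.
DEFAULT_EXACT_CAP = 20

# chunk rows of the 2^N state table so pair features never exceed ~1.6e7 floats
_CHUNK_BUDGET = 16_000_000


@lru_cache(maxsize=8)
def _enumeration(n_neurons: int):
    """All 2^N binary patterns (bit i of the row index = neuron i)."""
    states = ((np.arange(1 << n_neurons)[:, None] >> np.arange(n_neurons)) & 1)
    return states.astype(np.float64)


@lru_cache(maxsize=4)
def _enumeration_pairs(n_neurons: int):
    """Cached 2^N x N(N-1)/2 pair-product features, or None if too large."""
    iu, ju = np.triu_indices(n_neurons, k=1)
    if (1 << n_neurons) * max(len(iu), 1) > _CHUNK_BUDGET:
        return None
    states = _enumeration(n_neurons)
    return states[:, iu] * states[:, ju]


def _pair_idx(n_neurons: int):
    return np.triu_indices(n_neurons, k=1)


def _check_cap(n_neurons: int, exact_cap: int) -> None:
    if n_neurons > exact_cap:
        raise ValueError(
            f"population size {n_neurons} exceeds the exact-enumeration cap "
            f"{exact_cap}; reduce the neuron group size (pairwise maxent fits "
            "here enumerate all 2^N patterns)")


def _pattern_matrix(patterns) -> np.ndarray:
    pats = np.asarray(patterns, dtype=np.float64)
    if pats.ndim == 1:
        pats = pats[None, :]
    if pats.ndim != 2:
        raise ValueError("patterns must be a (n_samples, n_neurons) array")
    return pats


def empirical_moments(patterns) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in first (<r_i>) and second (<r_i r_j>, i<j) moments of a sample."""
    pats = _pattern_matrix(patterns)
    if pats.shape[0] == 0:
        raise ValueError("empty pattern sample")
    iu, ju = _pair_idx(pats.shape[1])
    return pats.mean(axis=0), (pats[:, iu] * pats[:, ju]).mean(axis=0)


def smoothed_moments(patterns, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    """Moments after mixing pseudo-observations of the 1...1 and 0...0 words.

    With ``R`` samples and pseudocount ``c`` the first moments become
    ``(count_i + c) / (R + 2c)`` and pair moments ``(paircount_ij + c) /
    (R + 2c)``: the moment vector of an achievable distribution.
    """
    pats = _pattern_matrix(patterns)
    R, N = pats.shape
    if R == 0:
        raise ValueError("empty pattern sample")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    iu, ju = _pair_idx(N)
    denom = R + 2.0 * pseudocount
    first = (pats.sum(axis=0) + pseudocount) / denom
    second = ((pats[:, iu] * pats[:, ju]).sum(axis=0) + pseudocount) / denom
    return first, second


# ---------------------------------------------------------------------------
# model containers


@dataclass(frozen=True)
class CondIndepModel:
    """Conditionally independent encoding model: per-stimulus Bernoulli rates.

    ``rates[s, i]`` is the smoothed spiking probability of neuron ``i``
    given stimulus ``s``; strictly inside (0, 1).
    """

    rates: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        r = np.atleast_2d(np.asarray(self.rates, dtype=np.float64))
        if np.any(r <= 0) or np.any(r >= 1):
            raise ValueError("rates must lie strictly in (0, 1); "
                             "use a positive pseudocount")
        object.__setattr__(self, "rates", r)

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]


@dataclass(frozen=True)
class PairwiseMaxEntModel:
    """Per-stimulus pairwise maximum-entropy (Ising) model.

    Natural logs internally: ``logZ[s]`` normalizes
    ``exp(alpha[s]·r + beta[s]·(r_i r_j))``. ``moment_error[s]`` is the
    max absolute mismatch between model and (smoothed) data moments at
    the end of the fit; ``converged[s]`` flags whether it met ``tol``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    logZ: np.ndarray
    pseudocount: float = 0.5
    l2_penalty: float = 0.0
    moment_error: np.ndarray | None = field(default=None)
    n_iterations: np.ndarray | None = field(default=None)
    converged: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.alpha, dtype=np.float64))
        b = np.atleast_2d(np.asarray(self.beta, dtype=np.float64))
        z = np.atleast_1d(np.asarray(self.logZ, dtype=np.float64))
        N = a.shape[1]
        if b.shape != (a.shape[0], N * (N - 1) // 2):
            raise ValueError("beta must have one row per stimulus and "
                             "N(N-1)/2 columns")
        if z.shape != (a.shape[0],):
            raise ValueError("logZ must have one entry per stimulus")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "logZ", z)

    @property
    def n_stimuli(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.alpha.shape[1]

    def to_npz(self, path) -> None:
        np.savez(path, alpha=self.alpha, beta=self.beta, logZ=self.logZ,
                 pseudocount=np.float64(self.pseudocount),
                 l2_penalty=np.float64(self.l2_penalty),
                 moment_error=(self.moment_error if self.moment_error is not None
                               else np.full(self.n_stimuli, np.nan)),
                 n_iterations=(self.n_iterations if self.n_iterations is not None
                               else np.zeros(self.n_stimuli, dtype=int)),
                 converged=(self.converged if self.converged is not None
                            else np.ones(self.n_stimuli, dtype=bool)))

    @classmethod
    def from_npz(cls, path) -> "PairwiseMaxEntModel":
        with np.load(path) as f:
            return cls(f["alpha"], f["beta"], f["logZ"],
                       pseudocount=float(f["pseudocount"]),
                       l2_penalty=float(f["l2_penalty"]),
                       moment_error=f["moment_error"],
                       n_iterations=f["n_iterations"],
                       converged=f["converged"])


@dataclass(frozen=True)
class PatternDistribution:
    """Explicit distribution over all 2^N patterns of one stimulus."""

    support: np.ndarray  # (2^N, N) uint8
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("probabilities must sum to 1 within 1e-10")
        object.__setattr__(self, "support", np.asarray(self.support, dtype=np.uint8))
        object.__setattr__(self, "probs", p)


# ---------------------------------------------------------------------------
# energies over the enumerated pattern space


def _log_weights(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Unnormalized log-probabilities over all 2^N patterns (chunked)."""
    N = alpha.shape[0]
    states = _enumeration(N)
    iu, ju = _pair_idx(N)
    n_pairs = len(iu)
    out = states @ alpha
    if n_pairs:
        pairs = _enumeration_pairs(N)
        if pairs is not None:
            out += pairs @ beta
        else:
            chunk = max(1, _CHUNK_BUDGET // n_pairs)
            for lo in range(0, states.shape[0], chunk):
                blk = states[lo:lo + chunk]
                out[lo:lo + chunk] += (blk[:, iu] * blk[:, ju]) @ beta
    return out


def _model_moments(probs: np.ndarray, N: int) -> np.ndarray:
    """Concatenated (first, second) moments of an enumerated distribution."""
    states = _enumeration(N)
    iu, ju = _pair_idx(N)
    first = probs @ states
    n_pairs = len(iu)
    second = np.zeros(n_pairs)
    if n_pairs:
        pairs = _enumeration_pairs(N)
        if pairs is not None:
            second = probs @ pairs
        else:
            chunk = max(1, _CHUNK_BUDGET // n_pairs)
            for lo in range(0, states.shape[0], chunk):
                blk = states[lo:lo + chunk]
                second += probs[lo:lo + chunk] @ (blk[:, iu] * blk[:, ju])
    return np.concatenate([first, second])


# ---------------------------------------------------------------------------
# fitting


def _per_stimulus(data) -> list[np.ndarray]:
    """Normalize input to a list of (repeats, neurons) arrays, one per stimulus."""
    from .raster import BinnedRaster

    if isinstance(data, BinnedRaster):
        return [data.words[:, t, :].astype(np.float64) for t in range(data.n_bins)]
    if isinstance(data, np.ndarray) and data.ndim == 2:
        return [_pattern_matrix(data)]
    return [_pattern_matrix(p) for p in data]


def fit_cond_independent(data, pseudocount: float = 0.5) -> CondIndepModel:
    """Fit per-stimulus independent Bernoulli rates with additive smoothing.

    ``p_i(s) = (spike count + pseudocount) / (R_s + 2 * pseudocount)``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive (a zero pseudocount "
                         "can produce degenerate rates of exactly 0 or 1)")
    groups = _per_stimulus(data)
    rates = np.vstack([
        (g.sum(axis=0) + pseudocount) / (g.shape[0] + 2.0 * pseudocount)
        for g in groups])
    return CondIndepModel(rates, pseudocount)


def _fit_one_maxent(moments: np.ndarray, N: int, l2_penalty: float,
                    tol: float, max_iter: int):
    """Convex fit of one stimulus: minimize logZ(theta) - theta.m (+ ridge)."""

    def objective(theta):
        lw = _log_weights(theta[:N], theta[N:])
        logZ = logsumexp(lw)
        probs = np.exp(lw - logZ)
        grad = _model_moments(probs, N) - moments
        f = logZ - theta @ moments
        if l2_penalty > 0:
            f += 0.5 * l2_penalty * theta @ theta
            grad = grad + l2_penalty * theta
        return f, grad

    theta0 = np.zeros(N + N * (N - 1) // 2)
    # initialize fields at the independent solution: alpha_i = logit(p_i)
    theta0[:N] = np.log(moments[:N] / (1.0 - moments[:N]))
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-13, "gtol": tol / 10})
    theta = res.x
    lw = _log_weights(theta[:N], theta[N:])
    logZ = logsumexp(lw)
    probs = np.exp(lw - logZ)
    err = np.max(np.abs(_model_moments(probs, N) - moments)) if l2_penalty == 0 \
        else np.max(np.abs(res.jac))
    return theta[:N], theta[N:], float(logZ), float(err), int(res.nit)


def fit_pairwise_maxent(data, l2_penalty: float = 0.0, tol: float = 1e-4,
                        max_iter: int = 1000,
                        exact_cap: int = DEFAULT_EXACT_CAP,
                        pseudocount: float = 0.5) -> PairwiseMaxEntModel:
    """Fit per-stimulus pairwise maxent models by exact-gradient L-BFGS.

    The penalized log-likelihood is concave, so any first-order method
    reaches the global optimum; convergence is declared when the max
    absolute mismatch between model and smoothed data moments is <= ``tol``
    (with ``l2_penalty == 0``; with a ridge term the gradient norm is used).
    Non-convergence is flagged in the result's diagnostics, never silent.
    """
    groups = _per_stimulus(data)
    N = groups[0].shape[1]
    _check_cap(N, exact_cap)
    alphas, betas, logZs, errs, nits = [], [], [], [], []
    for g in groups:
        if g.shape[1] != N:
            raise ValueError("all stimuli must share the same neuron set")
        first, second = smoothed_moments(g, pseudocount)
        a, b, z, e, it = _fit_one_maxent(np.concatenate([first, second]), N,
                                         l2_penalty, tol, max_iter)
        alphas.append(a); betas.append(b); logZs.append(z)
        errs.append(e); nits.append(it)
    errs = np.array(errs)
    return PairwiseMaxEntModel(np.vstack(alphas), np.vstack(betas),
                               np.array(logZs), pseudocount=pseudocount,
                               l2_penalty=l2_penalty, moment_error=errs,
                               n_iterations=np.array(nits),
                               converged=errs <= max(tol, 1e-12) * 1.5
                               if l2_penalty == 0 else errs <= tol * 1.5)


# ---------------------------------------------------------------------------
# evaluation


def enumerate_distribution(model, stimulus: int,
                           exact_cap: int = DEFAULT_EXACT_CAP) -> PatternDistribution:
    """Explicit probabilities over all 2^N patterns for one stimulus."""
    N = model.n_neurons
    _check_cap(N, exact_cap)
    states = _enumeration(N)
    if isinstance(model, CondIndepModel):
        p = model.rates[stimulus]
        logp = states @ np.log(p) + (1.0 - states) @ np.log1p(-p)
        probs = np.exp(logp)
    elif isinstance(model, PairwiseMaxEntModel):
        lw = _log_weights(model.alpha[stimulus], model.beta[stimulus])
        probs = np.exp(lw - logsumexp(lw))
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    probs = probs / probs.sum()
    return PatternDistribution(states.astype(np.uint8), probs)


def log_likelihood_matrix(model, patterns) -> np.ndarray:
    """log2 P(r|s) for every pattern (rows) and stimulus (columns).

    Finite for every binary pattern: both model families put strictly
    positive probability on all 2^N words.
    """
    pats = _pattern_matrix(patterns)
    if pats.shape[1] != model.n_neurons:
        raise ValueError("pattern length does not match the model's neuron count")
    if isinstance(model, CondIndepModel):
        logp = np.log(model.rates)          # (T, N)
        log1mp = np.log1p(-model.rates)
        out = pats @ logp.T + (1.0 - pats) @ log1mp.T
    elif isinstance(model, PairwiseMaxEntModel):
        iu, ju = _pair_idx(model.n_neurons)
        feats = np.hstack([pats, pats[:, iu] * pats[:, ju]])
        theta = np.hstack([model.alpha, model.beta])
        out = feats @ theta.T - model.logZ[None, :]
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return out / LN2


def pattern_log_probability(model, stimulus: int, pattern) -> float:
    """log2 probability of one pattern under one stimulus's model."""
    T = model.n_stimuli
    if not 0 <= stimulus < T:
        raise IndexError(f"stimulus index {stimulus} outside [0, {T})")
    return float(log_likelihood_matrix(model, np.asarray(pattern))[0, stimulus])


def log_likelihood_ratio(model_a, model_b, heldout) -> np.ndarray:
    """Per-stimulus held-out log2-likelihood difference (A minus B)."""
    if model_a.n_neurons != model_b.n_neurons:
        raise ValueError("models were fitted on different neuron sets")
    groups = _per_stimulus(heldout)
    if len(groups) != model_a.n_stimuli or len(groups) != model_b.n_stimuli:
        raise ValueError("held-out data must provide one sample set per stimulus")
    out = np.empty(len(groups))
    for s, g in enumerate(groups):
        lla = log_likelihood_matrix(model_a, g)[:, s].sum()
        llb = log_likelihood_matrix(model_b, g)[:, s].sum()
        out[s] = lla - llb
    return out


def sample_patterns(model, stimulus: int, n: int, seed: int,
                    exact_cap: int = DEFAULT_EXACT_CAP) -> np.ndarray:
    """Draw i.i.d. words from the enumerated distribution (seeded)."""
    dist = enumerate_distribution(model, stimulus, exact_cap=exact_cap)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(dist.probs), size=int(n), p=dist.probs)
    return dist.support[idx]


def spike_count_distribution(source) -> np.ndarray:
    """Probability of observing k = 0..N spikes in a word."""
    if isinstance(source, PatternDistribution):
        counts = source.support.sum(axis=1).astype(int)
        N = source.support.shape[1]
        return np.bincount(counts, weights=source.probs, minlength=N + 1)
    pats = _pattern_matrix(source)
    N = pats.shape[1]
    counts = pats.sum(axis=1).astype(int)
    return np.bincount(counts, minlength=N + 1) / pats.shape[0]
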
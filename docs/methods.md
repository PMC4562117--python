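# Methods

## Data model

The unit of analysis is a binary raster `words[repeat, time_bin, neuron]`
from repeated presentations of one identical stimulus clip. Spike times
are discretized into half-open bins `[tΔ, (t+1)Δ)` (default Δ = 20 ms); a
trailing partial bin is dropped, so a clip of duration `D` yields
`T = floor(D/Δ)` stimuli. Bins are binarized — two spikes from one
neuron in one bin count as a single 1 — because the codeword alphabet is
the set of spike/silence patterns, not count vectors. The time-bin index
doubles as the stimulus identity, with a uniform prior over the `T` bins.

Repeats are split at random (seeded) into a train and a test half; the
time axis is never split, so both halves see every stimulus. The train
half fits the encoding models; the test half supplies the words whose
similarity structure, cluster reliability, information curves and
decoding are measured. This is the only split consistent with asking how
well structure learned from some repeats describes responses in others.

## Stimulus-conditional encoding models

Two families model the trial-to-trial noise `P(r|s)` at each stimulus:

- **Conditionally independent**: `P(r|s) = Πᵢ pᵢ(s)^rᵢ (1−pᵢ(s))^(1−rᵢ)`
  with smoothed rates `pᵢ(s) = (cᵢ + pc) / (R + 2·pc)`.
- **Pairwise maximum entropy (Ising)**:
  `P(r|s) ∝ exp(Σ αᵢ(s) rᵢ + Σᵢ<ⱼ βᵢⱼ(s) rᵢrⱼ)`, the maximum-entropy
  distribution matching the smoothed first and second moments.

Smoothing mixes `pc` pseudo-observations (default 0.5) of the all-ones
and all-zeros words into each stimulus's sample. This choice does two
jobs at once: it keeps every rate strictly inside (0, 1) when a neuron
never or always fired in a stimulus's repeats, and — because the
smoothed moment vector is the moment vector of an actual distribution (a
mixture) — it guarantees the maxent problem is feasible.

The maxent fit minimizes `log Z(θ) − θ·m` (θ = (α, β), m = smoothed
moments) with L-BFGS-B on the exact gradient
`⟨φ(r)⟩_model − m`; the objective is convex, so the optimum is global.
The partition function and all model moments are computed by exact
enumeration of the `2^N` pattern space (capped at N = 20; the intended
group size). Convergence is declared when the maximum absolute moment
mismatch is ≤ `tol` (default 1e-4); non-convergence is flagged in the
returned diagnostics, never silent. An optional ridge (`l2_penalty`) is
available for badly undersampled stimuli and shifts the convergence
check to the penalized gradient norm. All internal logs are natural;
every reported entropy, information and divergence is in bits.

## Semantic distance and the thesaurus

The posterior of any word — observed or novel — is
`P(s|r) ∝ P(r|s) P(s)` over the train-half stimuli (likelihoods are
strictly positive by construction, so the marginal never vanishes).
The semantic distance is the base-2 Jensen-Shannon divergence between
posteriors, `d = H[(P+Q)/2] − (H[P]+H[Q])/2 ∈ [0, 1]` bits. The
similarity matrix is computed over the deduplicated test words;
multiplicities are retained separately for reliability and information
analyses. Words present in both halves are treated exactly like
test-only words: the posterior always comes from the model, never from
raw counts.

Average-linkage agglomerative clustering of the distance matrix gives
the dendrogram; a cut at `k` labels every test trial through its word.
A novel word absent from the leaves is assigned the cluster of its
semantically nearest leaf (ties to the lowest pattern index), consistent
with the decoding rule. Clustering validity uses the Hubert–Levin
C-Index — `(S − S_min)/(S_max − S_min)` over within-cluster distance
sums, smaller is better — with significance from 100 symmetric shuffles
of the off-diagonal distances, each re-clustered before scoring; the
p-value is the fraction of shuffles at or below the observed C-Index.

## Information estimation

Plug-in entropies of discrete samples are biased down by finite
sampling. Following the extrapolation approach, the plug-in entropy is
evaluated at data fractions {1.0, 0.9, 0.8, 0.7, 0.5}, fit as a
quadratic in inverse sample size, and read off at 1/n → 0. One
implementation detail improves on the usual recipe at no cost: instead
of averaging a finite number of random subsamples per fraction, the
expectation of the plug-in entropy over subsamples drawn without
replacement is computed in closed form (each symbol's subsample count is
hypergeometric). This removes subsampling noise entirely and makes the
estimator deterministic. In calibration against enumerated ground-truth
distributions at 200 samples per stimulus, the analytic protocol roughly
halves both the residual bias and the spread of the subsampled version;
residual bias of order 0.03–0.06 bits per stimulus remains at that
sample size and is the dominant measurement error in information
fractions. Negative corrected informations are clipped to zero.

`I(s;r)` is `H(r) − ⟨H(r|t)⟩_t` with the pooled entropy over all repeats
and bins; `I(s;C_k(r))` replaces words by cluster labels, with the
conditional term the per-bin label entropy averaged over bins. Both
numerator and denominator of the information fraction are
extrapolation-corrected (plug-in variants are available via
`extrapolate=False`; the plug-in estimator is the one with the exact
monotonicity guarantees asserted in the tests). The exact entropy of a
fitted model (by enumeration) is exposed as the `model_upper_bound`
companion to the sampled estimates, and the multi-information
`I_N = H_ind − H_joint` quantifies stimulus-conditional network
correlation either exactly from a model or from samples.

## Decoding

For each unique held-out word, the "true" posterior comes from models
refitted on the test half (configurable to the train half), and three
estimates are compared by their divergence to it: the posterior of the
semantically nearest other word (leave-one-out), of the Hamming-nearest
other word, and the uniform prior. Averages are restricted to words
whose nearest semantic neighbor lies within 0.25 bits (the
close-neighbor threshold), reported as mean ± SE per mode. Ties resolve
to the lowest pattern index so runs are bit-reproducible.

## Embedding

Because semantic distances saturate at 1 bit, only local distances are
metrically trustworthy. Words (or cluster centroids, via mean
inter-cluster distance) closer than ε = 0.5 bits are joined in a graph;
geodesics are all-pairs shortest weighted paths; classical Torgerson MDS
of the geodesic matrix of the largest connected component gives
coordinates (eigen-signs fixed by a largest-coordinate convention;
disconnected nodes are reported, not dropped silently). Fit quality per
dimensionality is the residual variance `1 − r²(d_G, d_Iso)`. The
cluster-triggered average is the mean stimulus segment in the 250 ms
window ending at the response bin, per cluster; its pairwise waveform
correlations versus inter-cluster distance carry a Spearman trend
statistic.

## Weighted similarity approximations

Two linear families probe whether a fixed pattern-space formula can
reproduce `d`: `δ₁ = Σ w_μ (rᵢ^μ − rⱼ^μ)²` (unit weights = Hamming) and
`δ₂ = Σ_μν w_μν (rᵢ^μ − rⱼ^ν)²` (features symmetrized so predictions are
pair-order invariant). Weights are fit by least squares, globally or per
cluster; evaluation reports out-of-sample R² and a column-normalized
joint histogram of true versus predicted distances. Note these models
have no intercept: a constant distance function is representable only on
pair sets with compatible features. Underdetermined fits raise an error
with the design rank; a ridge toggle handles ill-conditioning.

## Synthetic data generator

The generator plants a known codebook: `T` stimuli in `K` contiguous
blocks, each block one semantic cluster sharing a generating pairwise
maxent model up to a small per-stimulus logit-scale jitter (SD 0.05).
Each cluster assigns roles to neurons — precise-on (rate 0.985),
precise-off (0.005), and noisy (uniform rates, 0.40–0.60 in "event"
clusters, 0.10–0.30 in baseline clusters). Event clusters (default 2 of
8) additionally couple their noisy neurons (β = 0.3), reproducing the
empirical coupling of high firing rates with strong stimulus-conditional
correlation. Words are sampled from the exactly enumerated generating
distributions, so ground-truth posteriors, the exact semantic distance
matrix, and exact information quantities are all computable.

Neuron roles are rejection-sampled so every cluster keeps at least one
precise-off neuron inside every other cluster's precise-on set (and vice
versa): mimicking a foreign signature then requires precise-bit flips,
which keeps the planted clusters statistically separable. With the
default rates the exact fraction of stimulus information carried by the
ground-truth cluster identity is 0.975–0.987 across structure draws —
the planted structure, not the estimators, sets the ceiling the recovery
tests measure against.

Default sizes (N = 10, T = 100, R = 400, K = 8) keep a full pipeline
run — generation, 100 maxent fits, a ~600-word thesaurus, clustering,
information curves, decoding and 100 significance shuffles — around half
a minute on one CPU; the unit-test fixture uses a smaller cousin
(N = 8, T = 24, R = 120, K = 4).

What the generator does *not* emulate: temporal dependencies across bins
(each stimulus is sampled independently), stimulus-driven receptive-field
structure (rates are assigned, not derived from the waveform), higher-
than-pairwise correlations, and non-stationarity across repeats. Passing
the recovery tests therefore demonstrates correctness of the machinery
on data matching the model class, not that real recordings satisfy these
assumptions.

## Numerical choices and conventions

- Pattern index convention: bit `i` of the enumeration index is neuron
  `i`, so the support row order is fixed and shared by all modules.
- Deduplicated words are sorted lexicographically (np.unique); all
  distance matrices follow that order.
- Dendrogram construction is deterministic given its input; tie order
  inside the linkage is scipy's.
- JSD values are clipped to [0, 1] against rounding; posterior rows are
  renormalized after log-space Bayes to guard 1e-16-level drift.
- Posteriors whose likelihood maxima fall below 1e-300 trigger a warning
  (they cannot occur with smoothed models but could with hand-built ones).
- Seeds: every stochastic routine takes an explicit seed; a pipeline run
  derives all of its randomness from the single config seed.

## Limitations

- Exact enumeration limits populations to N ≤ 20 neurons per group (the
  intended scale); larger groups need sampling-based fitting, which is
  out of scope here.
- The extrapolation estimator retains a residual downward bias in
  per-stimulus word entropies at a few hundred repeats (see above);
  information fractions inherit a corresponding percent-level
  uncertainty.
- Per-stimulus models are fit independently; no smoothing across
  adjacent time bins, no stimulus-parametric (LN/GLM) structure.
- The weighted-similarity module fits only first- and second-order
  linear families; it is a diagnostic, not a general regressor of `d`.
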
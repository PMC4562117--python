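# neural-thesaurus

Semantic similarity analysis for neural population codes.

When the same stimulus clip is shown to a neural population hundreds of
times, the population never answers twice with exactly the same spike
pattern. Which of those binary activity patterns ("words") are
interchangeable — synonyms carrying the same message — and which are not?
Pattern-space intuition (e.g. Hamming distance, the number of neurons
that switch between spiking and silence) measures similarity of *form*;
this package measures similarity of *meaning*.

It is aimed at systems/computational neuroscientists analyzing
repeated-stimulus population recordings (retinal ganglion cells, cortical
populations) binned into binary words, and at anyone who needs a careful
reference implementation of stimulus-conditional maximum-entropy noise
models with information-theoretic downstream analyses.

## The method

Responses are binned (20 ms by default) into words `r ∈ {0,1}^N`; the
time bin `t` of the repeated clip identifies the stimulus `s(t)`. For
each stimulus the trial-to-trial noise is modeled by the pairwise
maximum-entropy (Ising) distribution

    P(r|s) = 1/Z(s) · exp( Σᵢ αᵢ(s) rᵢ + Σᵢ<ⱼ βᵢⱼ(s) rᵢ rⱼ ),

the least-structured model matching each stimulus's firing rates and
pairwise co-firing probabilities. The log-likelihood is concave with
gradient `⟨rᵢ⟩_data − ⟨rᵢ⟩_model`, so the fit is an exact convex
optimization over the enumerated pattern space (N ≤ 20).

The *meaning* of a word is its posterior over stimuli,
`P(s|r) ∝ P(r|s) P(s)`, and the semantic distance between two words is
the Jensen-Shannon divergence between their posteriors (base-2 logs):

    d(rᵢ, rⱼ) = D_JS( P(s|rᵢ) ‖ P(s|rⱼ) )  ∈ [0, 1] bits,

0 for perfect synonyms, 1 for words with non-overlapping meaning. The
pairwise distance matrix over held-out words is clustered by
average-linkage agglomeration into synonym groups; replacing each word by
its cluster label `C_k(r)` and computing `I(s; C_k(r)) / I(s; r)` asks how
much stimulus information survives the compression. Entropies and
informations are corrected for finite sampling by quadratic extrapolation
of the subsampled plug-in entropy to infinite data. Novel words are
decoded by borrowing the posterior of their semantically nearest
neighbor, benchmarked against Hamming nearest neighbor and the prior,
and the codebook geometry is mapped by Isomap (ε-neighborhood geodesics
plus classical MDS).

A planted-codebook generator (`synthgen`) produces rasters with known
ground truth — clusters of stimuli sharing precise always-on/always-off
neurons plus noisy neurons, with couplings at high-rate "event" epochs —
so every stage of the pipeline is testable end to end without
recordings.

## Worked example

```python
from neurothesaurus import ThesaurusModel, GeneratorConfig, \
    generate_codebook_dataset

cfg = GeneratorConfig(n_neurons=8, n_stimuli=50, n_repeats=200,
                      n_clusters=5, n_precise_on=2, n_noisy=3, seed=42)
raster, truth, waveform = generate_codebook_dataset(cfg)

results = ThesaurusModel(raster).fit(seed=42)
print(results.summary(k=5))
```

```
Neural thesaurus fit
==========================================================
Encoding model:        pairwise (pseudocount 0.5)
Neurons:               8
Stimuli (time bins):   50
Repeats (train/test):  100/100
Unique test words:     119
Semantic distance:     mean 0.914 bits, median 1.000 bits
Synonym pairs (<0.25): 2.7%
Maxent fits converged: 50/50
C-Index at k=5:       0.1673
```

Half of the 200 repeats train the per-stimulus encoding models; the 119
distinct words observed in the other half form the thesaurus. Most word
pairs are semantically maximal (median 1.000 bits — different meanings),
while 2.7% are near-synonyms; the low C-Index says the synonym clusters
are tight relative to the distance distribution.

```python
print(results.information_curve([1, 2, 5, 10, 50]).to_string(index=False))
```

```
 k  info_bits  fraction
 1   0.000000  0.000000
 2   0.943175  0.400888
 5   2.207514  0.938284
10   2.213753  0.940936
50   2.308157  0.981062
```

Five clusters — the number planted by the generator — already retain 94%
of the stimulus information carried by the full words: cluster identity
is almost all that matters.

```python
summary, per_word = results.decoding()
print(summary.to_string(index=False))
```

```
    mode     mean      sem  n
semantic 0.351379 0.044528 77
 hamming 0.581223 0.041191 77
   prior 0.724391 0.014262 77
```

For each held-out word (77 had a semantic neighbor within 0.25 bits),
the divergence between its true posterior and the estimate: the semantic
nearest neighbor (0.35 bits) beats the Hamming nearest neighbor
(0.58 bits), which beats knowing only the prior (0.72 bits).

## Command line

```bash
neural-thesaurus all -c config.yaml      # simulate→fit→…→embed
neural-thesaurus cluster -c config.yaml  # one stage, from saved artifacts
```

The YAML config selects input (spike-list CSV, raster NPZ, or the
synthetic generator), bin width, train fraction, the k grid, thresholds
(0.25-bit close-neighbor, 0.5-bit ε-neighborhood) and the master seed;
every artifact is written to the run directory as CSV/NPZ plus a JSON
manifest.

## Documentation

`docs/methods.md` describes the model and estimators, every tunable
parameter with its default and rationale, what the synthetic generator
does and does not emulate, and known limitations.
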
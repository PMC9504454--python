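# ctxpred

**Context-dependent prediction of DNA bases, and what the predictions reveal.**

How well can the base at a genomic position be predicted from its flanking
sequence?  `ctxpred` estimates the conditional distribution

```
p(base_i = x | context_i),        x ∈ {A, C, G, T}
```

where `context_i` is the pair of flanks of equal size around position *i*
(the focus base itself is excluded), and predicts the missing base as

```
base_i* = argmax_x p(base_i = x | context_i).
```

Three model families share a common prediction contract:

* **central models** — counts of the focus base per both-flank context of
  size *k* (3 × 4^2k free parameters; k = 3 gives 12,288, "~12,000");
* **Markov models** — order-*k* conditioning on the left flank only
  (3 × 4^k parameters; k = 14 gives ~0.8 billion, stored sparsely);
* a **conv + bidirectional-LSTM network** — one-hot contexts, convolutional
  "word encoding" of tri-/quadro-nucleotides, bidirectional LSTM layers and
  a 4-way softmax head, trained by categorical cross-entropy in rounds with
  validation (implemented in numpy with manual backpropagation, gradient-
  checked in the test suite).

Around the models sits the evaluation machinery: accuracy overall / per
chromosome / per annotation (BED intervals and soft-masked repeats),
strand-averaged (bidirectional) prediction, reference-base probability
arrays, 50×50 model-vs-model probability density grids, the Vuong
likelihood-ratio z-test for non-nested models with per-chromosome tests
pooled into a genome-level statistic, and a windowed Fourier pipeline that
segments chromosomes into adjacent 1 Mb blocks (excluding blocks with more
than 10% disqualified positions), transforms reference-base-probability or
GC/AT indicator arrays, and reports the Euclidean norm of the Fourier
magnitudes in a sliding window of 1,000 frequencies (step 100) — the
"cumulative power spectrum in a running window" used to detect
nucleosome-scale periodicities.

A synthetic-genome generator (known Markov chains, planted periodic GC
modulation, soft-masked repeat insertions, N blocks) provides test data
with exact oracles: stationary distributions, Bayes accuracy and
conditional entropy of the generating chain.

Intended users: computational biologists studying sequence predictability,
compositional periodicity, or model comparison on genomes, and anyone who
needs a clean, tested reference implementation of these statistics.

## Worked example

```python
import ctxpred as cp

# a 1 Mb genome from a known order-2 chain with a planted 200 bp GC period
spec = cp.small_genome_spec(seed=1, length=1_000_000)
genome, chain = cp.generate_genome(spec)

central = cp.CentralModel(genome, k=3).fit()
markov = cp.MarkovModel(genome, k=2).fit()
print(central.summary())

print(cp.accuracy(central, genome).summary())
print("Bayes accuracy (left, order 2): %.4f" % chain.bayes_accuracy(2))

mask = cp.build_position_mask(genome, 3)
pos = cp.sample_test_positions(genome, mask, fraction=0.10, seed=1)
lr = cp.vuong_test(cp.log_likelihoods(central, genome, pos),
                   cp.log_likelihoods(markov, genome, pos))
print(lr.summary())

arr = cp.reference_base_probabilities(central, genome)
ws = cp.windowed_norm_spectrum(cp.fourier_magnitudes(arr.values),
                               window=1000, step=100)
f0, _ = cp.peak_window(ws)
pw = cp.frequency_window_to_periods(f0, 1000, len(genome))
print(f"peak window: [{f0}, {f0+1000}) -> periods "
      f"({pw.period_low} bp, {pw.period_high} bp), mid {pw.period_mid} bp")
```

Output:

```
Central count model (k = 3)
============================================
context width          6 bases
free parameters        12,288 (dense, 3 x 4^6)
contexts observed      4,064
training positions     999,994
pseudocount            0.0
unseen-context fallback uniform (0.25 per base)
   stratum        name  accuracy      n
       all         all    0.5836 999994
chromosome synthetic_1    0.5836 999994
annotation      repeat    0.4887   7500
Bayes accuracy (left, order 2): 0.5550
Vuong non-nested likelihood-ratio test
------------------------------------------
n positions   99,999
mean log-LR   0.257733
sd log-LR     0.584267
z             139.4944
p (two-sided) 0
positive z favours the numerator model
peak window: frequencies [4101, 5101) -> periods (196 bp, 244 bp), mid 217 bp
```

Reading the numbers: the k = 3 central model scores 58.4% on its training
genome — above the 55.5% ceiling of any *left-context* order-2 predictor
because both flanks inform the focus base.  The Vuong z of +139 says the
central model's per-position log-likelihoods beat the order-2 Markov
model's by a decisive margin on a 10% position sample.  The spectral peak
window contains frequency 5,000 cycles/Mb — the planted 200 bp GC period —
and its mid-frequency period (217 bp) approximates it from the window's
center.

The same workflows are scriptable via the `ctxpred` console command
(`simulate`, `fit`, `evaluate`, `lrtest`, `fourier`); each run writes a
JSON manifest so it can be repeated exactly.

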
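# Methods

This note documents the models, the numerical and design choices, and what
the synthetic-data tests do and do not demonstrate.

## The prediction problem

For a sequence over {A, C, G, T, N} and a flank size F, the *context* of
position *i* is the pair of flanks `(s[i-F..i-1], s[i+1..i+F])`; the focus
base is never part of its own context.  A position is **disqualified**
when the window `[i-F, i+F]` contains an N (including the focus base) or
falls off a sequence end; disqualified positions are excluded from
estimation and scoring.  For an N-free sequence exactly 2F end positions
are disqualified.  Coordinates are 0-based, intervals half-open (the BED
convention); any non-ACGT letter (IUPAC ambiguity codes included) is
coerced to N at parse time, and lowercase FASTA letters define the repeat
annotation.

## Count models

The **central model** of size k tabulates, for each of the 4^2k both-flank
contexts, how often each base occupies the focus position; conditional
probabilities are the per-context frequencies.  The **Markov model** of
order k does the same for the 4^k left k-mers (a position qualifies when
it has k non-N left bases and a non-N focus, so the usable range differs
from the central model's).  Free-parameter counts follow the dense
formulas 3·4^2k and 3·4^k; the tables themselves are sparse (observed
contexts only), which is what makes an order-14 Markov fit on a small
genome feasible even though its dense table would hold ~0.8 billion
parameters.

Choices the estimation problem leaves open:

* **Unseen contexts** fall back to the uniform distribution (0.25 per
  base).  An additive pseudocount α (default 0) is available; α = 0 keeps
  seen-context estimates exactly equal to frequencies.
* **Argmax ties** break alphabetically (A < C < G < T) for determinism.
* Models are estimated on the **forward strand only**; bidirectional
  averaging is a prediction-time option:
  `q(x) = ½[p_fwd(x | ctx) + p_rev(x̄ | rc(ctx))]`, with `x̄` the
  complement.  The average of two distributions under an outcome bijection
  is again a distribution, and the operation is invariant under swapping
  the roles of the strands.

## Neural model

The network consumes the one-hot context of 2F bases and emits a 4-way
softmax.  Architecture: one or two valid-padding 1-D convolutions with
kernel length 3 or 4 ("word encoding" of tri-/quadro-nucleotides), ReLU;
one or more bidirectional LSTM layers (all but the last return the full
sequence; the last contributes the concatenated final hidden states of the
two directions); an optional ReLU dense layer; a linear layer to 4 logits.
Training minimizes categorical cross-entropy with Adam over a randomly
sampled fraction of the qualified positions (default one third), in
rounds that each end with a validation pass (loss and accuracy logged per
round, so overfitting is visible).  The validation sample is drawn first
and removed from the training pool; when a shared pool would be exhausted
the validation take is capped at half of it.  Train/validation splits by
chromosome are supported for true held-out evaluation.

No deep-learning framework is used: the layers are implemented directly
in numpy with hand-derived backward passes, verified against numerical
derivatives (relative error < 1e-4 on random parameters) in the test
suite.  LSTM gate order is input/forget/cell/output with the forget bias
initialized to 1; weights are Glorot-uniform from a seeded generator.
Given a seed and single-threaded BLAS the training log is bit-reproducible;
under threaded BLAS only statistical reproducibility is promised.

The reference desk-scale configuration ("tiny": flank 5, one conv of 16
filters kernel 3, one biLSTM of 16 units, ~4,600 parameters; 8 rounds of
300 batches of 256) trains in under a minute on one CPU and reaches the
order-2 oracle ceiling (below).  The flank-50 default spec (one conv of 64
filters kernel 4, two biLSTMs of 100) is provided as configuration only;
genome-scale training is out of scope here.

## Evaluation

* **Accuracy** is the fraction of qualified positions where the argmax
  prediction equals the reference base, reported overall, per chromosome,
  and per annotation stratum (BED labels; soft-masked repeats are reported
  automatically).  Empty strata are absent from the report, not zero.
* **Reference-base probability arrays** store, per position, the
  probability the model assigns to the true base; disqualified positions
  are flagged and imputed with a constant (default 0.25) so downstream
  spectral arrays are gap-free.  The constant is configurable.
* **Density grids** are 50×50 histograms of paired reference-base
  probabilities on [0,1]²; edges at i/50, last bin right-closed.
* **Vuong test**: with d_i the per-position log-likelihood difference
  (numerator − denominator), z = √n · mean(d)/sd(d), two-sided normal
  p-value.  The basic non-nested statistic is implemented (no variance
  correction for overlapping models).  sd = 0 raises a degenerate-test
  error rather than returning z = ∞.  Log-likelihoods use natural log with
  probabilities floored at 1e-12.  Genome-level tests pool per-chromosome
  sufficient statistics (Σd, Σd², n) — equivalent to testing the union
  sample.  Per-chromosome samples default to 10% of qualified positions,
  seeded.  No multiple-testing correction is applied.

## Spectral pipeline

Chromosomes are cut into adjacent segments of 1 Mb starting at position 0;
the trailing remainder is dropped.  A segment is excluded when *strictly
more than* 10% of its positions are disqualified (exactly 10% is kept).
Each included segment's array (reference-base probabilities, or the GC/AT
indicator: 1 at G/C, 0 at A/T, 0 at flagged N) is Fourier transformed;
raw unnormalized one-sided DFT magnitudes are kept at integer frequencies
(cycles per segment), so a pure cosine of amplitude a contributes
magnitude a·L/2.  A window of 1,000 consecutive frequencies slides in
steps of 100 over frequencies 1..L/2; the statistic per window is the
Euclidean norm of the magnitudes (the square root of the windowed power;
plain summed power via `squared=True`).  Frequency 0 is always excluded —
the segment mean carries no periodicity and would dominate GC arrays; the
windowed norm is therefore invariant under adding a constant, and under
sign flip.  A frequency window [f0, f0+W] maps to periods
`L/(f0+W) .. L/f0`, with the conventional single period at the mid
frequency, `L/(f0+W/2)`, all rounded to the nearest integer bp — e.g. at
L = 1 Mb the window starting at 4,000 spans (200 bp, 250 bp) with mid
222 bp.  Controls: a seeded full permutation (destroys all phase
coherence; a planted peak vanishes into the flat-noise floor) and seeded
replacement of a position subset by Uniform(0,1) draws (half-position
randomization leaves roughly half the coherent amplitude, so the peak
survives).  Peak identification is by inspection of the exported spectra;
only an argmax-window helper is provided, and no significance machinery is
attached to the spectra.

## Synthetic genomes and oracles

Genomes are sampled from an order-m Markov chain (m ≤ 3 for oracle use;
sampling supports larger m), seeded with a stationary draw.  Optional
features:

* **Planted GC modulation**: the G/C class probability at position i is
  forced to `baseline + amplitude·cos(2πi/period)`; within each class the
  split (G vs C, A vs T) follows the chain's conditional, falling back to
  an even split if the chain gives the class zero mass.  The empirical GC
  fraction therefore averages to the baseline exactly, and the planted
  cosine appears at frequency L/period.  With modulation on, the process
  is position-dependent; the chain oracles below describe the unmodulated
  chain, which is why oracle-based tests use unmodulated genomes.
* **Repeats**: a fixed motif overwritten at seeded non-overlapping
  positions, flagged lowercase.  Note that unlike real genomic repeats,
  these synthetic repeats are *not* intrinsically easier to predict than
  the background — a random motif has no skewed composition — so repeat-
  stratum accuracies on synthetic data say nothing about the repeat
  advantage seen in real genomes.
* **N blocks**, overwritten last so masks are unambiguous.

Exact oracles from the generating chain: the stationary distribution
(power iteration over the 4^m states, tolerance 1e-13); the **Bayes
accuracy** Σ_ctx π(ctx)·max_x p(x|ctx); and the **conditional entropy**
Σ_ctx π(ctx)·H(p(·|ctx)) in nats.  Both come in a left-context form (the
ceiling/floor for Markov-style predictors) and a both-flank form obtained
by enumerating the joint law of (left m-mer, focus, right m bases) — the
relevant bound for central and neural models, which condition on both
sides.  Requesting a context order below the generating order is refused,
since the result would not be the Bayes bound.

The reference study genome ("small" spec) is 2 Mb from a fixed order-2
chain (Dirichlet(0.6) rows from a frozen internal seed; left Bayes
accuracy 0.555, both-flank 0.772, both-flank conditional entropy 0.593
nats), with a 200 bp GC period of amplitude 0.1 around baseline 0.4 and a
repeat density of 50 motif copies (300 bp each) per 2 Mb, scaled
proportionally when a shorter genome is requested.  These sizes let the
full pipeline — generation, count-model fits, neural training, Vuong
tests, spectra — run in a few minutes on one CPU while keeping sampling
error well inside the test tolerances (e.g. binomial s.e. ≈ 0.0005 on an
accuracy estimated from 1 M positions).

## What the tests show — and don't

On synthetic data the package demonstrates: exact agreement of fitted
probabilities with brute-force counts; training-set optimality of the
fitted argmax predictor; recovery of generating conditionals within ±0.01
from 2 Mb; held-out accuracy at the enumerated Bayes ceiling within
±0.005; Vuong type-I calibration at α = 0.05 under a symmetric null and
decisive power when the numerator is the generating model; recovery of a
planted 200 bp period in both GC arrays and model probability arrays,
destroyed by shuffling; and a small conv-biLSTM reaching the both-flank
Bayes accuracy within 2 percentage points with validation cross-entropy
approaching the conditional-entropy floor.

Synthetic genomes lack isochores, CpG decay, transposable-element families
and every other long-range feature of real genomes, so none of this
certifies accuracy figures on real DNA; it certifies that the estimators,
tests and spectra compute what they claim.  The neural results here are
desk-scale; genome-scale claims would require the full-size architectures
and genome-length training runs, which this package deliberately does not
ship.
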
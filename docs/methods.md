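# Methods

## Model and procedure

The analysis treats nucleosome formation as a property readable from the
local dinucleotide (diad) composition of a fixed-length DNA fragment.  Its
inputs are a pool of L = 150 bp oligos and, per oligo, an affinity value:
the log-ratio of the oligo's abundance in the nucleosome-reconstituted
fraction of a competitive in-vitro assay versus the initial pool.  The
chain of steps is:

1. **Affinity filter.**  Oligos with affinity strictly greater than 1
   become the positive class, strictly less than 0 the negative class; the
   interval [0, 1] is discarded as uninformative.  The inequalities are
   strict, so affinities exactly 0 or 1 are dropped.
2. **Diad partition.**  An experiment fixes a positive diad set
   (nucleosome-favouring, G/C-rich) and a disjoint negative set
   (disfavouring, A/T-rich).  Three variants are built in: 4-4
   ({CC,CG,GC,GG} vs {AA,AT,TA,TT}), 4-3 (TA removed from the negative set
   because it shows little class contrast) and 5-4 (AC added to the
   positive set because it does).
3. **Per-sequence score.**  With n1/n2 the overlapping counts of
   positive/negative diads in a sequence, the affinity-weighted score is
   w = af·(n1−n2) for af ≥ 0 and w = af·(n2−n1) for af < 0.  The two
   branches are algebraically |af|·(n1−n2); this identity is
   property-tested.  |w| is used as a per-sample training weight, so the
   class label (sign of affinity) and the confidence (|w|) are carried
   separately.
4. **Position-weight learning.**  Each oligo becomes a ternary feature
   vector over the L−1 = 149 diad start positions: +1 where its diad is in
   the positive set, −1 in the negative set, 0 otherwise.  A single-layer
   network — linear score plus logistic output — is trained to separate the
   classes.  "Single layer" is deliberate: the product of the analysis is
   one weight per position, which is exactly a single layer's weight
   vector; a hidden layer would not yield per-position weights directly.
5. **9-1 protocol.**  Records are divided into K = 10 label-stratified
   parts of near-equal size (sizes differ by at most one).  Each part in
   turn is held out; the network trains on the other nine and is evaluated
   on the held-out part.  The reported weight curve is the arithmetic mean
   of the ten fold weight vectors, and confusion counts are reported as
   means over folds — hence fractional TP/FP/TN/FN values.  Every metric is
   invariant to rescaling all four counts, so fractional means are legal
   metric inputs.
6. **Key positions.**  The k positions of largest |mean weight| (ties to
   the smaller index) are selected; k = 10 or 20 in the reference
   experiments.  Ranking by magnitude keeps strong negative-effect
   positions; a signed-ranking switch exists for sensitivity analysis.
7. **Key-position-only classification.**  A sequence is scored with the
   trained weights restricted to the key positions (non-key weights
   contribute nothing) plus the intercept, thresholded at 0 (strict:
   score = 0 is negative).  Performance is summarised as Acc, Sen, PPV and
   MCC, reported ×100 with one decimal.  A zero denominator yields NaN for
   that metric, never an exception.

For single-class weight profiles (positive-only or negative-only pools)
classification is ill-posed, so the linear score is instead fit to the
affinity by least squares.  This is a design choice: it produces weight
curves comparable in peak structure to the classifier's, which is the use
those profiles serve.

## Training details

Full-batch gradient descent on the sample-weighted logistic loss;
weights initialised from seeded Gaussian noise (sd 1e-3), bias at 0.
Defaults: learning rate 0.5, 400 epochs.  On 149 ternary features and a
few thousand samples this converges comfortably; an independent
cross-check against an (effectively unregularised) logistic regression
from scikit-learn shows weight correlation > 0.95 and ≥ 8/10 agreement in
the top-10 positions.  Normalising sample weights to sum to one makes the
loss — and therefore the learned weights — invariant under dataset
duplication, which is also tested.  All randomness is seeded; identical
(data, config) pairs give bit-identical weights.

In the pipeline, every stage seed (synthetic generation, fold assignment,
training initialisation) is spawned deterministically from the single run
seed via `numpy.random.SeedSequence`, so a run directory is reproducible
byte-for-byte from its config (the log file, which carries elapsed times,
is the only exception).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the measurement process.  Per record: the class is Bernoulli
(positive fraction 0.69, matching the class balance of an
affinity-filtered reconstitution pool); the affinity is Gaussian given
class, N(1.5, 0.5) positive / N(−0.75, 0.5) negative, so the >1 / <0
filter keeps most records while dropping a realistic middle tranche;
bases are drawn i.i.d. from a uniform (configurable) composition; then at
each planted position, with probability Δ (the effect size) the diad is
overwritten by one drawn uniformly from the class-consistent diad set.
Planted positions are processed in ascending order, so overlapping plants
resolve left-to-right.  At a planted position the probability of a
class-consistent diad is therefore Δ + (1−Δ)·|set|/16 exactly, which the
tests verify within three binomial standard errors.

Defaults: n = 2000 oligos, L = 150, ten planted positions
(10, 25, …, 145), Δ = 0.30.  These are the desk-scale recovery
conditions used throughout the tests and the reproducibility script.

What the generator does **not** model: mechanistic dependence of affinity
on sequence (affinity is a measured label here, so a class-conditional
Gaussian is the simplest adequate model), strand symmetry
(generation is single-strand, and profiles are computed on the given
strand only), helical-period (~10 bp) diad phasing, microarray or PCR
measurement noise, and the read-count filtering of the upstream wet-lab
pipeline.  Passing recovery tests therefore show that the estimator finds
planted positional diad biases of the stated size under clean background —
not that real pools contain such biases, nor that affinity noise of real
measurements is Gaussian.

## Numerical and reporting choices

* Coordinates are 1-based inclusive in every user-facing structure; a diad
  "at position p" starts at base p, p ∈ 1..L−1.
* Overlapping diad occurrences count (standard k-mer convention).
* Frequency profiles are per-position proportions over sequences; each
  position's 16 proportions sum to 1 within 1e−9.
* Metrics are rounded with Python's round-half-even at one decimal on the
  ×100 scale; unrounded values are retained alongside.
* Key-position selection is invariant to positive rescaling of the weight
  vector, and the top-k set is monotone in k under the stated tie-break.
* Tolerant overlap between key-position sets is a maximum one-to-one
  matching within ± tolerance, computed by optimal assignment (not greedy
  pairing).
* The affinity-table reader auto-detects an optional header by whether the
  second field of the first row parses as a number; sequences are
  uppercased on read and ambiguity codes rejected, since the analysis has
  no defined behaviour for ambiguous bases.

## Open choices made here

The learning step of the original protocol is underspecified (no stated
architecture, loss, learning rate, epochs or encoding); the realisation
above — ternary encoding, logistic single layer, |w| as sample weight,
10-fold leave-one-part-out, mean aggregation — is this package's own
design, chosen so that each stated output (one weight per position, mean
fractional confusion counts) falls out directly.  Key-position weights are
reused from training rather than refit on the restricted feature set; a
flag enables refitting.  The decision threshold defaults to 0 and is
configurable.

## Problem sizes

Tests and the reproducibility script run at n = 2000 sequences with 10- or
20-seed replication, the desk-scale setting at which the planted-recovery
guarantees (≥ 8/10 positions in ≥ 90% of seeds at Δ = 0.30; chance-level
recovery at Δ = 0) hold comfortably.  The pipeline itself is linear in
pool size and handles the tens-of-thousands scale of real reconstitution
pools without modification.

## Known limitations

* The classifier is evaluated on the same synthetic distribution it is
  trained on; no cross-pool generalisation is claimed.
* Selection reports position sets only; no periodicity statistic is
  implemented for the spacing of key positions.
* Real pools may contain sequences whose affinity sign and diad excess
  disagree; the sample-weighting scheme down-weights but does not model
  such records.
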
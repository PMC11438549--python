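# Methods

## Problem setting

pepforge builds binary classifiers that discriminate peptides (3–50
residues over the canonical 20-letter alphabet) carrying a target
bioactivity from peptides that do not. The design goal throughout is a
*trustworthy* held-out performance estimate: every stage that could leak
information from test to train, or let the model exploit confounders, is
controlled explicitly and reported.

## Negative sampling

Drawing negatives from a database of peptides with other bioactivities
places the negative class between two failure modes: negatives that are
random sequences (the model learns "bioactive vs random", inflating
apparent performance) and negatives from a single other bioactivity (the
model learns a narrow two-activity contrast that does not generalize).

Mechanics: the positives' length histogram is computed with half-open bins
`[k·w, (k+1)·w)` aligned to multiples of the bin width *w* (default 5
residues) — an alignment convention chosen so the binning is a pure
function of the lengths. For each bin, that bin's count of negatives is
drawn uniformly without replacement from database peptides in the length
range, after removing every peptide carrying an excluded bioactivity tag
(any-match rule) and every peptide whose sequence equals a positive.
Shortfalls carry to the next bin in ascending length, continuing past the
histogram's top edge into the database's longer peptides; a residual
deficit is then back-filled from the nearest preceding (shorter) bins,
and whatever cannot be filled is reported in the result metadata — never
silently dropped. The negatives:positives ratio is fixed at 1:1.

Whether draws within a bin should be uniform or stratified by tag is an
open choice; uniform was chosen and is noted as such. Sequence *similarity*
between negatives and positives is deliberately not controlled here —
homology control is the partitioner's job, and doing it twice would make
the negative distribution harder to reason about.

## Similarity and identity

Two peptides are similar when their pairwise identity strictly exceeds
0.30. Identity is the number of identical aligned residue pairs in an
optimal Smith–Waterman local alignment (BLOSUM62, gap open 10, gap extend
1) divided by the length of the longer sequence. Normalizing by the longer
sequence keeps short spurious alignments between length-mismatched
peptides from counting as similarity. Exact matches only are counted —
positive substitution scores do not contribute.

Numerical notes. Co-optimal alignments can differ in their match count;
the implementation scores the first optimal alignment and orders the pair
canonically before aligning, which makes the function symmetric and
deterministic. The test suite bounds the reported count between the
minimum and maximum achievable over co-optimal alignments, computed by an
independent dynamic program. Alignment parameters are declared defaults,
not values inherited from any particular search tool.

A k-mer prefilter (≥ 1 shared exact k-mer) limits alignment to candidate
pairs. The default is k = 2 rather than the more conventional k = 3:
testing k = 3 against exhaustive all-pairs alignment exposed real misses —
unrelated peptide pairs just above the 30% threshold whose identical
aligned residues never include three consecutive positions. With k = 2 no
miss was observed over 80 randomized family datasets, and at peptide
lengths the weaker pruning costs little. The prefilter is configurable
off, and the test suite asserts prefiltered and exhaustive graphs are
identical on desk-scale datasets.

## Partitioning

Clusters are the connected components of the similarity graph. The
homology partitioner (ccpart) moves whole clusters into the test set in
ascending size order — ties broken by a seeded shuffle, then lowest member
id — until the test set first reaches the target fraction (default 20%).
Consequences:

* **Zero leakage, by construction.** No edge crosses the boundary, so the
  interdependence statistic (fraction of training sequences with at least
  one similar test sequence) is exactly 0.
* **Diverse test sets.** Small clusters are the most "unique" sequences;
  packing many of them into the test set emulates predicting genuinely
  novel peptides. The cluster-diversity ratio (#test clusters / #train
  clusters) is exposed as a diagnostic.
* **Overshoot ≤ (last cluster − 1)**, recorded in the split metadata; the
  stop rule is "first crossing".

If reaching the target requires moving more than (1 − target) of the data
(one dominant cluster), no valid split exists at this threshold and the
partitioner refuses with an explanation rather than degrading. A
training set left with a single class is an error; a single-class *test*
set is allowed but flagged as degenerate in the split metadata.

Cross-validation folds over the training set are random-stratified over
peptides, not homology-aware (per-fold class counts within one sample of
proportionality). This is a known within-train leakage channel, accepted
deliberately: folds steer hyperparameter selection only, while the
held-out test set carries the honest estimate.

The random partitioner (|test| = round-half-even(n·fraction)) exists as
the baseline against which the leakage diagnostics are computed.

## Representations

All backends produce an n × e residue matrix pooled by the column-wise
mean. One-hot (e = 20) pools to the amino-acid composition vector and is
deliberately pooled by the same rule as language-model embeddings so every
backend satisfies one downstream contract. The mock language-model backend
(e = 32) hashes the k-mer window at each position into a seeded Gaussian
row — deterministic across processes, position- and context-sensitive,
and labelled synthetic: it exists to exercise the interface, not to model
biology. Real pretrained models are optional adapters; the interface
requires residue rows only (no special-token rows), and a missing adapter
raises an actionable error instead of silently substituting a different
representation.

Physico-chemical descriptors (for dataset comparison, not features):
aliphatic index 100·(x_A + 2.9·x_V + 3.9·(x_I + x_L)); Boman index as the
mean per-residue interaction potential over a shipped published scale;
net charge by Henderson–Hasselbalch over a shipped pKa set including both
termini (default pH 7.0); isoelectric point by bisection on [0, 14] to
|charge| < 1e−4 (net charge is strictly decreasing in pH, so bisection
converges); hydrophobic moment (1/n)·|Σⱼ Hⱼ·e^(ij·100°)| on the Eisenberg
consensus scale. Scales live in `data/scales.json` as configuration.
Dataset-level comparisons report aligned histograms plus the Wasserstein-1
distance between empirical distributions, as data (no plotting).

## Training

Hyperparameter search runs separately per algorithm, maximizing the mean
held-fold MCC across the CV folds. Default spaces: k-NN neighbours 1–30,
uniform/distance weights; LightGBM 50–500 trees, learning rate 1e−3–0.3
(log), 8–128 leaves, min child samples 2–50; random forest 50–500 trees,
depth 2–32, min leaf 1–10. Budget defaults to 100 trials per algorithm.
The default sampler warms up with random draws (¼ of the budget, at least
10) then fits a Gaussian-process surrogate (Matérn 5/2 on unit-cube
encodings, log-scaled where the domain is) and picks the
expected-improvement maximizer from a 128-candidate random pool. A pure
seeded random-search sampler is available so nothing downstream depends on
surrogate internals. Every trial lands in a JSONL trace; ties keep the
earlier trial; the whole search is reproducible from its seed.

The ensemble fits one member per (algorithm, fold) — trained on all folds
but its own — and predicts the unweighted mean of member positive-class
probabilities, so the score is a convex combination of member scores.
LightGBM members are fitted single-threaded and deterministic so that a
rebuilt pipeline reproduces predictions bit-for-bit. Model bundles carry a
manifest (format version, backend, dimension, seeds, train ids, folds,
per-member hyperparameters) plus one file per member; loading refuses
version mismatches and incomplete bundles outright.

## Evaluation

Scores are binarized positive iff strictly above 0.5. MCC uses the
zero-denominator → 0 convention (a constant predictor carries no
information). AUROC, accuracy, precision, recall and specificity are
secondary. Evaluation hard-fails if any test id appears in the bundle's
recorded training ids. The prediction mode reports, per peptide, the mean
member score and the standard deviation across members as an uncertainty
proxy — a dispersion measure (members disagree), not a calibrated
probability interval.

## Synthetic data: what it does and does not show

The generator grows each family from a random seed sequence (default
lengths 25–35) and mutates members by point substitution at a configurable
rate (indels optional, off by default, so identity stays analytically
boundable). At these lengths the local-alignment identity of *unrelated*
random peptides was measured at mean ≈ 0.10 with a maximum ≈ 0.27 over 200
pairs — safely below the 0.30 threshold — so families map onto graph
components, with occasional single-edge merges at dataset scale (which the
partitioner handles by design). Labels are assigned per family, half the
families positive.

Label signal is injected by overwriting part of each chosen positive with
a motif (default `WWRRWK`), preserving length. Placement matters more than
expected: a **contiguous** motif shared by all positives is itself
homology — it creates >30% identity edges between unrelated positives,
merges them into one giant cluster, and the homology partitioner then
(correctly) builds a test set from the remaining small, mostly negative
clusters, making held-out evaluation degenerate. The **scatter** mode
writes the motif's letters at random non-contiguous positions: the
composition signal (visible to mean-pooled representations) is identical,
but aligning two scattered insertions needs one gap per matched residue,
which the affine gap penalties price out. Signal-recovery experiments
therefore use scramble+scatter; the contiguous default remains for tests
of the operation's contract.

Passing on this synthetic data shows the machinery is correct — leakage
control, stratification arithmetic, ensemble cardinality, determinism,
signal recovery. It does not show real-data performance: real peptide
families have biased compositions, indel structure, and label noise the
generator does not model.

## Problem sizes used in the checks

Chosen as the package's own test conditions: zero-leakage sweep over 50
randomized family datasets (6–14 families × 3–7 members); signal recovery
at fractions {0, 0.5, 1.0} × 5 seeds on 30 families × 5 members with 5
folds and a 10-trial budget; the full default build (3 × 10 ensemble) on
20 families × 10 members with negatives sampled from a 1500-peptide
synthetic database; determinism on two complete rebuilds with a 20-peptide
probe set.

## Known limitations

* The k-mer prefilter can in principle drop a >30%-identity pair sharing
  no exact 3-mer; not observed on test datasets, and the exhaustive mode
  exists for verification.
* CV folds are not homology-aware (see above) — by design.
* The class balance of the ccpart test set is whatever the clusters give;
  skew is reported, not corrected.
* The uncertainty column is member dispersion, not calibrated uncertainty.
* The mock embedder is a plumbing stand-in; conclusions about language
  models require a real adapter.
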
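# Methods

## The prediction problem

Heat shock proteins (HSPs) are molecular chaperones found in all domains of
life, conventionally divided into six families by approximate molecular
weight: HSP20 (small HSPs), HSP40 (J-proteins), HSP60 (chaperonins), HSP70,
HSP90 and HSP100.  Annotating them from primary sequence alone is a two-part
problem: deciding whether a query protein is an HSP at all, and if so which
family it belongs to.  A flat multi-class classifier silently assumes every
query is an HSP; `hspclass` instead uses a **two-tier schema** — a binary
gate (HSP vs non-HSP) followed by family classification applied only to
gate-positive sequences — so that non-chaperones are filtered out before a
family label can be forced onto them.

## Feature encodings

Both tiers operate on fixed-length percentage vectors computed from the
20-letter amino-acid alphabet `ACDEFGHIKLMNPQRSTVWY`:

* **Discrete composition** (20-dim): `comp(i) = 100 · R_i / N`, the
  percentage of residue *i* among the *N* residues of the sequence.
* **Coupled composition** (400-dim): the percentage of each *ordered*
  adjacent residue pair among the `L − 1` overlapping dipeptides of a
  length-`L` sequence.  This is the default encoding: it retains local
  sequence order, which the discrete composition discards, and on every
  benchmark here (and in the literature this design follows) it separates
  chaperone families better.

Coupling distance is adjacency (gap 0) by default; a `gap` parameter is
exposed for experimentation.  Features go to the classifier as raw
percentages in double precision with no standardization; the scale
interacts with kernel hyper-parameters, which is why those are grid-searched
rather than copied from any external tool.

Sequences are sanitized on input: lowercase is uppercased, and
non-canonical letters (B, J, O, U, X, Z, stops, gaps) are dropped under the
default `skip-invalid` policy so the 20/400 dimensionalities hold exactly;
a `strict` policy rejects such records instead.

## Classifier

Each of the seven models (one gate + six one-vs-rest family models) is a
soft-margin kernel SVM.  Training is delegated to libsvm via scikit-learn;
the fitted model is immediately frozen into its support vectors, dual
coefficients and intercept, and all scoring is done by the package's own
kernel code.  This gives one deterministic scoring path, plain-JSON
persistence, and bit-exact save/load round-trips.

Kernel conventions: linear `x·z`; polynomial `(x·z + 1)^d`; rbf
`exp(−g‖x−z‖²)`.  The `cost_ratio` knob (classically `-j`) multiplies the
penalty on positive-class training errors, the standard lever against the
heavy class imbalance of one-vs-rest stacks (the smallest family here is
~3% of the HSP corpus).  The optimizer tolerance is set to 1e-6 (tighter
than the libsvm default 1e-3) so that dual symmetries — e.g. negating all
training labels negating all decision values — hold to ~1e-4 rather than
~1e-3.

The default hyper-parameter grid crosses polynomial degrees 1–5 and rbf
gammas {5e-4, 5e-3, 1e-2, 5e-2, 1e-1} with cost ratios
{1, 2, 4, 5, 7, 10, 20, 40}; selection is by pooled CV accuracy, ties
broken by MCC then grid order.  The library and CLI default to a linear
kernel with `C = 1`, which is fast and already saturates the synthetic
benchmarks; `--grid` turns the search on.

### Family resolution

The six one-vs-rest outputs are resolved to a single family by **argmax of
the raw decision values**, with ties broken by canonical family order
(HSP20 < HSP40 < HSP60 < HSP70 < HSP90 < HSP100).  When even the winning
score is negative the verdict is flagged `low` confidence rather than
refused — deterministic and total, at the cost of never abstaining.  The
tier-1 threshold defaults to 0 and is configurable.

## Evaluation

Sensitivity, specificity and accuracy are percentages of the binary
confusion matrix; MCC is the matrix correlation coefficient in [−1, 1].
Degenerate denominators: an empty positive (negative) class makes
sensitivity (specificity) NaN with a warning — not 0, which would be a
claim; MCC with a zero marginal is defined as 0, the standard convention.

ROC curves sweep thresholds over the distinct decision values; AUC is the
trapezoidal area, which equals the Mann–Whitney pair-counting statistic
(ties count ½) — asserted by test on exhaustively enumerable instances.

Cross-validation is stratified five-fold for the gate (large, imbalanced
corpus) and leave-one-out for the family models (small positive classes).
Fold results are **pooled**: confusion counts are summed over folds and one
report computed from the pooled counts, held-out scores concatenated for
the AUC.  Pooling was chosen over macro-averaging because it is the only
aggregation that is also well-defined for leave-one-out singleton folds.
All fold shuffling is seed-controlled.

## Enrichment profiling

For a query sample X and background sample Y the per-residue statistic is
the fractional difference `(X_aa − Y_aa) / Y_aa`, with X_aa and Y_aa the
**pooled** residue fractions (all residues of all sequences counted
together, not per-sequence means; pooling matches the sample-level
definition of the statistic).  +1.0 means the residue is twice as frequent
in the query; a zero background fraction makes the statistic NaN with a
warning.

Significance is a seeded two-sided bootstrap (default 10,000 iterations):
sequences are resampled with replacement within each sample, the bootstrap
differences are recentred on their mean to form the null spread, and the
p-value is the add-one-smoothed fraction of null draws at least as extreme
as the observed statistic.  Resampling is implemented as multinomial
sequence weights times the per-sequence count matrix, which makes 10,000
iterations a handful of matrix products.  These p-values are a transparent,
reproducible significance recipe for the fractional-difference statistic;
they are not expected to match any particular external profiling service
numerically.  Calls at `p ≤ alpha` (default 0.05) are `enriched`/`depleted`
by sign; no multiple-testing correction is applied by default (a
Benjamini–Hochberg helper is provided).

Grouped summaries aggregate calls over conventional residue classes —
positively charged K/R/H, negatively charged D/E, polar uncharged
S/T/N/Q/C/Y, hydrophobic A/V/L/I/M/F/W/G/P, aromatic F/W/Y/H — with
overlapping membership (H, F, W, Y) deliberate and documented; the lists
are overridable.

## Synthetic corpora

The generator produces sequences from first-order Markov chains over the
20-letter alphabet.  First-order chains (not i.i.d. residues) are the point:
they give the corpus genuine dipeptide structure, so the coupled encoding
carries signal beyond the discrete one — the regime the tool is built for.

A chain is specified by multiplicative biases: residue biases scale
stationary weights, dipeptide biases scale individual transition
probabilities.  Lengths are uniform on [50, 400] by default, spanning
typical small-HSP to HSP100 lengths without claiming biological realism.

The default benchmark emulates the class structure of a curated HSP
training corpus at one fifth scale: HSP20 71, HSP40 256, HSP60 33, HSP70
57, HSP90 12, HSP100 17, plus 2,000 non-HSP background records (the
full-scale shape is 357/1279/163/283/58/85 HSPs vs 10,000 non-HSPs).  The
scale-down keeps the complete test suite under a minute while preserving
the strong class imbalance.  Separation levels:

| level    | residue bias | dipeptide bias |
|----------|--------------|----------------|
| strong   | ×3.0         | ×8.0           |
| moderate | ×1.8         | ×3.0           |
| weak     | ×1.2         | ×1.5           |

All six HSP classes share a charged-residue (K, R, D, E) enrichment against
a uniform background — mirroring the compositional signature real
chaperones show against generic proteins — so the tier-1 signal is largely
compositional.  Each family additionally boosts transitions from every
residue to the residue a family-specific offset ahead in the alphabet
(offsets 1, 3, 5, 7, 9, 11), so family identity lives almost entirely in
sequence order: family stationary compositions stay near-identical while
transition matrices are pairwise far apart.  This is what passing tests do
and do not show: the pipeline provably recovers planted compositional and
dipeptide structure end-to-end, but synthetic chains have no domain
architecture, homology, or length–family correlation, so recovery rates
here do not transfer to real proteomes.

## Problem sizes and runtimes

The acceptance script trains both encodings on the default benchmark
(2,446 records), evaluates on an independently seeded corpus of the same
shape, five-fold cross-validates the gate, and runs 20 seeded
enrichment-recovery replicates (200+200 sequences, 200 bootstrap
iterations each); the whole run takes a few seconds on one CPU.  The test
suite uses a smaller benchmark (124 HSPs / 80 background) for unit-level
checks and the full default shape for the end-to-end criterion.

## Known limitations

* Family resolution never abstains; all-negative score vectors are flagged,
  not rejected.
* The gate threshold default of 0 is a convention; calibration to a target
  false-positive rate is left to the user via ROC export.
* Bootstrap p-values are approximate for very small samples (few sequences)
  because sequence-level resampling is coarse there.
* Hyper-parameter values reported for earlier SVM-light-based HSP
  classifiers serve as grid anchors only; solver internals and feature
  scaling differ across implementations, so no single configuration is
  privileged.
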
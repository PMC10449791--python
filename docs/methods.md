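# Methods

## Seriousness labeling from spontaneous reports

Each report row carries a primary-suspect drug, one ADR preferred term and
one of seven treatment-outcome codes (OT, RI, CA, DS, HO, LT, DE; class
indices 1–7 in that order). For a known pair (d, s) and outcome k the four
contingency counts are taken at report granularity: reports with the pair
and the outcome, reports with the pair, reports with the outcome, all
reports. The PRR compares the pair's outcome share against the share in
all *other* reports; its log-normal 95 % interval uses the standard error
`sqrt(1/a - 1/b + 1/(c-a) + 1/(d-b))`. A class bit is set when the lower
bound exceeds 1 — the usual one-sided pharmacovigilance signal reading;
the upper bound exceeds 1 almost always, so the alternative reading would
be vacuous. The serious flag is the OR of the seven bits.

Conventions for degenerate counts: a zero numerator, an unreported pair,
or an outcome absent from the background raise an explicit undefined-PRR
signal and the class is treated as non-significant; no continuity
correction is applied. A pair absent from the reports entirely is labeled
non-serious with provenance `"unreported"`, distinguishable from a
computed all-non-significant zero vector. Reports listing several ADRs or
outcome codes are expected pre-exploded into one row per (drug, ADR,
outcome). An optional minimum report count for significance
(`min_reports`, common practice ≥ 3) is off by default, and an optional
date window on a report `date` column is off by default. ADRs kept in the
benchmark must have strictly more than `min_drugs` (default 50) associated
drugs. Drug and ADR orderings are lexicographic so matrix indices are
stable across runs.

## Input representations

* **SMILES tokens.** Greedy longest match over a fixed symbol table:
  bracket atoms (`[nH]`), `%nn` ring closures, two-letter halogens `Cl`
  and `Br`, single-letter elements and aromatic atoms, bonds, digits,
  parentheses. Unmatched characters map to a reserved unknown token with a
  warning. The vocabulary is frozen from the training corpus with the
  unknown token at index 0. One-hot encoding fills an `l_max × V` matrix
  (`l_max = 100`), zero-padded past the token count, truncated above.
* **Molecular graph.** RDKit parses the SMILES; atoms carry element
  one-hot (+other), degree one-hot, formal charge, aromaticity and
  hydrogen-count one-hot; bonds carry type one-hot, conjugation and ring
  flags. Projection to the common hidden width happens in the network's
  input layer.
* **Semantic vectors.** Each ADR's four-level dotted hierarchy IDs yield a
  DAG whose nodes are every proper level-prefix of every ID plus the ADR
  term itself as a single leaf (two IDs sharing no prefix give
  3 + 3 + 1 = 7 descriptors). The dataset vocabulary is the sorted union
  of all DAG node labels, including leaf terms — the worked descriptor
  count requires the leaf to be a descriptor — and the ADR's vector is
  multi-hot over it.
* **Profiles.** The n × m binary matrices R_interaction and R_seriousness
  hold known pairs and serious pairs. A pair's features are its drug's two
  rows and its ADR's two columns. The pair's own entries are masked
  (zeroed) by default in *both* training and evaluation features: leaving
  the entry visible lets the network copy the label it is asked to
  predict, which both trivializes evaluation and teaches a shortcut that
  fails the moment the entry is hidden. In fold-wise protocols the
  seriousness entries of all held-out pairs are additionally zeroed in the
  training-fold matrix.

## Network

Seven width-d representations per pair, stacked in fixed order into a
7 × d matrix M:

1. **Graph branch (multi-level graph attention).** Atom and bond features
   are projected to width d with ReLU. Stage 1 (per layer): the
   contribution of each incident edge to node v is a scalar
   `ReLU(W₁[h_v ‖ h_e])`, softmax-normalized over the node's incident set;
   the attended edge sum passes through ReLU and a GRU updates the node
   state. Stage 2 repeats the mechanism with neighbor node states in place
   of edge features. Stage 3 builds a supernode initialized as the sum of
   node states, connected to all atoms, and updates it with the same
   attention + GRU for a configurable number of layers; a final linear
   layer emits the drug vector. Each stage owns one GRU shared across its
   layers and one attention scorer per layer. Isolated nodes pass through
   unchanged. Per-atom supernode attention scores are exported for
   inspection.
2. **Sequence branch (multi-scale residual CNN).** The one-hot SMILES
   matrix is embedded to width d; each layer runs four parallel
   same-length 1-D filter banks (scales 1, 3, 5, 7; padding (h−1)/2,
   stride 1), ReLU, concatenates the maps back to width d and adds a
   residual link to the layer input; a final max-pool over the 100
   positions yields the drug vector. Even scales are rejected at
   construction.
3. **Profile and semantic branches.** Each of the remaining five inputs
   passes through its own fully connected ReLU projection to width d.

Fusion is multi-head self-attention over the 7 rows: per head,
`softmax(QKᵀ/√L_e)·V` with L_e = d/R; heads are concatenated and the rows
mean-pooled (max is a config alternative). The printed form that divides
the softmax by √L_e instead of scaling the logits is available as a
`literal_eq9` switch; it changes only a global scale on the attended
values and breaks the row-stochastic reading, so the standard form is the
default. Two MLP heads (one hidden ReLU layer each, equal width) emit the
association probability and the seven class probabilities.

## Training

`loss_association` is mean binary cross-entropy over the batch;
`loss_severity` is the mean of elementwise binary cross-entropy over all
included (class, sample) pairs. The printed per-class prefactor 1/(C·N_i)
is internally inconsistent (N_i varies inside the outer sum), so the mean
form is the default and a literal transcription is kept for comparison.
Class labels exist only for serious pairs, so `severity_mask_mode =
"serious_only"` (default) excludes non-serious samples from the severity
term. Totals combine as `loss_association + α·loss_severity` with α = 1 by
default. Predictions are clipped to [1e−7, 1 − 1e−7] before logs. Adam
(lr 1e−3 default, β = 0.9/0.999) updates all parameters; weights
initialize from a uniform fan-in scheme under a recorded seed, and two
runs with equal seeds produce identical loss curves. The best-loss state
(validation if supplied, else training) is checkpointed. A non-finite loss
aborts with a diagnostic.

The autodiff engine underneath is a ~300-line reverse-mode implementation
over float64 NumPy arrays (broadcast-aware elementwise ops, batched
matmul, softmax, reductions, gather, same-length convolution). All
gradients are checked against central finite differences in the test
suite, and the full forward pass is checked against a from-scratch
loop-based reimplementation to ≤ 1e−10.

## Evaluation protocols

AUC is the probability a random positive outranks a random negative (ties
half); AUPR is average precision by step integration — both via
scikit-learn, verified in tests against brute-force pair counting and an
exhaustive threshold sweep. Protocols:

* **Repeated stratified k-fold CV** over pairs (serious vs non-serious
  strata); each repeat reshuffles folds by default (`reshuffle=False`
  keeps folds fixed and only reseeds the model).
* **Incremental removal**: for every drug with more than 10 known
  interactions, `floor(fraction · degree)` (at least 1) random pairs move
  to the test set.
* **De novo (cold start)**: each drug in turn has its entire matrix row
  zeroed (features and labels) and all its pairs scored; drugs with
  single-class truth are flagged undefined. Per-class metrics skip classes
  without positive test pairs and report them as excluded.
* **Leakage filter**: SMILES sequence similarity
  `1 − edit_distance/max(len)` (edlib); training drugs at or above the
  threshold (default 0.9) to a query drug are removed, so a threshold of
  1.0 removes exactly the duplicates.

## Synthetic data

The generator emulates the four input tables with known ground truth.
Background outcome rates default to a FAERS-flavoured simplex
(OT 0.45, RI 0.02, CA 0.01, DS 0.05, HO 0.25, LT 0.07, DE 0.15). Planted
signals multiply one outcome's probability for one pair and renormalize,
keeping the expected PRR analytically computable; every known pair
receives at least `pair_report_floor` (default 30) reports so the PRR is
defined. An `exact_counts` mode allocates outcome counts by largest
remainder instead of multinomial sampling, removing sampling noise for
exactness tests. Hierarchy IDs enumerate a four-level grid; every fifth
ADR carries two IDs from different roots to exercise the DAG prefix
union. SMILES come from four parseable template families; the block
benchmark assigns families by drug group so structure correlates with
labels.

Two properties of the significance rule shape the tests. First, the 95 %
CI is calibrated: a null (pair, outcome) test crosses `ci_low > 1` with
probability ≈ 2–5 %, so any fixture with more than a couple of null tests
will produce occasional false-positive serious labels — exactly as in
real disproportionality screening. Recovery of planted signals is
therefore measured as recall across seeds (all planted triples flagged)
in the stochastic mode, and exact precision/recall are asserted in the
deterministic `exact_counts` mode where the null PRRs sit at 1 by
construction. Second, planted pairs skew the global outcome totals; with
too few pairs this contaminates the background and can make *null* pairs
significant for the diluted outcomes, so fixtures keep the planted share
of report volume small (≲ 10 %).

What the generator does not emulate: FAERS case versioning and
de-duplication, demographics, polypharmacy, reporting biases, real MedDRA
term structure, or chemically diverse molecules. Passing tests therefore
demonstrate the statistical machinery and the learnability of planted
structure, not clinical performance.

## Study sizes and defaults

Desk-scale defaults were chosen so the whole suite trains on one CPU:
hidden width 64 (16 in tests), 2 layers per attention stage, 2 CNN
layers, 4 fusion heads, head width 128. The capacity check overfits a
50-pair benchmark to total loss < 0.05 in 500 full-batch epochs; the
generalization check runs 10-fold CV on a 20 × 10 block benchmark (200
pairs) for 25 epochs per fold and reaches mean AUC ≈ 0.99. Cold-start
runs use 60 epochs so the molecular branch, not the (zeroed) profile
branch, carries the decision. Full-scale benchmarks (≈ 10³ drugs × 10³
ADRs, 10 × 10-fold CV) use the same code paths unchanged and are stretch
runs, not tests.

## Known limitations

* The PRR takes reports as independent; duplicated FAERS cases would bias
  counts.
* Sequence-edit-distance similarity is a crude chemical similarity;
  fingerprint similarity would be the stronger leakage filter (the hook
  exists but only the edit-distance form ships).
* The exact token vocabulary and atom/bond feature lists are configurable
  conventions, not canonical.
* Training is plain full-graph-per-molecule NumPy; it is deliberately
  simple and CPU-bound, fine at desk scale and slow beyond it.
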
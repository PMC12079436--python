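# Methods

## Problem and scope

`bbbpep` is a sequence-only predictor of blood–brain-barrier penetration
for peptides over the 20 canonical amino acids. It covers descriptor
computation, moment compression, six parametric neural classifiers, and
three evaluation protocols. Out of scope by design: benchmark-dataset
curation (UniProt queries, CD-HIT redundancy removal), protein-language-model
fine-tuning, and automated hyperparameter search. Ambiguous residue codes
(B, J, O, U, X, Z) are rejected at construction rather than silently
dropped, mirroring how curated BBB peptide sets are filtered.

## Descriptors

All residue indexing is alphabetical (A=1 … Y=20) and sequence positions
are 1-based; with these conventions the accumulative position vectors
satisfy the exact identity Σᵢ AAPIVᵢ = n(n+1)/2, which the property tests
assert on random fixtures.

**FV** stores raw occurrence counts rather than length-normalized
frequencies. Counts preserve the peptide's length information, and
normalization, when wanted, belongs to the scaling stage — this keeps each
block's meaning independent of the scaler.

**PRIM** needs an operational definition of "the relative placement of the
i-th residue with respect to the j-th": we adopt entry
(i, j) = Σ_q (q − firstpos(i)) over the positions q of residue j, with the
whole row zero when residue i is absent. A second convention (offsets
summed over *every* occurrence of i) is available behind
`PrimStrategy.ALL_OCCURRENCES`; both are verified against independent
brute-force double loops. RPRIM/RAAPIV are defined literally as the same
encoders applied to the reversed sequence, and that identity — not a
re-implementation — is what the tests check.

**AAPIV** is a single 20-vector. Descriptions of this encoder sometimes
speak of quartering the sequence; a quartered variant would have length 80
and cannot be reconciled with a 20-element vector definition, so the
20-element form is implemented.

## Moment compression

Each square matrix is reduced to the 10 moments of aggregate order ≤ 3 per
family, in the fixed order (0,0),(0,1),(1,0),(1,1),(0,2),(2,0),(1,2),(2,1),
(0,3),(3,0). Including the (0,1) moment gives 10 per family and 3 × 10 = 30
features per matrix, which is the only count consistent with the
"thirty features" contract; prose lists that name nine raw moments are
treated as omitting U01 by accident.

Raw and central moments use 1-based grid indices (so U00 is the matrix
mass and v10 = v01 = 0 exactly); a zero-mass matrix has all central moments
defined as 0 instead of dividing by U00 = 0.

The Hahn family is taken at parameters a = b = 0, the standard
image-moment choice, where the weight is uniform and the polynomials
coincide with the discrete Chebyshev family. The basis is computed by the
orthonormal three-term recurrence with Jacobi coefficients
b_n = (N−1)/2 and a_n² = n²(N²−n²)/(4(4n²−1)), not by the
factorial/Pochhammer closed form: the closed form overflows and loses
precision long before N = 20, while the recurrence keeps the Gram matrix
within ~1e−13 of the identity for every grid size this package produces
(N ≤ 20; a hard cap of 128 guards against unbounded requests). The test
suite checks the basis against an *independent* construction — exact
rational Gram–Schmidt over the monomials — and exploits orthonormality for
a full-order inverse transform whose round-trip error is measured directly
(< 1e−12 observed for k ≤ 12, against a 1e−6 contract).

Sequence reshaping uses k = ⌈√n⌉ with zero padding; the ceiling is the
standard reading of "k = √n" for non-square lengths, and zero cells are
inert in all three moment families.

## Feature assembly and scaling

Default layout FV ‖ AAPIV ‖ RAAPIV ‖ PRIM-moments ‖ RPRIM-moments ‖
sequence-matrix-moments = 20+20+20+30+30+30 = 150 features. Published
architecture tables for this method print an input width of 153 without
itemizing it; 150 is the only total consistent with the described blocks,
so the architecture builders take the true input width as a parameter and
the parameter audit is run at 153 as printed. Min-max scaling is fitted on
training rows only and applied unclipped elsewhere (held-out values may
fall outside [0, 1]); constant training columns map to 0. The
fit-on-train-only property is asserted by permuting held-out rows and
checking the fitted parameters do not move.

## Classifiers

The six architectures are fixed-width: FCN (dense 288 → dropout →
dense 2); CNN (conv 464 filters kernel 9, valid → pool 2 → conv 464×9 →
pool 2 → flatten → dense 96 → dense 2); simple RNN 128; LSTM 128;
Bi-LSTM 128 per direction; GRU 256 — each recurrent stack followed by
dropout → dense (64 or 128, ReLU) → dropout → dense 2. All heads end in a
2-unit softmax; the decision threshold is 0.5 on the positive-class
probability with ties going positive.

Input presentation was reverse-engineered from the published per-layer
weight totals, which are the one exactly checkable contract:

- The CNN consumes the descriptor as an N×1 single-channel sequence. With
  kernel 9, valid padding and pool width 2 the step axis shrinks
  153 → 145 → 72 → 64 → 32, giving the printed flatten width
  32 · 464 = 14,848 — the only integer-consistent geometry.
- The recurrent cells consume the whole descriptor as **one timestep of
  width N**. At N = 153 this reproduces the printed LSTM total
  4·((153+128)·128+128) = 144,384 and, with separate input and recurrent
  biases per gate, the printed GRU total 3·(153·256+256²+2·256) = 315,648.
  A length-N sequence of single channels (the other plausible reading)
  gives 66,560 and 198,912 instead, so it is ruled out by the tables
  themselves.
- Bias conventions follow the same arithmetic: LSTM and the simple RNN
  carry a single bias per gate, the GRU dual biases with the reset gate
  applied after the recurrent product.

Two published recurrent cells are internally inconsistent at width 153
under *any* standard convention: the simple-RNN total 35,840 implies input
width 151 and the Bi-LSTM total 295,936 implies 160. The audit
(`verify-params`, `architectures.audit`) reports the closed-form counts
(36,096 and 288,768) and flags the discrepancy instead of reproducing it.

No deep-learning framework is used: the layers, backpropagation (including
backprop through time for the recurrent cells, which remain fully general
even though the classifiers use a single timestep), softmax cross-entropy
and Adam live in `bbbpep.nn` on numpy. Every layer's analytic gradient is
verified against central finite differences in the test suite, and seeded
training is bit-reproducible on one thread (one seed spawns separate
generators for initialization, dropout masks and batch order).

Training defaults — Adam, learning rate 1e−3, batch 32, up to 200 epochs,
early stop after 10 epochs without training-loss improvement, dropout
0.3 — are ordinary choices for networks of this size on sub-thousand-sample
tables; the original study tuned FCN/CNN hyperparameters with an external
search tool that is out of scope here, so all of these are plain `TrainConfig`
parameters rather than baked-in constants. Initialization is Glorot
uniform with zero biases (LSTM forget gate 1). A non-finite training loss
aborts with a diagnostic instead of silently continuing.

## Evaluation

Accuracy, sensitivity, specificity and MCC are computed exactly from the
confusion counts, with MCC defined as 0 when a denominator factor
vanishes and an undefined sensitivity/specificity (empty class) reported
as 0. ROC/AUC uses the trapezoidal curve, identical to the Mann–Whitney
probability with ties counted half; both are cross-checked against
scikit-learn and against brute-force pairwise comparison in the tests.

Protocols: self-consistency trains and evaluates on the identical full
dataset (a capacity check — its numbers say nothing about generalization);
the independent test uses one stratified 77/23 split with the per-class
floor rule (425+425 → 327+327 train, 98+98 test) and fits both the scaler
and the model on the training partition only; five-fold CV uses stratified
folds with every sample tested exactly once. Whether the original 77/23
split was stratified is not stated anywhere; stratification is this
package's choice, made for determinism and class balance. Fold metrics are
averaged over folds (the stated aggregation for accuracy, extended to all
four metrics); a pooled-confusion mode is available behind
`aggregate="pooled"`. The ROC attached to a CV report is built from the
pooled out-of-fold scores either way.

## Synthetic data

The generator emulates a labeled BBB peptide set with a two-component
multinomial residue model: positives draw residues from a composition
tilted toward {K, R, L, F, W} — basic and hydrophobic residues, the
signature enrichment of barrier-penetrating peptides — and negatives
toward the complement, with `bias_strength` interpolating from shared
uniform (0) to disjoint (1) compositions. Defaults are 425 peptides per
class (the benchmark's class sizes), lengths uniform on 5–50 residues
(typical peptide territory), bias 0.5. Learnability checks use 200 per
class at bias 0.8 (strong signal) and bias 0 (null); these sizes keep a
full five-fold CV of the FCN under half a minute on one CPU while leaving
very wide margins to the pass bands.

What the synthetic data does *not* emulate: positional motifs, length
differences between classes, homology structure, or any physicochemical
property beyond composition. Passing the end-to-end checks therefore shows
the pipeline can extract a compositional signal and scores at chance when
none exists — it does not certify real-data accuracy, which depends on the
external benchmark.

## Known limitations

- The numpy engine is CPU-only and single-threaded by design; the CNN
  (3.4 M parameters) trains orders of magnitude slower than the FCN and is
  exercised on small fixtures in the tests.
- Hahn moments are computed at a = b = 0 only; other parameterizations of
  the family (and Krawtchouk/Tchebichef variants) are not implemented.
- Checkpoints store weights plus the architecture descriptor; optimizer
  state is not serialized, so training cannot be resumed mid-run.
- `independent_test` featurizes the full dataset before splitting. The
  encoders are strictly per-peptide, so no information crosses the split;
  only the scaler and model are partition-aware.
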
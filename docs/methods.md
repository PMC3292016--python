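# Methods

## Problem setting

Antifreeze proteins (AFPs) bind nascent ice crystals and depress the
freezing point of body fluids. Because ice presents many different lattice
faces, AFP ice-binding domains evolved convergently and share little
sequence similarity, which defeats homology search and motivates
machine-learning predictors built on alignment-free encodings. `afpkit`
implements the standard architecture for this problem class: fixed-length
sequence encodings feeding a grid-searched RBF-kernel SVM, evaluated by
stratified cross-validation and an independent test protocol.

## Alphabet and input handling

All encoders index features by one canonical alphabet: the 20 amino-acid
one-letter codes in alphabetical order (`ACDEFGHIKLMNPQRSTVWY`). PSI-BLAST
ASCII PSSMs use a different column order (`ARNDCQEGHILKMFPSTWYV`); the
parser remaps columns at read time so nothing downstream ever sees the
native order.

Non-canonical codes (B, J, O, U, X, Z, `*`) have two handling policies:
`strict` (raise, naming the record and character) and `drop-unknown`
(remove with a logged warning). Training inputs default to `strict` —
label quality matters most there — while the CLI's `encode` step defaults
to `drop-unknown`, the forgiving behaviour a prediction service should
have. Sources rarely document how such residues were handled upstream;
making the policy explicit and per-call keeps it auditable.

## Encoders

**AAC / dipeptide.** Frequencies with denominators L and L−1 (the number
of adjacent pairs) respectively. Both sum to 1 by construction.

**PseAAC.** The correlation factor of tier d is the mean squared
difference of three standardized property values between residues d
positions apart, averaged over the three scales:

    theta(d) = 1/(L-d) * sum_i Theta(i, i+d)
    Theta(i, k) = 1/3 * sum_j (H_j,i - H_j,k)^2

The shipped scales (`src/afpkit/data/chou_properties.json`) are the
canonical PseAAC triplet — hydrophobicity, Hopp–Woods hydrophilicity, and
side-chain mass — each standardized to mean 0 and population SD 1 over
the 20 residues before use. The `PropertyTable` is injectable so users can
substitute other scales; the validation (mean 0, SD 1 to 1e-9) runs on
construction either way. λ defaults to 30 (50 features total) but is a
parameter, so sequences of length 21–31 remain usable with explicit
intent; sequences with L ≤ λ are rejected with advice rather than padded.

Numerically the implementation multiplies the numerator and denominator of
the textbook frequency form by L, keeping integer residue counts in the
numerator. This is algebraically identical but makes two limit cases exact
to the bit: at ω = 0, and for any homopolymer (all θ(d) = 0), the first 20
components equal AAC and the tail is exactly zero.

**PSSM-400.** The defining papers for this encoding family state
"composition of occurrences" without a normalization formula. The choice
here: squash each log-odds score x through the logistic function
1/(1+e⁻ˣ), then average the squashed rows per query-residue type, with an
exact-zero 20-block for types absent from the sequence. Rationale:
features are bounded in [0,1] independent of sequence length and score
magnitude (raw log-odds grow with profile depth), sigmoid-scaled PSSM
features are the established convention in this line of predictors, and
zero blocks keep the dimensionality fixed for the SVM. The squashing
function is a parameter (`sigmoid` | `identity`) and is recorded in
trained-model metadata so a persisted model is unambiguous about the
features it expects.

Only the first 20-column block of the ASCII PSSM (log-odds) is read; the
weighted-percentage block and trailing Karlin–Altschul statistics are
ignored. The parser accepts both the legacy `blastpgp -Q` and modern
`psiblast -out_ascii_pssm` dialects, keyed on the header line; it was
validated against genuine `psiblast` 2.17 output.

**Mock profiles.** `generate_mock_pssm` draws integer scores uniformly
from [−8, 11] (a typical log-odds range) and raises the query residue's
own column to at least the row median plus a small bonus, mimicking the
self-conservation of real profiles. It is a synthetic stand-in for
PSI-BLAST output, sufficient to exercise parsing, encoding, and the
pipeline end to end; it does not emulate positional conservation
structure, so PSSM-400 carries only weak class signal on mock data (the
own-column bias transmits composition, nothing more). Passing tests on
mock profiles therefore demonstrate correctness of the machinery, not the
biological superiority of the evolutionary encoding.

## Classifier

Soft-margin SVM, RBF kernel. The quadratic program is delegated to
scikit-learn's libsvm binding; `afpkit` owns the surrounding contract:

- **Scaling**: min-max to [0,1] using training-set statistics, persisted
  in the model and applied (with clipping) at prediction time. Computed
  once on the full training set before the hyperparameter search — the
  libsvm-era convention — rather than per fold; with bounded
  composition features the difference is negligible.
- **Grid**: C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (the standard
  libsvm-guide lattice) selected by stratified 5-fold CV accuracy. A
  `coarse` preset (C ∈ {2⁻³, 2⁰, …, 2⁹}, γ ∈ {2⁻⁹, 2⁻⁶, 2⁻³, 2⁰}) exists
  for interactive runs and the test suite.
- **Tie-break**: smallest C, then smallest γ — prefer the smoother model;
  deterministic because the grid is iterated in sorted order and only a
  strictly better accuracy displaces the incumbent.
- **Probabilities**: sigmoid (Platt) calibration fitted on cross-validated
  decision values (`CalibratedClassifierCV`, `ensemble=False`, stratified
  folds seeded from the model seed), with the final SVC refit on all data.
  This replaces libsvm's internal Platt scaling, which can invert
  probabilities on small separable sets.
- **Class weighting**: none by default; the intended training design is
  balanced.
- A call is positive iff probability ≥ threshold (default 0.5), so
  threshold 0 calls everything positive and raising the threshold is
  monotone — it only converts positives to negatives.

Model files are single joblib archives with a format version, the scheme
tag, (C, γ), scaling statistics, and metadata (alphabet ordering, PSSM
squashing, seed). Loading verifies the version, required fields, and
alphabet compatibility, and turns any deserialization failure into a
`ModelFileError` rather than a crash.

## Evaluation

Sn, Sp, Acc as percentages from the confusion counts. When a class is
absent the corresponding metric is **NaN (undefined), never 0** — a
deliberate contract so degenerate test sets cannot masquerade as poor
performance. ROC curves sweep all unique score thresholds (ties grouped);
AUC is the trapezoidal area and is property-tested against the all-pairs
Mann–Whitney statistic at 1e-12.

k-fold CV (default k = 10) uses stratified folds (fold sizes within 1,
class ratio within 1 item of global), a recorded seed, and a full inner
grid search per fold. Two accuracy conventions exist in the literature, so
both are computed and labeled: `mean_acc` (mean of per-fold accuracies —
the headline figure) and `pooled_acc` (accuracy of summed confusion
counts). The CV ROC is built from pooled out-of-fold probabilities.
`compare_encoders` runs the identical fold assignment (same seed) for
each encoding and tabulates accuracy and AUC per encoder.

## Synthetic data

`SyntheticSpec` draws residues i.i.d. from per-class composition bias
vectors, lengths uniform in a range (default 50–150, long enough for
PseAAC at λ = 30), balanced 100/100 by default — a reduced-scale mirror
of the balanced training designs used for real AFP benchmarks. Helper
constructors give a no-signal pair (identical biases → CV accuracy at
chance), a disjoint-support pair (→ 100%), and a moderate AGST-enrichment
mimicking the small-residue bias of ice-binding repeats. The i.i.d. model
deliberately has no positional structure: it can exercise every encoder
and create tunable separability, but it says nothing about how encoders
rank on real proteins.

## Problem sizes and numerical choices

The test suite and acceptance script run CV at n = 200 sequences (100 per
class) with the coarse grid and 10 folds, and oracle comparisons over 100
random instances at 1e-12 — sizes chosen so the full suite completes in
well under a minute while still exercising every code path at meaningful
scale. Normalization invariants are asserted to 1e-9 across 1,000 random
sequences. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`, scikit-learn `random_state`); two runs with
one seed are byte-identical, including saved model files.

## Known limitations

- Published AFP benchmark accuracies are not reproducible here: they
  require the original curated datasets and a PSI-BLAST run against a
  contemporaneous Swiss-Prot release. This package reproduces the method
  and its protocol, not those numbers.
- The exact property-scale values and the PSSM-400 normalization used by
  specific published predictors are not printed in their papers; the
  choices above are documented conventions, not recovered constants.
- The mock PSSM generator does not simulate evolutionary conservation;
  conclusions about encoder ranking require real profiles.
- Binary classification only; one RBF kernel; no class weighting beyond
  an optional flag-level hook.
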
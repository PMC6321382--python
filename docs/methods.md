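# Methods notes

## Problem and model

The package predicts which lysines of a bacterial protein carry the
prokaryotic ubiquitin-like protein Pup. The unit of prediction is a
K-centered peptide window of odd length `2w + 1` (default `w = 10`, length
21), padded with the pseudo-residue `X` where the window runs past a
terminus. Windows are embedded in a fixed feature space, the training set
is rebalanced, and an RBF-kernel SVM separates modified from unmodified
lysines. Nothing in the pipeline uses structure, conservation beyond an
optional input profile, or downstream annotation — it is a pure
sequence-window model, with the usual caveat that correlated sites on the
same protein are treated as independent samples.

## Coordinate and alphabet conventions

User-facing tables are 1-based and inclusive; internal indices are
0-based. The alphabet is the 20 standard amino acids in alphabetical
one-letter order plus `X`, which doubles as terminal padding and unknown
residue. `X` is excluded from every composition numerator and denominator
(a window of pure `X` is a hard error); only the positional bi-profile
treats `X` as a 21st residue row so padded windows encode without special
cases.

## Encoders

* **AAC / AAPC.** Plain frequency vectors. For AAPC the denominator is the
  number of `X`-free adjacent pairs, so terminal padding shortens the
  effective window instead of diluting the distribution. An all-`X`
  neighborhood (no valid pair) is an error rather than a zero vector.
* **ANBPB.** Counts `X_aj` per (residue, position) from each training
  class. The encoding is `Φ((X_aj − m·p) / V_j)` with `p = 1/21` and, by
  default, the binomial SD `V_j = √(m·p·(1−p))` — constant across
  positions, which is what the underlying normal approximation of the
  binomial prescribes. An empirical per-position SD is available via
  `v_mode="empirical"`. The count-scale subtraction `m·p` fixes the
  interpretation of `X_aj` as counts, not frequencies. Outputs are clipped
  to `[1e-12, 1 − 1e-12]`: `Φ` is strictly inside (0, 1) but saturates in
  double precision beyond |z| ≈ 8, and downstream checks rely on the open
  interval.
* **Top-n-gram.** Supported for n ∈ {1, 2}. Ties in per-position
  frequency are broken alphabetically so word formation is deterministic.
  Building alignment profiles is out of scope: profiles are accepted as
  row-stochastic L×20 files, or synthesized one-hot from the window
  (uniform rows at `X` positions, which makes the tie-break visible there:
  a uniform row yields the word "A" for n = 1).
* **PC-PseAAC.** Properties (hydrophobicity, hydrophilicity, side-chain
  mass; canonical published tables shipped as
  `data/pseaac_properties.tsv`, overridable by file) are standardized with
  the population (1/20) variance convention. Tier factors run over the
  concatenated non-`X` residue string. λ must satisfy `0 ≤ λ < L_eff`;
  defaults λ = 5, w = 0.05 are the conventional pseudo-composition
  settings, giving 25 features. The shared denominator `1 + wΣθ` makes the
  vector sum to 1 exactly.

## Pair ranking and selection

The correlation of two amino acids is the sample Pearson correlation of
their AAC columns across training samples; an ordered pair inherits the
correlation of its letters, so `score(AC) = score(CA)`. Self-pairs are
pinned to the top with score exactly 1 rather than computed (numerically
they are 1 anyway; pinning also fixes their order — alphabetical — and
keeps them ahead of any accidental cross-pair with r = 1). A zero-variance
AAC column makes its cross pairs undefined; they rank last, flagged NaN,
with a logged warning. Stepwise search evaluates n = 20, 40, …, 400 and
picks the best accuracy, breaking ties by MCC and then by smaller n
(parsimony). Whether SVM parameters should be retuned per subset size is
left to the caller: the evaluator is injected, and the pipeline exposes
both a fixed configuration and per-fit grid search.

## Rebalancing

* **FUS.** Class statistics use population (1/N) standard deviations as a
  deliberate convention. A zero-variance feature gets the σ → 0 limit of
  the Gaussian membership: indicator of equality with the class mean.
  Scores are computed on the feature matrix as given, before any SVM-side
  scaling. Retention keeps the lowest-scoring negatives with ties broken
  by original index, so the operation is deterministic.
* **KPCA oversampling.** Per k-means repeat and cluster: standardize
  (σ = 0 replaced by 1, logged; singleton clusters skipped with a
  warning), eigendecompose the correlation matrix of the standardized
  members (cross-products over norm products; all-zero columns contribute
  identity rows), and project each standardized member on all principal
  axes, in descending-eigenvalue order with a deterministic sign
  convention (first entry within a relative 1e-6 of the column's maximum
  magnitude made positive — an exact argmax would tie-break on last-ulp
  noise between eigensolvers). Projections are mapped back to feature
  scale (`y·σ + μ`) so synthetic and original samples are commensurable;
  a generation run over-produces (repeats × n_pos candidates) and the
  configured surplus is drawn without replacement under the run seed.
  All eigenvectors are used; synthetic samples therefore stay in the
  affine span of their source cluster and preserve standardized norms.
* **Targets.** `balance_dataset` takes explicit positive/negative targets.
  The pipeline default grows positives toward 2× but never past the
  negative count, and trims negatives to match — already-balanced data
  passes through unchanged, and a 1:12 set lands on an exact 1:1 ratio
  (e.g. 183:2196 → 366:366). The 377:365 configuration used historically
  for this problem is reproduced by setting the targets explicitly.
* k-means is plain Lloyd iteration: k distinct samples as initial centers
  (drawn without replacement), Euclidean assignment, convergence when
  assignments stabilize or after 300 rounds, emptied clusters reseeded to
  the sample farthest from its center.

## Classifier and evaluation

scikit-learn's `SVC` provides the RBF machine; the wrapper pins feature
names and rejects mismatched prediction inputs. The default
`C = 0.70711 (= 2^−1/2), γ = 1.4142 (= 2^1/2)` is the historically
reported optimum for the 407-dimensional combined representation; because
the optimal γ tracks the feature space, `PipelineConfig(tune=True)` runs a
coarse internal grid search (C ∈ {2⁻³, 1, 2³}, γ ∈ {2⁻⁵, 2⁻²·⁵, 1, 2²·⁵} —
a sub-grid of the √2-spaced search grid) scored by internal k-fold
accuracy. No feature scaling is applied by default: every encoder already
emits bounded values.

Metrics: Sn, Sp, Acc as percentages, MCC with the square-rooted
denominator (without the root the quantity is not confined to [−1, 1]),
AUC by the rank-based Mann–Whitney statistic with ties counting ½.
Undefined ratios (empty class, vanishing MCC denominator) are reported as
NaN (MCC: 0) and flagged, never silently dropped. Repeated k-fold reports
pool confusion counts within each repeat and average metrics across
repeats; pooled counts over all repeats are also emitted. `k = n` is
routed to leave-one-out (stratification is meaningless there), which makes
the jackknife a special case. A training split that collapses to one class
predicts that class, with a logged warning.

**Leakage modes.** `paper-faithful` balances the full training set before
the folds are drawn. Synthetic positives derived from held-out windows
then leak into training, and the FUS statistics see the test fold; CV
scores from this mode are optimistic and are labeled as such in the
report. `leak-free` refits ranking, positional profiles and resampling
inside every training fold and evaluates on untouched original windows.
The default is paper-faithful (with a logged warning) for comparability;
every report records its mode.

## Synthetic fixtures

`MotifSpec` generates K-centered 21-mers: positives draw enriched
positions from per-position bias vectors, everything else from a
background composition; negatives are pure background; the
negative:positive ratio defaults to 12. This emulates the statistical
shape of a pupylation training set — positional residue enrichment around
the modified lysine under class imbalance — but not real proteome
structure: no codon or compositional bias, no homology between windows,
no shared-protein correlation, and negatives are i.i.d. rather than drawn
from real unannotated lysines. Passing tests therefore demonstrate that
the pipeline recovers positional composition signal at realistic effect
sizes and is calibrated under the null; they do not certify accuracy on
any particular proteome. Noisy profiles are Dirichlet perturbations of the
one-hot profile, converging to it as the concentration grows.

## Problem sizes and defaults used in checks

The shipped checks run at deliberately modest scale: ranking and dimension
checks on 50:100 datasets; rebalancing on a 183:2196 fixture (the
historical training-set scale); fuzzy-undersampling purification on
100:200 Gaussian sets with a 2σ class offset, 5 replicates; and
cross-validation power/null runs at n_pos = 100 per class with single-
repeat 10-fold CV. These sizes give stable pass/fail behavior for the
properties tested while keeping a full run in minutes on one CPU core.

## Known limitations

* The paper-faithful protocol's optimistic bias is reproduced by design;
  use leak-free mode for honest numbers.
* KPCA synthesis assumes clusters with ≥ 2 members and produces samples
  only in the affine span of each cluster — it cannot extrapolate outside
  observed directions.
* Top-2-gram uses a 400-dimensional word space from one-hot or noisy
  profiles; with one-hot fallback profiles it degenerates to information
  already present in AAPC.
* The ANBPB normal approximation is poor for very small training classes
  (m·p < 1); the encoder still works but the Φ scores lose their
  probabilistic reading.
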
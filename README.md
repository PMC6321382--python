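# pupsite

Sequence-based prediction of protein **pupylation sites**.

Pupylation — the covalent attachment of the prokaryotic ubiquitin-like
protein (Pup) to a substrate lysine — is the bacterial analog of
ubiquitination, and experimentally mapping the modified lysines is slow and
laborious. `pupsite` implements a classical machine-learning predictor for
this problem: every lysine in a protein is represented by a 21-residue
peptide window centered on the candidate K (padded with `X` at the protein
termini), the window is encoded by several complementary sequence feature
schemes, the heavily imbalanced training set (~1 annotated site per 12
unannotated lysines) is rebalanced by resampling, and an RBF-kernel support
vector machine is trained and evaluated by jackknife and repeated
stratified 10-fold cross-validation.

## Method

**Feature encoders** (all emitted as named-column `FeatureMatrix` blocks):

- **AAC** — amino acid composition: the 20 residue frequencies
  `f_i = N_i / N` over the non-`X` part of the window.
- **AAPC** — amino acid pair composition: the 400 ordered adjacent
  dipeptide frequencies; pairs containing `X` are excluded from numerator
  and denominator.
- **ANBPB** — adapted normal-distribution bi-profile Bayes. Per-position
  residue counts `X_aj` are tallied separately on positive and negative
  training windows; by the de Moivre–Laplace theorem the standardized count
  `(X_aj − mp)/√(mp(1−p))` with `p = 1/21` is approximately standard
  normal, and position `j` encodes to `Φ(z)` — the positive profile gives
  components 1…L, the negative profile components L+1…2L (42 features for
  21-mers).
- **Top-n-gram** — for each position of a residue frequency profile, the
  word of the `n` most frequent residues (descending frequency,
  alphabetical tie-break); features are normalized word counts. Profiles
  can be read from PSSM-like files or synthesized one-hot from the
  sequence.
- **PC-PseAAC** — parallel-correlation pseudo amino acid composition:
  `x_u = f_u / (1 + w·Σθ_j)` for `u ≤ 20` and
  `x_{20+k} = w·θ_k / (1 + w·Σθ_j)`, where the tier factor `θ_k` averages
  the mean squared difference of standardized hydrophobicity,
  hydrophilicity and side-chain mass between residues `k` apart
  (defaults λ = 5, w = 0.05).

**Feature selection.** The 20 amino acids are correlated through their AAC
profiles across training samples (Pearson's r); an ordered pair (a, b)
inherits `r(AAC_a, AAC_b)`. The 20 self-pairs (AA … YY) have r = 1 and are
pinned to the top; dipeptide subsets are grown in steps of 20 ranked pairs
and scored by jackknife or k-fold CV. The default pipeline keeps the top
320 of 400.

**Rebalancing.**

- *Fuzzy undersampling (FUS)*: every negative is scored by
  `Σ_j [u_pos_j(x) + (1 − u_neg_j(x))]` with Gaussian memberships built
  from per-feature class means and population SDs; the highest-scoring
  (most positive-like) negatives are removed.
- *KPCA oversampling*: positives are k-means clustered (k = 3, 4 repeats);
  each cluster is standardized, its correlation matrix eigendecomposed,
  and every standardized member projected onto the principal axes to
  synthesize a new sample, mapped back to feature scale. Pooled candidates
  are subsampled (seeded) to the configured target.

**Classifier and metrics.** RBF SVM (`K(s,t) = exp(−γ‖s−t‖²)`), default
`C = 0.70711, γ = 1.4142`, optional per-fit grid search on a √2-spaced
grid. Performance: Sn, Sp, Acc (percent), MCC (square-rooted denominator)
and rank-based AUC. Cross-validation runs in two leakage modes:
`paper-faithful` (balance once, then CV — synthetic positives derived from
test-fold windows can leak into training) and `leak-free` (ranking,
profiles and resampling refit inside every training fold).

## Worked example

```python
import pupsite as ps

spec = ps.MotifSpec.strong(residue="L", positions=(7, 8, 12), prob=0.9,
                           imbalance=12.0, seed=0)
dataset = ps.generate_motif_dataset(183, spec)
results = ps.PupylationSVM(dataset, ps.PipelineConfig(seed=0)).fit()
print(results.summary())
```

```
Pupylation-site SVM results
============================================================
windows:            2379 (183 positive, 2196 negative)
encoders:           aapc, top1gram, anbpb, pcpseaac
dipeptide subset:   320
feature dimension:  407
SVM:                RBF, C=0.70711, gamma=1.4142
leakage mode:       paper-faithful
rebalanced:         183:2196 -> 366:366 (k=3, repeats=4, seed=0)
------------------------------------------------------------
resubstitution (training windows):
  Sn=100.00%  Sp=99.77%  Acc=99.79%  MCC=0.9855  AUC=1.0000
```

The dataset holds 183 annotated sites among 2379 candidate lysines; after
fuzzy undersampling of the negatives and KPCA oversampling of the
positives the SVM trains on a 366:366 set of 407-dimensional vectors
(320 selected dipeptides + 20 top-1-gram + 42 positional bi-profile + 25
pseudo-composition features). Resubstitution metrics describe training-set
fit only; for honest generalization use leak-free cross-validation:

```python
cfg = ps.PipelineConfig(leakage_mode=ps.LEAK_FREE, tune=True, seed=0)
report = ps.cross_validate_windows(dataset, cfg, k=10, repeats=1, seed=0)
print(report.means)
```

```
10-fold CV (leak-free, tuned): Sn=95.63%  Sp=93.08%  Acc=93.27%  MCC=0.6865  AUC=0.9884
```

The same workflow is available from the shell:

```bash
pupsite simulate --n-pos 183 --imbalance 12 --seed 0 --out windows.tsv
pupsite evaluate windows.tsv --mode leak-free --k 10 --repeats 1 \
    --seed 0 --report-out cv.tsv
pupsite train windows.tsv --model-out model.joblib
pupsite predict model.joblib windows.tsv --out predictions.tsv
```

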
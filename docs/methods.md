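# Methods

## Model and procedure

`birf` performs backward feature elimination on a genes × samples expression
matrix with a class-imbalance-aware random forest as the scoring engine.
One selection run proceeds as follows.

1. **Validation split.** A stratified fraction (default 0.25) of samples is
   held out. Per class, round-half-even `round(fraction · n_k)` samples are
   withheld, clamped so both parts keep at least one sample of every class;
   round-half-even makes the split counts exactly reproducible (e.g. a
   53/11/6 cohort at fraction 0.25 holds out 13/3/2). With
   `validation_fraction=0` the split is skipped entirely.
2. **Optional chunked first pass.** If the gene count exceeds `chunk_size`
   the genes are randomly partitioned into near-equal chunks, each chunk is
   screened with its own forest, and only genes with positive permutation
   importance in their chunk survive. This trades cross-chunk correlation
   for speed in the first iteration only; later iterations always see all
   survivors together.
3. **Elimination loop.** Each iteration fits a fresh forest on the training
   samples restricted to the surviving genes (no tree reuse between
   iterations), records the OOB error and the validation error, computes
   OOB permutation importance, and drops every gene with importance ≤ 0.
   Since permutation importance of a gene never reached by any split is
   exactly zero, the bulk of pure-noise genes disappears within the first
   few iterations. Once every survivor has positive importance the plain
   rule would stall, so the lowest `ceil(elimination_floor_fraction · d)`
   genes are dropped instead (default 10%). The surviving set never falls
   below `min_genes`; when the drop list would cross that floor it is
   truncated, returning its highest-importance members to the kept set.
4. **Early stopping.** After each iteration the stopping rule inspects the
   validation-error sequence: the running minimum (earliest iteration on
   ties) is the *best* iteration, and the loop stops once `patience`
   (default 3) consecutive iterations have passed without improving on it.
   A single-step "stops rising" rule would trigger on noise — validation
   errors on small splits fluctuate by whole 1/n_val increments — hence the
   patience window. Without a validation split the loop runs until no
   elimination is possible and the smallest-OOB-error subset is selected.
5. **Subset choice.** The returned gene set is the surviving set at the
   minimum of the validation-error sequence (OOB sequence when validation
   is off). **Ties at the minimum resolve toward the latest, i.e. smallest,
   set.** This is a deliberate design choice: with a small validation set
   the error typically reaches its floor early and stays there across many
   iterations; picking the earliest tied iteration would return nearly the
   full gene list, defeating the purpose of selection, whereas equal
   measured error at fewer genes is the more parsimonious — and therefore
   preferable — subset. The early-stopping clock (step 4) still runs from
   the earliest tie, so the loop never wanders long past the minimum.
   Selected genes are ordered by descending importance at the chosen
   iteration, making "top k" well defined downstream.

## The imbalance machinery

**Balanced bootstrap.** In `balance_mode="balanced"` every tree is grown on
K·n_min indices: n_min draws with replacement from each class, n_min being
the smallest class size. In-bag indices are recorded per tree, so OOB
membership is exact rather than probabilistic. `balance_mode="plain"` draws
a conventional bootstrap of size n and serves as the unbalanced baseline.

**Cutoff voting.** Forest-level decisions are
argmax_k (vote fraction_k / cutoff_k), ties to the smallest class index in
the (lexicographically fixed) class order. The default cutoff in balanced
mode is uniform (1/K): the balanced bootstrap already equalizes priors, and
stacking a second prior correction on top would over-weight minorities.
`cutoff="prior"` (weights n_k/n) gives cost-sensitive-only operation on
plain bootstraps, and an explicit K-vector is accepted for hand tuning.

**Permutation importance.** For each tree, its OOB error (from the tree's
own argmax prediction — no cutoff at tree level, matching the R
`randomForest` convention) is compared with the error after one fresh
permutation of a gene's values among that tree's OOB samples; the mean
difference over all trees is the gene's importance, in units of error-rate
increase. Genes unused by a tree's splits contribute exactly 0 for that
tree and are skipped, which both preserves the exact-zero property the
elimination rule needs and makes the computation cheap (a tree on tens of
samples uses tens of genes, not thousands). Mean-decrease-in-impurity
importance is deliberately not offered: it is almost never exactly zero, so
the "drop non-positive importance" rule would lose its meaning.

Trees are scikit-learn `DecisionTreeClassifier`s grown to purity with
`max_features=mtry`; the ensemble logic around them (sampling, vote
aggregation, OOB accounting, importance) is implemented here because no
installed forest exposes per-class bootstrap sizes or R-style cutoff voting.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ntree` | 500 | trees per forest; 100–300 suffice for the simulated scales |
| `mtry` | `"sqrt"` → ceil(√d) | candidate genes per split; the classification default of reference implementations. `mtry=d` would disable feature subsampling and make the forest a bagged ensemble |
| `chunk_size` | 2000 | first-pass chunk width; `None` disables chunking |
| `validation_fraction` | 0.25 | stratified hold-out driving early stopping |
| `patience` | 3 | post-minimum iterations tolerated before stopping |
| `min_genes` | 2 | hard floor on the surviving set |
| `balance_mode` | `"balanced"` | balanced vs plain bootstraps |
| `cutoff` | `"uniform"` | vote weights: uniform, `"prior"`, or explicit vector |
| `elimination_floor_fraction` | 0.10 | fallback drop fraction when all importances are positive |
| `n_repeats` | 3 | runs in the stability analysis |
| `seed` | 0 | master seed; a run is bit-reproducible given the config |

## Synthetic data

The generator emulates the target regime: tens-to-hundreds of samples,
hundreds-to-thousands of genes, 2–8 classes with severe imbalance (cohorts
such as 53/11/6 or 90/10), and a small planted set of informative genes.
Every gene is i.i.d. Normal(0, `noise_sd`²) across samples; each planted
gene receives a class-specific mean offset `effect_size · noise_sd ·
u(g,k)` with u drawn from {−1, 0, +1} per (gene, class), redrawn until at
least two classes differ. Drawing offsets per (gene, class) rather than one
global contrast means different planted genes separate different class
subsets — including minority-only markers, the case the balanced bootstrap
exists for. Default `effect_size` is 2.0 noise-SDs, a clearly detectable
but not trivial univariate separation at these sample sizes.

What the generator does **not** emulate: gene–gene correlation blocks,
batch effects, heavy-tailed or heteroscedastic noise, probe-level
artifacts, and missing values. Passing tests on this generator therefore
demonstrate the algorithmic properties (imbalance handling, elimination
dynamics, stability behaviour, determinism) — not performance on any
particular real cohort, where correlated genes make selected lists less
unique and noisier than the simulations suggest.

## Evaluation and stability

Hold-out evaluation fits a balanced forest on the training samples
restricted to the selected genes and scores an independent test set with
the same cutoff voting. Overall error is misclassified/total
((total − trace)/total of the confusion matrix) and per-class accuracy is
the diagonal over the row total, reported as NaN for a class absent from
the test set.

The stability analysis reruns the entire pipeline `n_repeats` times with
independent seeds derived from the master seed — each repeat redraws its
validation split, so the repeats probe split-to-split variability as well
as forest randomness. Reported statistics: the core set (genes in every
list) and, for each k in {20, 100, smallest-list size} (capped at the
smallest list), `overlap_at_k` = |∩ top-k| / |∪ top-k| (Jaccard across
repeats) alongside the plain |∩ top-k| / k ratio, since published overlap
percentages rarely state which of the two they mean.

## Numerical and degenerate-input choices

* Class order is fixed by lexicographic sort of labels, never file order.
* Cutoff-vote ties go to the smallest class index; elimination ties at the
  floor drop resolve by (importance, original gene order), stable.
* Samples that are in-bag in every tree (never OOB) are excluded from the
  OOB error and logged; with hundreds of trees the expected count is ~0
  (each sample is OOB for ≈ e⁻¹ of balanced-bootstrap trees of its class).
* `mtry` exceeding the current gene count is clamped with a warning.
* Loaders reject missing values and duplicate identifiers outright and name
  the offending gene/sample; datasets with a single class, or a class with
  a single sample under stratification, are hard errors.
* All randomness flows from one `numpy` generator seeded by `seed`; derived
  seeds (stability repeats) are drawn from it below 2³¹.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on simulated cohorts of
60–120 samples and 100–1000 genes with 100–500 trees — sizes at which the
method's behaviour (mass elimination of zero-importance noise, recovery of
planted markers, minority-recall advantage of balancing) is already stable
and a full run takes seconds. Larger matrices simply scale the first
iterations linearly in genes × trees; the chunked first pass exists for
matrices in the tens of thousands of genes.

## Known limitations

* The balanced bootstrap shrinks per-tree sample size to K·n_min; with an
  extremely small minority class individual trees become shallow and more
  trees are needed for stable votes.
* Validation-driven stopping inherits the variance of a small validation
  split; on very small cohorts the selected-set size can vary noticeably
  between seeds (the stability analysis exists to quantify exactly this).
* Chunked first passes can discard genes whose signal is only visible
  jointly with genes in another chunk.
* No nested cross-validation: error estimates at the selected subset are
  optimistically biased, and hold-out evaluation on untouched samples is
  the honest measure.
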
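# Methods

## Model and search procedure

`mevax` wraps an XGBoost binary classifier in a multiobjective evolutionary
search.  The genotype is hybrid: a length-p binary feature mask, a
categorical FS gene over {none, kbest, wilcoxon, jmi, mrmr} with an integer
depth gene k ∈ [1, k_max], and seven real/integer classifier genes.  The
phenotype restricts the mask to the named filter's top-k features (the raw
mask when the FS gene is `none` or when the intersection is empty, so no
solution silently loses all its features) and configures the booster.

Evaluation is stratified 10-fold cross-validation.  The fold split is
drawn once per generation with seed `base_seed + generation` and shared by
every solution of that generation: candidates compete on identical splits,
while the split itself changes each generation so the population cannot
overfit a single partition.  Per fold, boosting is monitored on the
validation-fold AUC and stops after 50 rounds without improvement (cap 500
rounds); the retained model is the ensemble up to the best validation
iteration, whose internal split nodes are counted for the split-complexity
objective.  The validation fold doubles as the early-stopping monitor — a
deliberate choice: with n below 100 a further inner split would leave too
few samples to rank iterations on, and all solutions share the same mild
optimism, which cancels in the comparison.

Ten objectives are maximized: eight fold-averaged classification metrics
(accuracy, wGM, F1, F2, precision, recall, balanced accuracy, AUC) and two
simplicity scores.  Conventions for degenerate arithmetic: any ratio with a
zero denominator scores 0 (the worst value, pushing selection away from
one-class confusion matrices), AUC with a single-class truth is 0, and an
empty active set zeroes all eight classification metrics.  The overall
score is the unweighted mean of the ten; a user-supplied weight vector
gives the weighted overall used for reporting (defaults to equal weights).

Ranking is fast nondominated sorting (all objectives maximized; front 0
nondominated).  Within each front, fitness sharing uses the dual distance

d(a, b) = ½ · d_params + ½ · d_mask,

where d_params is the mean of the range-normalized absolute gene
differences — the seven hyperparameters, a 0/1 mismatch for the FS method,
and |Δk|/k_max — and d_mask is the Jaccard distance of the active-bit sets
(0 for two empty masks).  The sharing kernel is triangular, sh(d) = 1 −
d/σ for d < σ with σ = 0.2, summed over the front including self, so
niche counts are ≥ 1; the niched score is overall/niche_count.  Division
(rather than a subtractive penalty) keeps scores in [0, 1] and makes c
exact clones split their fitness c ways.

Selection is binary tournament on (lower front, higher niched score, lower
chromosome hash — the hash only breaks exact ties, making runs fully
deterministic).  Variation: uniform crossover per mask bit and per gene
(probability 0.9 per pair), then mutation — bit flips at rate max(1/p,
0.001) (≈1 expected flip), Gaussian perturbation of each hyperparameter
with σ = 10% of its range at rate 0.2 (small enough that one mutation
rarely jumps a niche), FS-gene resampling at rate 0.05.  Elites are the
first front ordered by niched score, capped at half the population; the
best-overall chromosome is always among them.  Because elites are
re-evaluated under the next generation's CV plan, their *measured* score
can fluctuate; the run history therefore tracks the best score seen so
far, which is what the stall criterion watches (stop after 20 generations
without >1e-6 improvement, or at the generation budget).

Finalization recomputes front 0, drops degenerate members (single-class
pooled out-of-fold predictions), and refits each survivor on the full
dataset with its median per-fold best iteration as the boosting budget —
at deploy time there is no held-out fold to monitor, and the median is
robust to one unstable fold.  Hard voting takes the per-sample majority
label with ties resolved by the highest-overall member; soft voting
averages the members' positive-class probabilities and thresholds at 0.5
(≥ counts as positive).

## Preprocessing

Four steps, in order: (1) nominal columns become integer codes in sorted
lexical order of their distinct values — deterministic, and it keeps p
fixed for the feature mask, unlike one-hot; (2) missing values are filled
with the per-feature, per-class median (global median where a class never
observed the feature; `mean` and `knn-k` are available by config); (3)
min-max scaling to [0, 1] learned once on the full matrix (constant
features map to 0; z-score and none selectable); (4) columns sharing a
feature name (e.g. probes mapping to one gene) are averaged element-wise.
Labels map to {0, 1} with the minority class as positive — in biomarker
settings the rare class is the class of interest — with ties broken toward
the lexicographically larger label.  Recognized missing markers: empty
string, NA, NaN, null (case-insensitive).

## Filter prescreen

The four rankings are computed once before generation 0.  ANOVA-F and
rank-sum rankings are stored in full; the greedy JMI and mRMR orderings
are cut at k_max = 50, since no chromosome references deeper entries (the
depth gene is folded into the available list length).  For the
information-theoretic methods, continuous features are discretized by
equal-frequency binning into min(5, ⌈√n⌉) bins (columns with at most that
many distinct values pass through unchanged), and mutual information is
the plug-in estimate in bits.  JMI follows the pairwise joint-variable
form: after the max-relevance first pick, each candidate f scores
Σ_{s∈S} I((f, s); y).  mRMR uses the difference (MID) criterion
I(f; y) − (1/|S|) Σ_{s∈S} I(f; s).  All ties break toward the lower
feature index.  An exact duplicate of a selected feature has redundancy
equal to its relevance, so mRMR provably never picks it while any feature
with a positive criterion remains — the mechanism by which the wrapper
avoids co-expressed redundancy.

## Synthetic data

The generator emulates the two regimes the method targets.  Noise features
are standard normal; each informative feature gains a mean shift of
`effect_size` standard deviations in the positive class (a 1-SD shift
gives a single-feature AUC of Φ(1/√2) ≈ 0.76 — weakly informative on its
own); redundant duplicates are informative columns remixed with fresh
noise at correlation ρ (default 0.9); missingness is completely at random;
nominal columns arise by quantile-binning trailing noise features into
four labeled levels.  Two presets: expression-like (n = 89, 35:54
imbalance, 5 informative + 5 duplicates, p = 2000 — scaled from the
tens-of-thousands regime so that a full evolutionary run remains a
minutes-scale computation while n/p stays ≪ 1) and questionnaire-like
(n = 631, p = 50, 1:9 imbalance, 40% nominal columns, 5% missing cells).

What passing tests on these fixtures do show: the search improves on its
initial population, recovers planted signal far above the random-mask
baseline, respects all ranking/niching/voting contracts, and is bitwise
reproducible under a seed.  What they do not show: behaviour under batch
effects, probe-level microarray noise, informative missingness, or
correlated noise structure between non-duplicate features — real cohorts
can be harder than this generator.

## Numerical and design choices

- Infinite ANOVA F statistics (zero within-group variance) are capped at
  1e12 so rankings stay total; constant features score 0.
- The rank-sum test uses midranks; scipy's exact null for small tie-free
  groups, the tie-corrected normal approximation otherwise.
- AUC is the rank-statistic (Mann–Whitney) form with midrank ties.
- F2 weights recall four times precision: missing a true responder costs
  more than a false alert in screening settings.
- Split complexity is linear with cap S_max = 256 total split nodes; beyond
  that a model simply scores 0 on this objective.
- Boosters train single-threaded (`nthread=1`, fixed seed, `hist` trees)
  so identical evaluations agree bit for bit.
- Initial masks carry 1–29 active bits (uniform size, uniform positions):
  the search starts from low-complexity models and grows only where the
  objectives reward it.
- Per-fold metrics are averaged arithmetically across folds; pooled
  out-of-fold predictions are kept only for the degenerate filter and the
  voting ensembles.
- Problem sizes in the test suite and the acceptance script (p = 500–2000,
  populations of 10–24, 15–20 generations) are desk-scale choices: large
  enough to exercise every mechanism, small enough that a full verification
  run completes in minutes.

## Known limitations

- Single CV plan per generation: no repeated-CV variance estimate; the
  reported fold-averaged metrics carry the usual small-n CV noise.
- Generalization estimates are in-protocol (the validation fold also stops
  boosting); for an unbiased estimate, hold out an external test set.
- Binary labels only; no batch-effect correction; MCAR missingness only in
  the generator.
- The mutation/crossover rates and sharing radius are sensible defaults,
  not tuned per dataset; all are exposed through `RunConfig` / YAML.
- With weak effects and small n, the best-*compromise* model (highest
  overall score) tends toward a minimal feature subset in which features
  that separate the classes by sampling luck can tie genuinely informative
  ones — the filter rankings are computed on the full dataset, so such
  features also look good in cross-validation.  For biomarker candidates,
  inspect the whole first front and the voting members, not only the
  single best model; features recurring across front members are the more
  trustworthy signal.
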
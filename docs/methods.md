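# Methods

## Model

A drug pair is classified from the chemical–protein interactome: for drugs
*a*, *b* with docking-score vectors `x_a`, `x_b` (kcal/mol, more negative =
stronger predicted binding) over a fixed panel of `T` protein structures, the
pair's features are, per target `j`, the sum `S_j = x_a(j) + x_b(j)` and the
absolute difference `AD_j = |x_a(j) − x_b(j)|`, interleaved as
`[S_1, AD_1, …, S_T, AD_T]`. Both families are order-invariant, so the pair
representation is symmetric by construction; `AD ≥ 0` always. The interleaved
layout (rather than an S-block followed by an AD-block) was an open choice;
it is fixed by the machine-readable feature-name header (`S:<target>`,
`AD:<target>`) written into every design-matrix export and model file, so
models remain portable regardless of layout convention.

The classifier is logistic regression with an L2 penalty on the weights
(intercept unpenalized), fitted on z-scored features:

    L(w, b) = −Σ_i [ y_i log p_i + (1−y_i) log(1−p_i) ] + (λ/2)‖w‖²

Standardization is applied because the S features are roughly twice the scale
of raw docking scores; the per-feature mean/sd come from the training data
and are stored inside the model, so prediction is self-contained. Constant
features get sd 1 (detected with a relative tolerance of 1e−12) and end up
with zero weight.

## Optimization and numerical choices

The penalized loss is smooth and strictly convex (for λ > 0), so the
optimizer is deterministic: an L-BFGS-B warm start followed by damped Newton
steps (exact Hessian, Cholesky solve, halving line search) until the gradient
max-norm is below 1e−9 or 200 Newton iterations. The convergence contract is
1e−6; the tighter default makes refits agree to ~1e−10 in the weights even
when rows are permuted, which is what the determinism tests assert (1e−8).
The sigmoid and log(1+e^z) are evaluated in overflow-safe branches; predicted
probabilities are clipped away from exact 0/1 by the smallest positive float
so log-losses and thresholds stay finite. A unit test cross-checks the fit
against an independent solver (scikit-learn's `LogisticRegression` with
`C = 1/λ`) to 1e−6.

λ defaults to 1.0 on standardized features — a scale-free choice, exposed as
a flag/config entry; no claim is made that it matches any particular
historical fit, and the evaluation protocol can grid it externally.

## Training-set construction

Positives are taken from a supplied pair list as given. Negatives are drawn
uniformly without replacement from all `C(n,2)` unordered pairs excluding the
positives and self-pairs — "random pairs not in the positive set" is read as
the uniform distribution, the minimal assumption. The implementation uses
full enumeration when the request is dense relative to capacity (or the
library is small) and rejection sampling otherwise; both are uniform and
deterministic per seed. Self-pairs are never generated or accepted (their AD
features would be identically zero). Pairs are canonicalized by sorted drug
id for deduplication, and any pair in which either drug has a missing docking
score is dropped from the design matrix and reported — only pairs with
complete CPI annotations are trainable.

## Evaluation protocol

* **Repeated CV.** Stratified k-fold (default k = 10); repeat *r* seeds its
  fold assignment with `base_seed + r`. Out-of-fold probabilities are pooled
  within a repeat; the threshold maximizing the F-score over the unique
  pooled scores (ties broken toward the lowest threshold) defines the
  confusion metrics for that repeat. Stratification is not essential on
  balanced data but stabilizes small fixtures. Pooling (rather than per-fold
  threshold selection) was an open choice; it uses all out-of-fold scores for
  one threshold per repeat.
* **Hold-out.** A stratified 50/50 split; repeated CV runs on the training
  half, the final model is trained on that whole half, and the hold-out is
  scored once at the arithmetic mean of all CV-selected thresholds.
* **Metrics.** AUROC (Mann–Whitney concordance, ties ½) and AUPR (step-wise
  average precision) via scikit-learn, verified in tests against exhaustive
  brute-force enumeration on all label patterns up to n = 12 and on random
  instances. Accuracy/precision/sensitivity/specificity derive from a single
  confusion table at the selected threshold. The R² readout is the squared
  Pearson correlation between predicted probability and 0/1 label (zero for
  constant scores by convention); this definition is isolated in one function
  (`pseudo_r2`) so a different pseudo-R² (McFadden, Nagelkerke) can be
  swapped without touching the protocol. Which pseudo-R² convention other
  implementations of this style of model used is generally not stated, so no
  cross-implementation comparison of R² values is meaningful.

## Rank-percentile readout

For a drug and target, the readout is `rank/N` where rank 1 is the most
negative score among the drug's `N` non-missing targets and ties share the
mean rank (order-independent). Values ≤ 0.20 are flagged "top 20%". The
ranking runs over all panel columns, including multiple structures of the
same protein, since deduplication to one structure per protein would need
annotation the CPI file does not carry.

## Synthetic fixtures and what they do (not) show

`gen_cpi` draws scores i.i.d. normal (mean −7.0, sd 1.5 kcal/mol — the range
of typical best-pose Vina affinities); `gen_planted_world` samples distinct
pairs, draws a sparse weight vector (default 30% of features nonzero) on the
standardized pair features, and assigns labels `Bernoulli(σ(b + w·z))`. The
intercept is solved by bisection so the realized positive fraction is within
2% of the requested one; when no effect scale is given, the weight magnitude
is calibrated by bisection so the oracle AUROC of the planted linear score
lands in a requested band (default 0.85–0.88, the operating regime of a
well-performing interaction classifier). Every generator is a pure function
of its arguments including the seed, and the stored oracle AUROC equals the
AUROC of the stored linear scores on the stored labels exactly.

Limitations: real docking scores correlate across similar binding pockets and
real positive pairs come from a curated interaction network with strong
degree structure; the independent-normal scores and label-sampled positives
here have neither. Passing the recovery tests therefore shows that the
pipeline is statistically correct and well calibrated, not that any
particular real-data performance is reproduced.

## Problem sizes used in tests and the acceptance script

Structural checks run at full library scale (2515 drugs × 611 targets,
12 656 × 1222 design matrix — a few seconds, vectorized). Recovery checks use
the default planted world: 2000 pairs over a 20-target panel (40 features),
10-fold CV with 5 repeats, and weight recovery at 5000 pairs; these sizes
give stable recovery (CV AUROC within 0.01 of oracle across seeds, weight
correlation > 0.98) while keeping the whole suite fast. A single 50%
hold-out half of 1000 pairs carries ~0.013 AUROC standard error, so hold-out
recovery is judged on the mean over three split seeds rather than one split.

## Redundancy filter

Tanimoto similarity on binary fingerprints, `|A∩B| / |A∪B|` (0 when both are
empty). The filter drops **every** molecule participating in any
over-threshold pair (symmetric removal), rather than greedily keeping one of
each pair — the stricter reading; the resulting counts differ between the
two readings, which is why the convention is pinned here and verified by an
idempotence test. The fingerprint type is the caller's choice: the core
operates on any supplied binary fingerprints (hex TSV format), and an
optional rdkit adapter generates hashed Morgan fingerprints from SMILES.
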
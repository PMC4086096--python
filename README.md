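# ddicpi

Predict drug–drug interactions (DDIs) from chemical–protein interactome (CPI)
profiles — the vectors of docking scores a small molecule obtains when docked
against a panel of human protein structures.

Many clinically relevant DDIs arise from two drugs binding, often
unexpectedly, the same pharmacokinetic (metabolizing enzyme, transporter) or
pharmacodynamic (target/off-target) protein. `ddicpi` turns that idea into a
classifier: given a library of drugs docked against a panel of PK/PD protein
structures, it scores every unordered drug pair by the probability of an
interaction and points at the proteins plausibly mediating it. It is aimed at
computational chemists and pharmacologists who already have reverse-docking
results (e.g. from AutoDock Vina) and want a structure-only DDI screen.

## Method

Let `x_a(j)` be drug *a*'s best (lowest-energy, kcal/mol) docking score
against target *j* of a `T`-target panel. An unordered pair `(a, b)` is
represented by, for every target `j`,

    S_j  = x_a(j) + x_b(j)          (combined binding strength)
    AD_j = |x_a(j) − x_b(j)|        (binding asymmetry)

giving a `2T`-dimensional feature vector that is invariant to the drug order
(a 611-structure panel yields 1222 features). Known interacting pairs are the
positives; an equal number of negatives is sampled uniformly from the pairs
not in the positive set. An L2-regularized logistic regression

    min_{w,b}  −Σ_i [ y_i log p_i + (1−y_i) log(1−p_i) ] + (λ/2)‖w‖²,
    p_i = σ(b + w·z_i)

is fitted on z-scored features (intercept unpenalized, λ = 1 by default).
Evaluation follows a repeated protocol: stratified 10-fold cross-validation,
repeated with fresh fold seeds to report mean ± sd of AUROC, AUPR, accuracy,
precision, sensitivity, specificity and R²; confusion metrics use the
probability cutoff that maximizes the F-score on pooled out-of-fold
predictions; an independent 50% hold-out is scored once at the mean of the
CV-selected thresholds. Predictions are explained by rank percentiles: a
target that both drugs of a high-probability pair rank in the top 20% of
their own score vectors is a candidate mechanism. A Tanimoto redundancy
filter (drop every molecule with similarity > 0.75 to any other) supports
checking that performance is not driven by near-duplicate structures.

Everything runs on synthetic fixtures generated by the package itself
(`ddicpi.synthetic`): random CPI matrices on the Vina score scale and
*planted worlds* whose labels come from a known logistic model, so the whole
pipeline can be validated by how well it recovers the planted truth.

## Worked example

Generate a planted dataset, train, and screen one library drug:

```sh
ddicpi fixtures world --n-drugs 120 --n-targets 12 \
    --n-pos 400 --n-neg 400 --seed 7 --out-dir world
ddicpi train --cpi world/cpi.tsv --pairs world/pairs.tsv \
    --k-folds 10 --n-repeats 5 --seed 7 \
    --out-model model.txt --out-report cv.json
ddicpi predict --model model.txt --cpi world/cpi.tsv \
    --query D0001 --out predictions.tsv --top-k 3
```

which logs

```
INFO ddicpi: wrote planted world to world (oracle AUROC 0.860)
INFO ddicpi: config b7a8b3bc2a7c: 120 drugs, 12 targets, 800 pairs kept (0 dropped)
INFO ddicpi: CV AUROC 0.848 ± 0.001; model -> model.txt, report -> cv.json
INFO ddicpi: wrote 119 predictions to predictions.tsv (0 pairs dropped for missing scores)
```

The planted world's generating model ranks its own labels with AUROC 0.860
(the oracle); cross-validated recovery reaches 0.848 ± 0.001 — the gap is the
estimation error of fitting 24 features on 720 training pairs per fold.
`predictions.tsv` ranks the 119 candidate partners by interaction
probability:

```
rank	query	library_drug	probability
1	D0001	D0067	0.929689
2	D0001	D0017	0.929212
3	D0001	D0100	0.917277
```

and `predictions.tsv.targets.tsv` annotates the top pairs with per-target
rank percentiles (flag `top20%both` marks targets both drugs rank in the top
20% of their score vectors — the mechanistic candidates):

```
drug_a	drug_b	target_id	class	pct_a	pct_b	flag
D0001	D0067	T0001	unknown	0.2500	0.0833	top20%one
D0001	D0067	T0002	unknown	0.1667	0.3333	top20%one
```

Real docking results enter through `ddicpi build-cpi`, which assembles a CPI
matrix from per-(drug, target) Vina output files (stdout logs or PDBQT
result files, named `<drug>__<target>.*`); a query molecule docked externally
can be supplied to `predict` as a one-row CPI file.

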
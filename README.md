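# acpstep

Two-step classification of anticancer peptides (ACPs): peptides are first
assigned to a **subtype** by where they concentrate positive charge — in the
last five residues (**C+**), the first five (**N+**), or neither
(**Other**) — and then classified active/inactive by a **subtype-specific
RBF-SVM** trained on hybrid sequence + physicochemical features.

## Why two steps

Cationic anticancer peptides disrupt the anionic membranes of cancer cells,
and their activity depends on the *arrangement* of charge, not just the
amount. Composition features cannot see arrangement: `FLWCPCLKKC` and
`CPCLKKCFLW` have identical amino-acid composition (C 30 %, K and L 20 %,
F/P/W 10 % each), yet only the first has the canonical hydrophobic
N-terminus + cationic C-terminus architecture. Splitting the data by the
terminal-charge rule before training lets each submodel specialize on one
charge architecture.

For a peptide *x* of length *L*, the subtype rule compares
`#\{i ≤ 5 : x_i ∈ {H,K,R}\}` with `#\{i > L−5 : x_i ∈ {H,K,R}\}`; ties go to
Other. Each subtype's SVM uses an RBF kernel
`K(u,v) = exp(−γ‖u−v‖²)` with (C, γ) chosen by per-subtype grid search
under stratified cross-validation. Features are any ordered combination of

| block | dims | content |
|---|---|---|
| `aac` | 20 | amino-acid composition |
| `dpc` | 400 | dipeptide composition |
| `cksaap:k=…` | 400·#k | k-spaced residue-pair composition |
| `pcp` | 8 | net charge, charge density, pI, aliphatic index, aromaticity, hydrophobic ratio, Boman index, instability index |
| `taac` | 40 | terminal-window (N & C) composition |
| `tpcp` | 16 | terminal-window physicochemical profile |

Performance is reported as Sensitivity, Specificity, Accuracy, Balanced
Accuracy = (Sen+Spec)/2 and MCC, from repeated (5×) stratified five-fold
cross-validation with the five held-out folds of each repetition pooled
into one confusion table. See `docs/methods.md` for the full model
description.

## Worked example

```python
from acpstep import (ACPClassifier, SynthConfig, aac, assign_group, confusion,
                     generate, metrics, physchem_profile, split_train_test)

g = assign_group("FLWCPCLKKC")
print(g.group.value, g.n_window_count, g.c_window_count)
# C+ 0 2        <- no H/K/R in FLWCP, two in CLKKC: charge sits C-terminally

prof = physchem_profile("FLWCPCLKKC")  # net charge, density, pI, AI, arom., HR, Boman, II
print(round(prof[0], 2), round(prof[2], 2), round(prof[7], 1))
# 1.73 8.68 55.2   <- cationic at pH 7, basic pI, instability 55.2 (> 40: unstable)

ds = generate(SynthConfig(n_pos=300, n_neg=600, seed=1))   # synthetic corpus
train, test = split_train_test(ds, 0.2, seed=1)
clf = ACPClassifier(features="aac+pcp+taac+tpcp", class_weight="balanced",
                    C_grid=(1., 8., 64., 512.), gamma_grid=(2**-9, 2**-6, 2**-3, 1.),
                    cv=3, random_state=1)
clf.fit(train["sequence"].tolist(), train["label"].to_numpy())
for name, m in clf.meta_["per_group"].items():
    print(name, m["n"], m["C"], m["gamma"], round(m["cv_score"], 3))
# C+ 245 8.0 0.001953125 0.98     <- each subtype selects its own (C, gamma)
# N+ 225 1.0 0.125 0.982
# Other 250 1.0 0.015625 0.892

m = metrics(confusion(test["label"].to_numpy(), clf.predict(test["sequence"].tolist())))
print(round(m.sensitivity, 3), round(m.specificity, 3), round(m.balanced_accuracy, 3))
# 0.9 0.975 0.938                 <- held-out performance on the synthetic corpus
```

The same pipeline is available from the shell:

```bash
acpstep synth --out corpus.fasta --n-pos 300 --n-neg 600 --seed 1
acpstep train corpus.fasta --out model.joblib --features aac+pcp+taac+tpcp --seed 1
acpstep predict corpus.fasta --model model.joblib --out predictions.tsv
acpstep cv corpus.fasta --out cv.tsv --mode two_step --seed 1
```

plus `clean` (validation, deduplication, greedy 90 %-identity redundancy
reduction), `group` (subtype table) and `featurize` (feature matrix TSV).

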
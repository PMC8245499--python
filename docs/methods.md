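# Methods

## Problem and model

Cationic anticancer peptides (ACPs) act through electrostatic attraction to
the anionic membranes of cancer cells, so their activity depends not only on
*which* residues they contain but on *where* the positive charge sits.
`acpstep` implements a two-step classifier built around that observation:

1. **Subtype assignment.** For each peptide the number of positively charged
   residues (H, K, R) in the first and the last `window` residues
   (default 5) is compared. More charge at the C-terminus → subtype **C+**;
   more at the N-terminus → **N+**; a tie → **Other**. The count is an
   integer residue count, making the rule deterministic; a variant that
   compares Henderson–Hasselbalch fractional charges (so histidine counts
   ~0.1 at pH 7) is available as `assign_group_by_charge`.
2. **Per-subtype SVM.** Each subtype gets its own RBF-kernel support vector
   machine trained on that subtype's rows only, with per-feature min-max
   scaling fit on the same rows. (C, γ) are chosen per subtype by exhaustive
   grid search — defaults C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}, steps of 2² — with
   stratified internal cross-validation; the highest CV accuracy wins, ties
   resolved toward smaller C then smaller γ, and the winner is refit on all
   of the subtype's rows. Setting `two_step=False` trains a single SVM on
   the undivided data: the one-step baseline the design is compared against.

The estimator (`ACPClassifier`) follows scikit-learn conventions with raw
sequence strings as samples.

## Features

- **AAC** (20 dims): residue frequencies; order-free by construction.
- **DPC** (400 dims): overlapping dipeptide frequencies, denominator L−1.
- **CKSAAP** (400 dims per spacing k): frequencies of ordered residue pairs
  separated by exactly k positions, denominator L−k−1 (the number of
  k-spaced windows, which makes each block sum to 1; k = 0 reduces exactly
  to DPC). Exact-k blocks are encoded; stacking k ∈ {1,2,3} is expressed in
  the spec string (`cksaap:k=1,2,3`).
- **PCP** (8 dims): net charge, charge density, isoelectric point,
  aliphatic index, aromaticity, hydrophobic ratio, Boman index, instability
  index (details below).
- **TAAC** (40 dims) and **TPCP** (16 dims): the terminal-window variants of
  AAC and PCP, computed on the first and last `terminal_window` (default 5)
  residues. These are optional blocks; the default hybrid set remains
  `aac+dpc+pcp` (428 dims). They exist because every whole-sequence block is
  position-free: two peptides with identical composition but opposite
  charge placement are indistinguishable to AAC/DPC/CKSAAP/PCP beyond local
  pair clustering, whereas terminal blocks expose the placement directly.
  The recovery experiment below quantifies this.

Feature order and column names are fixed by the spec string, so matrices
are reproducible across train and predict.

## Physicochemical descriptors

All eight are computed for the whole peptide (and optionally for terminal
windows) at a configurable pH, default 7.0 (neutral):

- **Net charge**: Henderson–Hasselbalch sum over ionizable groups — basic
  (N-terminus, H, K, R) contribute +1/(1+10^(pH−pKa)), acidic (C-terminus,
  D, E, C, Y) −1/(1+10^(pKa−pH)). The shipped pKa table is the Bjellqvist
  set (`scales/pka_bjellqvist.tsv`); both termini are always ionizable.
- **Isoelectric point**: the unique root of the (strictly decreasing)
  charge curve, found by bisection on [0, 14] to 10⁻⁴ pH units.
- **Charge density**: net charge divided by average molecular weight (free
  termini, peptide-bond water subtracted).
- **Aliphatic index**: X_A + 2.9·X_V + 3.9·(X_I + X_L), X in mole percent —
  a thermostability proxy weighted by side-chain volume.
- **Aromaticity**: fraction of F/W/Y. **Hydrophobic ratio**: fraction of
  A/C/F/I/L/M/V.
- **Boman index**: mean per-residue side-chain transfer free energy
  (`scales/boman_scale.tsv`, kcal/mol; proline 0 by convention); values ≤ 1
  indicate low protein-binding potential, hence a low off-target profile.
- **Instability index**: (10/L)·Σ DIWV(xᵢ, xᵢ₊₁) over the Guruprasad
  dipeptide weight matrix (taken from Biopython's ProtParam data); > 40
  predicts an unstable molecule. This is the only order-sensitive
  descriptor: all others are invariant under any permutation of the
  sequence, a property the test suite checks in both directions.

## Dataset hygiene

Curation mirrors standard activity-benchmark practice: a strict length
filter (keep L > 10, i.e. `min_length=11`; relaxable, since some classic
example peptides are exactly length 10), exact-duplicate removal in which a
sequence appearing in both classes is dropped from both (a conflicting
label is unusable), and greedy redundancy reduction: sequences are visited
longest-first and discarded when their global-alignment identity to a
retained same-class representative reaches the threshold (default 0.90).
Identity is the maximal number of matched columns (match 1, mismatch 0,
zero gap cost) divided by the longer sequence's length — with zero gap cost
the alignment column count is not unique across co-optimal alignments, so
the longer length is the stable denominator. This reproduces the intent of
CD-HIT clustering deterministically; CD-HIT's k-mer screening heuristics
are deliberately not reimplemented. Negative subsampling (default 1:2
positive:negative) and the train/test split are seeded and
label-stratified.

## Evaluation protocol

Metrics come from pooled confusion counts with the active class positive:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, balanced accuracy
= (Sen+Spec)/2 (robust to the 1:2 imbalance), and MCC with a 0 fallback
when any denominator factor is zero. `repeated_cv` runs stratified k-fold
CV (default 5 folds) repeated (default 5 times) with fresh seeded fold
assignments; within one repetition the five held-out folds' predictions are
**pooled into a single confusion table**, giving one measurement per metric
per repetition, and mean ± SD over repetitions is reported (per-fold
averaging is available behind `pool=False`). In two-step mode the subtype
rule is applied before fold assignment and stratification is by
subtype × label, so every subtype model is validated on held-out members of
its own subtype and no fold can lose a class within a subtype.

## Synthetic data

The generator emulates the structure the method assumes, so the whole
pipeline is testable without any external corpus. Positives are assigned a
subtype at proportions 394:158:248 (C+ : N+ : Other, the proportions
observed in curated training corpora); the charged terminal window draws
H/K/R with probability `charge_enrichment` (default 0.8), the opposite
window draws hydrophobics with probability `hydrophobic_enrichment`
(default 0.8), and the interior is background. "Other" positives split the
same charge budget evenly: both windows share an identical charged count
drawn at rate `charge_enrichment/2` blended with the background rate, so
the terminal comparison ties by construction and the rate reduces exactly
to background when enrichment is 0. Negatives are drawn entirely from the
background distribution (default uniform 1/20, which keeps the null clean:
at zero enrichment positives and negatives are exchangeable). Lengths are
uniform on [11, 55], the short-peptide regime of curated activity
databases.

What the generator does **not** emulate: real amino-acid background
frequencies, global compositional signatures of natural ACPs (glycine
richness, whole-sequence cationicity), length–activity correlation, and any
actual anticancer mechanism. Passing recovery tests therefore show that the
pipeline finds planted terminal-charge structure, not that it would reach
any particular accuracy on curated corpora.

### Recovery experiment and the role of terminal features

With the planted structure confined to two 5-residue windows and lengths up
to 55, whole-sequence features carry only a diluted trace of the signal: an
oracle experiment (logistic regression on the true sufficient statistics at
n = 3,000) caps whole-sequence information at ≈ 0.80 pooled CV balanced
accuracy, while adding terminal-window statistics lifts the oracle to
≈ 0.94. The recovery experiment therefore uses `aac+pcp+taac+tpcp` with
inverse-frequency class weights: on 300 positives / 600 negatives the
two-step model reaches ≈ 0.92–0.93 mean balanced accuracy under default
enrichment and stays at ≈ 0.50 when no structure is planted — the
classifier finds signal iff signal exists. The same experiment shows the
two-step model outperforming the one-step baseline on identically
structured data, the design contrast the method is built on.

## Numerical choices and edge cases

- Grid-search tie-break: highest CV score, then smallest C, then smallest γ
  (the scan order), for reproducibility.
- Scaling: per-feature min-max to [0, 1], fit per subtype on training rows
  only, stored in the model bundle.
- Class weighting off by default (an RBF-SVM handles the 1:2 imbalance
  reasonably); `class_weight="balanced"` is a flag.
- Probabilities via Platt-style sigmoid calibration
  (`CalibratedClassifierCV`, single calibrated model, seeded folds) when
  `probability=True`.
- MCC and sensitivity/specificity return 0 on zero denominators; peptides
  shorter than a block's minimum (2 for DPC/PCP, k+2 for CKSAAP, the window
  for terminal blocks) are rejected with their ids listed.
- Degenerate inputs: empty prediction input yields empty output; a subtype
  with no rows or only one class aborts training with the subtype named.
- All randomness (fold assignment, grid-search CV, subsampling, generation)
  flows from explicit integer seeds; rerunning any step with the same seed
  reproduces outputs byte-for-byte.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the recovery experiment at
300/600 records with a 4×4 (C, γ) grid and 3-fold inner CV, and the smoke
datasets at 120/240 — sizes chosen so the full pipeline (grid search inside
repeated CV) stays interactive on a single core while keeping every
subtype×label stratum comfortably above the fold count.

## Known limitations

- The greedy identity clustering is O(n²) alignments; for corpora beyond a
  few thousand sequences a k-mer prefilter (i.e. actual CD-HIT) is the
  right tool.
- Reported CV numbers on synthetic data say nothing quantitative about
  curated ACP corpora (see above).
- The pKa model ignores position-specific terminal corrections and assumes
  independent ionization; fine for ranking peptides, not for exact pI of
  unusual compositions.
- Sequences are restricted to the 20 canonical residues; peptides with
  modifications or non-natural residues are rejected rather than
  approximated.
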
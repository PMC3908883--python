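# recurnet

Graph-based semi-supervised prediction of cancer recurrence from gene
expression and protein–protein interaction (PPI) data.

Cohorts with clinical follow-up are small: many expression profiles exist,
but only a fraction of patients carry a reliable recurrence / non-recurrence
label. `recurnet` is for computational biologists who want to use the
*unlabeled* patients too. It treats samples — not genes — as the nodes of a
graph and infers labels transductively: unlabeled samples are classified by
where they sit in the graph, not by a fitted decision function.

## The method

Given a genes × samples expression matrix with labels y ∈ {−1, +1, U}
(non-recurrence, recurrence, unlabeled) and an undirected PPI network:

1. **Informative gene pairs.** Every PPI edge (i, j) is scored by the change
   of within-class co-expression between the two labeled classes,

   `Score(i, j) = | r(g_i^C1, g_j^C1) − r(g_i^C2, g_j^C2) | ∈ [0, 2]`,

   with r the Pearson correlation over each class's labeled samples. Pairs
   with `Score > threshold_g` are kept; the union of their endpoints is the
   informative gene set. Restricting candidates to PPI edges injects
   functional prior knowledge, and scoring correlation *change* captures
   interactions that are rewired in recurring tumours even when no single
   gene is differentially expressed.

2. **Sample graph.** Each pair of samples (labeled and unlabeled alike) is
   connected with weight `W_ij = |r(S_i, S_j)|` if it strictly exceeds
   `threshold_s`, else 0, where S_i is sample i's expression restricted to
   the informative genes. Strong negative patterns count as relationships,
   hence the absolute value.

3. **Harmonic label propagation.** With labels encoded {0, 1} and clamped on
   the labeled block, the estimated labels minimise the quadratic cost
   `J(ŷ) = Σ_{i≤l} (ŷ_i − y_i)² + ½ Σ_{ij} W_ij (ŷ_i − ŷ_j)² `, i.e. the
   unlabeled block solves `L_uu ŷ_u = W_ul y_l` with L = D − W the
   un-normalized graph Laplacian. Discrete labels come from the plain 0.5
   rule or from **Class Mass Normalization** (CMN), which rescales the score
   mass by the labeled class proportions — important when the classes are
   imbalanced.

4. **Tuning and self-training.** The two thresholds are tuned by stratified
   k-fold cross-validation over a grid (defaults: threshold_g 0.15–0.6 step
   0.05 × threshold_s 0.72–0.9 step 0.02 — 100 cells), re-selecting pairs
   inside every fold to avoid selection leakage. Predicted unlabeled samples
   are then absorbed as newly labeled data and the whole loop repeats until
   the predictions stop changing.

## Worked example

```python
from recurnet import RecurrenceSSL, SimulationConfig, simulate

ds, ppi, truth = simulate(SimulationConfig(seed=1))   # 200 genes, 140 samples
res = RecurrenceSSL(ds, ppi, k=10).fit(seed=1)
print(res.summary())
```

```
    Graph-Regularized Semi-Supervised Recurrence Model
==========================================================
No. samples:            140       No. labeled:    100
Class -1 / +1:          50/50     No. unlabeled:  40
PPI edges:              110       k folds:        10
Decision rule:          cmn       Balanced:       no
----------------------------------------------------------
threshold_g             0.15
threshold_s             0.72
CV accuracy             1.000
Informative pairs       44        genes:          82
Iterations              2         converged:      yes
==========================================================
```

The synthetic dataset plants 10 gene pairs whose co-expression flips sign
between classes; on it the grid search ties at CV accuracy 1.000 across many
cells (the tie-break picks the smallest thresholds), self-training converges
after 2 iterations, and the classifier recovers every unlabeled sample's
true class:

```python
s = res.evaluate(truth)
print(s.accuracy, s.sensitivity, s.specificity, s.auc)
# 1.0 1.0 1.0 1.0
```

`res.predictions` holds the per-sample continuous propagation scores and
discrete CMN labels; `res.export_network(path)` writes the selected
recurrence-specific gene network as a scored edge list.

The same pipeline is scriptable from the shell:

```sh
recurnet simulate --seed 1 --out data/
recurnet tune    --expression data/expression.tsv --labels data/labels.tsv \
                 --ppi data/ppi.tsv --k 10 --seed 1 --out tuned/
recurnet predict --expression data/expression.tsv --labels data/labels.tsv \
                 --ppi data/ppi.tsv --k 10 --seed 1 --out pred/
recurnet evaluate --predictions pred/predictions.tsv --truth data/truth.tsv \
                 --out eval/
```

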
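# primir

Modeling the expression of primary microRNA transcripts (pri-miRNAs) from
CAGE peak data with sparse linear models.

## The problem

miRNA biogenesis starts with the transcription of a pri-miRNA from its own
transcription start site (TSS), often tens of kilobases away from the mature
miRNA locus. Pri-miRNAs are short-lived and weakly expressed, so their
expression is rarely measured directly. CAGE (Cap Analysis of Gene
Expression) offers a way in: it quantifies capped 5′ ends at TSSs, measuring
pri-miRNA and mRNA expression *in the same libraries*.

`primir` asks: can the expression of a pri-miRNA across many samples be
predicted from the expression of a small set of mRNAs measured alongside it?
The mRNAs retained by the model are its **associated mRNAs** — a signature
of shared transcriptional regulation, distinct from the *target* mRNAs that
the mature miRNA represses.

## The model

For each pri-miRNA with expression $y_i$ in sample $i$ and mRNA expression
$x_{ij}$, the package minimizes the L1-penalized least-squares objective

$$\sum_{i=1}^{n}\Big(y_i-\sum_{j=1}^{m}x_{ij}w_j\Big)^2+\alpha\sum_{j=1}^{m}|w_j|$$

with both sides standardized to mean 0, sd 1 (population sd). Note there is
no $1/(2n)$ factor; penalties from conventions that include one map via
$\alpha_{\text{here}} = 2n\,\alpha_{\text{scaled}}$. The solver is a
from-scratch cyclic coordinate descent on the Gram matrix with
soft-thresholding updates $w_j \leftarrow S(c_j, \alpha/2)/x_j^\top x_j$,
run until both the coefficient changes and the KKT residuals fall below
tolerance. Genes with $|w_j|$ above a zero tolerance form the associated
set.

Around the model, the package implements the full analysis:

* **quantify** — peak-to-TSS expression: the per-sample maximum (or sum /
  mean) of CAGE peak TPM within a ±window neighborhood of each TSS;
* **filters** — activity (drop genes with zero expression in >80% of
  samples), cross-platform consistency (keep transcripts with Spearman
  > 0.75 between matched platforms, best transcript per gene), and per-miRNA
  proximal exclusion (drop mRNA predictors whose TSS is within 100 bp);
* **evaluate** — per-gene / per-sample Pearson and Spearman correlations with
  one-sided t-test p-values ($t = r\sqrt{n-2}/\sqrt{1-r^2}$, df $n-2$),
  repeated two-fold cross-validation that removes test samples sharing a
  cell type with training, and two permutation negative controls
  (per-mRNA across samples; per-sample across mRNAs);
* **enrich** — exact log-space hypergeometric enrichment of target genes in
  associated sets, Benjamini–Hochberg FDR, Mann–Whitney U comparisons, and
  the pri- vs mature-miRNA correlation analysis;
* **synth** — a generator of synthetic CAGE worlds with planted sparse
  structure, so every stage is testable without external data.

## Worked example

Fit one pri-miRNA on a synthetic world with a planted support of 6 mRNAs at
a signal-to-noise ratio of R² ≈ 0.8:

```python
import numpy as np
from primir import (SynthConfig, generate_world, select_alpha,
                    default_alpha_grid, fit_pri_mirna, associated_genes,
                    predict, correlation_pvalue)

world = generate_world(SynthConfig(n_samples=200, n_mrnas=100,
                                   n_primirnas=1, support_size=6,
                                   target_r2=0.8, seed=42))
mrna = world.mrna_matrix()
X = mrna.values.T                       # samples x genes
y = world.mirna_matrix().values[0]     # the pri-miRNA's expression
pri = world.mirna_ids[0]

Xs = (X - X.mean(0)) / X.std(0)
ys = (y - y.mean()) / y.std()
grid = np.sort(default_alpha_grid(Xs, ys, n_alphas=16, eps=1e-2))
alpha = select_alpha(Xs, ys, grid, k_folds=5, seed=0, rule="sparse")
model = fit_pri_mirna(pri, X, mrna.gene_ids, y, alpha=alpha)

assoc = associated_genes(model)
r = np.corrcoef(predict(model, X), y)[0, 1]
planted = set(world.truth.support[pri])
print(f"penalty alpha        : {alpha:.1f}")
print(f"associated mRNAs     : {len(assoc)}")
print(f"planted support hit  : {len(assoc.gene_ids & planted)}/{len(planted)}")
print(f"fit Pearson r        : {r:.3f}")
print(f"one-sided p-value    : {correlation_pvalue(r, len(y)):.3g}")
```

prints

```
penalty alpha        : 39.4
associated mRNAs     : 6
planted support hit  : 6/6
fit Pearson r        : 0.886
one-sided p-value    : 2.02e-68
```

The cross-validated penalty recovers exactly the six planted predictors, and
the fitted values correlate with the true expression at r = 0.886 — close to
the ceiling of √0.8 ≈ 0.894 set by the generator's noise level.

The same analysis runs end to end from the shell:

```bash
primir run --seed 1 --outdir my_run        # simulate -> ... -> enrich
primir simulate --seed 1 --outdir world    # just the synthetic inputs
```

`primir run` writes every stage's tables plus a `manifest.json` recording
the config hash and per-stage seeds; reruns with the same seed are
byte-identical.

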
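# palmer

A constrained Bernoulli latent block model for assigning candidate genes to
biological pathways from GO-guided literature-mining data.

## The problem

GO-guided literature mining summarizes the biomedical literature as a binary
matrix **X** (n genes × p GO terms), where `x_ij = 1` means gene *i* is
associated with GO term *j* (typically obtained by thresholding association
p-values at 0.1). Genes that share GO-term profiles are indirectly related —
plausibly members of the same pathway — but classical clustering handles this
data poorly: GO terms are redundant and correlated, and signals are often
weak. Moreover, curated databases such as KEGG already tell us the pathway
membership of *some* genes, and that knowledge should inform the clustering
rather than be ignored.

## The model

`palmer` fits a latent block model: genes carry latent cluster labels
`w_i ∈ {1..K}` with weights `α`, GO terms carry labels `z_j ∈ {1..L}` with
weights `β`, and each co-cluster shares one Bernoulli rate,

    x_ij | w_i = k, z_j = l  ~  Bernoulli(θ_kl).

Fitting alternates two conditional mixture EMs that share `θ`:

- **genes given GO labels** — each gene's row collapses to per-GO-cluster
  one-counts `y_il` (out of cluster sizes `n_l`) and the genes follow a
  K-component product-binomial mixture;
- **GO terms given gene labels** — the mirror image over counts `u_jk`.

Known pathway members enter as hard *force-in* constraints: a constrained
gene's responsibility row is pinned to its pathway at every E-step, which
shapes that pathway's `θ` row and thereby steers the assignment of the free
(candidate) genes. The alternation stops when neither label vector changes.

Confidence of each gene assignment is estimated by a *within-cluster
bootstrap*: GO-term columns are resampled with replacement inside each fitted
GO cluster (preserving cluster sizes), the constrained gene EM is re-run per
resample, and a gene's score is the fraction of replicates agreeing with its
majority-voted label.

The package also ships the preprocessing path from a raw p-value matrix
(GO-term selection by smallest average p, candidate selection by largest
average cosine similarity, binarization), a synthetic-data generator with
planted block structure, and a replicated evaluation harness.

## Worked example

```bash
python examples/fit_simulated.py
```

```
matrix: 100 genes x 100 GO terms, 50 constrained genes
  constrained: gene error 0.050, GO-term error 0.050, 3 outer iteration(s)
unconstrained: gene error 0.440, GO-term error 0.340, 6 outer iteration(s)
```

The script simulates a weak-signal dataset of two gene clusters (each owning
one GO-term cluster, plus one GO-term cluster shared by both), anchors half
of each gene cluster, and fits both model variants. The error rate is the
fraction of misclustered genes (resp. GO terms). Under this weak
signal-to-noise ratio the unconstrained latent block model collapses most of
one gene cluster into the other (44% of genes misclustered), while anchoring
half the genes drops the error to 5% — the value of using prior pathway
knowledge.

Other examples: `examples/bootstrap_confidence.py` (confidence scores),
`examples/preprocess_pvalues.py` (from a p-value matrix to a fitted model),
`examples/error_rate_study.py` (a small replicated study).

A command-line interface mirrors the library:

```bash
palmer simulate --scenario two-weak --seed 4 --out sim/
palmer fit --matrix sim/matrix.tsv --constraints sim/constraints.tsv \
    --n-gene-clusters 2 --n-go-clusters 3 --out fit/
palmer bootstrap --matrix sim/matrix.tsv --constraints sim/constraints.tsv \
    --n-gene-clusters 2 --n-go-clusters 3 -B 1000 --seed 1 --out fit/
palmer evaluate --truth sim/true_genes.tsv --pred fit/genes.tsv
```

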
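# Methods

## Model

The data are an n × p binary matrix `X` with genes as rows and GO terms as
columns. Genes carry latent cluster labels `w_i ∈ {1..K}` with prior weights
`α` (a K-simplex), GO terms carry labels `z_j ∈ {1..L}` with weights `β`,
and cells are conditionally independent Bernoulli draws with a single rate
per co-cluster: `x_ij | w_i=k, z_j=l ~ Bernoulli(θ_kl)`. Both K and L are
fixed by the user — in the intended use K is the number of pathways under
study, so model selection over K is deliberately out of scope.

Rather than maximizing the joint block likelihood directly, the fit
alternates two *conditional* mixtures that share `θ`:

- Given hard GO labels, gene i's sufficient statistics are the counts
  `y_il = Σ_j x_ij 1{z_j=l}` with cluster sizes `n_l`; the genes follow a
  K-component mixture with component log-density
  `ln α_k + Σ_l [ y_il ln θ_kl + (n_l − y_il) ln(1−θ_kl) ]`.
- Given hard gene labels, the GO terms follow the mirrored L-component
  mixture over `u_jk = Σ_i x_ij 1{w_i=k}` and sizes `p_k`.

Each side is fitted by EM. The M-steps are the weighted block rates
`θ_kl = Σ_i y_il w_ik / (n_l Σ_i w_ik)` (gene side; the GO side uses
`u_jk`, `z_jl`, `p_k`) and the mixing weights are responsibility means.

### Constraints

Prior pathway knowledge is a partial map gene → cluster. Constrained genes
are *forced in*: their responsibility rows are set one-hot at every E-step
of every iteration, so they (a) never change cluster and (b) dominate the
estimate of their cluster's `θ` row early on, anchoring the cluster's
identity. This is what makes gene labels directly comparable to pathway
identities without any label-matching step. Constraints apply to the gene
side only; GO clusters remain exchangeable.

### Outer alternation and initialization

One outer iteration = gene EM (against current GO labels) → hard gene
labels by per-row argmax (ties to the lowest index) → GO EM initialized
with the gene EM's final `θ` → hard GO labels. The alternation stops when
neither label vector changed from the previous outer iteration, or after
`max_outer` (default 50) iterations; mixing weights `α`, `β` are carried
forward across outer iterations rather than reset.

GO labels are initialized by agglomerative Ward clustering of the columns
under Euclidean distance, cut at L groups (on binary vectors squared
Euclidean distance is the mismatch count, so this is a natural Hamming-style
grouping). The first `θ` is estimated from the constrained genes' block
means against those initial GO labels with uniform `α`; in unconstrained
mode the gene clusters are seeded by Ward clustering of the rows into K and
`θ` comes from those blocks.

### Numerical choices

- `θ` is clipped to `[1e−6, 1−1e−6]` after every M-step so all-zero or
  all-one blocks keep finite log-likelihoods; with K = L = 1 the fitted `θ`
  therefore equals the global matrix mean up to this clipping.
- E-steps are computed in log space with log-sum-exp normalization.
- Inner EMs stop when the relative change of the monitored log-likelihood
  falls below `tol` (default 1e−6) or after `max_inner` (default 200)
  sweeps. The monitored quantity is the observed-data (mixture)
  log-likelihood, with constrained genes contributing their forced
  component's log-density: this choice makes the monotonicity guarantee of
  EM exact, which the classification-style complete log-likelihood (exposed
  separately as `gene_complete_loglik` / `go_complete_loglik`) does not
  enjoy with soft responsibilities. Both criteria agree in practice on
  where the fit converges.
- Empty clusters are allowed to die: denominators are ε-guarded, dead
  components keep vanishing weight, and a warning is logged. No reseeding
  is attempted, matching plain EM semantics.

## Bootstrap confidence

A naive bootstrap over GO columns can eliminate small GO clusters outright.
The within-cluster variant resamples columns with replacement *inside* each
fitted GO cluster, preserving every cluster's size; resampled columns
inherit their cluster's label. Per replicate, only the constrained gene EM
is re-run, warm-started from the fitted model (the GO structure is treated
as the fixed reference being perturbed, so the GO side is not re-fit). A
gene's voted label is its modal label over B replicates (default B = 1000;
ties break toward the higher mean responsibility, then the lower index) and
its confidence is the fraction of replicates agreeing with the vote.
Replicates draw from independent RNG substreams spawned from one seed, so
results are reproducible and independent of execution order.

## Preprocessing from p-value matrices

When the input is a raw gene × GO-term association p-value matrix plus two
disjoint input gene lists, the model-ready matrix is built per list:
`ceil(go_ratio·|list|)` GO terms with the smallest average p over the list
(default ratio 1), and `ceil(candidate_ratio·|list|)` candidate genes with
the largest average cosine similarity to the list's genes (default ratio
2). Cosine similarity is computed over *all* GO columns. Its input scale is
configurable because p-values themselves are a poor similarity basis (two
genes with no associations would look maximally similar); the default is
`−log10(p)`, with `1−p` and raw-p modes available. Selections are unioned —
GO terms or candidates picked by both lists appear once. The sub-matrix is
binarized at `p < cutoff` (default 0.1, strict; a closed `≤` variant is
provided since usage of the boundary varies), and the input genes become
the constraints (list 1 → cluster 1, list 2 → cluster 2). Binarization is
monotone in the cutoff by construction.

The TSV layouts consumed and produced here (genes as rows, GO ids as the
header; two-column constraint tables) are this package's own conventions —
a stand-in for whatever export format a particular literature-mining
service uses.

## Synthetic data

The generator plants the block structure the model assumes, calibrated to
mimic literature-mining matrices. Cluster sizes are multinomial
(`Multinomial(n, gene_cluster_probs)`, likewise for GO columns; a draw with
an empty cluster is redrawn, up to 100 attempts). Each gene cluster owns
one GO cluster; designated GO clusters are shared across all gene clusters.
Signal cells get p-values `Beta(α_i, 1)` — so `P(p < c) = c^α_i` — with one
`α_i` per gene drawn uniformly from the condition's signal range, and an
independent per-gene draw from the shared range (default `U(0,1)`) for
shared-cluster cells; background cells are `U(0,1)`. The matrix is
binarized at the cutoff (default 0.1), and `floor(fraction · size_k)` genes
per cluster (default fraction 0.5) are sampled without replacement as
constraints.

Two stock conditions are provided:

- **two-cluster**: 100 genes (probs 0.5/0.5), 100 GO terms (0.4/0.4/0.2,
  third cluster shared); signal ranges strong `U(0.2,0.5)`, weak
  `U(0.4,0.8)`, mid `U(0.3,0.7)`.
- **three-cluster**: 200 genes in 3 equal clusters, 100 GO terms in 4 equal
  clusters, fourth shared across all gene clusters (the sharing pattern is
  configurable via `go_owner`/`shared_go_clusters`), same signal ranges.

What the generator does *not* emulate: correlations among GO terms beyond
shared block membership, heavy-tailed gene coverage (well-studied genes
having denser rows), or any text-mining artifacts. Passing tests on this
generator therefore demonstrate correctness of the estimator under its own
model assumptions, not robustness to real literature-mining pathologies.

## Evaluation

The error rate is misclustered items / all items. Constrained gene fits
are scored against the anchored labels directly; unconstrained fits and the
GO side (which has no anchors) are scored after applying the
error-minimizing bijection between predicted and true labels, found by
optimal assignment on the contingency table (greedy matching can be
suboptimal for three or more clusters). Note that the anchored error over
all genes mechanically decreases as the constraint fraction grows —
constrained genes cannot be misclustered — reaching exactly zero at full
constraint; comparisons across constraint fractions should keep this in
mind (the per-candidate-gene error is the scale-free alternative).

`run_simulation_study` replicates simulate → fit → score: replicate r draws
its dataset from substream r of the master seed, so every method sees the
same data within a replicate and partial reruns agree; the report rows
carry mean and SD over replicates, with failed fits recorded as NaN rather
than aborting. The study sizes used by the shipped acceptance script are 100
replicates per condition (seconds of runtime); the robustness sweeps in the
test suite use 50 replicates per grid point.
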
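"""Build a model-ready input from a raw association p-value matrix.

Emulates the literature-mining front end on synthetic p-values: two input
gene lists play the role of known pathway members, GO terms are selected
per list by smallest average p-value, candidate genes by largest average
cosine similarity (on the -log10 p scale, over all GO columns), and the
selected sub-matrix is binarized at p < 0.1. The result is the binary
matrix plus the constraint table that the model consumes directly.
"""

import numpy as np

from palmer import (
    AssociationPValueMatrix,
    FitOptions,
    PreprocessConfig,
    build_palmer_input,
    fit_palmer,
)

rng = np.random.default_rng(5)
n, p = 40, 60
values = rng.uniform(0, 1, (n, p))
# pathway 1: genes 0-7 strongly associated with GO terms 0-14
values[0:8, 0:15] = rng.uniform(0, 0.1, (8, 15))
# pathway 2: genes 8-15 with GO terms 15-29
values[8:16, 15:30] = rng.uniform(0, 0.1, (8, 15))
# two candidates that echo each pathway's profile
values[16] = values[0] * rng.uniform(0.8, 1.2, p)
values[17] = values[8] * rng.uniform(0.8, 1.2, p)
P = AssociationPValueMatrix(
    values=np.clip(values, 0, 1),
    gene_ids=[f"gene{i}" for i in range(n)],
    go_ids=[f"GO:{j:07d}" for j in range(p)],
)

list1 = [f"gene{i}" for i in range(0, 8)]
list2 = [f"gene{i}" for i in range(8, 16)]
X, constraints = build_palmer_input(
    P, list1, list2, PreprocessConfig(cutoff=0.1, go_ratio=1, candidate_ratio=0.5)
)
print(f"built matrix: {X.n_genes} genes x {X.n_go} GO terms "
      f"({len(constraints)} constrained, "
      f"{X.n_genes - len(constraints)} candidates)")

result = fit_palmer(X, constraints, FitOptions(K=2, L=2))
for g, lab in zip(X.gene_ids, result.assignment.gene_labels):
    if g not in constraints.assignments:
        print(f"candidate {g} assigned to pathway cluster {lab}")
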
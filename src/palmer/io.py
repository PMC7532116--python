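"""Readers and writers for the on-disk artifacts.

Matrices travel as TSV (CSV via ``dialect="csv"``): header row = GO-term
ids, first column = gene ids, genes as rows. Constraints are a two-column
table ``gene_id<TAB>label`` with labels 1..K. A fitted model is stored as a
single JSON document. All labels are 1-based on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AssociationPValueMatrix,
    BinaryAssociationMatrix,
    BootstrapResult,
    CoClusterModel,
    ConstraintSet,
    FitResult,
)

_SEP = {"tsv": "\t", "csv": ","}


def _read_frame(path, dialect: str) -> pd.DataFrame:
    if dialect not in _SEP:
        raise ValueError(f"dialect must be one of {sorted(_SEP)}")
    df = pd.read_csv(path, sep=_SEP[dialect], index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_binary_matrix(path, dialect: str = "tsv") -> BinaryAssociationMatrix:
    """Read a {0,1} gene x GO-term matrix; non-binary cells are rejected
    with the offending row/column named."""
    df = _read_frame(path, dialect)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: cell at gene {df.index[i]!r}, GO term {df.columns[j]!r} "
            f"is {values[i, j]!r}, expected 0 or 1"
        )
    return BinaryAssociationMatrix(
        values=values.astype(np.int8),
        gene_ids=list(df.index),
        go_ids=list(df.columns),
    )


def write_binary_matrix(X: BinaryAssociationMatrix, path, dialect: str = "tsv") -> None:
    pd.DataFrame(X.values, index=X.gene_ids, columns=X.go_ids).to_csv(
        path, sep=_SEP[dialect]
    )


def read_pvalue_matrix(path, dialect: str = "tsv") -> AssociationPValueMatrix:
    df = _read_frame(path, dialect)
    return AssociationPValueMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=list(df.index),
        go_ids=list(df.columns),
    )


def write_pvalue_matrix(P: AssociationPValueMatrix, path, dialect: str = "tsv") -> None:
    pd.DataFrame(P.values, index=P.gene_ids, columns=P.go_ids).to_csv(
        path, sep=_SEP[dialect]
    )


def read_constraints(path, K: int, dialect: str = "tsv") -> ConstraintSet:
    """Read the two-column gene_id / label table; order-independent."""
    df = pd.read_csv(
        path, sep=_SEP[dialect], header=None, names=["gene_id", "label"], comment="#"
    )
    # tolerate a header line
    if df.iloc[0]["gene_id"] == "gene_id":
        df = df.iloc[1:]
    assignments: dict[str, int] = {}
    for _, row in df.iterrows():
        g, k = str(row["gene_id"]), int(row["label"])
        if g in assignments and assignments[g] != k:
            raise ValueError(f"{path}: gene {g!r} constrained to both {assignments[g]} and {k}")
        assignments[g] = k
    return ConstraintSet(assignments=assignments, n_clusters=K)


def write_constraints(constraints: ConstraintSet, path) -> None:
    with open(path, "w") as fh:
        for g, k in constraints.assignments.items():
            fh.write(f"{g}\t{k}\n")


def model_to_dict(model: CoClusterModel) -> dict:
    return {
        "theta": model.theta.tolist(),
        "alpha": model.alpha.tolist(),
        "beta": model.beta.tolist(),
    }


def model_from_dict(d: dict) -> CoClusterModel:
    return CoClusterModel(
        theta=np.asarray(d["theta"]),
        alpha=np.asarray(d["alpha"]),
        beta=np.asarray(d["beta"]),
    )


def read_model(path) -> CoClusterModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh)["model"])


def write_fit_result(
    result: FitResult,
    X: BinaryAssociationMatrix,
    constraints: ConstraintSet | None,
    out_dir,
    confidence: BootstrapResult | None = None,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Emit the three artifacts of a fit into ``out_dir``:

    - ``genes.tsv``: gene_id, cluster, is_constrained, confidence (NA if no
      bootstrap was run);
    - ``go_terms.tsv``: go_id, cluster;
    - ``model.json``: theta/alpha/beta plus run metadata.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    constrained_ids = set(constraints.assignments) if constraints else set()
    genes = pd.DataFrame(
        {
            "gene_id": X.gene_ids,
            "cluster": result.assignment.gene_labels,
            "is_constrained": [g in constrained_ids for g in X.gene_ids],
            "confidence": (
                confidence.probabilities if confidence is not None else "NA"
            ),
        }
    )
    go = pd.DataFrame({"go_id": X.go_ids, "cluster": result.assignment.go_labels})
    paths = {
        "genes": out_dir / "genes.tsv",
        "go_terms": out_dir / "go_terms.tsv",
        "model": out_dir / "model.json",
    }
    genes.to_csv(paths["genes"], sep="\t", index=False)
    go.to_csv(paths["go_terms"], sep="\t", index=False)
    doc = {
        "model": model_to_dict(result.model),
        "n_outer_iterations": result.n_outer_iterations,
        "converged": result.converged,
        "metadata": metadata or {},
    }
    with open(paths["model"], "w") as fh:
        json.dump(doc, fh, indent=1)
    return paths
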
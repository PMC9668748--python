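"""Plain-text readers and writers for the pipeline's tabular artifacts.

Counts and expression matrices are genes x samples TSVs (first column
gene_id, header row of sample ids); counts may alternatively be stored as a
MatrixMarket triplet with sidecar row/column name files. Effective lengths
travel in a two-column TSV. Everything round-trips bit-identically through
pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CountMatrix
from .synthetic import SyntheticTruth


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts(cm: CountMatrix, counts_path: str | Path, lengths_path: str | Path) -> None:
    write_matrix_tsv(cm.counts, counts_path)
    cm.effective_length.rename("effective_length").to_csv(
        lengths_path, sep="\t", index_label="gene_id"
    )


def read_counts(
    counts_path: str | Path,
    lengths_path: str | Path | None = None,
    default_length: float = 1000.0,
) -> CountMatrix:
    counts = read_matrix_tsv(counts_path).astype(np.int64)
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")[
            "effective_length"
        ]
    else:
        lengths = pd.Series(default_length, index=counts.index)
    return CountMatrix(counts=counts, effective_length=lengths)


def write_counts_mtx(cm: CountMatrix, prefix: str | Path) -> None:
    """MatrixMarket triplet plus row/column name sidecars ({prefix}.mtx/.rows/.cols)."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(cm.counts.to_numpy()))
    prefix.with_suffix(".rows").write_text("\n".join(cm.counts.index) + "\n")
    prefix.with_suffix(".cols").write_text("\n".join(cm.counts.columns) + "\n")


def read_counts_mtx(
    prefix: str | Path,
    lengths_path: str | Path | None = None,
    default_length: float = 1000.0,
) -> CountMatrix:
    from scipy import io as spio

    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(np.int64)
    rows = prefix.with_suffix(".rows").read_text().splitlines()
    cols = prefix.with_suffix(".cols").read_text().splitlines()
    counts = pd.DataFrame(mat, index=pd.Index(rows, name="gene_id"), columns=cols)
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")[
            "effective_length"
        ]
    else:
        lengths = pd.Series(default_length, index=counts.index)
    return CountMatrix(counts=counts, effective_length=lengths)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": list(truth.per_gene_slope),
            "slope": list(truth.per_gene_slope.values()),
            "is_gradient": [
                g in truth.gradient_gene_ids for g in truth.per_gene_slope
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
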
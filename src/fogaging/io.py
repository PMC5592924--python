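"""TSV readers and writers for the pipeline's table types.

All tables are tab-separated UTF-8 with '.' decimals, matching genomics
convention.  Readers validate structure eagerly and report the offending
row or cell in their error messages.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("fogaging")


def read_expression(path) -> pd.DataFrame:
    """Read a feature x sample expression TSV (first column: feature ids).

    Rejects duplicate feature or sample ids and negative values, naming the
    offender; logs counts of all-zero and zero-variance features.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.index.name = "feature"
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated feature id {dup[0]!r}")
    dup_cols = table.columns[table.columns.duplicated()]
    if len(dup_cols):
        raise ValueError(f"{path}: duplicated sample id {dup_cols[0]!r}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric expression values")
    if np.any(np.isnan(values)):
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value at feature {table.index[i]!r}, sample {table.columns[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value {values[i, j]!r} at feature "
            f"{table.index[i]!r}, sample {table.columns[j]!r}"
        )
    n_zero = int((values == 0).all(axis=1).sum())
    n_flat = int((values.std(axis=1) == 0).sum()) - n_zero
    if n_zero:
        log.info("%s: %d all-zero features (excluded from testing)", path, n_zero)
    if n_flat:
        log.info("%s: %d constant non-zero features", path, n_flat)
    return table


def read_design(path) -> pd.DataFrame:
    """Read a design TSV with columns sample, age, genotype (0/1)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "age", "genotype"):
        if col not in table.columns:
            raise ValueError(f"{path}: design table lacks column {col!r}")
    table = table.set_index("sample")
    for col in ("age", "genotype"):
        vals = set(table[col].unique().tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"{path}: column {col!r} must be binary 0/1, found {sorted(vals)}")
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated sample id {dup[0]!r}")
    return table


def read_coefficients(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    required = {"beta0", "betaA", "betaG", "betaAG", "qA", "qG", "qAG"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: coefficient table lacks columns {sorted(missing)}")
    return table


def read_truth(path) -> pd.DataFrame:
    # keep_default_na=False: the regime label "null" is a value, not missing
    table = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[""])
    table.index = table.index.astype(str)
    return table


def read_feature_map(path) -> dict[str, str]:
    """Read a two-column feature -> gene TSV into a dict."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: feature map needs two columns (feature, gene)")
    feats, genes = table.iloc[:, 0], table.iloc[:, 1]
    if feats.duplicated().any():
        raise ValueError(f"{path}: duplicated feature {feats[feats.duplicated()].iloc[0]!r}")
    return dict(zip(feats, genes))


def read_gene_list(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def write_table(table: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write any indexed table as TSV, creating parent directories."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index_label=index_label or table.index.name)


def write_design(design: pd.DataFrame, path) -> None:
    write_table(design, path, index_label="sample")
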
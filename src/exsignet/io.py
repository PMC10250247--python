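"""Readers for the pipeline's standard input formats."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import scipy.io

from .errors import ValidationError


def read_expression_mtx(
    matrix: str | Path, genes: str | Path, barcodes: str | Path
) -> pd.DataFrame:
    """Read an MTX triplet (matrix + gene index + cell barcode index).

    Returns a dense genes x cells DataFrame.  The matrix may be stored
    either genes-by-cells or cells-by-genes; orientation is resolved
    from the index file lengths.
    """
    m = scipy.io.mmread(matrix)
    gene_list = [line.split("\t")[0].strip()
                 for line in Path(genes).read_text().splitlines() if line.strip()]
    cell_list = [line.strip()
                 for line in Path(barcodes).read_text().splitlines() if line.strip()]
    arr = m.toarray() if hasattr(m, "toarray") else m
    if arr.shape == (len(gene_list), len(cell_list)):
        pass
    elif arr.shape == (len(cell_list), len(gene_list)):
        arr = arr.T
    else:
        raise ValidationError(
            f"matrix shape {arr.shape} matches neither ({len(gene_list)} genes, "
            f"{len(cell_list)} cells) nor its transpose"
        )
    return pd.DataFrame(arr, index=gene_list, columns=cell_list)


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    """Read a dense genes x cells CSV (first column gene symbols)."""
    return pd.read_csv(path, index_col=0)


def read_cell_labels(path: str | Path) -> pd.Series:
    """Read a two-column ``cell,group`` CSV into a cell -> group Series."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (cell, group)")
    return pd.Series(df.iloc[:, 1].astype(str).values,
                     index=df.iloc[:, 0].astype(str).values, name="group")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file."""
    genes = [line.strip() for line in Path(path).read_text().splitlines()
             if line.strip()]
    if not genes:
        raise ValidationError(f"{path}: empty gene list")
    return genes


def read_term_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GO-term gene sets from GMT or two-column TSV.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``; the
    TSV form is one ``term<TAB>gene`` pair per line (no header needed,
    but a ``term\tgene`` header row is tolerated).
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms.setdefault(parts[0], set()).update(
                g for g in parts[2:] if g)
    else:
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts == ["term", "gene"]:
                continue
            terms.setdefault(parts[0], set()).add(parts[1])
    if not terms:
        raise ValidationError(f"{path}: no term sets parsed")
    return terms
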
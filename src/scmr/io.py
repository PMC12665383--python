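"""Readers and writers for the pipeline's plain-text formats.

Summary statistics use a tab-separated GWAS-SSF-like dialect with header
``snp chr pos effect_allele other_allele eaf beta se pval n``; count
matrices are MatrixMarket triplets (``matrix.mtx`` + ``genes.tsv`` +
``barcodes.tsv``) or dense TSV (genes as the index, samples/cells as
columns).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import InputError
from .synthetic import CountsData, SUMMARY_COLUMNS

logger = logging.getLogger(__name__)

REQUIRED_SUMMARY_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele", "beta", "se", "pval",
]
VALID_ALLELES = frozenset("ACGT")


def read_summary_stats(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Read and validate a summary-statistic TSV.

    ``column_map`` renames foreign headers to the canonical dialect
    (``{"their_name": "canonical_name"}``).  Rows with non-positive
    standard errors, p-values outside (0, 1], or invalid alleles are
    rejected and logged with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"missing required column(s): {', '.join(missing)}")
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan
    extra = "gene" if "gene" in df.columns else None

    bad = pd.Series(False, index=df.index)
    bad |= ~(pd.to_numeric(df["se"], errors="coerce") > 0)
    pv = pd.to_numeric(df["pval"], errors="coerce")
    bad |= ~((pv > 0) & (pv <= 1))
    for col in ("effect_allele", "other_allele"):
        bad |= ~df[col].astype(str).str.upper().isin(VALID_ALLELES)
    bad |= df["effect_allele"].astype(str).str.upper() == df["other_allele"].astype(str).str.upper()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s",
                       path.name, int(bad.sum()), lines)
    df = df[~bad].reset_index(drop=True)
    cols = (["gene"] if extra else []) + SUMMARY_COLUMNS
    return df[[c for c in cols if c in df.columns]]


def write_summary_stats(df: pd.DataFrame, path) -> None:
    cols = [c for c in (["gene"] + SUMMARY_COLUMNS) if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_counts(path) -> CountsData:
    """Read a gene-by-cell matrix from an MTX-triplet directory, a
    ``.mtx`` file (with sibling ``genes.tsv``/``barcodes.tsv``), or a
    dense TSV."""
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        mtx = path / "matrix.mtx" if path.is_dir() else path
        base = mtx.parent
        for req in (mtx, base / "genes.tsv", base / "barcodes.tsv"):
            if not req.exists():
                raise InputError(f"no such file: {req}")
        mat = sparse.csr_matrix(spio.mmread(mtx))
        genes = (base / "genes.tsv").read_text().split()
        barcodes = (base / "barcodes.tsv").read_text().split()
        if mat.shape != (len(genes), len(barcodes)):
            raise InputError(
                f"matrix is {mat.shape} but {len(genes)} genes / "
                f"{len(barcodes)} barcodes were listed")
    else:
        if not path.exists():
            raise InputError(f"no such file: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
        mat = sparse.csr_matrix(df.to_numpy(dtype=float))
    if len(set(genes)) != len(genes):
        raise InputError("duplicate gene names in counts input")
    return CountsData(mat, genes, barcodes)


def write_counts(data: CountsData, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(data.matrix))
    (out / "genes.tsv").write_text("\n".join(data.genes) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(data.barcodes) + "\n")


def read_labels(path, value_column: str) -> pd.Series:
    """Two-column TSV ``id <tab> value`` -> Series indexed by id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path.name}: expected two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(),
                  name=value_column)
    return s


def write_labels(series: pd.Series, path, id_name: str, value_name: str) -> None:
    pd.DataFrame({id_name: series.index, value_name: series.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def read_bulk(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InputError("duplicate gene names in bulk table")
    return df


def read_ld_matrix(path) -> pd.DataFrame:
    """Square TSV with variant-id header/index, or long-format triplets
    ``id1 id2 r2`` (symmetrized, unit diagonal)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    head = pd.read_csv(path, sep="\t", nrows=1)
    if list(head.columns[:3]) == ["id1", "id2", "r2"]:
        long = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
        ids = sorted(set(long["id1"]) | set(long["id2"]))
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for _, r in long.iterrows():
            mat.at[r["id1"], r["id2"]] = r["r2"]
            mat.at[r["id2"], r["id1"]] = r["r2"]
        np.fill_diagonal(mat.values, 1.0)
        return mat
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    if mat.shape[0] != mat.shape[1]:
        raise InputError("LD matrix must be square")
    return mat
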
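"""Per-cell QC metrics, MAD-rule filtering, normalization, and HVG selection.

Cells are filtered with the median-absolute-deviation rule: for each metric
the upper bound is ``median + n_mads * scale_constant * MAD`` computed over
the full input population, with an optional fixed lower bound (by default
only ``n_feature > 200``).  ``scale_constant`` defaults to 1.4826 (the
normal-consistency factor common in scRNA-seq QC) and can be set to 1 for
the raw MAD.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError, InputError
from .synthetic import CountsData

Matrix = Union[np.ndarray, sparse.spmatrix]

DEFAULT_MITO_PATTERN = r"(?i)^MT-"
DEFAULT_RIBO_PATTERN = r"(?i)^RP[SL]"


def _as_matrix(counts, genes=None, barcodes=None):
    if isinstance(counts, CountsData):
        return counts.matrix, counts.genes, counts.barcodes
    if genes is None:
        raise InputError("gene names are required with a bare matrix")
    n_genes, n_cells = counts.shape
    if len(genes) != n_genes:
        raise InputError("gene-name list does not match matrix rows")
    if barcodes is None:
        barcodes = [f"cell{i}" for i in range(n_cells)]
    return counts, list(genes), list(barcodes)


def compute_qc_metrics(counts, genes=None, barcodes=None,
                       mito_pattern: str = DEFAULT_MITO_PATTERN,
                       ribo_pattern: str = DEFAULT_RIBO_PATTERN) -> pd.DataFrame:
    """Per-cell QC metrics from a gene-by-cell count matrix.

    Returns a DataFrame indexed by barcode with columns ``n_count``
    (total molecules), ``n_feature`` (genes with count > 0), ``percent_mt``
    and ``percent_ribo`` (100 x matched-gene fraction of the total; defined
    as 0 for zero-total cells).
    """
    mat, genes, barcodes = _as_matrix(counts, genes, barcodes)
    if len(set(genes)) != len(genes):
        raise InputError("gene names must be unique")
    mat = sparse.csr_matrix(mat) if not sparse.issparse(mat) else mat.tocsr()
    if mat.nnz and mat.data.min() < 0:
        raise InputError("counts must be non-negative")

    total = np.asarray(mat.sum(axis=0)).ravel()
    n_feature = np.asarray((mat > 0).sum(axis=0)).ravel()
    mito = np.array([bool(re.search(mito_pattern, g)) for g in genes])
    ribo = np.array([bool(re.search(ribo_pattern, g)) for g in genes])
    mito_sum = np.asarray(mat[mito].sum(axis=0)).ravel() if mito.any() else np.zeros_like(total)
    ribo_sum = np.asarray(mat[ribo].sum(axis=0)).ravel() if ribo.any() else np.zeros_like(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mt = np.where(total > 0, 100.0 * mito_sum / np.maximum(total, 1), 0.0)
        pct_ribo = np.where(total > 0, 100.0 * ribo_sum / np.maximum(total, 1), 0.0)
    return pd.DataFrame({
        "n_count": total,
        "n_feature": n_feature,
        "percent_mt": pct_mt,
        "percent_ribo": pct_ribo,
    }, index=pd.Index(barcodes, name="barcode"))


def mad_upper_bound(values, n_mads: float = 3.0,
                    scale_constant: float = 1.4826) -> float:
    """``median + n_mads * scale_constant * median(|x - median|)``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("cannot compute a MAD bound on an empty vector")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return float(med + n_mads * scale_constant * mad)


@dataclass
class QCRule:
    """One filtering rule: optional strict lower bound plus an optional
    upper bound at median + n_mads x scale_constant x MAD."""

    metric: str
    lower: Optional[float] = None
    upper_mad: bool = True
    n_mads: float = 3.0
    scale_constant: float = 1.4826

    def __post_init__(self):
        if self.n_mads <= 0:
            raise ConfigurationError("n_mads must be > 0")


def default_qc_rules(min_features: float = 200.0, n_mads: float = 3.0,
                     scale_constant: float = 1.4826) -> list[QCRule]:
    """The standard rule set: n_feature > min_features plus upper MAD
    bounds on n_feature, n_count, percent_mt, and percent_ribo."""
    kw = dict(n_mads=n_mads, scale_constant=scale_constant)
    return [
        QCRule("n_feature", lower=min_features, upper_mad=True, **kw),
        QCRule("n_count", upper_mad=True, **kw),
        QCRule("percent_mt", upper_mad=True, **kw),
        QCRule("percent_ribo", upper_mad=True, **kw),
    ]


@dataclass
class QCResult:
    kept: list[str]
    report: pd.DataFrame
    thresholds: dict = field(default_factory=dict)


def apply_qc_filter(metrics: pd.DataFrame, rules: Sequence[QCRule],
                    thresholds: Optional[dict] = None) -> QCResult:
    """Keep cells passing every rule; report realized thresholds.

    Upper thresholds are computed on the full input population unless a
    frozen ``thresholds`` mapping (metric -> (lower, upper)) from an earlier
    run is supplied, in which case those are reused verbatim so that
    re-application reproduces the same kept set.
    """
    for rule in rules:
        if rule.metric not in metrics.columns:
            raise ConfigurationError(f"unknown QC metric: {rule.metric!r}")
    keep = np.ones(len(metrics), dtype=bool)
    rows = []
    realized: dict = {}
    for rule in rules:
        v = metrics[rule.metric].to_numpy(dtype=float)
        if thresholds is not None and rule.metric in thresholds:
            lower, upper = thresholds[rule.metric]
        else:
            lower = rule.lower
            upper = mad_upper_bound(v, rule.n_mads, rule.scale_constant) \
                if rule.upper_mad else None
        fail_low = (v <= lower) if lower is not None else np.zeros_like(keep)
        fail_high = (v > upper) if upper is not None else np.zeros_like(keep)
        keep &= ~(fail_low | fail_high)
        realized[rule.metric] = (lower, upper)
        rows.append({
            "metric": rule.metric,
            "lower": np.nan if lower is None else lower,
            "upper": np.nan if upper is None else upper,
            "n_fail_lower": int(fail_low.sum()),
            "n_fail_upper": int(fail_high.sum()),
        })
    report = pd.DataFrame(rows, columns=["metric", "lower", "upper",
                                         "n_fail_lower", "n_fail_upper"])
    kept = [str(b) for b in metrics.index[keep]]
    return QCResult(kept=kept, report=report, thresholds=realized)


def log_normalize(counts: Matrix, scale: float = 10_000.0) -> Matrix:
    """``ln(1 + scale * count / column_total)`` per entry; zeros stay zero.

    Raises InputError on zero-total columns (run QC first).  Sparse input
    yields sparse output.
    """
    if sparse.issparse(counts):
        mat = counts.tocsc().astype(float)
        totals = np.asarray(mat.sum(axis=0)).ravel()
        if np.any(totals <= 0):
            raise InputError("zero-total cell encountered; filter cells first")
        out = mat.copy()
        out.data = out.data * np.repeat(scale / totals, np.diff(mat.indptr))
        out.data = np.log1p(out.data)
        return out.tocsr()
    mat = np.asarray(counts, dtype=float)
    totals = mat.sum(axis=0)
    if np.any(totals <= 0):
        raise InputError("zero-total cell encountered; filter cells first")
    return np.log1p(scale * mat / totals)


def find_variable_genes(normalized: Matrix, genes: Sequence[str], k: int) -> list[str]:
    """The ``k`` genes with largest variance of normalized values.

    Ties are broken by gene-name lexicographic order, so the result is
    deterministic.
    """
    genes = list(genes)
    if k > len(genes):
        raise InputError(f"k={k} exceeds the number of genes ({len(genes)})")
    if sparse.issparse(normalized):
        mat = normalized.tocsr()
        mean = np.asarray(mat.mean(axis=1)).ravel()
        mean_sq = np.asarray(mat.multiply(mat).mean(axis=1)).ravel()
        var = mean_sq - mean ** 2
    else:
        var = np.var(np.asarray(normalized, dtype=float), axis=1)
    order = sorted(range(len(genes)), key=lambda i: (-var[i], genes[i]))
    return [genes[i] for i in order[:k]]
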
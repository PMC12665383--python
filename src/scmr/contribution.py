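"""Cluster marker genes and the FCscore disease-contribution statistic.

For a characteristic gene *i* of cell cluster *j*, the contribution score
combines the bulk case/control expression fold change FCexp(i) with the
cluster's case/control abundance fold change FCprop(j):

    FCscore(i, j) = sqrt(FCexp(i) * FCprop(j))

A cluster's overall contribution is the arithmetic mean FCscore over its
characteristic genes; clusters are ranked by that mean.  Characteristic
genes are one-vs-rest Wilcoxon rank-sum markers passing
``log2FC > logfc_min`` and ``BH-adjusted p < padj_max`` (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import InputError
from .stats import bh_fdr, rank_sum_test_matrix


def find_cluster_markers(normalized, genes, clusters,
                         logfc_min: float = 0.585,
                         padj_max: float = 0.05,
                         eps: float = 1e-9,
                         expm1_means: bool = True,
                         return_all: bool = False) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    ``normalized`` is a gene-by-cell matrix of log-normalized values,
    ``clusters`` a per-cell label vector.  For each cluster every gene is
    tested with a two-sided Wilcoxon rank-sum test (exact for small groups)
    and ``log2FC = log2((mean_in + eps) / (mean_out + eps))``; with
    ``expm1_means`` (the single-cell convention) the group means are taken
    on the un-logged scale, so the fold change is an expression-scale
    ratio rather than a ratio of log values.  BH adjustment is applied
    within each cluster's gene list.  Only rows passing both strict
    thresholds are returned unless ``return_all``.
    """
    genes = list(genes)
    labels = np.asarray(clusters)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise InputError("marker calling requires at least two clusters")
    mat = normalized.toarray() if sparse.issparse(normalized) else np.asarray(normalized, dtype=float)
    if mat.shape[0] != len(genes) or mat.shape[1] != labels.size:
        raise InputError("matrix dimensions do not match gene/cluster labels")

    frames = []
    for cl in uniq:
        mask = labels == cl
        x_in = mat[:, mask].T     # cells x genes
        x_out = mat[:, ~mask].T
        pvals = rank_sum_test_matrix(x_in, x_out)
        if expm1_means:
            mean_in = np.expm1(x_in).mean(axis=0)
            mean_out = np.expm1(x_out).mean(axis=0)
        else:
            mean_in = x_in.mean(axis=0)
            mean_out = x_out.mean(axis=0)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        padj = bh_fdr(pvals)
        frames.append(pd.DataFrame({
            "gene": genes,
            "cluster": cl,
            "log2fc": log2fc,
            "pval": pvals,
            "padj": padj,
        }))
    table = pd.concat(frames, ignore_index=True)
    if return_all:
        return table
    keep = (table["log2fc"] > logfc_min) & (table["padj"] < padj_max)
    return table[keep].reset_index(drop=True)


def bulk_fold_change(bulk: pd.DataFrame, groups: pd.Series, genes,
                     eps: float = 0.01,
                     case_label: str = "case",
                     control_label: str = "control") -> pd.Series:
    """Per-gene case/control mean expression ratio from a bulk table.

    ``bulk`` is genes x samples; ``groups`` maps sample id to group label.
    FCexp = (mean_case + eps) / (mean_control + eps) on the expression
    scale.  Genes absent from the bulk table get NaN (reported, never
    imputed).  Matching is by exact symbol after uppercasing.
    """
    groups = groups.reindex(bulk.columns)
    case_cols = groups.index[groups == case_label]
    ctrl_cols = groups.index[groups == control_label]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InputError("both groups need at least 2 bulk samples")
    upper_index = pd.Index([str(g).upper() for g in bulk.index])
    if upper_index.has_duplicates:
        raise InputError("bulk gene symbols collide after uppercasing")
    mean_case = pd.Series(bulk[case_cols].mean(axis=1).to_numpy(), index=upper_index)
    mean_ctrl = pd.Series(bulk[ctrl_cols].mean(axis=1).to_numpy(), index=upper_index)
    out = {}
    for g in genes:
        key = str(g).upper()
        if key in mean_case.index:
            out[g] = (mean_case[key] + eps) / (mean_ctrl[key] + eps)
        else:
            out[g] = np.nan
    return pd.Series(out, name="fcexp")


def proportion_fold_change(metadata: pd.DataFrame,
                           case_label: str = "case",
                           control_label: str = "control") -> pd.Series:
    """Per-cluster case/control proportion ratio.

    FCprop(j) = (n_case,j / n_case) / (n_control,j / n_control).  Clusters
    absent from one group receive a continuity correction of 0.5 cells in
    both groups.
    """
    for col in ("cluster", "group"):
        if col not in metadata.columns:
            raise InputError(f"cell metadata must have a {col!r} column")
    case = metadata[metadata["group"] == case_label]
    ctrl = metadata[metadata["group"] == control_label]
    if len(case) == 0 or len(ctrl) == 0:
        raise InputError("both case and control cells are required")
    clusters = sorted(metadata["cluster"].unique())
    n_case = case["cluster"].value_counts().reindex(clusters, fill_value=0).astype(float)
    n_ctrl = ctrl["cluster"].value_counts().reindex(clusters, fill_value=0).astype(float)
    absent = (n_case == 0) | (n_ctrl == 0)
    n_case[absent] += 0.5
    n_ctrl[absent] += 0.5
    ratio = (n_case / len(case)) / (n_ctrl / len(ctrl))
    ratio.name = "fcprop"
    ratio.index.name = "cluster"
    return ratio


@dataclass
class ContributionResult:
    clusters: pd.DataFrame   # cluster, n_markers, n_scored, fcprop, mean_fcscore, rank, flagged
    per_gene: pd.DataFrame   # gene, cluster, fcexp, fcprop, fcscore
    missing_genes: list[str]


def fcscore(markers: pd.DataFrame, fcexp: pd.Series,
            fcprop: pd.Series) -> ContributionResult:
    """Rank clusters by mean FCscore over their characteristic genes.

    Markers whose FCexp is missing (gene absent from bulk) are excluded
    from the average and counted; a cluster with zero scoreable markers
    gets an undefined score, is ranked last, and is flagged.
    """
    missing_clusters = set(markers["cluster"]) - set(fcprop.index)
    if missing_clusters:
        raise InputError(f"no FCprop for cluster(s): {sorted(missing_clusters)}")
    per = markers[["gene", "cluster"]].copy()
    per["fcexp"] = per["gene"].map(fcexp)
    per["fcprop"] = per["cluster"].map(fcprop)
    per["fcscore"] = np.sqrt(per["fcexp"] * per["fcprop"])
    missing = sorted(per.loc[per["fcexp"].isna(), "gene"].unique())

    rows = []
    for cl, grp in per.groupby("cluster", sort=True):
        scored = grp.dropna(subset=["fcscore"])
        rows.append({
            "cluster": cl,
            "n_markers": len(grp),
            "n_scored": len(scored),
            "fcprop": float(fcprop[cl]),
            "mean_fcscore": float(scored["fcscore"].mean()) if len(scored) else np.nan,
            "flagged": len(scored) == 0,
        })
    # also report clusters that have an FCprop but no markers at all
    for cl in fcprop.index:
        if cl not in set(markers["cluster"]):
            rows.append({"cluster": cl, "n_markers": 0, "n_scored": 0,
                         "fcprop": float(fcprop[cl]), "mean_fcscore": np.nan,
                         "flagged": True})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["mean_fcscore", "cluster"], ascending=[False, True],
        na_position="last", kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ContributionResult(clusters=table, per_gene=per, missing_genes=missing)
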
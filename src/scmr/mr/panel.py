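"""End-to-end MR over a panel of genes.

For each gene: instrument selection (p < threshold), optional LD clumping,
allele harmonization, every applicable estimator, and the sensitivity
report.  BH-FDR is applied to the primary (IVW, or Wald ratio when only one
instrument survives) p-values across the genes that produced an estimate;
genes with no surviving instruments are reported with status
``no_instruments`` and excluded from the FDR family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ..stats import bh_fdr
from .data import SensitivityReport
from .estimators import cochran_q, ivw, mr_egger, weighted_median, weighted_mode
from .harmonize import harmonize
from .instruments import ld_clump, select_instruments
from .sensitivity import leave_one_out


@dataclass
class MRPanelConfig:
    p_threshold: float = 1e-8
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    palindrome_window: tuple[float, float] = (0.42, 0.58)
    random_effects: bool = True
    n_boot: int = 1000
    seed: int = 20250101
    outcome_id: str = "outcome"


@dataclass
class MRPanelResult:
    results: pd.DataFrame                  # gene, method, nsnp, beta, se, or, ci, pval, fdr
    summary: pd.DataFrame                  # one primary row per gene (mirrors a forest plot)
    heterogeneity: pd.DataFrame            # gene, method, Q, Q_df, Q_pval
    loo: pd.DataFrame                      # leave-one-out rows, all genes
    harmonization_log: pd.DataFrame
    sensitivity: dict = field(default_factory=dict)
    statuses: dict = field(default_factory=dict)


def _split_by_gene(exposures) -> Mapping[str, pd.DataFrame]:
    if isinstance(exposures, pd.DataFrame):
        return {g: df.drop(columns=["gene"]).reset_index(drop=True)
                for g, df in exposures.groupby("gene", sort=True)}
    return dict(exposures)


def run_reverse_panel(exposures, outcome: pd.DataFrame,
                      config: Optional["MRPanelConfig"] = None,
                      ld=None) -> "MRPanelResult":
    """Reverse-direction MR: disease liability as exposure, each gene's
    expression as outcome.

    For every gene the disease summary statistics are instrumented
    (selection on the disease p-values) and harmonized against that gene's
    expression table.  The BH-FDR family is the reverse panel itself,
    separate from the forward family.
    """
    config = config or MRPanelConfig()
    per_gene = _split_by_gene(exposures)
    partials = []
    for gene, gene_table in per_gene.items():
        disease = outcome.copy()
        partials.append(run_mr_panel({gene: disease}, gene_table, config, ld=ld))
    return _merge_panels(partials)


def _merge_panels(partials) -> "MRPanelResult":
    def cat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    results = cat([p.results for p in partials])
    summary = cat([p.summary for p in partials])
    if len(summary):
        summary["fdr"] = bh_fdr(summary["pval"].to_numpy())
        fdr_of = dict(zip(summary["gene"], summary["fdr"]))
        results["fdr"] = [
            fdr_of[r["gene"]] if r["method"] in ("ivw", "wald_ratio") else np.nan
            for _, r in results.iterrows()
        ]
    sensitivity = {}
    statuses = {}
    for p in partials:
        sensitivity.update(p.sensitivity)
        statuses.update(p.statuses)
    return MRPanelResult(
        results=results, summary=summary,
        heterogeneity=cat([p.heterogeneity for p in partials]),
        loo=cat([p.loo for p in partials]),
        harmonization_log=cat([p.harmonization_log for p in partials]),
        sensitivity=sensitivity, statuses=statuses)


def run_mr_panel(exposures, outcome: pd.DataFrame,
                 config: Optional[MRPanelConfig] = None,
                 ld=None) -> MRPanelResult:
    """Run the full MR battery for every gene in ``exposures``.

    ``exposures`` is either a summary-statistic DataFrame with a ``gene``
    column or a mapping gene -> table.  ``ld`` is an optional r-squared
    source (square DataFrame keyed by variant id, aligned matrix, or
    callable); when omitted the instruments are assumed independent and
    clumping is skipped.
    """
    config = config or MRPanelConfig()
    per_gene = _split_by_gene(exposures)
    result_rows, het_rows, loo_frames, log_frames = [], [], [], []
    sensitivity: dict[str, SensitivityReport] = {}
    statuses: dict[str, str] = {}
    primaries: dict[str, dict] = {}
    boot_seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(per_gene))

    for gi, (gene, table) in enumerate(per_gene.items()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_instruments(table, config.p_threshold)
        if len(sel) == 0:
            statuses[gene] = "no_instruments"
            continue
        if ld is not None:
            sel = ld_clump(sel, ld, config.r2_max, config.window_kb)
        h = harmonize(sel, outcome, config.palindrome_window,
                      exposure_id=gene, outcome_id=config.outcome_id)
        if len(h.log):
            log_frames.append(h.log.assign(gene=gene))
        if h.nsnp == 0:
            statuses[gene] = "no_instruments"
            continue
        statuses[gene] = "ok"

        primary = ivw(h, random_effects=config.random_effects)
        estimates = [primary]
        report = SensitivityReport()
        if h.nsnp >= 3:
            egger = mr_egger(h, random_effects=config.random_effects)
            if egger is not None:
                estimates.extend(egger)
                report.egger_intercept = egger[1]
            wm = weighted_median(h, config.n_boot, int(boot_seeds[2 * gi]))
            wmode = weighted_mode(h, 1.0, config.n_boot, int(boot_seeds[2 * gi + 1]))
            estimates.extend(e for e in (wm, wmode) if e is not None)
        if h.nsnp >= 2:
            report.q_ivw = cochran_q(h, "ivw")
            het_rows.append({"gene": gene, "method": "Inverse variance weighted",
                             "Q": report.q_ivw[0], "Q_df": report.q_ivw[1],
                             "Q_pval": report.q_ivw[2]})
            loo = leave_one_out(h)
            report.leave_one_out = loo
            loo_frames.append(loo.assign(gene=gene))
        if h.nsnp >= 3:
            report.q_egger = cochran_q(h, "egger")
            het_rows.append({"gene": gene, "method": "MR Egger",
                             "Q": report.q_egger[0], "Q_df": report.q_egger[1],
                             "Q_pval": report.q_egger[2]})
        sensitivity[gene] = report
        for est in estimates:
            result_rows.append({"gene": gene, **est.to_dict()})
        primaries[gene] = {"gene": gene, **primary.to_dict()}

    results = pd.DataFrame(result_rows)
    summary = pd.DataFrame(list(primaries.values()))
    if len(summary):
        summary["abs_beta"] = summary["beta"].abs()
        summary["fdr"] = bh_fdr(summary["pval"].to_numpy())
        fdr_of = dict(zip(summary["gene"], summary["fdr"]))
        results["fdr"] = [
            fdr_of[r["gene"]] if r["method"] in ("ivw", "wald_ratio") else np.nan
            for _, r in results.iterrows()
        ]
    heterogeneity = pd.DataFrame(het_rows, columns=["gene", "method", "Q", "Q_df", "Q_pval"])
    loo = (pd.concat(loo_frames, ignore_index=True)
           if loo_frames else pd.DataFrame())
    log = (pd.concat(log_frames, ignore_index=True)
           if log_frames else pd.DataFrame(columns=["snp", "action", "reason", "gene"]))
    return MRPanelResult(results=results, summary=summary,
                         heterogeneity=heterogeneity, loo=loo,
                         harmonization_log=log, sensitivity=sensitivity,
                         statuses=statuses)
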
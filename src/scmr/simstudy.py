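"""Simulation studies validating the pipeline on data with known truth.

Each function runs one self-contained study — estimator identities,
parameter recovery, null calibration, robustness to invalid instruments,
harmonization invariance, FCscore cluster recovery, and the QC oracle —
and returns a dict of summary quantities plus the problem size ``n``.
They are shared by the test suite and by ``scripts/acceptance.py``.

Directional-pleiotropy studies orient instruments to the
exposure-increasing allele (``gamma_sign="positive"``): with random signs,
orienting the regression flips the pleiotropy term for half the variants
and directional pleiotropy averages out, which is a property of the model,
not of any estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contribution import bulk_fold_change, fcscore, find_cluster_markers, proportion_fold_change
from .mr import HarmonizedInstrumentSet, ivw, run_mr_panel, wald_ratio
from .mr.estimators import (
    Z95,
    _cochran_q_core,
    _egger_core,
    _ivw_core,
    _ratio_weights,
    _weighted_median_point,
    mr_egger,
)
from .mr.panel import MRPanelConfig
from .qc import apply_qc_filter, compute_qc_metrics, default_qc_rules, log_normalize, mad_upper_bound
from .synthetic import MRSimConfig, SCSimConfig, simulate_bulk_counts, simulate_mr_study, simulate_sc_counts


def _merged_gene_arrays(config: MRSimConfig):
    """Simulate a study and yield (gene, theta, bx, sx, by, sy) per gene.

    Alleles are generated strand-consistent here (no flips), so the tables
    can be joined on variant id directly; the harmonization path has its
    own dedicated study.
    """
    exposure, outcome, truth = simulate_mr_study(config)
    merged = exposure.merge(outcome[["snp", "beta", "se"]], on="snp",
                            suffixes=("_exp", "_out"))
    theta = dict(zip(truth.genes["gene"], truth.genes["theta"]))
    for gene, grp in merged.groupby("gene", sort=True):
        yield (gene, theta[gene],
               grp["beta_exp"].to_numpy(), grp["se_exp"].to_numpy(),
               grp["beta_out"].to_numpy(), grp["se_out"].to_numpy())


# ---------------------------------------------------------------------------

def estimator_identities(n_instances: int = 100, seed: int = 0) -> dict:
    """Algebraic identities of the estimators on random instances.

    * fixed-effect IVW equals the inverse-variance-weighted mean of the
      Wald ratios;
    * IVW with a single instrument equals the Wald ratio;
    * Egger on an exact affine relation recovers slope and intercept.
    """
    rng = np.random.default_rng(seed)
    max_ivw_gap = 0.0
    for _ in range(n_instances):
        m = int(rng.integers(2, 30))
        bx = rng.normal(0.2, 0.1, m)
        bx[np.abs(bx) < 1e-3] = 0.05
        by = rng.normal(0.0, 0.05, m)
        sy = rng.uniform(0.005, 0.05, m)
        beta, _, _ = _ivw_core(bx, 0.01, by, sy, random_effects=False)
        ratios, weights = _ratio_weights(bx, by, sy)
        ref = float(np.sum(weights * ratios) / np.sum(weights))
        max_ivw_gap = max(max_ivw_gap, abs(beta - ref))

    h1 = HarmonizedInstrumentSet.from_arrays([0.5], [0.01], [0.1], [0.05])
    single_gap = abs(ivw(h1).beta - wald_ratio(h1).beta)

    h3 = HarmonizedInstrumentSet.from_arrays(
        [1.0, 2.0, 3.0], [0.01], [1.1, 2.1, 3.1], [0.05])
    slope, intercept = mr_egger(h3)
    return {
        "ivw_identity_max_gap": max_ivw_gap,
        "single_snp_gap": single_gap,
        "egger_slope_error": abs(slope.beta - 1.0),
        "egger_intercept_error": abs(intercept.beta - 0.1),
        "n": n_instances,
    }


def parameter_recovery(n_genes: int = 500, m: int = 20,
                       theta_abs: float = 0.05, seed: int = 1) -> dict:
    """Bias and 95% CI coverage of random-effects IVW under strong,
    pleiotropy-free instruments with causal effects of +/- ``theta_abs``."""
    theta = np.where(np.arange(n_genes) % 2 == 0, theta_abs, -theta_abs)
    config = MRSimConfig(n_genes=n_genes, m_instruments=m, theta=theta,
                         p_palindromic=0.0, p_strand_flip=0.0, seed=seed)
    bias, covered = [], []
    for gene, th, bx, sx, by, sy in _merged_gene_arrays(config):
        beta, se, _ = _ivw_core(bx, sx, by, sy, random_effects=True)
        bias.append(beta - th)
        covered.append(abs(beta - th) <= Z95 * se)
    return {
        "mean_bias": float(np.mean(bias)),
        "coverage": float(np.mean(covered)),
        "n": n_genes,
    }


def calibration(n_reps: int = 2000, m: int = 20, seed: int = 2) -> dict:
    """Type-I error of IVW and the Egger-intercept test, and Cochran's Q
    calibration, under the global null (theta = 0, no pleiotropy)."""
    config = MRSimConfig(n_genes=n_reps, m_instruments=m, theta=0.0,
                         p_palindromic=0.0, p_strand_flip=0.0, seed=seed)
    ivw_p, egger_int_p, q_over_df = [], [], []
    for gene, th, bx, sx, by, sy in _merged_gene_arrays(config):
        beta, se, _ = _ivw_core(bx, sx, by, sy, random_effects=True)
        ivw_p.append(2.0 * sps.norm.sf(abs(beta / se)))
        _, _, inter, se_i, df = _egger_core(bx, by, sy, random_effects=True)
        egger_int_p.append(2.0 * sps.t.sf(abs(inter / se_i), df))
        q, qdf, _ = _cochran_q_core(bx, by, sy, "ivw")
        q_over_df.append(q / qdf)
    return {
        "ivw_type1_error": float(np.mean(np.asarray(ivw_p) < 0.05)),
        "egger_intercept_type1_error": float(np.mean(np.asarray(egger_int_p) < 0.05)),
        "q_mean_over_df": float(np.mean(q_over_df)),
        "n": n_reps,
    }


def robustness_ordering(n_reps: int = 500, m: int = 20,
                        theta: float = 0.05, invalid_frac: float = 0.4,
                        pleiotropy_mean: float = 0.03, seed: int = 3) -> dict:
    """Weighted-median vs IVW bias when 40% of instruments carry
    directional pleiotropy (instruments oriented exposure-increasing).

    The outcome standard error is set to the large-GWAS regime (2e-3):
    the weighted median's resistance to invalid instruments is a
    small-noise consistency property — the valid ratios must concentrate
    near the truth for the median to sit among them.
    """
    config = MRSimConfig(n_genes=n_reps, m_instruments=m, theta=theta,
                         gamma_sign="positive", se_outcome=0.002,
                         pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=0.005,
                         pleiotropy_frac=invalid_frac,
                         p_palindromic=0.0, p_strand_flip=0.0, seed=seed)
    ivw_est, wm_est = [], []
    for gene, th, bx, sx, by, sy in _merged_gene_arrays(config):
        beta, _, _ = _ivw_core(bx, sx, by, sy)
        ivw_est.append(beta)
        ratios, weights = _ratio_weights(bx, by, sy)
        wm_est.append(_weighted_median_point(ratios, weights))
    ivw_bias = abs(float(np.mean(ivw_est)) - theta)
    wm_bias = abs(float(np.mean(wm_est)) - theta)
    return {
        "ivw_abs_bias": ivw_bias,
        "weighted_median_abs_bias": wm_bias,
        "bias_ratio": wm_bias / ivw_bias if ivw_bias > 0 else np.inf,
        "n": n_reps,
    }


def egger_pleiotropy_recovery(n_reps: int = 1000, m: int = 20,
                              alpha_mean: float = 0.05, seed: int = 4) -> dict:
    """Mean Egger intercept under directional pleiotropy on every
    instrument (oriented exposure-increasing); consistent for the mean
    pleiotropic effect under InSIDE."""
    config = MRSimConfig(n_genes=n_reps, m_instruments=m, theta=0.05,
                         gamma_sign="positive",
                         pleiotropy_mean=alpha_mean, pleiotropy_sd=0.01,
                         pleiotropy_frac=1.0,
                         p_palindromic=0.0, p_strand_flip=0.0, seed=seed)
    intercepts = []
    for gene, th, bx, sx, by, sy in _merged_gene_arrays(config):
        _, _, inter, _, _ = _egger_core(bx, by, sy)
        intercepts.append(inter)
    return {"mean_intercept": float(np.mean(intercepts)), "n": n_reps}


def harmonization_invariance(seed: int = 5) -> dict:
    """Strand-complementing outcome alleles must change no estimate.

    Two studies identical except for the strand-flip flags are run through
    the full panel; the maximum absolute difference across every
    (gene, method) estimate is reported, along with the count of ambiguous
    palindromic variants dropped (which must all be logged).
    """
    base = dict(n_genes=5, m_instruments=10, theta=0.05,
                p_palindromic=0.3, maf_range=(0.05, 0.45), seed=seed)
    results = {}
    logs = {}
    for label, flip in (("flipped", 0.5), ("plain", 0.0)):
        exposure, outcome, truth = simulate_mr_study(
            MRSimConfig(**base, p_strand_flip=flip))
        cfg = MRPanelConfig(n_boot=200, seed=seed)
        res = run_mr_panel(exposure, outcome, cfg)
        results[label] = res.results.set_index(["gene", "method"])["beta"]
        logs[label] = res.harmonization_log
    joined = pd.concat([results["flipped"].rename("a"),
                        results["plain"].rename("b")], axis=1)
    max_shift = float((joined["a"] - joined["b"]).abs().max())

    # deterministic palindromic-ambiguity check: three A/T / C/G variants
    # with eaf inside (0.42, 0.58) must be dropped and logged
    from .mr import harmonize
    amb = pd.DataFrame({
        "snp": ["rsP1", "rsP2", "rsP3", "rsOK"],
        "effect_allele": ["A", "C", "T", "A"],
        "other_allele": ["T", "G", "A", "G"],
        "eaf": [0.50, 0.45, 0.57, 0.30],
        "beta": [0.2, 0.2, 0.2, 0.2],
        "se": [0.05, 0.05, 0.05, 0.05],
    })
    out_amb = amb.assign(beta=0.01)
    h = harmonize(amb, out_amb)
    dropped = set(h.log.loc[h.log["reason"] == "palindromic_ambiguous", "snp"])
    return {
        "max_estimate_shift": max_shift,
        "n_palindromic_dropped": len(dropped),
        "palindromic_drop_correct": float(dropped == {"rsP1", "rsP2", "rsP3"}
                                          and h.nsnp == 1),
        "n": int(len(joined)),
    }


def fcscore_recovery(n_reps: int = 100, seed: int = 6) -> dict:
    """Fraction of replicates in which the planted cluster (FCprop = 2,
    marker FCexp = 4 by construction) ranks first by mean FCscore."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    hits = 0
    for rep_seed in child_seeds:
        config = SCSimConfig(n_cells_per_group=200, n_genes=120,
                             n_clusters=3, markers_per_cluster=8,
                             marker_logfc=2.0, proportion_shift=2.0,
                             shifted_cluster=0, bulk_marker_fc=4.0,
                             mito_fraction_outliers=0, seed=int(rep_seed))
        data, meta, truth = simulate_sc_counts(config)
        norm = log_normalize(data.matrix)
        markers = find_cluster_markers(norm, data.genes,
                                       meta["cluster"].to_numpy())
        bulk, labels = simulate_bulk_counts(config, 30)
        fcexp = bulk_fold_change(bulk, labels, markers["gene"].unique())
        fcprop = proportion_fold_change(meta)
        res = fcscore(markers, fcexp, fcprop)
        if res.clusters.iloc[0]["cluster"] == "C0":
            hits += 1
    return {"recovery_fraction": hits / n_reps, "n": n_reps}


def qc_oracle(seed: int = 7) -> dict:
    """The hand-computable MAD bound plus planted-outlier removal on
    synthetic single-cell data at the default 3-MAD rules."""
    values = list(range(1, 10)) + [100]
    bound = mad_upper_bound(values, n_mads=3, scale_constant=1.0)
    n_above = int(np.sum(np.asarray(values) > bound))

    config = SCSimConfig(n_cells_per_group=300, mito_fraction_outliers=8,
                         seed=seed)
    data, meta, _ = simulate_sc_counts(config)
    metrics = compute_qc_metrics(data)
    result = apply_qc_filter(metrics, default_qc_rules())
    kept = set(result.kept)
    outliers = set(meta.loc[meta["planted_outlier"], "barcode"])
    normal = set(meta["barcode"]) - outliers
    return {
        "mad_bound": float(bound),
        "n_values_above_bound": n_above,
        "outliers_removed_fraction": 1.0 - len(kept & outliers) / len(outliers),
        "non_outliers_kept_fraction": len(kept & normal) / len(normal),
        "n": len(meta),
    }
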
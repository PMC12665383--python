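"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Two generators are provided:

* :func:`simulate_mr_study` draws GWAS/eQTL-style summary statistics from a
  linear instrumental-variable model.  Per gene ``g`` with causal effect
  ``theta_g`` and instruments ``j``: the true instrument-exposure effect is
  ``gamma_j`` (uniform over ``gamma_range``), the true instrument-outcome
  effect is ``theta_g * gamma_j + alpha_j`` where ``alpha_j`` is a
  pleiotropic direct effect, and observed effects are the truths plus
  Gaussian estimation noise at the configured standard-error scales.
  Allele coding, palindromic variants, and strand flips are drawn so that
  every harmonization branch is exercised.

* :func:`simulate_sc_counts` / :func:`simulate_bulk_counts` draw
  negative-binomial gene-by-cell (and gene-by-sample) count matrices with
  planted clusters, cluster marker genes, a case/control abundance shift for
  one cluster, and planted high-mitochondrial QC outlier cells.

All generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

from .errors import ConfigurationError

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))

SUMMARY_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]


@dataclass
class MRSimConfig:
    """Conditions for one simulated two-sample MR study.

    ``theta`` may be a scalar (shared causal effect) or a length-``n_genes``
    sequence.  ``gamma_sign`` controls the sign convention of the true
    instrument-exposure effects: ``"random"`` assigns each a random sign,
    ``"positive"`` orients every instrument to the exposure-increasing
    allele (the convention needed for directional pleiotropy to be
    directional after orientation).  ``pleiotropy_frac`` is the fraction of
    instruments per gene that receive a pleiotropic direct effect.
    ``m_outcome_instruments`` adds outcome-specific loci (direct outcome
    effects, null exposure effects) so the reverse analysis has instruments
    of its own.
    """

    n_genes: int = 1
    m_instruments: int = 20
    theta: float | Sequence[float] = 0.05
    gamma_range: tuple[float, float] = (0.1, 0.3)
    gamma_sign: str = "random"
    se_exposure: float = 0.01
    se_outcome: float = 0.005
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.45)
    p_palindromic: float = 0.1
    p_strand_flip: float = 0.0
    m_outcome_instruments: int = 0
    n_exposure: int = 31684
    n_outcome: int = 484598
    seed: int = 20250101

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.m_instruments < 1:
            raise ConfigurationError("m_instruments must be >= 1")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ConfigurationError("standard-error scales must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5)")
        if self.gamma_sign not in ("random", "positive", "negative"):
            raise ConfigurationError("gamma_sign must be random|positive|negative")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ConfigurationError("pleiotropy_frac must lie in [0, 1]")
        for p in (self.p_palindromic, self.p_strand_flip):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")

    def theta_per_gene(self) -> np.ndarray:
        theta = np.broadcast_to(np.asarray(self.theta, dtype=float), (self.n_genes,))
        return np.array(theta, dtype=float)


@dataclass
class SCSimConfig:
    """Conditions for the synthetic single-cell (and matched bulk) study.

    One cluster (``shifted_cluster``) is planted with a case/control
    abundance ratio of ``proportion_shift`` exactly: case proportions are
    ``q_j = shift * p_j`` for the shifted cluster with the remaining mass
    spread over the other clusters.  Each cluster receives
    ``markers_per_cluster`` marker genes up-shifted by ``marker_logfc``
    (log2) within the cluster; the shifted cluster's markers additionally
    carry a ``bulk_marker_fc`` case/control ratio in the bulk generator.
    """

    n_cells_per_group: int = 300
    n_clusters: int = 3
    n_genes: int = 500
    markers_per_cluster: int = 10
    marker_logfc: float = 2.0
    proportion_shift: float = 2.0
    shifted_cluster: int = 0
    bulk_marker_fc: float = 4.0
    nb_dispersion: float = 0.05
    n_mito_genes: int = 13
    n_ribo_genes: int = 10
    mito_fraction_outliers: int = 5
    seed: int = 20250101

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if self.n_clusters > self.n_cells_per_group:
            raise ConfigurationError("n_clusters must not exceed n_cells_per_group")
        if not 0 <= self.shifted_cluster < self.n_clusters:
            raise ConfigurationError("shifted_cluster out of range")
        if self.proportion_shift <= 0:
            raise ConfigurationError("proportion_shift must be > 0")
        if self.proportion_shift >= self.n_clusters:
            raise ConfigurationError(
                "proportion_shift * (1/n_clusters) must leave mass for other clusters"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        n_special = self.n_mito_genes + self.n_ribo_genes
        if self.n_genes < n_special + self.n_clusters * self.markers_per_cluster:
            raise ConfigurationError("n_genes too small for markers + mito/ribo genes")


@dataclass
class TruthTable:
    """Ground truth keyed one-to-one to the generated records."""

    genes: Optional[pd.DataFrame] = None      # gene, theta
    variants: Optional[pd.DataFrame] = None   # snp, gene, gamma, alpha, strand_flipped
    clusters: Optional[pd.DataFrame] = None   # cluster, prop_control, prop_case,
                                              # prop_ratio, markers (comma list)


@dataclass
class CountsData:
    """A gene-by-cell (or gene-by-sample) count matrix with names."""

    matrix: sparse.csr_matrix
    genes: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)

    def toarray(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def _draw_alleles(rng: np.random.Generator, n: int, p_palindromic: float):
    """Effect/other allele pairs; palindromic = A/T or C/G."""
    bases = np.array(["A", "C", "G", "T"])
    ea = np.empty(n, dtype="<U1")
    oa = np.empty(n, dtype="<U1")
    is_pal = rng.random(n) < p_palindromic
    pair_idx = rng.integers(0, len(PALINDROMIC_PAIRS), n)
    ea_idx = rng.integers(0, 4, n)
    for i in range(n):
        if is_pal[i]:
            ea[i], oa[i] = PALINDROMIC_PAIRS[pair_idx[i]]
        else:
            a = bases[ea_idx[i]]
            choices = [b for b in bases if b != a and b != COMPLEMENT[a]]
            oa[i] = choices[rng.integers(0, len(choices))]
            ea[i] = a
    return ea, oa, is_pal


def simulate_mr_study(config: MRSimConfig):
    """Simulate exposure and outcome summary-statistic tables plus truth.

    Returns ``(exposure, outcome, truth)``.  The exposure table has one row
    per (gene, variant); the outcome table has one row per variant.  Outcome
    rows are reported on the opposite strand (both alleles complemented,
    signed beta unchanged) with probability ``p_strand_flip``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rng_eff, rng_alleles, rng_flip = rng.spawn(3)

    g, m = config.n_genes, config.m_instruments
    n_eqtl = g * m
    theta = config.theta_per_gene()
    theta_per_variant = np.repeat(theta, m)

    gamma = rng_eff.uniform(*config.gamma_range, n_eqtl)
    if config.gamma_sign == "random":
        gamma *= rng_eff.choice([-1.0, 1.0], n_eqtl)
    elif config.gamma_sign == "negative":
        gamma = -gamma
    alpha = np.zeros(n_eqtl)
    has_pleio = rng_eff.random(n_eqtl) < config.pleiotropy_frac
    if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0:
        alpha[has_pleio] = rng_eff.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, int(has_pleio.sum())
        )
    gamma_hat = gamma + rng_eff.normal(0.0, config.se_exposure, n_eqtl)
    big_gamma = theta_per_variant * gamma + alpha
    big_gamma_hat = big_gamma + rng_eff.normal(0.0, config.se_outcome, n_eqtl)

    # outcome-specific loci: direct outcome effects, null exposure effects
    m_out = config.m_outcome_instruments
    out_gamma = rng_eff.uniform(*config.gamma_range, m_out)
    if m_out:
        out_gamma *= rng_eff.choice([-1.0, 1.0], m_out)
    out_beta_hat = out_gamma + rng_eff.normal(0.0, config.se_outcome, max(m_out, 0))
    # observed (null) exposure effect of each outcome locus on each gene
    null_exp_hat = rng_eff.normal(0.0, config.se_exposure, (g, m_out))

    n_var = n_eqtl + m_out
    maf = rng_alleles.uniform(*config.maf_range, n_var)
    eaf = np.where(rng_alleles.random(n_var) < 0.5, maf, 1.0 - maf)
    ea, oa, is_pal = _draw_alleles(rng_alleles, n_var, config.p_palindromic)
    flipped = rng_flip.random(n_var) < config.p_strand_flip

    snp = np.array([f"rs{i + 1:06d}" for i in range(n_var)])
    gene_ids = np.array([f"G{i + 1:03d}" for i in range(g)])
    gene_of_eqtl = np.repeat(gene_ids, m)
    # spread genes across chromosomes, instruments 100 kb apart
    chrom = np.empty(n_var, dtype=int)
    pos = np.empty(n_var, dtype=int)
    for i in range(g):
        sl = slice(i * m, (i + 1) * m)
        chrom[sl] = (i % 22) + 1
        pos[sl] = 1 + (i // 22) * 50_000_000 + np.arange(m) * 100_000
    for j in range(m_out):
        k = n_eqtl + j
        chrom[k] = (j % 22) + 1
        pos[k] = 2_000_000_000 + j * 100_000

    sf = sps.norm.sf

    def pvals(beta, se):
        return np.maximum(2.0 * sf(np.abs(beta) / se), np.finfo(float).tiny)

    # exposure table: eQTL rows + null rows for each (gene, outcome locus)
    exp_rows = {
        "gene": np.concatenate([gene_of_eqtl, np.repeat(gene_ids, m_out)]),
        "snp": np.concatenate([snp[:n_eqtl], np.tile(snp[n_eqtl:], g)]),
        "chr": np.concatenate([chrom[:n_eqtl], np.tile(chrom[n_eqtl:], g)]),
        "pos": np.concatenate([pos[:n_eqtl], np.tile(pos[n_eqtl:], g)]),
        "effect_allele": np.concatenate([ea[:n_eqtl], np.tile(ea[n_eqtl:], g)]),
        "other_allele": np.concatenate([oa[:n_eqtl], np.tile(oa[n_eqtl:], g)]),
        "eaf": np.concatenate([eaf[:n_eqtl], np.tile(eaf[n_eqtl:], g)]),
        "beta": np.concatenate([gamma_hat, null_exp_hat.ravel()]),
        "se": np.full(n_eqtl + g * m_out, config.se_exposure),
    }
    exposure = pd.DataFrame(exp_rows)
    exposure["pval"] = pvals(exposure["beta"].to_numpy(), exposure["se"].to_numpy())
    exposure["n"] = config.n_exposure

    out_ea = np.array([COMPLEMENT[a] if f else a for a, f in zip(ea, flipped)])
    out_oa = np.array([COMPLEMENT[a] if f else a for a, f in zip(oa, flipped)])
    out_beta = np.concatenate([big_gamma_hat, out_beta_hat])
    outcome = pd.DataFrame({
        "snp": snp,
        "chr": chrom,
        "pos": pos,
        "effect_allele": out_ea,
        "other_allele": out_oa,
        "eaf": eaf,
        "beta": out_beta,
        "se": np.full(n_var, config.se_outcome),
    })
    outcome["pval"] = pvals(outcome["beta"].to_numpy(), outcome["se"].to_numpy())
    outcome["n"] = config.n_outcome

    truth = TruthTable(
        genes=pd.DataFrame({"gene": gene_ids, "theta": theta}),
        variants=pd.DataFrame({
            "snp": snp,
            "gene": np.concatenate([gene_of_eqtl, np.full(m_out, "outcome")]),
            "gamma": np.concatenate([gamma, np.zeros(m_out)]),
            "alpha": np.concatenate([alpha, out_gamma]),
            "palindromic": is_pal,
            "strand_flipped": flipped,
        }),
    )
    return exposure, outcome, truth


def simulate_ld_matrix(m: int, block_size: int, within_block_r2: float,
                       seed: int = 0) -> np.ndarray:
    """Block-diagonal r-squared matrix: unit diagonal, ``within_block_r2``
    inside each block of ``block_size`` consecutive variants, zero across
    blocks."""
    if m < 1 or block_size < 1:
        raise ConfigurationError("m and block_size must be >= 1")
    if not 0.0 <= within_block_r2 <= 1.0:
        raise ConfigurationError("within_block_r2 must lie in [0, 1]")
    ld = np.zeros((m, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        ld[start:stop, start:stop] = within_block_r2
    np.fill_diagonal(ld, 1.0)
    return ld


def _gene_names(config: SCSimConfig) -> list[str]:
    names = [f"MT-G{i + 1}" for i in range(config.n_mito_genes)]
    half = config.n_ribo_genes // 2
    names += [f"RPS{i + 1}" for i in range(half)]
    names += [f"RPL{i + 1}" for i in range(config.n_ribo_genes - half)]
    n_rest = config.n_genes - len(names)
    names += [f"GENE{i + 1:04d}" for i in range(n_rest)]
    return names


def _cluster_proportions(config: SCSimConfig):
    k = config.n_clusters
    p_ctrl = np.full(k, 1.0 / k)
    p_case = p_ctrl.copy()
    if k > 1:
        j = config.shifted_cluster
        p_case[j] = config.proportion_shift * p_ctrl[j]
        rest = [i for i in range(k) if i != j]
        p_case[rest] = (1.0 - p_case[j]) * p_ctrl[rest] / p_ctrl[rest].sum()
    return p_ctrl, p_case


def _marker_assignment(config: SCSimConfig) -> dict[int, list[int]]:
    offset = config.n_mito_genes + config.n_ribo_genes
    out = {}
    for c in range(config.n_clusters):
        start = offset + c * config.markers_per_cluster
        out[c] = list(range(start, start + config.markers_per_cluster))
    return out


def simulate_sc_counts(config: SCSimConfig):
    """Simulate a gene-by-cell NB count matrix with planted structure.

    Returns ``(CountsData, metadata, truth)``.  Metadata columns: barcode,
    group (case/control), cluster, planted_outlier.  Planted outlier cells
    have their mitochondrial counts set to three times their non-mito total,
    i.e. percent_mt = 75, far above any 3-MAD bound computed from the
    remaining cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    n_genes = config.n_genes
    n_per = config.n_cells_per_group
    p_ctrl, p_case = _cluster_proportions(config)
    markers = _marker_assignment(config)

    base_mean = rng.uniform(2.0, 6.0, n_genes)
    clusters = np.concatenate([
        rng.choice(config.n_clusters, n_per, p=p_ctrl),
        rng.choice(config.n_clusters, n_per, p=p_case),
    ])
    groups = np.array(["control"] * n_per + ["case"] * n_per)
    n_cells = 2 * n_per

    mu = np.tile(base_mean[:, None], (1, n_cells))
    fc = 2.0 ** config.marker_logfc
    for c, gene_idx in markers.items():
        cell_mask = clusters == c
        mu[np.ix_(gene_idx, cell_mask)] *= fc

    size = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)

    outlier_idx = np.array([], dtype=int)
    if config.mito_fraction_outliers > 0:
        outlier_idx = rng.choice(n_cells, config.mito_fraction_outliers, replace=False)
        n_mito = config.n_mito_genes
        for i in outlier_idx:
            non_mito_total = counts[n_mito:, i].sum()
            per_gene = max(int(np.ceil(3.0 * non_mito_total / max(n_mito, 1))), 1)
            counts[:n_mito, i] = per_gene

    barcodes = [f"CELL{i + 1:05d}" for i in range(n_cells)]
    metadata = pd.DataFrame({
        "barcode": barcodes,
        "group": groups,
        "cluster": [f"C{c}" for c in clusters],
        "planted_outlier": np.isin(np.arange(n_cells), outlier_idx),
    })
    truth = TruthTable(clusters=pd.DataFrame({
        "cluster": [f"C{c}" for c in range(config.n_clusters)],
        "prop_control": p_ctrl,
        "prop_case": p_case,
        "prop_ratio": p_case / p_ctrl,
        "markers": [",".join(genes[i] for i in markers[c])
                    for c in range(config.n_clusters)],
    }))
    data = CountsData(sparse.csr_matrix(counts), genes, barcodes)
    return data, metadata, truth


def simulate_bulk_counts(config: SCSimConfig, n_samples_per_group: int = 50):
    """Simulate a bulk gene-by-sample expression table with group labels.

    The shifted cluster's marker genes have a case/control mean ratio of
    ``bulk_marker_fc`` in expectation; every other gene has ratio 1.
    Returns ``(DataFrame genes x samples, Series sample -> group)``.
    """
    config.validate()
    if n_samples_per_group < 2:
        raise ConfigurationError("n_samples_per_group must be >= 2")
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_names(config)
    base_mean = rng.uniform(20.0, 100.0, config.n_genes)
    marker_idx = _marker_assignment(config)[config.shifted_cluster]

    mean_ctrl = base_mean
    mean_case = base_mean.copy()
    mean_case[marker_idx] *= config.bulk_marker_fc

    size = 1.0 / 0.02  # mild biological overdispersion for bulk samples
    ctrl = rng.negative_binomial(size, size / (size + mean_ctrl[:, None]),
                                 (config.n_genes, n_samples_per_group))
    case = rng.negative_binomial(size, size / (size + mean_case[:, None]),
                                 (config.n_genes, n_samples_per_group))
    samples = ([f"CTRL{i + 1:03d}" for i in range(n_samples_per_group)]
               + [f"CASE{i + 1:03d}" for i in range(n_samples_per_group)])
    bulk = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=samples)
    labels = pd.Series(["control"] * n_samples_per_group
                       + ["case"] * n_samples_per_group, index=samples, name="group")
    return bulk, labels
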
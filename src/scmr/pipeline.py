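"""Run orchestration: configuration, stage sequencing, and the manifest.

``run_pipeline`` executes QC -> cluster contribution -> MR -> report in
order, writing every stage's outputs plus a JSON manifest with the config
hash, seed, and per-file checksums, so that a rerun with the same
configuration and inputs is verifiably identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contribution import bulk_fold_change, fcscore, find_cluster_markers, proportion_fold_change
from .errors import ConfigurationError, InputError
from .io import (
    read_bulk,
    read_counts,
    read_labels,
    read_ld_matrix,
    read_summary_stats,
    write_counts,
    write_labels,
    write_summary_stats,
)
from .mr import MRPanelConfig, run_mr_panel, run_reverse_panel
from .qc import apply_qc_filter, compute_qc_metrics, default_qc_rules, find_variable_genes, log_normalize
from .synthetic import (
    CountsData,
    MRSimConfig,
    SCSimConfig,
    simulate_bulk_counts,
    simulate_mr_study,
    simulate_sc_counts,
)

_ALLOWED_KEYS = {
    "": {"seed", "output_dir", "stages", "inputs", "simulate", "qc",
         "contribution", "mr"},
    "stages": {"simulate", "qc", "contribution", "mr"},
    "inputs": {"counts", "clusters", "groups", "bulk", "bulk_groups",
               "exposure", "outcome", "ld", "genes"},
    "simulate": {"mr", "sc", "bulk_samples_per_group"},
    "qc": {"n_mads", "scale_constant", "min_features", "normalize_scale",
           "n_hvgs", "mito_pattern", "ribo_pattern"},
    "contribution": {"logfc_min", "padj_max", "eps"},
    "mr": {"p_threshold", "r2_max", "window_kb", "n_boot", "reverse",
           "palindrome_low", "palindrome_high"},
}


@dataclass
class RunConfig:
    """Whole-run configuration; serializes to/from one YAML document."""

    seed: int = 20250101
    output_dir: str = "scmr_out"
    stages: dict = field(default_factory=lambda: {
        "simulate": False, "qc": True, "contribution": True, "mr": True})
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    contribution: dict = field(default_factory=dict)
    mr: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_KEYS[""]
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for section in ("stages", "inputs", "simulate", "qc", "contribution", "mr"):
            sub = raw.get(section) or {}
            if not isinstance(sub, dict):
                raise ConfigurationError(f"config section {section!r} must be a mapping")
            bad = set(sub) - _ALLOWED_KEYS[section]
            if bad:
                raise ConfigurationError(
                    f"unknown key(s) in {section!r}: {sorted(bad)}")
        cfg = cls(seed=int(raw.get("seed", 20250101)),
                  output_dir=str(raw.get("output_dir", "scmr_out")))
        cfg.stages.update(raw.get("stages") or {})
        cfg.inputs = dict(raw.get("inputs") or {})
        cfg.simulate = dict(raw.get("simulate") or {})
        cfg.qc = dict(raw.get("qc") or {})
        cfg.contribution = dict(raw.get("contribution") or {})
        cfg.mr = dict(raw.get("mr") or {})
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)

    def record(self, name: str, outputs: dict, started: float) -> None:
        self.stages.append({
            "stage": name,
            "outputs": outputs,
            "started": started,
            "finished": time.time(),
        })

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksums(paths) -> dict:
    return {p.name: _sha256(p) for p in paths}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and return the manifest.

    Any stage error aborts the run; the manifest (recording the stages that
    completed) is written before the exception propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        seed=config.seed,
    )
    inputs = dict(config.inputs)
    try:
        if config.stages.get("simulate"):
            _stage_simulate(config, out, manifest, inputs)
        norm = genes = None
        if config.stages.get("qc"):
            norm, genes, kept = _stage_qc(config, out, manifest, inputs)
        gene_list = None
        if config.stages.get("contribution"):
            gene_list = _stage_contribution(config, out, manifest, inputs, norm, genes)
        if config.stages.get("mr"):
            _stage_mr(config, out, manifest, inputs, gene_list)
        _stage_report(out, manifest)
    finally:
        manifest.write(out / "manifest.json")
    return manifest


def _stage_simulate(config, out, manifest, inputs):
    t0 = time.time()
    sim_dir = out / "simulated"
    sim_dir.mkdir(exist_ok=True)
    mr_cfg = MRSimConfig(**config.simulate.get("mr", {}), seed=config.seed)
    exposure, outcome, truth = simulate_mr_study(mr_cfg)
    write_summary_stats(exposure, sim_dir / "exposure.tsv")
    write_summary_stats(outcome, sim_dir / "outcome.tsv")
    truth.variants.to_csv(sim_dir / "truth_variants.tsv", sep="\t", index=False)
    truth.genes.to_csv(sim_dir / "truth_genes.tsv", sep="\t", index=False)

    sc_cfg = SCSimConfig(**config.simulate.get("sc", {}), seed=config.seed)
    data, meta, sc_truth = simulate_sc_counts(sc_cfg)
    write_counts(data, sim_dir / "counts")
    meta.to_csv(sim_dir / "cell_metadata.tsv", sep="\t", index=False)
    sc_truth.clusters.to_csv(sim_dir / "truth_clusters.tsv", sep="\t", index=False)
    bulk, labels = simulate_bulk_counts(
        sc_cfg, config.simulate.get("bulk_samples_per_group", 50))
    bulk.to_csv(sim_dir / "bulk.tsv", sep="\t")
    write_labels(labels, sim_dir / "bulk_groups.tsv", "sample", "group")

    inputs.setdefault("counts", str(sim_dir / "counts"))
    inputs.setdefault("clusters", str(sim_dir / "cell_metadata.tsv"))
    inputs.setdefault("groups", str(sim_dir / "cell_metadata.tsv"))
    inputs.setdefault("bulk", str(sim_dir / "bulk.tsv"))
    inputs.setdefault("bulk_groups", str(sim_dir / "bulk_groups.tsv"))
    inputs.setdefault("exposure", str(sim_dir / "exposure.tsv"))
    inputs.setdefault("outcome", str(sim_dir / "outcome.tsv"))
    manifest.record("simulate", _checksums(sim_dir.glob("*.tsv")), t0)


def _load_cell_metadata(inputs) -> pd.DataFrame:
    path = inputs.get("clusters") or inputs.get("groups")
    if path is None:
        raise InputError("cell metadata (clusters/groups) input is required")
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "barcode"})
    return meta


def _stage_qc(config, out, manifest, inputs):
    t0 = time.time()
    if "counts" not in inputs:
        raise InputError("qc stage requires a counts input")
    data = read_counts(inputs["counts"])
    qc_opts = dict(config.qc)
    metrics = compute_qc_metrics(
        data,
        mito_pattern=qc_opts.get("mito_pattern", r"(?i)^MT-"),
        ribo_pattern=qc_opts.get("ribo_pattern", r"(?i)^RP[SL]"))
    rules = default_qc_rules(
        min_features=qc_opts.get("min_features", 200),
        n_mads=qc_opts.get("n_mads", 3.0),
        scale_constant=qc_opts.get("scale_constant", 1.4826))
    result = apply_qc_filter(metrics, rules)
    kept = result.kept
    (out / "kept_barcodes.txt").write_text("\n".join(kept) + "\n")
    result.report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    (out / "qc_thresholds.yaml").write_text(yaml.safe_dump({
        m: {"lower": None if lo is None else float(lo),
            "upper": None if up is None else float(up)}
        for m, (lo, up) in result.thresholds.items()}))

    col_idx = [data.barcodes.index(b) for b in kept]
    filtered = CountsData(data.matrix[:, col_idx], data.genes, kept)
    norm = log_normalize(filtered.matrix, qc_opts.get("normalize_scale", 10_000.0))
    n_hvgs = min(int(qc_opts.get("n_hvgs", 2000)), len(data.genes))
    hvgs = find_variable_genes(norm, data.genes, n_hvgs)
    (out / "hvgs.txt").write_text("\n".join(hvgs) + "\n")
    manifest.record("qc", _checksums([
        out / "kept_barcodes.txt", out / "qc_report.tsv",
        out / "qc_thresholds.yaml", out / "hvgs.txt"]), t0)
    return norm, data.genes, kept


def _stage_contribution(config, out, manifest, inputs, norm, genes):
    t0 = time.time()
    meta = _load_cell_metadata(inputs)
    if norm is None:
        if "counts" not in inputs:
            raise InputError("contribution stage requires counts (or the qc stage)")
        data = read_counts(inputs["counts"])
        norm = log_normalize(data.matrix)
        genes = data.genes
        kept = data.barcodes
    else:
        kept = (out / "kept_barcodes.txt").read_text().split()
    meta = meta[meta["barcode"].isin(kept)].reset_index(drop=True)
    order = {b: i for i, b in enumerate(kept)}
    meta = meta.sort_values("barcode", key=lambda s: s.map(order))
    col_idx = [order[b] for b in meta["barcode"]]
    norm_kept = norm[:, col_idx]

    opts = dict(config.contribution)
    markers = find_cluster_markers(
        norm_kept, genes, meta["cluster"].to_numpy(),
        logfc_min=opts.get("logfc_min", 0.585),
        padj_max=opts.get("padj_max", 0.05))
    markers.to_csv(out / "markers.tsv", sep="\t", index=False)

    if "bulk" not in inputs:
        raise InputError("contribution stage requires a bulk input")
    bulk = read_bulk(inputs["bulk"])
    if "bulk_groups" not in inputs:
        raise InputError("bulk group labels are required for the contribution stage")
    bulk_groups = read_labels(inputs["bulk_groups"], "group")
    fcexp = bulk_fold_change(bulk, bulk_groups, markers["gene"].unique(),
                             eps=opts.get("eps", 0.01))
    fcprop = proportion_fold_change(meta)
    contrib = fcscore(markers, fcexp, fcprop)
    table = contrib.clusters
    table.to_csv(out / "cluster_contribution.tsv", sep="\t", index=False)
    contrib.per_gene.to_csv(out / "fcscore_per_gene.tsv", sep="\t", index=False)
    manifest.record("contribution", _checksums([
        out / "markers.tsv", out / "cluster_contribution.tsv",
        out / "fcscore_per_gene.tsv"]), t0)
    top = table.iloc[0]["cluster"] if len(table) else None
    top_markers = markers.loc[markers["cluster"] == top, "gene"].tolist()
    return top_markers or None


def _stage_mr(config, out, manifest, inputs, gene_list):
    t0 = time.time()
    for req in ("exposure", "outcome"):
        if req not in inputs:
            raise InputError(f"mr stage requires an {req} input")
    exposure = read_summary_stats(inputs["exposure"])
    outcome = read_summary_stats(inputs["outcome"])
    if "gene" not in exposure.columns:
        raise InputError("exposure table must carry a 'gene' column")
    if gene_list:
        wanted = {g.upper() for g in gene_list}
        sub = exposure[exposure["gene"].str.upper().isin(wanted)]
        exposure = sub if len(sub) else exposure
    ld = read_ld_matrix(inputs["ld"]) if inputs.get("ld") else None
    opts = dict(config.mr)
    pw = (opts.get("palindrome_low", 0.42), opts.get("palindrome_high", 0.58))
    panel_cfg = MRPanelConfig(
        p_threshold=opts.get("p_threshold", 1e-8),
        r2_max=opts.get("r2_max", 0.001),
        window_kb=opts.get("window_kb", 10_000.0),
        palindrome_window=pw,
        n_boot=int(opts.get("n_boot", 1000)),
        seed=config.seed)
    if opts.get("reverse"):
        res = run_reverse_panel(exposure, outcome, panel_cfg, ld=ld)
    else:
        res = run_mr_panel(exposure, outcome, panel_cfg, ld=ld)
    res.results.to_csv(out / "mr_results.tsv", sep="\t", index=False)
    res.heterogeneity.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
    res.loo.to_csv(out / "loo.tsv", sep="\t", index=False)
    res.harmonization_log.to_csv(out / "harmonization_log.tsv", sep="\t", index=False)
    res.summary.to_csv(out / "mr_summary.tsv", sep="\t", index=False)
    manifest.record("mr", _checksums([
        out / "mr_results.tsv", out / "heterogeneity.tsv", out / "loo.tsv",
        out / "harmonization_log.tsv", out / "mr_summary.tsv"]), t0)


def _stage_report(out, manifest):
    t0 = time.time()
    parts = []
    for name in ("cluster_contribution.tsv", "mr_summary.tsv", "heterogeneity.tsv"):
        p = out / name
        if p.exists():
            parts.append(f"## {name}\n{p.read_text()}")
    report = out / "report.txt"
    report.write_text("\n".join(parts) if parts else "no stages produced output\n")
    manifest.record("report", _checksums([report]), t0)
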
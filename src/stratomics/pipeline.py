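"""End-to-end orchestration of the mutation-stratified multi-omics analysis.

Stage order: stratify the cohort on the mutation table and restrict to
samples with all three omics layers; differential expression on the mRNA
counts; differential methylation; miRNA differential expression; cross-layer
integration (miRNA targets, hyper-down genes, four-set Venn); enrichment of
each result gene set separately; co-expression networks (up-regulated, and
the hyper-down core of the down-regulated network).  Every intermediate is
serialized into the output directory with the configuration hash stamped in
its header, and the run report records every count, threshold and seed, so a
rerun with the same configuration reproduces the report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import enrichment as enr_mod
from . import integration as int_mod
from . import io as sio
from . import methylation as meth_mod
from . import network as net_mod
from .errors import ConfigError, InputError
from .stratify import require_matched_omics, stratify
from .types import CohortDesign

log = logging.getLogger("stratomics")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    maf: str
    mrna_counts: str
    mirna_counts: str
    beta: str
    probe_annotation: str
    targets: str
    gmt: str
    ppi: str
    tf_list: str
    outdir: str
    target_gene: str = "PBRM1"
    exclusion_genes: tuple[str, ...] = ("VHL", "BAP1", "SETD2", "PTEN", "KDM5C")
    lfc_thresh: float = 1.0
    p_de: float = 0.05
    delta_thresh: float = 0.15
    p_dm: float = 0.01
    padj_enrich: float = 0.05
    top_fraction: float = 0.05
    corr_mode: str = "absolute"
    min_degree: int = 3
    min_cpm: float = 1.0
    min_samples: int = 2
    per_group_filter: bool = False
    prior_cpm: float = 0.5
    n_perm: int = 1000
    restrict_targets_to_expressed: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ConfigError("top_fraction must be in (0, 1]")
        for name in ("p_de", "p_dm", "padj_enrich"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1]")
        if self.delta_thresh < 0 or self.delta_thresh > 1:
            raise ConfigError("delta_thresh must be in [0, 1]")
        if self.min_degree < 0:
            raise ConfigError("min_degree must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exclusion_genes" in raw:
            raw["exclusion_genes"] = tuple(raw["exclusion_genes"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def design(self) -> CohortDesign:
        return CohortDesign(
            target_gene=self.target_gene, exclusion_genes=tuple(self.exclusion_genes)
        )


@dataclass
class RunReport:
    """Per-stage counts and provenance for one run."""

    config_hash: str
    seed: int
    thresholds: dict
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "thresholds": self.thresholds,
            "stages": self.stages,
        }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


class _Stage:
    """Context manager that marks failures with the stage name."""

    def __init__(self, name: str, outdir: Path):
        self.name = name
        self.outdir = outdir

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            marker = self.outdir / "FAILED"
            marker.write_text(f"stage={self.name}\ncause={exc}\n")
            log.error("stage %s FAILED: %s", self.name, exc)
            raise type(exc)(f"stage {self.name!r}: {exc}") from exc
        log.info("stage %s: done", self.name)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``outdir/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"stratomics config_hash={chash}"
    report = RunReport(
        config_hash=chash,
        seed=config.seed,
        thresholds={
            "lfc_thresh": config.lfc_thresh,
            "p_de": config.p_de,
            "delta_thresh": config.delta_thresh,
            "p_dm": config.p_dm,
            "padj_enrich": config.padj_enrich,
            "top_fraction": config.top_fraction,
            "corr_mode": config.corr_mode,
            "min_degree": config.min_degree,
            "min_cpm": config.min_cpm,
            "min_samples": config.min_samples,
            "n_perm": config.n_perm,
        },
    )

    with _Stage("stratification", outdir):
        mutations = sio.read_maf(config.maf)
        mrna = sio.read_counts_tsv(config.mrna_counts)
        mirna = sio.read_counts_tsv(config.mirna_counts)
        beta = sio.read_beta_tsv(config.beta)
        anno = sio.read_probe_annotation(config.probe_annotation)

        cohort = stratify(mutations, config.design())
        cohort = require_matched_omics(
            cohort,
            {
                "rna": set(mrna.samples),
                "meth": set(beta.columns),
                "mirna": set(mirna.samples),
            },
        )
        if not cohort.case_ids or not cohort.control_ids:
            raise InputError(
                f"empty group after stratification "
                f"(cases={len(cohort.case_ids)}, controls={len(cohort.control_ids)})"
            )
        cases, controls = cohort.case_ids, cohort.control_ids
        reasons = pd.Series(cohort.excluded).value_counts().to_dict() if cohort.excluded else {}
        report.stages["stratification"] = {
            "n_input_samples": len(mutations.samples),
            "n_cases": len(cases),
            "n_controls": len(controls),
            "n_excluded": len(cohort.excluded),
            "excluded_reasons": {k: int(v) for k, v in sorted(reasons.items())},
        }
        sio.write_gene_list(cases, outdir / "case_ids.txt")
        sio.write_gene_list(controls, outdir / "control_ids.txt")

    with _Stage("mrna_de", outdir):
        mrna_sub = mrna.subset_samples(cases + controls)
        mrna_filt = de_mod.filter_low_expression(
            mrna_sub, config.min_cpm, config.min_samples,
            groups=(cases, controls) if config.per_group_filter else None,
        )
        if not len(mrna_filt.features):
            raise InputError("no mRNA features left after filtering")
        factors = de_mod.tmm_norm_factors(mrna_filt)
        phi = de_mod.estimate_common_dispersion(mrna_filt, (cases, controls), factors)
        de_table = de_mod.exact_test(
            mrna_filt, (cases, controls), phi, factors, config.prior_cpm
        )
        up_genes, down_genes = de_mod.call_de(de_table, config.lfc_thresh, config.p_de)
        tf_list = sio.read_gene_list(config.tf_list)
        tf_up, tf_down = de_mod.annotate_tfs(up_genes, down_genes, tf_list)
        expressed = set(mrna_filt.features)
        sio._write_tsv(de_table, outdir / "mrna_de.tsv", stamp)
        report.stages["mrna_de"] = {
            "n_features_input": int(len(mrna.features)),
            "n_features_filtered": int(len(mrna_filt.features)),
            "dispersion": float(phi),
            "n_up": len(up_genes),
            "n_down": len(down_genes),
            "n_tf_up": len(tf_up),
            "n_tf_down": len(tf_down),
        }

    with _Stage("methylation", outdir):
        beta_sub = beta[cases + controls]
        dm_table = meth_mod.dm_analysis(
            beta_sub, anno, cases, controls, n_perm=config.n_perm, seed=config.seed
        )
        hyper_probes, hypo_probes, hyper_genes, hypo_genes = meth_mod.call_dm(
            dm_table, anno, config.delta_thresh, config.p_dm
        )
        sio._write_tsv(dm_table, outdir / "methylation_dm.tsv", stamp)
        region_table = None
        if hyper_probes and hypo_probes:
            region_table = meth_mod.region_distribution_test(hyper_probes, hypo_probes, anno)
            sio._write_tsv(region_table, outdir / "region_distribution.tsv", stamp)
        report.stages["methylation"] = {
            "n_probes_input": int(beta.shape[0]),
            "n_probes_tested": int(len(dm_table)),
            "s0": float(dm_table.attrs["s0"]),
            "n_hyper_probes": len(hyper_probes),
            "n_hypo_probes": len(hypo_probes),
            "n_hyper_genes": len(hyper_genes),
            "n_hypo_genes": len(hypo_genes),
        }

    with _Stage("mirna_de", outdir):
        mirna_sub = mirna.subset_samples(cases + controls)
        mirna_table, up_mirnas, down_mirnas = de_mod.de_analysis(
            mirna_sub, cases, controls,
            min_cpm=config.min_cpm, min_samples=config.min_samples,
            per_group_filter=config.per_group_filter,
            lfc_thresh=config.lfc_thresh, p_thresh=config.p_de,
            prior_cpm=config.prior_cpm,
        )
        sio._write_tsv(mirna_table, outdir / "mirna_de.tsv", stamp)
        report.stages["mirna_de"] = {
            "n_features_input": int(len(mirna.features)),
            "n_features_tested": int(len(mirna_table)),
            "dispersion": float(mirna_table.attrs["dispersion"]),
            "n_up": len(up_mirnas),
            "n_down": len(down_mirnas),
        }

    with _Stage("integration", outdir):
        target_map = sio.read_target_map(config.targets)
        result = int_mod.integrate(
            up_genes,
            down_genes,
            sorted(up_mirnas),
            sorted(down_mirnas),
            hyper_genes,
            target_map,
            universe=expressed if config.restrict_targets_to_expressed else None,
        )
        sio._write_tsv(result.venn, outdir / "venn_counts.tsv", stamp, index=False)
        sio.write_gene_list(sorted(result.hyper_down_genes), outdir / "hyper_down_genes.txt")
        report.stages["integration"] = {
            **result.counts(),
            "venn": {
                row["region"]: int(row["count"]) for _, row in result.venn.iterrows()
            },
        }

    with _Stage("enrichment", outdir):
        catalog = sio.read_gmt(config.gmt).restricted(expressed)
        queries = {
            "up_genes": up_genes,
            "down_genes": down_genes,
            "hyper_genes": hyper_genes & expressed,
            "hypo_genes": hypo_genes & expressed,
            "mirna_targets": result.up_targets | result.down_targets,
        }
        enr_summary = {}
        for name, query in queries.items():
            if not (query & set(catalog.universe)):
                enr_summary[name] = {"n_terms_tested": 0, "n_retained": 0}
                continue
            table = enr_mod.enrich(query, catalog, config.padj_enrich)
            sio._write_tsv(table, outdir / f"enrichment_{name}.tsv", stamp, index=False)
            retained = table[table["retained"]]
            enr_summary[name] = {
                "n_terms_tested": int(len(table)),
                "n_retained": int(len(retained)),
                "top_term": str(table.iloc[0]["term_id"]) if len(table) else "",
                "top_padj": float(table.iloc[0]["padj"]) if len(table) else 1.0,
            }
        report.stages["enrichment"] = enr_summary

    with _Stage("network", outdir):
        ppi = sio.read_ppi(config.ppi)
        log_cpm = np.log2(de_mod.cpm(mrna_filt) + 1.0)
        background = net_mod.coexpression_analysis(
            log_cpm, cases, ppi, config.top_fraction, config.corr_mode
        )
        up_net = net_mod.project_subnetwork(
            background, up_genes, sorted(up_mirnas | down_mirnas), target_map, "up"
        )
        down_net = net_mod.project_subnetwork(
            background, down_genes, sorted(up_mirnas | down_mirnas), target_map, "down"
        )
        core = net_mod.core_network(down_net, result.hyper_down_genes)
        up_display = net_mod.filter_by_degree(up_net, config.min_degree)
        core_display = net_mod.filter_by_degree(core, config.min_degree)
        for name, g in [
            ("background", background),
            ("up_network", up_net),
            ("down_network", down_net),
            ("core_network", core),
            ("up_network_display", up_display),
            ("core_network_display", core_display),
        ]:
            edges, nodes = net_mod.network_tables(g)
            sio._write_tsv(edges, outdir / f"{name}_edges.tsv", stamp, index=False)
            sio._write_tsv(nodes, outdir / f"{name}_nodes.tsv", stamp, index=False)
        report.stages["network"] = {
            name: {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
            for name, g in [
                ("background", background),
                ("up_network", up_net),
                ("down_network", down_net),
                ("core_network", core),
                ("up_network_display", up_display),
                ("core_network_display", core_display),
            ]
        }

    payload = report.to_dict()
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonable)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return payload
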
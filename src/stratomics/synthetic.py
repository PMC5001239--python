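"""Synthetic multi-omics cohort with recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* a somatic-mutation table in which every case carries a truncating variant
  in the target gene, controls are pan-negative, and "other" samples carry a
  disqualifying variant (an exclusion-gene mutation or a non-truncating
  target variant) so stratification has something to exclude;
* negative-binomial count matrices (mRNA and miRNA) with per-sample library
  sizes and a common dispersion; planted features have their case-group mean
  multiplied by 2^(+-effect_log2fc);
* beta-distributed methylation values with planted case-group mean shifts,
  plus a 450K-style probe annotation (chromosome, gene, region label, SNP
  flag) — planted probes are always autosomal, gene-annotated and SNP-free so
  the standard probe filter cannot remove the signal;
* annotation resources: a miRNA target map, a gene-set catalog with one term
  enriched in the planted down-regulated genes, a random PPI with the planted
  co-expression module wired as a clique, and a transcription-factor list.

One global seed is expanded into fixed per-layer substreams, so adding or
regenerating a layer never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    GeneSetCatalog,
    GroundTruth,
    MutationTable,
    PROBE_REGIONS,
    SimulationConfig,
)

# Fixed substream indices: regenerating one layer leaves the others untouched.
_STREAMS = {
    "cohort": 0,
    "truth": 1,
    "mrna": 2,
    "mirna": 3,
    "beta": 4,
    "anno_probes": 5,
    "annotations": 6,
    "module": 7,
}

#: Truncating-class frequencies among planted case variants (the observed
#: 5 nonsense : 3 splice-site : 3 frameshift-deletion pattern).
_TRUNCATING_WEIGHTS = {
    "nonsense": 5 / 11,
    "splice_site": 3 / 11,
    "frameshift_del": 3 / 11,
}

_REGION_WEIGHTS = {
    "TSS1500": 0.12,
    "TSS200": 0.10,
    "5UTR": 0.10,
    "1stExon": 0.08,
    "Body": 0.35,
    "3UTR": 0.08,
    "IGR": 0.17,
}

#: Hyper-planted probes are biased toward promoter/body labels.
_HYPER_REGION_WEIGHTS = {
    "TSS1500": 0.22,
    "TSS200": 0.18,
    "5UTR": 0.08,
    "1stExon": 0.06,
    "Body": 0.38,
    "3UTR": 0.04,
    "IGR": 0.04,
}

_FRAC_PROBES_HYPER = 0.75        # of planted probes, fraction shifted up
_FRAC_HYPER_ON_DOWN = 0.25       # of planted hyper probes, fraction on down genes
_FRAC_TF_OF_DE = 0.15            # fraction of planted DE genes on the TF list
_MODULE_LATENT_SD = 1.0          # log-scale sd of the shared module factor
_PPI_MEAN_DEGREE = 6.0


def _rng(config: SimulationConfig, layer: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[layer],))
    )


def _weighted_choice(rng, options: dict[str, float], size: int) -> np.ndarray:
    keys = list(options)
    probs = np.array([options[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return rng.choice(keys, size=size, p=probs)


# ----------------------------------------------------------------- cohort ---

def simulate_cohort(config: SimulationConfig) -> tuple[MutationTable, GroundTruth]:
    """Generate the mutation table and the full planted ground truth.

    Feature universes and every planted assignment (DE genes with signed
    effects, DM probes with signed beta shifts, DE miRNAs, the enriched term,
    the co-expression module) are decided here so every later layer can be
    simulated independently.
    """
    config.validate()
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    mirnas = [f"miR-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    probes = [f"cg{i:08d}" for i in range(1, config.n_probes + 1)]

    rng_t = _rng(config, "truth")
    # sample assignment first: feature-layer truth draws must not perturb it
    n_total = config.n_case + config.n_control + config.n_other
    sample_ids = [f"SAMP{i:03d}" for i in range(1, n_total + 1)]
    order = rng_t.permutation(n_total)
    case_ids = [sample_ids[i] for i in order[: config.n_case]]
    control_ids = [sample_ids[i] for i in order[config.n_case : config.n_case + config.n_control]]
    other_ids = [sample_ids[i] for i in order[config.n_case + config.n_control :]]

    de_genes = list(rng_t.choice(genes, size=config.n_de_genes, replace=False))
    n_down = int(round(config.frac_down * config.n_de_genes))
    de_down = {g: -config.effect_log2fc for g in de_genes[:n_down]}
    de_up = {g: config.effect_log2fc for g in de_genes[n_down:]}

    de_mirnas = list(rng_t.choice(mirnas, size=config.n_de_mirnas, replace=False))
    n_mdown = int(round(config.frac_down * config.n_de_mirnas))
    mirna_down = {m: -config.effect_log2fc for m in de_mirnas[:n_mdown]}
    mirna_up = {m: config.effect_log2fc for m in de_mirnas[n_mdown:]}

    dm_probes = list(rng_t.choice(probes, size=config.n_dm_probes, replace=False))
    n_hyper = int(round(_FRAC_PROBES_HYPER * config.n_dm_probes))
    dm_hyper = {p: config.delta_beta for p in dm_probes[:n_hyper]}
    dm_hypo = {p: -config.delta_beta for p in dm_probes[n_hyper:]}

    non_de = [g for g in genes if g not in de_down and g not in de_up]
    module_pool = non_de if len(non_de) >= config.module_size else genes
    module = list(rng_t.choice(module_pool, size=config.module_size, replace=False))

    truth = GroundTruth(
        case_ids=case_ids,
        control_ids=control_ids,
        other_ids=other_ids,
        de_genes_up=de_up,
        de_genes_down=de_down,
        dm_probes_hyper=dm_hyper,
        dm_probes_hypo=dm_hypo,
        de_mirnas_up=mirna_up,
        de_mirnas_down=mirna_down,
        planted_term="TERM_PLANTED",
        planted_module=module,
        genes=genes,
        mirnas=mirnas,
        probes=probes,
    )
    anno = simulate_probe_annotation(config, truth)
    truth.probe_gene = dict(zip(anno.index, anno["gene_symbol"]))

    table = _simulate_mutations(config, truth)
    return table, truth


def _simulate_mutations(config: SimulationConfig, truth: GroundTruth) -> MutationTable:
    rng = _rng(config, "cohort")
    target = "PBRM1"
    exclusion = ("VHL", "BAP1", "SETD2", "PTEN", "KDM5C")
    passenger_pool = truth.genes
    rows: list[dict] = []

    def passenger_rows(sample: str) -> None:
        # every tumor carries >= 1 somatic variant, so the sample roster is
        # recoverable from the MAF alone
        for _ in range(1 + rng.poisson(2)):
            rows.append(
                {
                    "sample_id": sample,
                    "gene_symbol": str(rng.choice(passenger_pool)),
                    "variant_class": str(
                        _weighted_choice(rng, {"missense": 0.6, "silent": 0.3, "other": 0.1}, 1)[0]
                    ),
                    "protein_pos": int(rng.integers(1, 1500)),
                }
            )

    for sample in truth.case_ids:
        rows.append(
            {
                "sample_id": sample,
                "gene_symbol": target,
                "variant_class": str(_weighted_choice(rng, _TRUNCATING_WEIGHTS, 1)[0]),
                "protein_pos": int(rng.integers(1, 1600)),
            }
        )
        passenger_rows(sample)
    for sample in truth.control_ids:
        passenger_rows(sample)
    for i, sample in enumerate(truth.other_ids):
        if i % 2 == 0:
            rows.append(
                {
                    "sample_id": sample,
                    "gene_symbol": str(rng.choice(exclusion)),
                    "variant_class": str(
                        rng.choice(["missense", "nonsense", "frameshift_del"])
                    ),
                    "protein_pos": int(rng.integers(1, 1000)),
                }
            )
        else:
            rows.append(
                {
                    "sample_id": sample,
                    "gene_symbol": target,
                    "variant_class": "missense",
                    "protein_pos": int(rng.integers(1, 1600)),
                }
            )
        passenger_rows(sample)

    records = pd.DataFrame(rows, columns=["sample_id", "gene_symbol", "variant_class", "protein_pos"])
    all_samples = truth.case_ids + truth.control_ids + truth.other_ids
    return MutationTable(records=records, samples=sorted(all_samples))


# ----------------------------------------------------------------- counts ---

def simulate_counts(
    config: SimulationConfig, truth: GroundTruth, layer: str = "mrna"
) -> CountMatrix:
    """Negative-binomial counts with library-size scaling and planted fold
    changes on the case group.

    Feature baseline abundances are log-normal; with ``nb_dispersion = 0``
    sampling is Poisson.  For the mRNA layer, genes of the planted module
    additionally share a log-normal per-sample latent factor, which makes
    them strongly pairwise-correlated on the log-cpm scale (the signal the
    co-expression stage must recover).
    """
    if layer not in ("mrna", "mirna"):
        raise ValueError(f"unknown layer {layer!r}")
    config.validate()
    rng = _rng(config, layer)
    features = truth.genes if layer == "mrna" else truth.mirnas
    up = truth.de_genes_up if layer == "mrna" else truth.de_mirnas_up
    down = truth.de_genes_down if layer == "mrna" else truth.de_mirnas_down

    samples = truth.case_ids + truth.control_ids + truth.other_ids
    n_feat, n_samp = len(features), len(samples)
    case_mask = np.array([s in set(truth.case_ids) for s in samples])

    weight = np.exp(rng.normal(0.0, 1.2, size=n_feat))
    rel = weight / weight.sum()
    lo, hi = config.lib_size_range
    libs = rng.integers(lo, hi + 1, size=n_samp).astype(float)

    fc = np.ones((n_feat, n_samp))
    effect = np.zeros(n_feat)
    for i, f in enumerate(features):
        if f in up:
            effect[i] = up[f]
        elif f in down:
            effect[i] = down[f]
    fc[:, case_mask] = 2.0 ** effect[:, None]

    mu = rel[:, None] * libs[None, :] * fc
    if layer == "mrna" and truth.planted_module:
        z = _rng(config, "module").normal(0.0, _MODULE_LATENT_SD, size=n_samp)
        module_idx = [features.index(g) for g in truth.planted_module]
        # shared latent factor, mean-corrected so expected counts are unchanged
        mu[module_idx, :] *= np.exp(z - _MODULE_LATENT_SD**2 / 2.0)[None, :]

    if config.nb_dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    frame = pd.DataFrame(counts.astype(np.int64), index=features, columns=samples)
    return CountMatrix(counts=frame)


# ------------------------------------------------------------- methylation --

def simulate_probe_annotation(
    config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """450K-style probe annotation, deterministic given the config seed.

    Planted probes are forced autosomal, SNP-free and gene-annotated; a fixed
    fraction of the planted hyper probes is annotated to planted down genes so
    hyper-down genes exist by construction.  Hyper probes draw their region
    label from a promoter/body-skewed distribution.
    """
    rng = _rng(config, "anno_probes")
    hyper = list(truth.dm_probes_hyper)
    hypo = list(truth.dm_probes_hypo)
    planted = set(hyper) | set(hypo)

    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=config.n_probes)], dtype=object)
    sexy = rng.random(config.n_probes) < 0.04
    chrom[sexy] = np.where(rng.random(int(sexy.sum())) < 0.8, "chrX", "chrY")
    pos = rng.integers(1, 2_000_000, size=config.n_probes)
    snp = rng.random(config.n_probes) < 0.05
    has_gene = rng.random(config.n_probes) < 0.85
    gene = np.where(has_gene, rng.choice(truth.genes, size=config.n_probes), "")
    region = _weighted_choice(rng, _REGION_WEIGHTS, config.n_probes)

    anno = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "gene_symbol": gene,
            "region": region,
            "snp_within_5bp": snp,
        },
        index=pd.Index(truth.probes, name="probe_id"),
    )
    # planted probes must survive the standard probe filter
    planted_list = sorted(planted)
    anno.loc[planted_list, "chrom"] = [
        f"chr{c}" for c in rng.integers(1, 23, size=len(planted_list))
    ]
    anno.loc[planted_list, "snp_within_5bp"] = False
    down_genes = sorted(truth.de_genes_down)
    n_on_down = int(round(_FRAC_HYPER_ON_DOWN * len(hyper))) if down_genes else 0
    for i, p in enumerate(hyper):
        if i < n_on_down:
            anno.loc[p, "gene_symbol"] = down_genes[i % len(down_genes)]
        elif not anno.loc[p, "gene_symbol"]:
            anno.loc[p, "gene_symbol"] = str(rng.choice(truth.genes))
    anno.loc[hyper, "region"] = _weighted_choice(rng, _HYPER_REGION_WEIGHTS, len(hyper))
    for p in hypo:
        if not anno.loc[p, "gene_symbol"]:
            anno.loc[p, "gene_symbol"] = str(rng.choice(truth.genes))
    return anno


def simulate_beta(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta-value matrix plus probe annotation.

    Each probe has a baseline mean in (0.05, 0.95); values are Beta-distributed
    with concentration ``beta_precision``.  Planted hyper (hypo) probes have
    the case-group mean shifted by +delta_beta (-delta_beta); baselines of
    planted probes are drawn away from the boundary so the shifted mean stays
    inside [0.01, 0.99] (means are clipped there regardless).
    """
    import warnings as _warnings

    config.validate()
    rng = _rng(config, "beta")
    samples = truth.case_ids + truth.control_ids + truth.other_ids
    n_probe, n_samp = config.n_probes, len(samples)
    case_mask = np.array([s in set(truth.case_ids) for s in samples])

    base = rng.uniform(0.05, 0.95, size=n_probe)
    shift = np.zeros(n_probe)
    probe_idx = {p: i for i, p in enumerate(truth.probes)}
    for p, d in truth.dm_probes_hyper.items():
        i = probe_idx[p]
        base[i] = rng.uniform(0.05, 0.95 - abs(d))
        shift[i] = d
    for p, d in truth.dm_probes_hypo.items():
        i = probe_idx[p]
        base[i] = rng.uniform(0.05 + abs(d), 0.95)
        shift[i] = d

    mean = base[:, None] + shift[:, None] * case_mask[None, :]
    if ((mean < 0) | (mean > 1)).any():
        _warnings.warn("planted beta shift pushes means outside [0, 1]; clipping")
    mean = np.clip(mean, 0.01, 0.99)
    a = mean * config.beta_precision
    b = (1.0 - mean) * config.beta_precision
    values = rng.beta(a, b)
    beta = pd.DataFrame(values, index=pd.Index(truth.probes, name="probe_id"), columns=samples)
    anno = simulate_probe_annotation(config, truth)
    return beta, anno


# -------------------------------------------------------------- resources ---

def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth, n_background_terms: int = 40
) -> tuple[dict[str, set[str]], GeneSetCatalog, pd.DataFrame, list[str]]:
    """Target map, gene-set catalog, PPI edge list and TF list.

    * every miRNA targets a random handful of genes; planted DE miRNAs get
      extra deliberate links to planted DE genes;
    * the catalog holds random background terms plus one planted term whose
      members are drawn preferentially (70%) from the planted down genes;
    * the PPI is a uniform random graph (mean degree ~6) with the planted
      module wired in as a clique;
    * the TF list holds a fixed fraction of the planted DE genes plus random
      non-DE genes.
    """
    config.validate()
    rng = _rng(config, "annotations")
    genes = truth.genes

    target_map: dict[str, set[str]] = {}
    for m in truth.mirnas:
        size = 1 + rng.poisson(12)
        target_map[m] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
    planted_de = sorted(truth.de_genes)
    for m in sorted(truth.de_mirnas):
        if planted_de:
            extra = rng.choice(planted_de, size=min(5, len(planted_de)), replace=False)
            target_map[m] |= set(extra)

    down = sorted(truth.de_genes_down)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    term_size = 30
    if down:
        n_from_down = min(int(round(0.7 * term_size)), len(down))
        members = set(rng.choice(down, size=n_from_down, replace=False))
        others = [g for g in genes if g not in members]
        members |= set(rng.choice(others, size=term_size - n_from_down, replace=False))
        terms[truth.planted_term] = ("planted enriched term", frozenset(members))
    for i in range(1, n_background_terms + 1):
        size = int(rng.integers(10, 41))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        terms[f"TERM{i:04d}"] = (f"background term {i}", members)
    catalog = GeneSetCatalog(terms=terms, universe=frozenset(genes))

    n_edges = int(_PPI_MEAN_DEGREE * len(genes) / 2)
    idx_a = rng.integers(0, len(genes), size=2 * n_edges)
    idx_b = rng.integers(0, len(genes), size=2 * n_edges)
    edges: set[tuple[str, str]] = set()
    for ia, ib in zip(idx_a, idx_b):
        if ia == ib:
            continue
        a, b = genes[ia], genes[ib]
        edges.add((a, b) if a <= b else (b, a))
        if len(edges) >= n_edges:
            break
    module = truth.planted_module
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            a, b = module[i], module[j]
            edges.add((a, b) if a <= b else (b, a))
    ppi = pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])

    de_sorted = sorted(truth.de_genes)
    n_tf_de = int(np.ceil(_FRAC_TF_OF_DE * len(de_sorted))) if de_sorted else 0
    tf_de = list(rng.choice(de_sorted, size=n_tf_de, replace=False)) if n_tf_de else []
    non_de = [g for g in genes if g not in truth.de_genes]
    tf_bg = list(rng.choice(non_de, size=min(20, len(non_de)), replace=False))
    tf_list = sorted(set(tf_de) | set(tf_bg))
    return target_map, catalog, ppi, tf_list


# ----------------------------------------------------------------- bundle ---

@dataclass
class SyntheticBundle:
    """Everything one synthetic cohort provides, in memory."""

    config: SimulationConfig
    truth: GroundTruth
    mutations: MutationTable
    mrna: CountMatrix
    mirna: CountMatrix
    beta: pd.DataFrame
    probe_annotation: pd.DataFrame
    target_map: dict[str, set[str]]
    catalog: GeneSetCatalog
    ppi: pd.DataFrame
    tf_list: list[str]


def simulate_bundle(config: Optional[SimulationConfig] = None) -> SyntheticBundle:
    """Simulate every layer with one call."""
    config = config or SimulationConfig()
    mutations, truth = simulate_cohort(config)
    mrna = simulate_counts(config, truth, "mrna")
    mirna = simulate_counts(config, truth, "mirna")
    beta, anno = simulate_beta(config, truth)
    target_map, catalog, ppi, tf_list = simulate_annotations(config, truth)
    return SyntheticBundle(
        config=config,
        truth=truth,
        mutations=mutations,
        mrna=mrna,
        mirna=mirna,
        beta=beta,
        probe_annotation=anno,
        target_map=target_map,
        catalog=catalog,
        ppi=ppi,
        tf_list=tf_list,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Serialize a bundle to TSV/GMT/JSON files; returns name -> path."""
    import json
    from pathlib import Path

    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": outdir / "mutations.maf.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "beta": outdir / "beta.tsv",
        "probe_annotation": outdir / "probe_annotation.tsv",
        "targets": outdir / "mirna_targets.tsv",
        "gmt": outdir / "genesets.gmt",
        "ppi": outdir / "ppi.tsv",
        "tf_list": outdir / "tf_list.txt",
        "truth": outdir / "truth.json",
    }
    sio.write_maf(bundle.mutations, paths["maf"])
    sio.write_counts_tsv(bundle.mrna, paths["mrna_counts"])
    sio.write_counts_tsv(bundle.mirna, paths["mirna_counts"])
    sio.write_beta_tsv(bundle.beta, paths["beta"])
    sio.write_probe_annotation(bundle.probe_annotation, paths["probe_annotation"])
    sio.write_target_map(bundle.target_map, paths["targets"])
    sio.write_gmt(bundle.catalog, paths["gmt"])
    sio.write_ppi(bundle.ppi, paths["ppi"])
    sio.write_gene_list(bundle.tf_list, paths["tf_list"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
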
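"""Synthetic-cohort generator: determinism, truth bookkeeping, planted-effect
magnitudes at large n, and referential integrity of the annotation layers."""

import numpy as np
import pandas as pd
import pytest

from stratomics import de
from stratomics.errors import ConfigError
from stratomics.methylation import filter_probes
from stratomics.stratify import stratify
from stratomics.synthetic import (
    SimulationConfig,
    simulate_beta,
    simulate_cohort,
    simulate_counts,
    simulate_annotations,
)
from stratomics.types import CohortDesign


SMALL = SimulationConfig(
    n_genes=200, n_mirnas=30, n_probes=200, n_de_genes=40, n_dm_probes=30,
    n_de_mirnas=8, n_other=5, seed=13,
)


def test_determinism_identical_outputs():
    t1, truth1 = simulate_cohort(SMALL)
    t2, truth2 = simulate_cohort(SMALL)
    pd.testing.assert_frame_equal(t1.records, t2.records)
    assert truth1.to_dict() == truth2.to_dict()
    c1 = simulate_counts(SMALL, truth1, "mrna")
    c2 = simulate_counts(SMALL, truth2, "mrna")
    pd.testing.assert_frame_equal(c1.counts, c2.counts)
    b1, a1 = simulate_beta(SMALL, truth1)
    b2, a2 = simulate_beta(SMALL, truth2)
    pd.testing.assert_frame_equal(b1, b2)
    pd.testing.assert_frame_equal(a1, a2)


def test_cohort_stratification_recovers_design(bundle):
    """Stratifying the generated mutation table returns exactly the planted
    case/control split."""
    cohort = stratify(bundle.mutations, CohortDesign())
    assert sorted(cohort.case_ids) == sorted(bundle.truth.case_ids)
    assert sorted(cohort.control_ids) == sorted(bundle.truth.control_ids)
    assert set(cohort.excluded) == set(bundle.truth.other_ids)


def test_empty_case_group_supported():
    cfg = SMALL.replace(n_case=0, seed=3)
    table, truth = simulate_cohort(cfg)
    cohort = stratify(table, CohortDesign())
    assert cohort.case_ids == []


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(n_genes=10, n_de_genes=20).validate()
    with pytest.raises(ConfigError):
        SimulationConfig(nb_dispersion=-1).validate()
    with pytest.raises(ConfigError):
        SimulationConfig(lib_size_range=(0, 10)).validate()


def test_truth_bookkeeping_counts():
    _, truth = simulate_cohort(SMALL)
    assert len(truth.de_genes) == SMALL.n_de_genes
    assert len(truth.dm_probes) == SMALL.n_dm_probes
    assert len(truth.de_mirnas) == SMALL.n_de_mirnas
    assert not (set(truth.de_genes_up) & set(truth.de_genes_down))
    assert not (set(truth.dm_probes_hyper) & set(truth.dm_probes_hypo))
    assert truth.de_genes <= set(truth.genes)
    assert truth.dm_probes <= set(truth.probes)


def test_library_sums_match_fixed_range():
    """With a degenerate library-size range and no planted effects, every
    column sum lands within 5% of the configured library (the expected value
    is exact; the tolerance covers count noise)."""
    cfg = SMALL.replace(
        lib_size_range=(1_000_000, 1_000_000), n_genes=1000, n_de_genes=0,
        n_dm_probes=0, n_de_mirnas=0, module_size=0, nb_dispersion=0.05, seed=5,
    )
    _, truth = simulate_cohort(cfg)
    counts = simulate_counts(cfg, truth, "mrna")
    sums = counts.counts.sum(axis=0).to_numpy()
    assert np.all(np.abs(sums - 1e6) / 1e6 < 0.05)


def test_planted_log2fc_recovered_at_large_n():
    """With 500 samples per group the empirical log2 mean-cpm ratio of each
    planted gene sits within 0.1 of the planted +-2."""
    cfg = SimulationConfig(
        n_case=500, n_control=500, n_other=0, n_genes=300, n_mirnas=10,
        n_probes=10, n_de_genes=30, n_dm_probes=0, n_de_mirnas=0,
        module_size=0, seed=21,
    )
    _, truth = simulate_cohort(cfg)
    counts = simulate_counts(cfg, truth, "mrna")
    vals = de.cpm(counts)
    case_mean = vals[truth.case_ids].mean(axis=1)
    ctrl_mean = vals[truth.control_ids].mean(axis=1)
    ratio = np.log2(case_mean / ctrl_mean)
    for gene, lfc in {**truth.de_genes_up, **truth.de_genes_down}.items():
        assert abs(ratio[gene] - lfc) < 0.1
    null = [g for g in truth.genes if g not in truth.de_genes]
    assert np.abs(ratio[null]).max() < 0.35


def test_beta_values_in_unit_interval_and_planted_shift():
    cfg = SimulationConfig(
        n_case=500, n_control=500, n_other=0, n_genes=50, n_mirnas=5,
        n_probes=100, n_de_genes=0, n_dm_probes=20, n_de_mirnas=0, seed=31,
    )
    _, truth = simulate_cohort(cfg)
    beta, anno = simulate_beta(cfg, truth)
    vals = beta.to_numpy()
    assert vals.min() >= 0.0 and vals.max() <= 1.0
    diff = beta[truth.case_ids].mean(axis=1) - beta[truth.control_ids].mean(axis=1)
    for probe, shift in {**truth.dm_probes_hyper, **truth.dm_probes_hypo}.items():
        assert abs(diff[probe] - shift) < 0.02


def test_planted_probes_survive_filter_and_snp_probes_do_not(bundle):
    kept = filter_probes(bundle.beta, bundle.probe_annotation)
    assert bundle.truth.dm_probes <= set(kept.index)
    flagged = set(bundle.probe_annotation.index[bundle.probe_annotation["snp_within_5bp"]])
    assert not (flagged & set(kept.index))


def test_annotation_referential_integrity(bundle):
    gene_universe = set(bundle.truth.genes)
    for targets in bundle.target_map.values():
        assert targets <= gene_universe
        assert targets  # no empty target sets stored
    ppi = bundle.ppi
    assert (ppi["gene_a"] != ppi["gene_b"]).all()
    keys = {tuple(sorted(e)) for e in zip(ppi["gene_a"], ppi["gene_b"])}
    assert len(keys) == len(ppi)
    assert set(bundle.tf_list) <= gene_universe
    # planted module is wired as a clique in the PPI
    mod = bundle.truth.planted_module
    for i, a in enumerate(mod):
        for b in mod[i + 1:]:
            assert tuple(sorted((a, b))) in keys


def test_planted_term_members_enriched_in_down_genes(bundle):
    desc, members = bundle.catalog.terms[bundle.truth.planted_term]
    down = set(bundle.truth.de_genes_down)
    assert len(members & down) >= 0.5 * len(members)


def test_layer_substreams_independent():
    """Changing the probe count must not perturb the simulated counts."""
    cfg_a = SMALL
    cfg_b = SMALL.replace(n_probes=SMALL.n_probes + 50, n_dm_probes=0)
    _, truth_a = simulate_cohort(cfg_a)
    _, truth_b = simulate_cohort(cfg_b)
    ca = simulate_counts(cfg_a, truth_a, "mirna")
    cb = simulate_counts(cfg_b, truth_b, "mirna")
    pd.testing.assert_frame_equal(ca.counts, cb.counts)
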
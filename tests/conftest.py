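"""Shared fixtures: one synthetic cohort and one full pipeline run, reused
across test modules to keep the suite fast."""

from __future__ import annotations

import pandas as pd
import pytest

from stratomics.pipeline import PipelineConfig, run_pipeline
from stratomics.synthetic import SimulationConfig, simulate_bundle, write_bundle
from stratomics.types import CountMatrix

#: Desk-scale cohort with planted effects on every layer (seed fixed).
BUNDLE_CONFIG = SimulationConfig(
    n_genes=600,
    n_mirnas=80,
    n_probes=800,
    n_de_genes=120,
    n_dm_probes=80,
    n_de_mirnas=20,
    seed=7,
)


@pytest.fixture(scope="session")
def bundle():
    return simulate_bundle(BUNDLE_CONFIG)


@pytest.fixture(scope="session")
def groups(bundle):
    truth = bundle.truth
    return list(truth.case_ids), list(truth.control_ids)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One end-to-end run on the shared bundle: (config, report, outdir)."""
    root = tmp_path_factory.mktemp("e2e")
    paths = write_bundle(bundle, root / "data")
    config = PipelineConfig(
        maf=paths["maf"],
        mrna_counts=paths["mrna_counts"],
        mirna_counts=paths["mirna_counts"],
        beta=paths["beta"],
        probe_annotation=paths["probe_annotation"],
        targets=paths["targets"],
        gmt=paths["gmt"],
        ppi=paths["ppi"],
        tf_list=paths["tf_list"],
        outdir=str(root / "run"),
        n_perm=400,
        seed=11,
    )
    report = run_pipeline(config)
    return config, report, root / "run"


def make_counts(rows: dict[str, list[int]], samples: list[str],
                lib_sizes: list[float] | None = None) -> CountMatrix:
    """Tiny count-matrix builder for hand examples."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    libs = None if lib_sizes is None else pd.Series(lib_sizes, index=samples, dtype=float)
    return CountMatrix(counts=frame.astype(int), lib_sizes=libs)
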
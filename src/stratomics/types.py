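"""Core in-memory containers shared across the pipeline.

The pipeline works on four kinds of data: somatic mutation calls (a MAF-like
table plus a sample roster), non-negative integer count matrices (mRNA and
miRNA expression), a probe-by-sample methylation beta-value matrix with a probe
annotation, and assorted set-valued resources (miRNA target maps, gene-set
catalogs, PPI edge lists, transcription-factor lists).  Everything is a thin
dataclass around pandas objects so the statistical modules can stay functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

# Controlled vocabulary for somatic variant consequence classes.
VARIANT_CLASSES = frozenset(
    {
        "nonsense",
        "frameshift_del",
        "frameshift_ins",
        "splice_site",
        "missense",
        "silent",
        "in_frame_indel",
        "other",
    }
)

#: Loss-of-function consequence classes used to define the mutated group.
DEFAULT_TRUNCATING_CLASSES = frozenset(
    {"nonsense", "frameshift_del", "frameshift_ins", "splice_site"}
)

#: Mapping from standard MAF ``Variant_Classification`` strings to the enum.
MAF_CLASS_MAP: Mapping[str, str] = {
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift_del",
    "Frame_Shift_Ins": "frameshift_ins",
    "Splice_Site": "splice_site",
    "Missense_Mutation": "missense",
    "Silent": "silent",
    "In_Frame_Del": "in_frame_indel",
    "In_Frame_Ins": "in_frame_indel",
    # already-normalized strings pass through
    **{c: c for c in VARIANT_CLASSES},
}

MUTATION_COLUMNS = ["sample_id", "gene_symbol", "variant_class", "protein_pos"]


@dataclass
class MutationTable:
    """Somatic variant calls plus the full sample roster.

    The roster matters: a tumor with no recorded variants is still a sample
    (and a candidate control), so group membership cannot be derived from the
    variant rows alone.
    """

    records: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in MUTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise InputError(f"mutation table missing columns: {missing}")
        rec = self.records
        if len(rec):
            if rec["sample_id"].astype(str).str.strip().eq("").any():
                raise InputError("mutation table contains empty sample_id")
            if rec["gene_symbol"].astype(str).str.strip().eq("").any():
                raise InputError("mutation table contains empty gene_symbol")
            bad = set(rec["variant_class"]) - VARIANT_CLASSES
            if bad:
                raise InputError(f"unknown variant classes: {sorted(bad)}")
            unknown = set(rec["sample_id"]) - set(self.samples)
            if unknown:
                raise InputError(
                    f"variant rows reference samples absent from roster: {sorted(unknown)[:5]}"
                )

    @classmethod
    def from_records(cls, records: pd.DataFrame, samples: Optional[Sequence[str]] = None):
        if samples is None:
            samples = list(dict.fromkeys(records["sample_id"]))
        return cls(records=records.reset_index(drop=True), samples=list(samples))


@dataclass
class CohortDesign:
    """Defines the case/control contrast: the target driver gene, the
    co-driver genes whose carriers are excluded from both groups, and which
    variant classes count as truncating."""

    target_gene: str = "PBRM1"
    exclusion_genes: tuple[str, ...] = ("VHL", "BAP1", "SETD2", "PTEN", "KDM5C")
    truncating_classes: frozenset[str] = DEFAULT_TRUNCATING_CLASSES

    def __post_init__(self) -> None:
        if not self.target_gene:
            raise ConfigError("target_gene must be non-empty")
        if self.target_gene in self.exclusion_genes:
            raise ConfigError("target_gene must not be in exclusion_genes")
        if not self.truncating_classes:
            raise ConfigError("truncating_classes must be non-empty")
        bad = set(self.truncating_classes) - VARIANT_CLASSES
        if bad:
            raise ConfigError(f"unknown truncating classes: {sorted(bad)}")


@dataclass
class StratifiedCohort:
    """Result of cohort stratification: ordered case/control id lists and a
    reason for every excluded sample."""

    case_ids: list[str]
    control_ids: list[str]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise InputError(f"samples in both groups: {sorted(overlap)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.case_ids) + len(self.control_ids) + len(self.excluded)


@dataclass
class CountMatrix:
    """Feature-by-sample matrix of non-negative integer counts.

    ``lib_sizes`` defaults to column sums; TMM factors are computed separately
    and multiply library sizes into effective library sizes.
    """

    counts: pd.DataFrame
    lib_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()][:5]
            raise InputError(f"duplicate feature ids: {list(dups)}")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise InputError("count matrix contains negative entries")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.reindex(self.counts.columns).astype(float)
            if self.lib_sizes.isna().any():
                raise InputError("lib_sizes missing for some samples")
        if len(self.counts.columns) and (self.lib_sizes <= 0).any():
            zero = list(self.lib_sizes.index[self.lib_sizes <= 0])[:5]
            raise InputError(f"non-positive library sizes for samples: {zero}")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise InputError(f"samples absent from count matrix: {missing[:5]}")
        return CountMatrix(
            counts=self.counts.loc[:, list(sample_ids)],
            lib_sizes=self.lib_sizes.loc[list(sample_ids)],
        )


PROBE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "IGR")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-omics cohort.

    Defaults mirror the study design the pipeline targets: 11 driver-truncated
    cases against 33 pan-negative controls, negative-binomial counts with a
    common dispersion, beta-distributed methylation values, and planted
    two-fold-per-unit effects (|log2FC| = 2 on counts, |delta beta| = 0.3 on
    probes) that downstream thresholds (|log2FC| > 1, |beta-difference| > 0.15)
    should recover.
    """

    n_case: int = 11
    n_control: int = 33
    n_other: int = 6
    n_genes: int = 1500
    n_mirnas: int = 150
    n_probes: int = 1500
    n_de_genes: int = 200
    n_dm_probes: int = 150
    n_de_mirnas: int = 30
    effect_log2fc: float = 2.0
    delta_beta: float = 0.3
    nb_dispersion: float = 0.1
    beta_precision: float = 50.0
    lib_size_range: tuple[int, int] = (800_000, 1_200_000)
    frac_down: float = 0.75
    module_size: int = 10
    seed: int = 7

    def validate(self) -> None:
        for name in (
            "n_case",
            "n_control",
            "n_other",
            "n_genes",
            "n_mirnas",
            "n_probes",
            "n_de_genes",
            "n_dm_probes",
            "n_de_mirnas",
            "module_size",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes exceeds n_genes")
        if self.n_dm_probes > self.n_probes:
            raise ConfigError("n_dm_probes exceeds n_probes")
        if self.n_de_mirnas > self.n_mirnas:
            raise ConfigError("n_de_mirnas exceeds n_mirnas")
        if self.module_size > self.n_genes:
            raise ConfigError("module_size exceeds n_genes")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.beta_precision <= 0:
            raise ConfigError("beta_precision must be > 0")
        if not (0.0 <= self.frac_down <= 1.0):
            raise ConfigError("frac_down must be in [0, 1]")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("lib_size_range must satisfy 0 < lo <= hi")

    def replace(self, **kw) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kw)
        return SimulationConfig(**current)


@dataclass
class GroundTruth:
    """Planted signal bookkeeping for a synthetic cohort.

    Direction maps carry the planted per-feature effect (signed log2FC for
    counts, signed beta shift for probes) keyed by feature id.
    """

    case_ids: list[str]
    control_ids: list[str]
    other_ids: list[str]
    de_genes_up: dict[str, float]
    de_genes_down: dict[str, float]
    dm_probes_hyper: dict[str, float]
    dm_probes_hypo: dict[str, float]
    de_mirnas_up: dict[str, float]
    de_mirnas_down: dict[str, float]
    planted_term: str
    planted_module: list[str]
    genes: list[str]
    mirnas: list[str]
    probes: list[str]
    probe_gene: dict[str, str] = field(default_factory=dict)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de_genes_up) | set(self.de_genes_down)

    @property
    def de_mirnas(self) -> set[str]:
        return set(self.de_mirnas_up) | set(self.de_mirnas_down)

    @property
    def dm_probes(self) -> set[str]:
        return set(self.dm_probes_hyper) | set(self.dm_probes_hypo)

    @property
    def hyper_genes(self) -> set[str]:
        return {
            self.probe_gene[p]
            for p in self.dm_probes_hyper
            if self.probe_gene.get(p)
        }

    @property
    def hyper_down_genes(self) -> set[str]:
        return self.hyper_genes & set(self.de_genes_down)

    def to_dict(self) -> dict:
        return {
            "case_ids": self.case_ids,
            "control_ids": self.control_ids,
            "other_ids": self.other_ids,
            "de_genes_up": self.de_genes_up,
            "de_genes_down": self.de_genes_down,
            "dm_probes_hyper": self.dm_probes_hyper,
            "dm_probes_hypo": self.dm_probes_hypo,
            "de_mirnas_up": self.de_mirnas_up,
            "de_mirnas_down": self.de_mirnas_down,
            "planted_term": self.planted_term,
            "planted_module": self.planted_module,
            "genes": self.genes,
            "mirnas": self.mirnas,
            "probes": self.probes,
            "probe_gene": self.probe_gene,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass
class GeneSetCatalog:
    """Named gene sets over a background universe (GMT semantics)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def restricted(self, universe: set[str]) -> "GeneSetCatalog":
        """Return a copy with members intersected with ``universe``."""
        uni = frozenset(universe)
        terms = {
            tid: (desc, members & uni) for tid, (desc, members) in self.terms.items()
        }
        return GeneSetCatalog(terms=terms, universe=uni)


def as_ordered_unique(ids: Sequence[str]) -> list[str]:
    """Deduplicate while preserving first-seen order."""
    return list(dict.fromkeys(ids))


def check_probabilities(p: np.ndarray | Sequence[float], name: str = "p") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise InputError(f"{name} values must lie in [0, 1]")
    return arr
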
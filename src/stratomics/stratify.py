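"""Cohort stratification by driver-gene mutation status.

A tumor sample becomes a *case* when it carries at least one truncating
(loss-of-function) variant in the target driver gene and no variant in any
co-driver exclusion gene.  A *control* ("pan-negative") sample carries no
variant in the target gene nor in any exclusion gene.  Everything else is
excluded with a recorded reason: carriers of exclusion-gene variants
(regardless of target status), and samples whose only target-gene variants are
non-truncating.  A sample with both truncating and non-truncating target
variants counts as a case — the truncating variant dominates.

A final restriction keeps only samples with data on every omics platform.
"""

from __future__ import annotations

from typing import Mapping, Set

from .errors import InputError
from .types import CohortDesign, MutationTable, StratifiedCohort

REASON_EXCLUSION = "exclusion_gene_mutation"
REASON_NONTRUNCATING = "target_nontruncating_only"
REASON_MISSING_OMICS = "missing_omics"


def is_truncating(gene_symbol: str, variant_class: str, design: CohortDesign) -> bool:
    """True iff the variant is a truncating event in the target gene."""
    return (
        gene_symbol == design.target_gene
        and variant_class in design.truncating_classes
    )


def stratify(table: MutationTable, design: CohortDesign) -> StratifiedCohort:
    """Partition the sample roster into cases, controls, and excluded samples.

    Every sample lands in exactly one of the three bins; input row order never
    affects membership.
    """
    if not table.samples:
        raise InputError("mutation table has an empty sample roster")

    rec = table.records
    exclusion = set(design.exclusion_genes)
    has_exclusion: Set[str] = set()
    has_truncating: Set[str] = set()
    has_target: Set[str] = set()
    for sample, gene, vclass in zip(
        rec["sample_id"], rec["gene_symbol"], rec["variant_class"]
    ):
        sample = sample.strip()
        if gene in exclusion:
            has_exclusion.add(sample)
        if gene == design.target_gene:
            has_target.add(sample)
            if vclass in design.truncating_classes:
                has_truncating.add(sample)

    case_ids, control_ids, excluded = [], [], {}
    for sample in table.samples:
        sid = sample.strip()
        if sid in has_exclusion:
            excluded[sid] = REASON_EXCLUSION
        elif sid in has_truncating:
            case_ids.append(sid)
        elif sid in has_target:
            excluded[sid] = REASON_NONTRUNCATING
        else:
            control_ids.append(sid)
    return StratifiedCohort(case_ids=case_ids, control_ids=control_ids, excluded=excluded)


def require_matched_omics(
    cohort: StratifiedCohort, available: Mapping[str, Set[str]]
) -> StratifiedCohort:
    """Restrict cases/controls to samples present on every omics platform.

    ``available`` maps a platform name (e.g. 'rna', 'meth', 'mirna') to the
    set of sample ids with data on it.  Samples dropped here are recorded
    as excluded for missing omics.
    """
    if not available:
        raise InputError("no omics availability sets provided")
    for platform, ids in available.items():
        if not ids:
            raise InputError(f"availability set for platform {platform!r} is empty")
    matched = set.intersection(*(set(ids) for ids in available.values()))

    excluded = dict(cohort.excluded)
    case_ids = [s for s in cohort.case_ids if s in matched]
    control_ids = [s for s in cohort.control_ids if s in matched]
    for s in cohort.case_ids + cohort.control_ids:
        if s not in matched:
            excluded[s] = REASON_MISSING_OMICS
    return StratifiedCohort(case_ids=case_ids, control_ids=control_ids, excluded=excluded)
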
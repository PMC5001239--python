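"""Cross-layer integration: miRNA targets, hyper-down genes, four-set Venn.

The four sets compared are the up- and down-regulated genes from the mRNA
layer and the target-gene unions of the up- and down-regulated miRNAs.
Hyper-down genes are the genes both down-regulated and hyper-methylated;
their intersection with the miRNA target union identifies genes hit by all
three layers at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import pandas as pd

VENN_SET_NAMES = ("deg_up", "deg_down", "up_mirna_targets", "down_mirna_targets")


def targets_of(
    mirnas: Sequence[str], target_map: Mapping[str, set[str]]
) -> tuple[set[str], int]:
    """Union of target sets of the queried miRNAs.

    Returns (target-gene union, number of query miRNAs with >= 1 target).
    miRNAs absent from the map contribute nothing.
    """
    genes: set[str] = set()
    with_targets = 0
    for m in set(mirnas):
        targets = target_map.get(m)
        if targets:
            genes |= targets
            with_targets += 1
    return genes, with_targets


def hyper_down_genes(down_genes: set[str], hyper_genes: set[str]) -> set[str]:
    """Genes both down-regulated and hyper-methylated."""
    return set(down_genes) & set(hyper_genes)


def venn_counts(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exclusive region counts for an n-set Venn diagram.

    One row per non-empty membership pattern; the counts over all regions sum
    to the size of the union.
    """
    names = list(sets)
    union = set().union(*sets.values()) if sets else set()
    rows = []
    for pattern in product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        inside = [n for n, f in zip(names, pattern) if f]
        outside = [n for n, f in zip(names, pattern) if not f]
        region = set(union)
        for n in inside:
            region &= sets[n]
        for n in outside:
            region -= sets[n]
        rows.append(
            {"region": "&".join(inside), "count": len(region)}
        )
    return pd.DataFrame(rows)


@dataclass
class IntegrationResult:
    """All cross-layer overlap products for one pipeline run."""

    up_mirnas: set[str]
    down_mirnas: set[str]
    up_targets: set[str]
    down_targets: set[str]
    n_up_mirnas_with_targets: int
    n_down_mirnas_with_targets: int
    venn: pd.DataFrame
    hyper_down_genes: set[str]
    hyper_down_mirna_targets: set[str]
    hyper_down_up_mirna_targets: set[str] = field(default_factory=set)
    hyper_down_down_mirna_targets: set[str] = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {
            "n_up_mirnas_with_targets": self.n_up_mirnas_with_targets,
            "n_down_mirnas_with_targets": self.n_down_mirnas_with_targets,
            "n_up_targets": len(self.up_targets),
            "n_down_targets": len(self.down_targets),
            "n_hyper_down_genes": len(self.hyper_down_genes),
            "n_hyper_down_mirna_targets": len(self.hyper_down_mirna_targets),
        }


def integrate(
    up_genes: set[str],
    down_genes: set[str],
    up_mirnas: Sequence[str],
    down_mirnas: Sequence[str],
    hyper_genes: set[str],
    target_map: Mapping[str, set[str]],
    universe: Optional[set[str]] = None,
) -> IntegrationResult:
    """Compute all cross-layer overlaps.

    ``universe`` (typically the post-filter expressed-gene set) restricts the
    miRNA target sets before any overlap, so target counts are comparable to
    the DE gene counts; pass None to keep raw target sets.
    """
    up_targets, n_up_wt = targets_of(up_mirnas, target_map)
    down_targets, n_down_wt = targets_of(down_mirnas, target_map)
    if universe is not None:
        up_targets &= universe
        down_targets &= universe

    sets = {
        "deg_up": set(up_genes),
        "deg_down": set(down_genes),
        "up_mirna_targets": up_targets,
        "down_mirna_targets": down_targets,
    }
    hd = hyper_down_genes(set(down_genes), set(hyper_genes))
    all_targets = up_targets | down_targets
    return IntegrationResult(
        up_mirnas=set(up_mirnas),
        down_mirnas=set(down_mirnas),
        up_targets=up_targets,
        down_targets=down_targets,
        n_up_mirnas_with_targets=n_up_wt,
        n_down_mirnas_with_targets=n_down_wt,
        venn=venn_counts(sets),
        hyper_down_genes=hd,
        hyper_down_mirna_targets=hd & all_targets,
        hyper_down_up_mirna_targets=hd & up_targets,
        hyper_down_down_mirna_targets=hd & down_targets,
    )
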
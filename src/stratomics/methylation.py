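"""Differential methylation on 450K-style beta values.

Probes are filtered on the standard exclusions (sex chromosomes, a SNP within
five base pairs of the CpG, no annotated gene), effect size is the plain
beta-difference (case mean minus control mean), and significance comes from a
moderated two-class d-statistic — mean difference over pooled standard error
plus an exchangeability constant s0 — with a label-permutation null.  Calls
use strict thresholds |beta-difference| > 0.15 and p < 0.01, summarized to
genes (a gene is hyper-methylated when at least one of its probes is).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .errors import ConfigError, InputError
from .types import PROBE_REGIONS

Groups = tuple[Sequence[str], Sequence[str]]


def filter_probes(beta: pd.DataFrame, anno: pd.DataFrame) -> pd.DataFrame:
    """Drop sex-chromosome probes, SNP-proximal probes, and probes without a
    reference gene; probe order is preserved.

    Every probe in the matrix must be annotated; a missing probe is an error
    naming it.
    """
    missing = beta.index.difference(anno.index)
    if len(missing):
        raise InputError(f"probe {missing[0]!r} missing from annotation")
    ann = anno.loc[beta.index]
    chrom = ann["chrom"].astype(str).str.replace("chr", "", regex=False)
    keep = (
        ~chrom.isin(["X", "Y"])
        & ~ann["snp_within_5bp"].astype(bool)
        & (ann["gene_symbol"].fillna("").astype(str).str.len() > 0)
    )
    return beta.loc[keep]


def beta_difference(beta: pd.DataFrame, groups: Groups) -> pd.Series:
    """Per-probe case mean minus control mean (pairwise-complete on NaNs).

    Probes with fewer than two observed values in either group are excluded
    with a warning.
    """
    case_ids, control_ids = list(groups[0]), list(groups[1])
    if not case_ids or not control_ids:
        raise InputError("both groups need at least one sample")
    case = beta[case_ids]
    control = beta[control_ids]
    enough = (case.notna().sum(axis=1) >= 2) & (control.notna().sum(axis=1) >= 2)
    if not enough.all():
        warnings.warn(
            f"{int((~enough).sum())} probes with < 2 observations per group excluded"
        )
    diff = case.mean(axis=1, skipna=True) - control.mean(axis=1, skipna=True)
    return diff[enough]


def _d_stat_matrix(
    x: np.ndarray, case_idx: np.ndarray, control_idx: np.ndarray,
    s0: Optional[float],
) -> tuple[np.ndarray, float]:
    """Vectorized d = (mean1 - mean2) / (s + s0) over probe rows.

    s is the pooled standard error of the mean difference; s0 defaults to the
    median of the per-probe s values.
    """
    n1, n2 = len(case_idx), len(control_idx)
    x1, x2 = x[:, case_idx], x[:, control_idx]
    m1, m2 = np.nanmean(x1, axis=1), np.nanmean(x2, axis=1)
    ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
    ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * (ss1 + ss2))
    if s0 is None:
        s0 = float(np.median(s))
        if s0 == 0.0:
            s0 = float(np.finfo(float).eps * max(1.0, np.nanmax(np.abs(x))))
            warnings.warn("all per-probe standard errors are zero; tiny s0 fallback used")
    d = (m1 - m2) / (s + s0)
    return d, s0


def sam_statistic(
    beta: pd.DataFrame, groups: Groups, s0: Optional[float] = None
) -> tuple[pd.Series, float]:
    """Moderated d-statistic per probe and the exchangeability constant used."""
    case_ids, control_ids = list(groups[0]), list(groups[1])
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise InputError("the d-statistic needs >= 2 samples per group")
    cols = case_ids + control_ids
    x = beta[cols].to_numpy(dtype=float)
    d, s0_used = _d_stat_matrix(
        x, np.arange(len(case_ids)), np.arange(len(case_ids), len(cols)), s0
    )
    return pd.Series(d, index=beta.index, name="d_stat"), s0_used


def permutation_pvalues(
    beta: pd.DataFrame,
    groups: Groups,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Two-sided permutation p-values for the d-statistic.

    Group labels are permuted jointly across probes and s0 is recomputed for
    every permutation.  When the number of distinct label assignments
    C(n1+n2, n1) is at most ``n_perm``, all assignments are enumerated and
    p = #{|d*| >= |d_obs|} / n_assignments (the observed split is one of
    them); otherwise ``n_perm`` random assignments are drawn and the add-one
    estimate p = (1 + #{|d*| >= |d_obs|}) / (1 + n_perm) is used.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    case_ids, control_ids = list(groups[0]), list(groups[1])
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise InputError("permutation test needs >= 2 samples per group")
    cols = case_ids + control_ids
    x = beta[cols].to_numpy(dtype=float)
    n1, n = len(case_ids), len(cols)
    obs_d, _ = _d_stat_matrix(x, np.arange(n1), np.arange(n1, n), None)
    obs_abs = np.abs(obs_d) * (1.0 - 1e-12)

    n_comb = math.comb(n, n1)
    exceed = np.zeros(len(x))
    if n_comb <= n_perm:
        denom = n_comb
        for case_pos in combinations(range(n), n1):
            case_idx = np.array(case_pos)
            control_idx = np.setdiff1d(np.arange(n), case_idx)
            d, _ = _d_stat_matrix(x, case_idx, control_idx, None)
            exceed += np.abs(d) >= obs_abs
        p = exceed / denom
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            case_idx = rng.choice(n, size=n1, replace=False)
            control_idx = np.setdiff1d(np.arange(n), case_idx)
            d, _ = _d_stat_matrix(x, case_idx, control_idx, None)
            exceed += np.abs(d) >= obs_abs
        p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(p, index=beta.index, name="pvalue")


def dm_analysis(
    beta: pd.DataFrame,
    anno: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Filter probes, compute beta-differences, d-statistics and permutation
    p-values; returns the per-probe table (attrs carry s0)."""
    filtered = filter_probes(beta, anno)
    groups = (list(case_ids), list(control_ids))
    diff = beta_difference(filtered, groups)
    filtered = filtered.loc[diff.index]
    d, s0 = sam_statistic(filtered, groups)
    p = permutation_pvalues(filtered, groups, n_perm=n_perm, seed=seed)
    table = pd.DataFrame(
        {
            "beta_diff": diff,
            "d_stat": d,
            "pvalue": p,
            "padj": multipletests(p.to_numpy(), method="fdr_bh")[1],
        }
    )
    table.attrs["s0"] = s0
    return table


def _genes_of(probes: Sequence[str], anno: pd.DataFrame) -> set[str]:
    """Union of gene symbols of the probes; multi-gene annotations split on ';'."""
    genes: set[str] = set()
    for p in probes:
        sym = str(anno.loc[p, "gene_symbol"] or "")
        genes.update(g for g in sym.split(";") if g)
    return genes


def call_dm(
    table: pd.DataFrame,
    anno: pd.DataFrame,
    delta_thresh: float = 0.15,
    p_thresh: float = 0.01,
) -> tuple[set[str], set[str], set[str], set[str]]:
    """Hyper/hypo calls at strict thresholds; returns
    (hyper probes, hypo probes, hyper genes, hypo genes).

    Gene summaries use set semantics: one gene with several called probes
    counts once, so #genes <= #called probes.
    """
    hyper = (table["beta_diff"] > delta_thresh) & (table["pvalue"] < p_thresh)
    hypo = (table["beta_diff"] < -delta_thresh) & (table["pvalue"] < p_thresh)
    call = pd.Series("ns", index=table.index)
    call[hyper] = "hyper"
    call[hypo] = "hypo"
    table["call"] = call
    hyper_probes = set(table.index[hyper])
    hypo_probes = set(table.index[hypo])
    return (
        hyper_probes,
        hypo_probes,
        _genes_of(sorted(hyper_probes), anno),
        _genes_of(sorted(hypo_probes), anno),
    )


def region_distribution_test(
    hyper_probes: set[str], hypo_probes: set[str], anno: pd.DataFrame
) -> pd.DataFrame:
    """Compare region-of-residence proportions between hyper and hypo probes.

    Per region label, a two-proportion z-test of membership (hyper vs hypo),
    BH-adjusted across regions.  Both sets must be non-empty.
    """
    if not hyper_probes or not hypo_probes:
        raise InputError("region comparison needs non-empty hyper and hypo sets")
    hyper_regions = anno.loc[sorted(hyper_probes), "region"]
    hypo_regions = anno.loc[sorted(hypo_probes), "region"]
    n1, n2 = len(hyper_regions), len(hypo_regions)
    rows = []
    for region in PROBE_REGIONS:
        x1 = int((hyper_regions == region).sum())
        x2 = int((hypo_regions == region).sum())
        if x1 + x2 == 0 or x1 + x2 == n1 + n2:
            z, p = 0.0, 1.0  # pooled proportion degenerate: no contrast
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                z, p = proportions_ztest([x1, x2], [n1, n2])
            if not np.isfinite(p):
                z, p = 0.0, 1.0
        rows.append(
            {
                "region": region,
                "prop_hyper": x1 / n1,
                "prop_hypo": x2 / n2,
                "zstat": float(z),
                "pvalue": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("region")
    out["padj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out
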
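"""Differential expression for count matrices (mRNA and miRNA alike).

The model is the classic two-group negative-binomial exact-test workflow:

1. drop features without cpm > 1 in at least two samples,
2. TMM (trimmed mean of M-values) normalization factors,
3. a single common dispersion phi estimated by conditional maximum
   likelihood on library-equalized pseudo-counts,
4. per-feature conditional exact test of the case-group sum given the total,
5. calls at |log2FC| > 1 and raw p < 0.05 (BH-adjusted p reported alongside).

Counts for feature g in sample j are modelled NB(mu_gj, phi) with
Var = mu + phi mu^2; phi = 0 recovers the Poisson.  Conditional on the total
count T of a feature across both groups, and with per-sample means equalized
by scaling counts to a common library, the case-group sum follows a negative
hypergeometric law that depends only on phi and the group sizes — for phi = 0
it is Binomial(T, n_case / (n_case + n_control)).  Two-sided p-values sum the
probabilities of all outcomes no more likely than the observed one
(probability ordering).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InputError
from .types import CountMatrix

Groups = tuple[Sequence[str], Sequence[str]]


# ------------------------------------------------------------------ cpm -----

def cpm(
    matrix: CountMatrix,
    normalized: bool = False,
    factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Counts per million: count / (lib_size * norm_factor) * 1e6.

    With ``normalized=False`` the factor is 1 for every sample; with
    ``normalized=True`` the supplied TMM ``factors`` are used (computed on the
    fly when absent).
    """
    libs = matrix.lib_sizes
    if (libs <= 0).any():
        raise InputError("zero or negative library size")
    if normalized:
        if factors is None:
            factors = tmm_norm_factors(matrix)
        eff = libs * factors.reindex(libs.index)
    else:
        eff = libs
    return matrix.counts.div(eff, axis=1) * 1e6


def filter_low_expression(
    matrix: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    groups: Optional[Groups] = None,
) -> CountMatrix:
    """Keep features with cpm strictly above ``min_cpm`` in >= ``min_samples``
    samples; all-zero features are always removed.

    By default the sample requirement is evaluated over the combined matrix.
    Passing ``groups`` switches to per-group mode: the requirement must hold
    within each group separately.
    """
    vals = cpm(matrix, normalized=False)
    if groups is None:
        keep = (vals > min_cpm).sum(axis=1) >= min_samples
    else:
        keep = pd.Series(True, index=matrix.features)
        for ids in groups:
            keep &= (vals[list(ids)] > min_cpm).sum(axis=1) >= min_samples
    keep &= matrix.counts.sum(axis=1) > 0
    return CountMatrix(counts=matrix.counts.loc[keep], lib_sizes=matrix.lib_sizes)


# ------------------------------------------------------------------ TMM -----

def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    logratio_trim: float = 0.3, sum_trim: float = 0.05,
) -> float:
    """Weighted trimmed mean of M-values between one sample and the reference.

    Trims 30% from each tail of the M (log-ratio) distribution and 5% from
    each tail of the A (log-abundance) distribution; remaining M-values are
    averaged with inverse approximate-variance weights.
    """
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        warnings.warn("sample shares no expressed features with reference; factor set to 1")
        return 1.0
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_norm_factors(matrix: CountMatrix, ref_sample: Optional[str] = None) -> pd.Series:
    """Per-sample TMM normalization factors, scaled to geometric mean 1.

    The reference sample defaults to the one whose 75th-percentile cpm is
    closest to the across-sample mean of that quantile.
    """
    if matrix.counts.shape[1] < 2:
        raise InputError("TMM needs at least two samples")
    counts = matrix.counts.to_numpy(dtype=float)
    libs = matrix.lib_sizes.to_numpy(dtype=float)
    if ref_sample is None:
        q75 = np.array(
            [np.quantile(counts[:, j] / libs[j], 0.75) for j in range(counts.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if ref_sample not in matrix.samples:
            raise InputError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = int(matrix.samples.get_loc(ref_sample))

    factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref_idx], libs[j], libs[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.samples, name="norm_factor")


# ------------------------------------------------- pseudo-count equalizer ---

def _effective_libs(matrix: CountMatrix, factors: Optional[pd.Series]) -> pd.Series:
    if factors is None:
        return matrix.lib_sizes.astype(float)
    return matrix.lib_sizes * factors.reindex(matrix.lib_sizes.index)


def equalize_counts(matrix: CountMatrix, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Scale counts to the geometric-mean effective library.

    Pseudo-count y' = rint(y * L* / L_j) with L* = geometric mean of the
    effective libraries; rounding is to nearest with ties to even.
    """
    eff = _effective_libs(matrix, factors).to_numpy()
    target = float(np.exp(np.mean(np.log(eff))))
    scaled = matrix.counts.to_numpy(dtype=float) * (target / eff)[None, :]
    return pd.DataFrame(
        np.rint(scaled), index=matrix.features, columns=matrix.samples
    )


# ------------------------------------------------------ common dispersion ---

def _cond_loglik(pseudo_group: np.ndarray, phi: float) -> float:
    """Conditional NB log-likelihood of one group's counts given row totals.

    For a feature with counts y_1..y_n (equal means) and total z the
    conditional likelihood is

        prod_j Gamma(y_j + r) / Gamma(r)  *  Gamma(n r) / Gamma(z + n r)

    up to a phi-free multinomial constant, with r = 1/phi.
    """
    n = pseudo_group.shape[1]
    r = 1.0 / phi
    z = pseudo_group.sum(axis=1)
    ll = (
        gammaln(pseudo_group + r).sum()
        - pseudo_group.shape[0] * n * gammaln(r)
        + pseudo_group.shape[0] * gammaln(n * r)
        - gammaln(z + n * r).sum()
    )
    return float(ll)


def estimate_common_dispersion(
    matrix: CountMatrix,
    groups: Groups,
    factors: Optional[pd.Series] = None,
    phi_max: float = 10.0,
    tol: float = 1e-6,
) -> float:
    """Single dispersion phi maximizing the conditional log-likelihood.

    Counts are first equalized to the geometric-mean effective library; the
    likelihood conditions on each feature's within-group total, which removes
    the per-feature means.  Maximization is a golden-section search on
    [~0, phi_max].
    """
    case_ids, control_ids = list(groups[0]), list(groups[1])
    if not case_ids or not control_ids:
        raise InputError("both groups need at least one sample")
    pseudo = equalize_counts(matrix, factors)
    if pseudo.to_numpy().sum() == 0:
        warnings.warn("all-zero count matrix; dispersion set to 0")
        return 0.0
    blocks = [
        pseudo[case_ids].to_numpy(dtype=float),
        pseudo[control_ids].to_numpy(dtype=float),
    ]
    # single-sample groups carry no conditional information
    blocks = [b for b in blocks if b.shape[1] >= 2]
    if not blocks:
        warnings.warn("no group with >= 2 samples; dispersion set to 0")
        return 0.0

    def objective(phi: float) -> float:
        return sum(_cond_loglik(b, phi) for b in blocks)

    lo, hi = 1e-8, phi_max
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = objective(c), objective(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = objective(d)
    phi_hat = 0.5 * (a + b)
    # prefer the boundary when the likelihood is maximized at (near) zero
    if objective(lo) >= objective(phi_hat):
        return 0.0
    return float(phi_hat)


# ------------------------------------------------------------- exact test ---

def _cond_logpmf(total: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Log-pmf of the case-group sum y = 0..total given the feature total.

    phi > 0: negative hypergeometric with shapes r1 = n1/phi, r2 = n2/phi
    (the NB success probability cancels when conditioning on the total).
    phi = 0: Binomial(total, n1 / (n1 + n2)).
    """
    y = np.arange(total + 1, dtype=float)
    if phi <= 0:
        logw = (
            gammaln(total + 1.0)
            - gammaln(y + 1.0)
            - gammaln(total - y + 1.0)
            + y * np.log(n1 / (n1 + n2))
            + (total - y) * np.log(n2 / (n1 + n2))
        )
    else:
        r1, r2 = n1 / phi, n2 / phi
        logw = (
            gammaln(y + r1)
            - gammaln(y + 1.0)
            + gammaln(total - y + r2)
            - gammaln(total - y + 1.0)
        )
    return logw - logsumexp(logw)


def cond_exact_pvalue(
    s_case: int, s_control: int, n_case: int, n_control: int, phi: float,
    tie_mode: str = "probability",
) -> float:
    """Two-sided conditional exact p-value for one feature.

    ``tie_mode='probability'`` (default) sums outcomes whose conditional
    probability does not exceed the observed outcome's; ``'doubling'`` doubles
    the smaller tail (capped at 1).
    """
    total = int(s_case + s_control)
    if total == 0:
        return 1.0
    logp = _cond_logpmf(total, n_case, n_control, phi)
    obs = int(s_case)
    if tie_mode == "probability":
        mask = logp <= logp[obs] + 1e-10
        return float(min(1.0, np.exp(logsumexp(logp[mask]))))
    if tie_mode == "doubling":
        lower = np.exp(logsumexp(logp[: obs + 1]))
        upper = np.exp(logsumexp(logp[obs:]))
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ConfigError(f"unknown tie_mode {tie_mode!r}")


def exact_test(
    matrix: CountMatrix,
    groups: Groups,
    dispersion: float,
    factors: Optional[pd.Series] = None,
    prior_cpm: float = 0.5,
    tie_mode: str = "probability",
) -> pd.DataFrame:
    """Per-feature conditional NB exact test, case versus control.

    Returns a table with columns log2fc (case over control, with a
    ``prior_cpm`` offset added to both means; set it to 0 for the raw ratio),
    pvalue, padj (BH), and mean_cpm; the common dispersion is stored in
    ``table.attrs['dispersion']``.
    """
    case_ids, control_ids = list(groups[0]), list(groups[1])
    if not case_ids or not control_ids:
        raise InputError("both groups need at least one sample")
    sub = matrix.subset_samples(case_ids + control_ids)
    sub_factors = None if factors is None else factors.loc[case_ids + control_ids]
    pseudo = equalize_counts(sub, sub_factors)
    s_case = pseudo[case_ids].sum(axis=1).to_numpy()
    s_control = pseudo[control_ids].sum(axis=1).to_numpy()
    n1, n2 = len(case_ids), len(control_ids)

    pvals = np.ones(len(pseudo))
    for i, (sc, sk) in enumerate(zip(s_case, s_control)):
        pvals[i] = cond_exact_pvalue(int(sc), int(sk), n1, n2, dispersion, tie_mode)

    vals = cpm(sub, normalized=factors is not None, factors=sub_factors)
    mean_case = vals[case_ids].mean(axis=1)
    mean_control = vals[control_ids].mean(axis=1)
    log2fc = np.log2((mean_case + prior_cpm) / (mean_control + prior_cpm))

    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "mean_cpm": vals.mean(axis=1),
        },
        index=matrix.features,
    )
    table.attrs["dispersion"] = float(dispersion)
    return table


def call_de(
    table: pd.DataFrame, lfc_thresh: float = 1.0, p_thresh: float = 0.05
) -> tuple[set[str], set[str]]:
    """Direction calls at strict thresholds on raw p and |log2FC|.

    Adds a ``call`` column (up/down/ns) in place and returns the up and down
    feature-id sets.
    """
    up = (table["log2fc"] > lfc_thresh) & (table["pvalue"] < p_thresh)
    down = (table["log2fc"] < -lfc_thresh) & (table["pvalue"] < p_thresh)
    call = pd.Series("ns", index=table.index)
    call[up] = "up"
    call[down] = "down"
    table["call"] = call
    return set(table.index[up]), set(table.index[down])


def annotate_tfs(
    up: set[str], down: set[str], tf_list: Sequence[str]
) -> tuple[set[str], set[str]]:
    """Intersect direction calls with a transcription-factor symbol list
    (case-sensitive exact match)."""
    tfs = set(tf_list)
    return up & tfs, down & tfs


def de_analysis(
    matrix: CountMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    min_cpm: float = 1.0,
    min_samples: int = 2,
    per_group_filter: bool = False,
    lfc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    prior_cpm: float = 0.5,
    tie_mode: str = "probability",
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Full two-group workflow: filter, TMM, dispersion, exact test, calls.

    Returns (DE table with call column, up set, down set).
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    sub = matrix.subset_samples(case_ids + control_ids)
    groups = (case_ids, control_ids)
    filtered = filter_low_expression(
        sub, min_cpm=min_cpm, min_samples=min_samples,
        groups=groups if per_group_filter else None,
    )
    if not len(filtered.features):
        raise InputError("no features left after expression filtering")
    factors = tmm_norm_factors(filtered)
    phi = estimate_common_dispersion(filtered, groups, factors)
    table = exact_test(filtered, groups, phi, factors, prior_cpm, tie_mode)
    up, down = call_de(table, lfc_thresh, p_thresh)
    return table, up, down
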
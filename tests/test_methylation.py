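"""Methylation analysis: probe filtering, beta-differences, the moderated
d-statistic, permutation exactness on enumerable designs, calls, and the
region-distribution comparison."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stratomics import methylation as meth
from stratomics.errors import ConfigError, InputError


def make_anno(index, chrom="chr1", gene="GENE1", region="Body", snp=False):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 100,
            "gene_symbol": gene,
            "region": region,
            "snp_within_5bp": snp,
        },
        index=pd.Index(index, name="probe_id"),
    )


def test_filter_probes_toy_counts():
    """Of six probes — one chrX, one SNP-flagged, one gene-less, three clean —
    exactly the three clean autosomal gene-annotated probes survive."""
    probes = [f"p{i}" for i in range(6)]
    anno = make_anno(probes)
    anno.loc["p0", "chrom"] = "chrX"
    anno.loc["p1", "snp_within_5bp"] = True
    anno.loc["p2", "gene_symbol"] = ""
    beta = pd.DataFrame(0.5, index=probes, columns=["a", "b"])
    kept = meth.filter_probes(beta, anno)
    assert list(kept.index) == ["p3", "p4", "p5"]


def test_filter_probes_missing_annotation_names_probe():
    beta = pd.DataFrame(0.5, index=["p0", "p_orphan"], columns=["a"])
    with pytest.raises(InputError, match="p_orphan"):
        meth.filter_probes(beta, make_anno(["p0"]))


@pytest.mark.parametrize(
    "case_vals,control_vals,expected",
    [
        ([0.8, 0.8], [0.5, 0.5], 0.3),
        ([0.5, 0.5], [0.5, 0.5], 0.0),
        ([0.2, 0.4], [0.6, 0.8], -0.4),
    ],
)
def test_beta_difference_arithmetic(case_vals, control_vals, expected):
    beta = pd.DataFrame([case_vals + control_vals], index=["p"],
                        columns=["c1", "c2", "k1", "k2"])
    diff = meth.beta_difference(beta, (["c1", "c2"], ["k1", "k2"]))
    assert diff["p"] == pytest.approx(expected)


def test_sam_statistic_hand_computation():
    """Zero within-group variance: s = 0, so d = mean difference / s0."""
    beta = pd.DataFrame([[1.0, 1.0, 0.0, 0.0]], index=["p"],
                        columns=["c1", "c2", "k1", "k2"])
    d, s0 = meth.sam_statistic(beta, (["c1", "c2"], ["k1", "k2"]), s0=0.5)
    assert d["p"] == pytest.approx(2.0)
    assert s0 == 0.5


def test_sam_statistic_zero_for_equal_means_and_linear_in_shift():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.3, 0.7, size=(5, 4))
    cols = ["c1", "c2", "k1", "k2"]
    beta = pd.DataFrame(base, index=[f"p{i}" for i in range(5)], columns=cols)
    groups = (["c1", "c2"], ["k1", "k2"])
    d1, s0 = meth.sam_statistic(beta, groups)
    shifted = beta.copy()
    shifted[["c1", "c2"]] += 0.1
    d2, _ = meth.sam_statistic(shifted, groups, s0=s0)
    # adding a constant to the case group leaves s unchanged and shifts the
    # numerator by 0.1
    same = beta.copy()
    same[["c1", "c2"]] = same[["k1", "k2"]].to_numpy()
    d0, _ = meth.sam_statistic(same, groups, s0=s0)
    assert np.allclose(d0, 0.0)
    assert (d2 > d1 - 1e-12).all()


def test_permutation_full_enumeration_extreme_split():
    """Groups of 2+2 with a perfectly separated probe: of the C(4,2)=6 label
    assignments only the observed one and its complement reach |d|, p = 2/6."""
    beta = pd.DataFrame([[1.0, 1.0, 0.0, 0.0]], index=["p"],
                        columns=["c1", "c2", "k1", "k2"])
    p = meth.permutation_pvalues(beta, (["c1", "c2"], ["k1", "k2"]), n_perm=100, seed=0)
    assert p["p"] == pytest.approx(2 / 6)


def test_permutation_constant_probe_p_one():
    beta = pd.DataFrame([[0.4] * 6], index=["p"],
                        columns=["c1", "c2", "c3", "k1", "k2", "k3"])
    p = meth.permutation_pvalues(beta, (["c1", "c2", "c3"], ["k1", "k2", "k3"]),
                                 n_perm=100, seed=0)
    assert p["p"] == 1.0


def test_permutation_matches_brute_force_on_small_random_matrix():
    """For enumerable designs the permutation p equals the exhaustive count
    computed independently with a plain loop."""
    rng = np.random.default_rng(5)
    n1, n2 = 3, 4
    cols = [f"s{i}" for i in range(n1 + n2)]
    beta = pd.DataFrame(rng.uniform(0, 1, size=(6, n1 + n2)), columns=cols,
                        index=[f"p{i}" for i in range(6)])
    groups = (cols[:n1], cols[n1:])
    p = meth.permutation_pvalues(beta, groups, n_perm=10_000, seed=0)

    x = beta.to_numpy()

    def d_stat(case_idx):
        case_idx = np.array(case_idx)
        ctrl_idx = np.setdiff1d(np.arange(n1 + n2), case_idx)
        x1, x2 = x[:, case_idx], x[:, ctrl_idx]
        m1, m2 = x1.mean(1), x2.mean(1)
        ss = ((x1 - m1[:, None]) ** 2).sum(1) + ((x2 - m2[:, None]) ** 2).sum(1)
        s = np.sqrt((1 / n1 + 1 / n2) / (n1 + n2 - 2) * ss)
        s0 = np.median(s)
        return (m1 - m2) / (s + s0)

    obs = np.abs(d_stat(range(n1)))
    splits = list(combinations(range(n1 + n2), n1))
    assert len(splits) == math.comb(n1 + n2, n1)
    counts = np.zeros(6)
    for split in splits:
        counts += np.abs(d_stat(split)) >= obs * (1 - 1e-12)
    np.testing.assert_allclose(p.to_numpy(), counts / len(splits), atol=1e-12)


def test_permutation_rejects_bad_n_perm():
    beta = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["p"],
                        columns=["c1", "c2", "k1", "k2"])
    with pytest.raises(ConfigError):
        meth.permutation_pvalues(beta, (["c1", "c2"], ["k1", "k2"]), n_perm=0)


# ------------------------------------------------------------------ calls ---

def test_call_dm_thresholds_and_gene_summary():
    probes = ["h1", "h2", "b1", "b2", "lo"]
    table = pd.DataFrame(
        {
            "beta_diff": [0.2, 0.25, 0.15, 0.2, -0.3],
            "pvalue": [0.005, 0.001, 0.001, 0.02, 0.001],
        },
        index=probes,
    )
    anno = make_anno(probes)
    anno.loc[["h1", "h2"], "gene_symbol"] = "SHARED"  # two probes, one gene
    anno.loc["lo", "gene_symbol"] = "LOW"
    hyper_p, hypo_p, hyper_g, hypo_g = meth.call_dm(table, anno)
    assert hyper_p == {"h1", "h2"}          # b1 fails strict delta, b2 fails p
    assert hypo_p == {"lo"}
    assert hyper_g == {"SHARED"}            # set semantics: genes <= probes
    assert hypo_g == {"LOW"}


def test_call_dm_sign_flip_swaps_hyper_hypo():
    rng = np.random.default_rng(1)
    table = pd.DataFrame(
        {
            "beta_diff": rng.uniform(-0.5, 0.5, 40),
            "pvalue": rng.uniform(0, 0.05, 40),
        },
        index=[f"p{i}" for i in range(40)],
    )
    anno = make_anno(table.index, gene="G")
    hyper1, hypo1, _, _ = meth.call_dm(table.copy(), anno)
    flipped = table.copy()
    flipped["beta_diff"] *= -1
    hyper2, hypo2, _, _ = meth.call_dm(flipped, anno)
    assert hyper1 == hypo2 and hypo1 == hyper2


def test_multigene_probe_annotation_split():
    table = pd.DataFrame({"beta_diff": [0.3], "pvalue": [0.001]}, index=["p"])
    anno = make_anno(["p"], gene="A;B")
    _, _, hyper_g, _ = meth.call_dm(table, anno)
    assert hyper_g == {"A", "B"}


# ----------------------------------------------------------------- region ---

def test_region_distribution_identical_sets_flat():
    probes = [f"p{i}" for i in range(20)]
    anno = make_anno(probes)
    anno.loc[probes[:10], "region"] = "Body"
    anno.loc[probes[10:], "region"] = "IGR"
    hyper = set(probes[:5] + probes[10:15])
    hypo = set(probes[5:10] + probes[15:])
    out = meth.region_distribution_test(hyper, hypo, anno)
    assert out["pvalue"].min() > 0.99
    assert out["prop_hyper"].sum() == pytest.approx(1.0)
    assert out["prop_hypo"].sum() == pytest.approx(1.0)


def test_region_distribution_extreme_contrast():
    """50 hyper probes all in gene bodies vs 50 hypo probes all intergenic:
    the two-proportion z on Body is 50/50 vs 0/50, p far below 0.001."""
    hyper_probes = [f"h{i}" for i in range(50)]
    hypo_probes = [f"l{i}" for i in range(50)]
    anno = pd.concat([
        make_anno(hyper_probes, region="Body"),
        make_anno(hypo_probes, region="IGR"),
    ])
    out = meth.region_distribution_test(set(hyper_probes), set(hypo_probes), anno)
    assert out.loc["Body", "pvalue"] < 1e-3
    assert out.loc["IGR", "pvalue"] < 1e-3


def test_region_distribution_requires_both_sets():
    anno = make_anno(["p0"])
    with pytest.raises(InputError):
        meth.region_distribution_test(set(), {"p0"}, anno)
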
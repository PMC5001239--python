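"""Co-expression network construction: correlations, top-fraction selection
with ties, PPI intersection, projection, core extraction, degree filter."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratomics import network as net
from stratomics.errors import ConfigError, InputError


def expr_frame(rows, samples):
    return pd.DataFrame(rows, columns=samples)


def test_pearson_hand_computation():
    expr = pd.DataFrame([[1, 2, 3], [3, 2, 4]], index=["x", "y"], columns=list("abc"))
    pairs = net.pearson_pairs(expr)
    assert len(pairs) == 1  # no self-pairs
    assert pairs.loc[0, "r"] == pytest.approx(0.5)


def test_pearson_affine_invariance():
    x = np.array([1.0, 4.0, 2.0, 8.0])
    expr = pd.DataFrame([x, 2 * x + 1], index=["x", "y"], columns=list("abcd"))
    pairs = net.pearson_pairs(expr)
    assert pairs.loc[0, "r"] == pytest.approx(1.0)


def test_pearson_requires_three_samples_and_drops_constant_features():
    expr = pd.DataFrame([[1, 2], [2, 3]], index=["x", "y"], columns=list("ab"))
    with pytest.raises(InputError):
        net.pearson_pairs(expr)
    expr3 = pd.DataFrame([[1, 2, 3], [5, 5, 5], [2, 1, 3]],
                         index=["x", "const", "y"], columns=list("abc"))
    with pytest.warns(UserWarning):
        pairs = net.pearson_pairs(expr3)
    assert set(pairs["gene_a"]) | set(pairs["gene_b"]) == {"x", "y"}


def test_pearson_blockwise_matches_full():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(size=(30, 8)),
                        index=[f"g{i}" for i in range(30)])
    a = net.pearson_pairs(expr, block_size=4).sort_values(["gene_a", "gene_b"])
    b = net.pearson_pairs(expr, block_size=1000).sort_values(["gene_a", "gene_b"])
    np.testing.assert_allclose(a["r"].to_numpy(), b["r"].to_numpy(), atol=1e-12)


def test_top_fraction_tie_rule():
    """Twenty pairs, fraction 0.1 nominally keeps 2, but the tie at the
    cutoff score pulls in a third."""
    scores = [0.9, 0.8, 0.8] + list(np.linspace(0.1, 0.7, 17))
    pairs = pd.DataFrame({"gene_a": "a", "gene_b": [f"b{i}" for i in range(20)],
                          "r": scores})
    out = net.top_fraction_pairs(pairs, fraction=0.1)
    assert len(out) == 3


def test_top_fraction_modes_and_bounds():
    pairs = pd.DataFrame({"gene_a": "a", "gene_b": ["b", "c", "d"],
                          "r": [-0.9, 0.5, 0.1]})
    absolute = net.top_fraction_pairs(pairs, fraction=0.33, mode="absolute")
    signed = net.top_fraction_pairs(pairs, fraction=0.33, mode="signed")
    assert list(absolute["r"]) == [-0.9]
    assert list(signed["r"]) == [0.5]
    assert len(net.top_fraction_pairs(pairs, fraction=1.0)) == 3
    with pytest.raises(ConfigError):
        net.top_fraction_pairs(pairs, fraction=0.0)


def test_build_background_intersection():
    pairs = pd.DataFrame({"gene_a": ["A", "B"], "gene_b": ["B", "C"],
                          "r": [0.9, 0.8]})
    ppi = pd.DataFrame({"gene_a": ["C", "C"], "gene_b": ["B", "D"]})
    g = net.build_background(pairs, ppi)
    assert set(map(frozenset, g.edges)) == {frozenset({"B", "C"})}
    assert "D" not in g  # isolated nodes dropped
    with pytest.warns(UserWarning):
        empty = net.build_background(pairs, pd.DataFrame({"gene_a": [], "gene_b": []}))
    assert empty.number_of_edges() == 0


def test_project_subnetwork_induced_property():
    rng = np.random.default_rng(1)
    background = nx.gnp_random_graph(25, 0.2, seed=3)
    background = nx.relabel_nodes(background, {i: f"g{i}" for i in background})
    genes = {f"g{i}" for i in rng.choice(25, size=12, replace=False)}
    sub = net.project_subnetwork(background, genes)
    for a, b in sub.edges:
        assert background.has_edge(a, b)
    expected = {frozenset(e) for e in background.subgraph(genes).edges}
    assert {frozenset(e) for e in sub.edges} == expected


def test_project_subnetwork_mirna_attachment():
    background = nx.Graph([("A", "B")])
    sub = net.project_subnetwork(background, {"A", "B"}, ["m1", "m2"],
                                 {"m1": {"A"}, "m2": {"Z"}})
    assert sub.nodes["m1"]["node_type"] == "mirna"
    assert sub.edges["m1", "A"]["source"] == "mirna_target"
    assert "m2" not in sub  # no retained target
    empty = net.project_subnetwork(background, {"X"}, ["m1"], {"m1": {"A"}})
    assert empty.number_of_nodes() == 0


def test_core_network_neighbor_definition():
    g = nx.Graph([("A", "B"), ("B", "C")])
    core = net.core_network(g, {"A"})
    assert set(core.nodes) == {"A", "B"}
    assert core.nodes["A"]["hyper_down"] is True
    assert core.nodes["B"]["hyper_down"] is False
    ident = net.core_network(g, {"A", "B", "C"})
    assert set(ident.nodes) == {"A", "B", "C"}


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_core_network_equals_closed_neighborhood(seed):
    """On random graphs the core equals the brute-force closed neighborhood
    of the seeds, and re-extracting with the same seeds is idempotent."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(15, 0.25, seed=int(rng.integers(1 << 30)))
    seeds = set(rng.choice(15, size=3, replace=False).tolist())
    core = net.core_network(g, seeds)
    closed = set(seeds) | {n for s in seeds for n in g.neighbors(s)}
    assert set(core.nodes) == closed
    again = net.core_network(core, seeds)
    assert set(again.nodes) == set(core.nodes)
    assert set(map(frozenset, again.edges)) == set(map(frozenset, core.edges))


def test_core_network_without_seeds_warns_empty():
    g = nx.Graph([("A", "B")])
    with pytest.warns(UserWarning):
        core = net.core_network(g, {"Z"})
    assert core.number_of_nodes() == 0


@pytest.mark.parametrize(
    "edges,expected_nodes",
    [
        # star: center degree 4 survives, leaves (degree 1) removed
        ([("c", "l1"), ("c", "l2"), ("c", "l3"), ("c", "l4")], {"c"}),
        # 4-clique: all degree 3, unchanged
        ([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")],
         {"a", "b", "c", "d"}),
        # path: max degree 2, everything removed
        ([("a", "b"), ("b", "c"), ("c", "d")], set()),
    ],
)
def test_filter_by_degree_fixtures(edges, expected_nodes):
    g = nx.Graph(edges)
    out = net.filter_by_degree(g, min_degree=3)
    assert set(out.nodes) == expected_nodes


def test_filter_by_degree_single_pass_vs_kcore():
    # two triangles sharing a chain: single pass keeps degree>=2 nodes once,
    # k-core recurses
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")])
    single = net.filter_by_degree(g, min_degree=2)
    assert set(single.nodes) == {"a", "b", "c", "d"}
    core = net.filter_by_degree(g, min_degree=2, iterative=True)
    assert set(core.nodes) == {"a", "b", "c"}
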
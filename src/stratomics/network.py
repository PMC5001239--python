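"""Mutation-specific co-expression networks on a PPI scaffold.

The background network keeps gene pairs that are simultaneously among the
top-fraction Pearson-correlated pairs (computed on case-group expression) and
present in the reference protein-protein interaction graph.  Differential
gene sets are projected onto it as induced subgraphs, miRNAs join through
their targets, and the core network is the closed neighborhood of the
hyper-down seed genes.  A final single-pass degree filter mirrors the usual
display rule (degree >= 3).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, InputError


def pearson_pairs(
    expr: pd.DataFrame, block_size: int = 512
) -> pd.DataFrame:
    """Pearson r for every unordered feature pair of a feature-by-sample
    matrix, computed in row blocks so the working set stays bounded.

    Zero-variance features are dropped with a warning; needs >= 3 samples.
    Returns a DataFrame with columns gene_a, gene_b, r.
    """
    if expr.shape[1] < 3:
        raise InputError("correlation needs at least 3 samples")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance features dropped")
    x = x[keep]
    names = expr.index[keep].to_numpy()
    n_feat, n_samp = x.shape
    z = (x - x.mean(axis=1, keepdims=True)) / (sd[keep][:, None] * np.sqrt(n_samp))

    frames = []
    for start in range(0, n_feat, block_size):
        stop = min(start + block_size, n_feat)
        block = z[start:stop] @ z.T  # (stop-start) x n_feat correlations
        for offset in range(stop - start):
            i = start + offset
            r = np.clip(block[offset, i + 1 :], -1.0, 1.0)
            if r.size:
                frames.append(
                    pd.DataFrame(
                        {
                            "gene_a": names[i],
                            "gene_b": names[i + 1 :],
                            "r": r,
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    return pd.concat(frames, ignore_index=True)


def top_fraction_pairs(
    pairs: pd.DataFrame, fraction: float = 0.05, mode: str = "absolute"
) -> pd.DataFrame:
    """The ceil(fraction * n) pairs with the largest score, ties included.

    Score is r in ``signed`` mode and |r| in ``absolute`` mode.  All pairs
    tied with the cutoff score are kept, so the result may exceed the nominal
    count.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigError("fraction must be in (0, 1]")
    if mode not in ("signed", "absolute"):
        raise ConfigError(f"unknown mode {mode!r}")
    if not len(pairs):
        raise InputError("no pairs to rank")
    score = pairs["r"].abs() if mode == "absolute" else pairs["r"]
    m = int(np.ceil(fraction * len(pairs)))
    cutoff = np.sort(score.to_numpy())[::-1][m - 1]
    return pairs.loc[score >= cutoff].reset_index(drop=True)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_background(pairs: pd.DataFrame, ppi: pd.DataFrame) -> nx.Graph:
    """Co-expression pairs intersected with PPI edges (undirected match).

    Nodes are only those carried by surviving edges, so isolated nodes never
    appear.  Edge attributes: source='coexpression', r = correlation.
    """
    ppi_keys = {
        _edge_key(a, b) for a, b in zip(ppi["gene_a"], ppi["gene_b"]) if a != b
    }
    g = nx.Graph()
    for a, b, r in zip(pairs["gene_a"], pairs["gene_b"], pairs["r"]):
        if a != b and _edge_key(a, b) in ppi_keys:
            g.add_edge(a, b, source="coexpression", r=float(r))
    if g.number_of_edges() == 0:
        warnings.warn("co-expression pairs and PPI share no edges; background is empty")
    nx.set_node_attributes(g, "gene", "node_type")
    return g


def project_subnetwork(
    background: nx.Graph,
    gene_set: Iterable[str],
    mirnas: Iterable[str] = (),
    target_map: Optional[Mapping[str, set[str]]] = None,
    direction: str = "none",
) -> nx.Graph:
    """Induced subgraph on ``gene_set``, plus miRNA nodes wired to their
    retained targets.

    Every gene-gene edge of the output exists in the background; miRNA edges
    carry source='mirna_target'.  Node attributes: node_type, direction.
    """
    genes = set(gene_set) & set(background.nodes)
    sub = nx.Graph(background.subgraph(genes).copy())
    nx.set_node_attributes(sub, "gene", "node_type")
    nx.set_node_attributes(sub, direction, "direction")
    if target_map:
        for m in mirnas:
            hits = target_map.get(m, set()) & genes
            for gene in hits:
                sub.add_node(m, node_type="mirna", direction="none")
                sub.add_edge(m, gene, source="mirna_target")
    return sub


def core_network(subnetwork: nx.Graph, seed_genes: Iterable[str]) -> nx.Graph:
    """Induced subgraph on the closed neighborhood of the seed genes.

    Seeds present in the subnetwork are flagged ``hyper_down=True``; with no
    seed present the result is an empty graph (with a warning).
    """
    seeds = set(seed_genes) & set(subnetwork.nodes)
    if not seeds:
        warnings.warn("no seed gene present in subnetwork; core network is empty")
        return nx.Graph()
    nodes = set(seeds)
    for s in seeds:
        nodes.update(subnetwork.neighbors(s))
    core = nx.Graph(subnetwork.subgraph(nodes).copy())
    nx.set_node_attributes(core, {n: n in seeds for n in core.nodes}, "hyper_down")
    return core


def filter_by_degree(network: nx.Graph, min_degree: int = 3, iterative: bool = False) -> nx.Graph:
    """Remove nodes below ``min_degree``.

    The default is a single pass on the degrees of the input network (a
    display filter): surviving nodes may end up with lower degree afterwards.
    ``iterative=True`` switches to the k-core instead.
    """
    if iterative:
        return nx.Graph(nx.k_core(network, k=min_degree))
    keep = [n for n, d in network.degree() if d >= min_degree]
    return nx.Graph(network.subgraph(keep).copy())


def network_tables(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a network as (edge table, node-attribute table)."""
    edges = pd.DataFrame(
        [
            {"node_a": a, "node_b": b, "source": d.get("source", ""), "r": d.get("r", "")}
            for a, b, d in sorted(g.edges(data=True), key=lambda e: _edge_key(e[0], e[1]))
        ],
        columns=["node_a", "node_b", "source", "r"],
    )
    nodes = pd.DataFrame(
        [
            {
                "node": n,
                "node_type": d.get("node_type", "gene"),
                "direction": d.get("direction", "none"),
                "hyper_down": bool(d.get("hyper_down", False)),
            }
            for n, d in sorted(g.nodes(data=True))
        ],
        columns=["node", "node_type", "direction", "hyper_down"],
    )
    return edges, nodes


def coexpression_analysis(
    expr_log_cpm: pd.DataFrame,
    case_ids: Sequence[str],
    ppi: pd.DataFrame,
    fraction: float = 0.05,
    mode: str = "absolute",
) -> nx.Graph:
    """Background network from case-sample expression and a PPI edge list."""
    pairs = pearson_pairs(expr_log_cpm[list(case_ids)])
    if not len(pairs):
        raise InputError("no feature pairs available for correlation")
    top = top_fraction_pairs(pairs, fraction=fraction, mode=mode)
    return build_background(top, ppi)
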
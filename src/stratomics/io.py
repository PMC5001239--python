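"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular files are tab-separated with a mandatory header row and ``#``
comment lines (GMT excepted: it is the standard headerless three-plus-column
format).  Writers accept an optional ``header_comment`` so the pipeline can
stamp its configuration hash into every artifact; readers skip comments.
Round-tripping ``write(read(x))`` preserves content and column order.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .types import CountMatrix, GeneSetCatalog, MAF_CLASS_MAP, MutationTable


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise InputError(f"{path}: malformed TSV ({exc})") from exc


def _write_tsv(frame: pd.DataFrame, path, header_comment: Optional[str] = None,
               index: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------- counts ----

def read_counts_tsv(path) -> CountMatrix:
    """Read a feature-by-sample integer count matrix.

    First column holds feature ids; remaining columns are samples.
    """
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate feature id {dup!r}")
    try:
        counts = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise InputError(f"{path}: non-integer cell in count matrix ({exc})") from exc
    return CountMatrix(counts=counts)


def write_counts_tsv(matrix: CountMatrix, path, header_comment: Optional[str] = None) -> None:
    frame = matrix.counts.copy()
    frame.index.name = frame.index.name or "feature"
    _write_tsv(frame, path, header_comment)


# ------------------------------------------------------------ methylation ---

def read_beta_tsv(path) -> pd.DataFrame:
    """Read a probe-by-sample beta-value matrix (values in [0, 1])."""
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate probe id {dup!r}")
    try:
        beta = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise InputError(f"{path}: non-numeric cell in beta matrix ({exc})") from exc
    vals = beta.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and ((finite < 0) | (finite > 1)).any():
        raise InputError(f"{path}: beta values outside [0, 1]")
    return beta


def write_beta_tsv(beta: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    frame = beta.copy()
    frame.index.name = frame.index.name or "probe_id"
    _write_tsv(frame, path, header_comment)


ANNO_COLUMNS = ["chrom", "pos", "gene_symbol", "region", "snp_within_5bp"]


def read_probe_annotation(path) -> pd.DataFrame:
    """Read a probe annotation table indexed by probe id.

    Columns: chrom, pos (1-based), gene_symbol (may be empty), region label,
    snp_within_5bp flag.
    """
    df = _read_tsv(path, index_col=0, dtype={"gene_symbol": "string"})
    missing = [c for c in ANNO_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: annotation missing columns {missing}")
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    df["snp_within_5bp"] = df["snp_within_5bp"].astype(bool)
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise InputError(f"{path}: annotation positions must be 1-based (>= 1)")
    return df


def write_probe_annotation(anno: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    frame = anno.copy()
    frame.index.name = frame.index.name or "probe_id"
    _write_tsv(frame, path, header_comment)


# ------------------------------------------------------------------- MAF ----

def read_maf(path, samples: Optional[Iterable[str]] = None) -> MutationTable:
    """Read a MAF-like variant table.

    Accepts either the package's own column names (sample_id, gene_symbol,
    variant_class, protein_pos) or standard MAF headers (Tumor_Sample_Barcode,
    Hugo_Symbol, Variant_Classification, Protein_position). Unknown variant
    classification strings map to 'other' with a warning. When no explicit
    roster is given, the samples are those seen in the file.
    """
    df = _read_tsv(path, dtype=str)
    rename = {
        "Tumor_Sample_Barcode": "sample_id",
        "Hugo_Symbol": "gene_symbol",
        "Variant_Classification": "variant_class",
        "Protein_position": "protein_pos",
    }
    df = df.rename(columns=rename)
    for col in ("sample_id", "gene_symbol", "variant_class"):
        if col not in df.columns:
            raise InputError(f"{path}: MAF missing column {col!r}")
    if "protein_pos" not in df.columns:
        df["protein_pos"] = pd.NA

    def map_class(value: str) -> str:
        mapped = MAF_CLASS_MAP.get(value)
        if mapped is None:
            warnings.warn(
                f"unknown Variant_Classification {value!r} mapped to 'other'",
                stacklevel=2,
            )
            return "other"
        return mapped

    df["variant_class"] = df["variant_class"].map(map_class)
    df["sample_id"] = df["sample_id"].str.strip()
    df["gene_symbol"] = df["gene_symbol"].str.strip()
    df["protein_pos"] = pd.to_numeric(df["protein_pos"], errors="coerce").astype("Int64")
    df = df[["sample_id", "gene_symbol", "variant_class", "protein_pos"]]
    return MutationTable.from_records(df, samples=samples)


def write_maf(table: MutationTable, path, header_comment: Optional[str] = None) -> None:
    _write_tsv(table.records, path, header_comment, index=False)


# ------------------------------------------------------------ set tables ----

def read_target_map(path) -> dict[str, set[str]]:
    """Read a two-column miRNA -> target-gene table into a dict of sets.

    Empty target sets are never stored (a miRNA with no rows is simply absent).
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: target map needs two columns (mirna_id, gene_symbol)")
    mirna_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for mirna, gene in zip(df[mirna_col], df[gene_col]):
        out.setdefault(mirna, set()).add(gene)
    return out


def write_target_map(target_map: dict[str, set[str]], path,
                     header_comment: Optional[str] = None) -> None:
    rows = [
        {"mirna_id": m, "gene_symbol": g}
        for m in sorted(target_map)
        for g in sorted(target_map[m])
    ]
    _write_tsv(pd.DataFrame(rows, columns=["mirna_id", "gene_symbol"]), path,
               header_comment, index=False)


def read_gmt(path, universe: Optional[Iterable[str]] = None) -> GeneSetCatalog:
    """Read a GMT catalog: one term per line, ``term<TAB>description<TAB>genes...``.

    The catalog universe defaults to the union of all member genes; pass an
    explicit background to override (members are then restricted to it by
    :meth:`GeneSetCatalog.restricted` at enrichment time, not here).
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    members_union: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in terms:
                raise InputError(f"{path}:{lineno}: duplicate term id {term!r}")
            terms[term] = (desc, frozenset(genes))
            members_union.update(genes)
    uni = frozenset(universe) if universe is not None else frozenset(members_union)
    return GeneSetCatalog(terms=terms, universe=uni)


def write_gmt(catalog: GeneSetCatalog, path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in catalog.terms.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def read_ppi(path) -> pd.DataFrame:
    """Read an undirected PPI edge list (columns gene_a, gene_b).

    Self-loops and duplicate undirected edges are dropped.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: PPI edge list needs two columns")
    a, b = df.columns[:2]
    df = df.rename(columns={a: "gene_a", b: "gene_b"})[["gene_a", "gene_b"]]
    df = df[df["gene_a"] != df["gene_b"]]
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    df = df.loc[~key.duplicated()].reset_index(drop=True)
    return df


def write_ppi(edges: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    _write_tsv(edges[["gene_a", "gene_b"]], path, header_comment, index=False)


def read_gene_list(path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_id_list(path) -> list[str]:
    return read_gene_list(path)
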
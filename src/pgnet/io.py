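"""Readers and writers for the plain-text formats used across the pipeline.

All tabular formats are tab-separated with a header line.  BED-like
interval files are 0-based half-open; variant positions are 1-based.
Readers are gzip-transparent (pandas ``compression='infer'``).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: Required columns of a summary-statistics table, in canonical order.
SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
]

GENE_ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene"]


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS/pQTL summary-statistics TSV.

    Validates the required header and, per record, warns (never fails)
    when the stored p-value is inconsistent with ``beta/se`` under a
    two-sided normal test by more than 10% relative error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("summary statistics contain non-positive SE")
    _warn_p_inconsistent(df)
    return df


def _warn_p_inconsistent(df: pd.DataFrame, rtol: float = 0.10) -> None:
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
    expected = 2.0 * norm.sf(z)
    p = df["p"].to_numpy(dtype=float)
    # only meaningful where the expected p is representable
    ok = expected > 1e-300
    bad = ok & (np.abs(p - expected) > rtol * np.maximum(expected, 1e-300))
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} records have p inconsistent with beta/se "
            "beyond 10% relative tolerance",
            stacklevel=3,
        )


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SUMSTATS_COLUMNS)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene annotation (chrom, start, end, gene)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENE_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene annotation missing columns: {missing}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene annotation has start >= end (0-based half-open)")
    return df


def write_gene_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=GENE_ANNOTATION_COLUMNS)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column PPI edge-list TSV (header optional).

    Raises a parse error naming the offending line number.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed edge line {lineno}: {line!r}")
            if lineno == 1 and parts[0].lower() in {"node_a", "source", "protein_a"}:
                continue
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(graph_or_edges, path: str | Path) -> None:
    if isinstance(graph_or_edges, nx.Graph):
        edges: Iterable = graph_or_edges.edges()
    else:
        edges = graph_or_edges
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}")
            sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


LOOP_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "cell_type",
    "genes1",
    "genes2",
]


def read_loops(path: str | Path) -> pd.DataFrame:
    """Read paired chromatin-loop anchors (BED-like, 0-based half-open).

    ``genes1``/``genes2`` are ;-joined gene symbols annotated to each anchor.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom1": str, "chrom2": str}, keep_default_na=False
    )
    missing = [c for c in LOOP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"loop file missing columns: {missing}")
    for s, e in (("start1", "end1"), ("start2", "end2")):
        if (df[s] >= df[e]).any():
            raise ValueError("loop anchors must satisfy start < end")
    if (df["chrom1"].str.replace("chr", "") != df["chrom2"].str.replace("chr", "")).any():
        raise ValueError("loop anchors must share a chromosome")
    return df


def write_loops(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=LOOP_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
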
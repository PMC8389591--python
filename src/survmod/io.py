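"""Tabular and graph I/O.

All tables are TSV with headers; graphs are edge-list TSV (u, v[, weight])
or GraphML via networkx; gene sets use the standard GMT layout
(name <tab> description <tab> gene ...).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV; first column is the gene identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    df.index = df.index.astype(str)
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_survival(path) -> pd.DataFrame:
    """Columns sample_id, time, event (0 censored / 1 death)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in survival table")
    if (df["time"] < 0).any() or not np.isfinite(df["time"]).all():
        raise ValueError("survival times must be finite and non-negative")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return df


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_classes(path) -> pd.Series:
    """Columns sample_id, class (tumor/normal)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "class"}.issubset(df.columns):
        raise ValueError("sample-class table needs columns sample_id, class")
    return df.set_index("sample_id")["class"]


def write_sample_classes(classes: pd.Series, path) -> None:
    classes.rename("class").to_csv(path, sep="\t", index_label="sample_id")


def read_edge_list(path, min_weight: float | None = None) -> nx.Graph:
    """Edge-list TSV with columns u, v and optionally weight.

    ``min_weight`` keeps only edges whose weight column exceeds it (the
    scaffold-confidence filter applied to e.g. STRING-style scores).
    """
    path = Path(path)
    if path.suffix == ".graphml":
        return nx.read_graphml(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("edge list needs at least two columns")
    G = nx.Graph()
    for _, row in df.iterrows():
        u, v = str(row[cols[0]]), str(row[cols[1]])
        attrs = {}
        if len(cols) > 2 and pd.notna(row[cols[2]]):
            w = float(row[cols[2]])
            if min_weight is not None and w <= min_weight:
                continue
            attrs["weight"] = w
        G.add_edge(u, v, **attrs)
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    rows = [
        {"u": min(u, v), "v": max(u, v), "weight": d.get("weight", 1.0)}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["u", "v", "weight"]).sort_values(["u", "v"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def read_gene_list(path) -> list[str]:
    """One-column (or first-column) gene list TSV, header optional via 'gene'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    col = "gene" if "gene" in df.columns else df.columns[0]
    return df[col].dropna().tolist()


def write_gene_list(genes, path) -> None:
    pd.DataFrame({"gene": sorted(genes)}).to_csv(path, sep="\t", index=False)
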
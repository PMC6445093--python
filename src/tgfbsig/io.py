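"""Readers and writers for the pipeline's on-disk dialects.

All formats are plain text: tab-separated quantification tables,
STRING-dialect edge lists (``protein1 protein2 combined_score``),
curated 2-column edge lists, GMT annotation files, the survival CSV and
the ground-truth JSON.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    """Peptide quantification table (one cohort)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "protein_symbol", "n_mapped_proteins",
                "peptide_score", "abundance_M", "abundance_nonM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_mouse_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_cellline_tsv(path: str | Path) -> pd.DataFrame:
    """Spectral-count matrix, proteins as rows."""
    return pd.read_csv(path, sep="\t").set_index("protein_symbol")


def read_secretome_tsv(path: str | Path) -> pd.DataFrame:
    """Two-pair conditioned-media ratio table."""
    return pd.read_csv(path, sep="\t").set_index("protein_symbol")


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")


def write_edges_tsv(graph: nx.Graph, path: str | Path) -> None:
    """STRING-dialect edge list; node order within an edge is sorted so
    a write/load round trip is exact."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\t{graph.edges[u, v]['confidence']}\n")


def write_gmt(annotation: Mapping[str, set], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            members = "\t".join(sorted(annotation[term]))
            fh.write(f"{term}\tsynthetic\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, set]:
    """GMT-style annotation: term, description, member symbols."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            out[parts[0]] = set(parts[2:])
    return out


def read_symbol_list(path: str | Path) -> list[str]:
    """One symbol per line, blank lines and #-comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
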
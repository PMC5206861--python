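"""Bipartite miRNA-mRNA regulatory network construction and filtering.

Edges come from target-prediction databases (TargetScan-like tables of
miRNA -> gene records); duplicate predictions of the same pair by several
databases collapse into one edge whose ``support`` counts the distinct
databases.  Gene nodes can be pruned by a minimum-targeting rule ("keep only
genes targeted by at least k of the differential miRNAs"), the filter used
to restrict a regulatory network to its most relevant interactions.
Consensus targets are genes predicted for a miRNA by at least a stated
number of independent databases.  Networks export to SIF and GraphML for
Cytoscape-style visualization.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "TargetEdgeTable",
    "build_bipartite",
    "filter_min_targeting",
    "consensus_targets",
    "annotate_nodes",
    "export_network",
    "load_network",
    "network_summary",
]

EDGE_RELATION = "targets"


@dataclass(frozen=True)
class TargetEdgeTable:
    """miRNA -> gene prediction records from one or more databases.

    Columns: ``mirna``, ``gene``, ``db`` and optionally ``score``.
    Duplicate (mirna, gene, db) triples collapse on load; ids must be
    non-empty strings.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mirna", "gene", "db"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"edge table missing column(s): {sorted(missing)}")
        rec = self.records
        for col in ("mirna", "gene", "db"):
            if rec[col].astype(str).str.len().eq(0).any() or rec[col].isna().any():
                raise ValueError(f"empty id in column {col!r}")
        deduped = rec.drop_duplicates(subset=["mirna", "gene", "db"])
        object.__setattr__(self, "records", deduped.reset_index(drop=True))

    @property
    def databases(self) -> list[str]:
        return sorted(self.records["db"].unique())

    def genes_of(self, mirna: str) -> set[str]:
        return set(self.records.loc[self.records["mirna"] == mirna, "gene"])

    def write_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TargetEdgeTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"mirna": str,
                                                      "gene": str,
                                                      "db": str}))

    @classmethod
    def concat(cls, tables: Sequence["TargetEdgeTable"]) -> "TargetEdgeTable":
        return cls(pd.concat([t.records for t in tables], ignore_index=True))


def build_bipartite(
    edges: TargetEdgeTable | Sequence[TargetEdgeTable],
    mirna_directions: Mapping[str, str],
) -> nx.Graph:
    """Build the regulatory network restricted to a differential miRNA set.

    Only edges whose miRNA appears in ``mirna_directions`` (id -> "up" or
    "down") are kept; each retained (miRNA, gene) pair becomes one edge with
    ``support`` = number of distinct predicting databases.  miRNAs with no
    surviving edge are retained as isolated nodes.
    """
    if not mirna_directions:
        raise ValueError("miRNA set must be non-empty")
    bad = {m: d for m, d in mirna_directions.items() if d not in ("up", "down")}
    if bad:
        raise ValueError(f"miRNA(s) without up/down direction: {sorted(bad)}")
    if isinstance(edges, TargetEdgeTable):
        table = edges
    else:
        table = TargetEdgeTable.concat(list(edges))

    net = nx.Graph()
    for mirna, direction in sorted(mirna_directions.items()):
        net.add_node(mirna, node_type="mirna", bipartite=0,
                     direction=direction)
    rec = table.records
    kept = rec[rec["mirna"].isin(mirna_directions)]
    support = kept.groupby(["mirna", "gene"])["db"].nunique()
    for (mirna, gene), n_db in support.items():
        if gene not in net:
            net.add_node(gene, node_type="gene", bipartite=1)
        net.add_edge(mirna, gene, support=int(n_db))
    return net


def _gene_nodes(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["node_type"] == "gene"]


def _mirna_nodes(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["node_type"] == "mirna"]


def filter_min_targeting(net: nx.Graph, k: int) -> nx.Graph:
    """Remove gene nodes targeted by fewer than ``k`` distinct miRNAs.

    miRNA nodes are always retained, whatever degree remains.  Idempotent;
    with k=1 this is the identity.
    """
    if k < 1:
        raise ValueError(f"min targeting must be >= 1, got {k}")
    out = net.copy()
    drop = [g for g in _gene_nodes(out) if out.degree(g) < k]
    out.remove_nodes_from(drop)
    return out


def consensus_targets(
    tables: Sequence[TargetEdgeTable],
    mirna: str,
    min_databases: int | None = None,
) -> set[str]:
    """Genes predicted as targets of ``mirna`` by >= ``min_databases``
    distinct databases (default: all supplied tables — the full
    intersection).  An unknown miRNA yields an empty set.
    """
    if min_databases is None:
        min_databases = len(tables)
    merged = TargetEdgeTable.concat(list(tables))
    if min_databases > len(merged.databases):
        raise ValueError(
            f"min_databases={min_databases} exceeds the "
            f"{len(merged.databases)} supplied database(s)")
    rec = merged.records
    mine = rec[rec["mirna"] == mirna]
    by_gene = mine.groupby("gene")["db"].nunique()
    return set(by_gene.index[by_gene >= min_databases])


def annotate_nodes(
    net: nx.Graph,
    gene_sets: Mapping[str, Iterable[str]],
    flag_map: Mapping[str, str],
) -> nx.Graph:
    """Attach boolean pathway flags to gene nodes.

    ``flag_map`` maps gene-set name -> node attribute name (e.g. a TGF-beta
    or Wnt membership set -> ``tgfb_wnt``).  Genes in no mapped set carry
    every flag False.
    """
    out = net.copy()
    memberships = {flag: set(gene_sets.get(name, ()))
                   for name, flag in flag_map.items()}
    for gene in _gene_nodes(out):
        for flag, members in memberships.items():
            out.nodes[gene][flag] = gene in members
    return out


def export_network(net: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write the network as SIF (``mirna targets gene`` lines) or GraphML.

    GraphML preserves node attributes (node_type, direction, pathway flags)
    and edge support, so a write/read round trip reproduces the network
    exactly.  Isolated miRNAs appear in SIF as single-column lines, the
    Cytoscape convention for unconnected nodes.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "sif":
        lines = []
        for mirna in sorted(_mirna_nodes(net)):
            genes = sorted(net.neighbors(mirna))
            if genes:
                lines.extend(f"{mirna}\t{EDGE_RELATION}\t{g}" for g in genes)
            else:
                lines.append(mirna)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def load_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`export_network`."""
    return nx.read_graphml(path)


def network_summary(net: nx.Graph) -> dict:
    mirnas = _mirna_nodes(net)
    genes = _gene_nodes(net)
    return {
        "n_mirnas": len(mirnas),
        "n_genes": len(genes),
        "n_edges": net.number_of_edges(),
        "n_isolated_mirnas": sum(1 for m in mirnas if net.degree(m) == 0),
    }
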
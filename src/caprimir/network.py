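"""miRNA-gene(-pathway) regulation networks: build, summarise, export.

Nodes are typed (miRNA, gene, pathway); ``regulates`` edges run
miRNA -> gene and ``participates_in`` edges run gene -> pathway.  Storage
is an undirected networkx graph with ``kind`` attributes on nodes and
edges; direction is implied by the endpoint kinds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

NODE_KINDS = ("miRNA", "gene", "pathway")
EDGE_KINDS = ("regulates", "participates_in")


class NetworkError(ValueError):
    pass


def build_network(
    mirna_gene,
    gene_pathway=None,
    de_set: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Assemble the (bi- or tri-partite) regulation network.

    ``mirna_gene`` needs columns ``mirna_id``/``gene_id``; the optional
    ``gene_pathway`` needs ``gene_id``/``pathway_id``.  When ``de_set`` is
    given, only edges of those miRNAs are kept.  Duplicate rows collapse to
    one edge; rows with blank ids are dropped.
    """
    g = nx.Graph()
    keep = set(de_set) if de_set is not None else None
    dropped = 0
    for row in mirna_gene.itertuples():
        m, t = str(row.mirna_id).strip(), str(row.gene_id).strip()
        if not m or not t or m == "nan" or t == "nan":
            dropped += 1
            continue
        if keep is not None and m not in keep:
            continue
        g.add_node(m, kind="miRNA")
        g.add_node(t, kind="gene")
        g.add_edge(m, t, kind="regulates")
    if gene_pathway is not None:
        genes_present = {n for n, k in g.nodes(data="kind") if k == "gene"}
        for row in gene_pathway.itertuples():
            t, p = str(row.gene_id).strip(), str(row.pathway_id).strip()
            if not t or not p or t == "nan" or p == "nan":
                dropped += 1
                continue
            if t not in genes_present:
                continue
            g.add_node(p, kind="pathway")
            g.add_edge(t, p, kind="participates_in")
    g.graph["dropped_rows"] = dropped
    validate(g)
    return g


def validate(g: nx.Graph) -> None:
    """Enforce the typed-bipartite edge constraints."""
    for n, kind in g.nodes(data="kind"):
        if kind not in NODE_KINDS:
            raise NetworkError(f"node {n!r} has invalid kind {kind!r}")
    for u, v, kind in g.edges(data="kind"):
        kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
        if kind == "regulates" and kinds != {"miRNA", "gene"}:
            raise NetworkError(f"regulates edge {u}-{v} must join miRNA and gene")
        if kind == "participates_in" and kinds != {"gene", "pathway"}:
            raise NetworkError(f"participates_in edge {u}-{v} must join gene and pathway")
        if kind not in EDGE_KINDS:
            raise NetworkError(f"edge {u}-{v} has invalid kind {kind!r}")


def network_stats(g: nx.Graph, hub_k: int = 4) -> dict:
    """Node/edge totals, per-kind counts, degrees and hub lists.

    Hubs are miRNAs regulating >= ``hub_k`` genes, genes targeted by >=
    ``hub_k`` miRNAs, and genes participating in >= ``hub_k`` pathways.
    """
    by_kind = {k: [n for n, kind in g.nodes(data="kind") if kind == k]
               for k in NODE_KINDS}

    def typed_degree(node: str, edge_kind: str) -> int:
        return sum(1 for _, _, k in g.edges(node, data="kind") if k == edge_kind)

    mirna_deg = {n: typed_degree(n, "regulates") for n in by_kind["miRNA"]}
    gene_deg = {n: typed_degree(n, "regulates") for n in by_kind["gene"]}
    gene_pw = {n: typed_degree(n, "participates_in") for n in by_kind["gene"]}
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_mirnas": len(by_kind["miRNA"]),
        "n_genes": len(by_kind["gene"]),
        "n_pathways": len(by_kind["pathway"]),
        "degree": dict(g.degree()),
        "hub_mirnas": sorted(n for n, d in mirna_deg.items() if d >= hub_k),
        "hub_genes": sorted(n for n, d in gene_deg.items() if d >= hub_k),
        "multi_pathway_genes": sorted(n for n, d in gene_pw.items() if d >= hub_k),
    }


# ---------------------------------------------------------------------------
# Export / import (lossless round trip)
# ---------------------------------------------------------------------------

def _oriented_edges(g: nx.Graph):
    """Edges in canonical direction: miRNA -> gene, gene -> pathway."""
    first = {"regulates": "miRNA", "participates_in": "gene"}
    for u, v, kind in g.edges(data="kind"):
        if g.nodes[u]["kind"] != first[kind]:
            u, v = v, u
        yield u, v, kind


def export_graph(g: nx.Graph, path, fmt: str = "graphml") -> None:
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, kind in sorted(_oriented_edges(g)):
                fh.write(f"{u}\t{kind}\t{v}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\tsource_kind\tedge_kind\ttarget\ttarget_kind\n")
            for u, v, kind in sorted(_oriented_edges(g)):
                fh.write(f"{u}\t{g.nodes[u]['kind']}\t{kind}\t{v}\t{g.nodes[v]['kind']}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r} (use graphml, sif or tsv)")


def import_graph(path, fmt: str = "graphml") -> nx.Graph:
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)
        # strip graph-level metadata written by exporters
        g.graph.clear()
        out = nx.Graph()
        for n, data in g.nodes(data=True):
            out.add_node(n, kind=data["kind"])
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, kind=data["kind"])
        validate(out)
        return out
    if fmt == "tsv":
        out = nx.Graph()
        with open(path) as fh:
            next(fh)
            for line in fh:
                u, uk, kind, v, vk = line.rstrip("\n").split("\t")
                out.add_node(u, kind=uk)
                out.add_node(v, kind=vk)
                out.add_edge(u, v, kind=kind)
        validate(out)
        return out
    if fmt == "sif":
        # canonical orientation makes node kinds recoverable
        out = nx.Graph()
        with open(path) as fh:
            for line in fh:
                u, kind, v = line.rstrip("\n").split("\t")
                left, right = (("miRNA", "gene") if kind == "regulates"
                               else ("gene", "pathway"))
                out.add_node(u, kind=left)
                out.add_node(v, kind=right)
                out.add_edge(u, v, kind=kind)
        validate(out)
        return out
    raise ValueError(f"unsupported format {fmt!r}")
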
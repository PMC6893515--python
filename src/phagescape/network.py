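"""Weighted co-occurrence networks of tissue-selective elementary binding
units (EBUs).

Nodes are tissue-selective 3-mers; an undirected edge connects two motifs with
weight equal to the number of distinct recovered peptides containing both
(possibly overlapping) as substrings.  Connected components fall into three
interaction classes: *isolated* motifs with no partners, *simple* chains in
which every co-occurring motif pair overlaps within supporting peptides
(extension of a primary EBU into a longer motif), and *complex* components in
which at least one motif pair co-occurs without overlapping (independent EBUs
combined at variable spacing).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .processing import PeptideRecord

DEFAULT_MIN_EDGE_WEIGHT = 20


def _peptide_seq(rec: PeptideRecord | str) -> str:
    return rec if isinstance(rec, str) else rec.peptide


def motif_positions(peptide: str, motif: str) -> list[int]:
    """All (possibly overlapping) start positions of ``motif`` in ``peptide``."""
    out, start = [], 0
    while True:
        i = peptide.find(motif, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _max_overlap(peptide: str, motif_a: str, motif_b: str) -> int:
    """Largest number of shared residue positions between any occurrence of
    motif_a and any occurrence of motif_b in this peptide."""
    best = 0
    for i in motif_positions(peptide, motif_a):
        for j in motif_positions(peptide, motif_b):
            overlap = min(i + len(motif_a), j + len(motif_b)) - max(i, j)
            best = max(best, overlap)
    return best


def build_network(
    peptides: Iterable[PeptideRecord | str],
    selective_motifs: Iterable[str],
) -> nx.Graph:
    """Build the weighted EBU co-occurrence graph over a peptide collection.

    Each edge also records ``max_overlap``: the largest residue overlap
    observed between the two motifs in any single supporting peptide (0 when
    they only ever co-occur disjointly), which drives component
    classification.
    """
    motifs = sorted(set(selective_motifs))
    if not motifs:
        raise ValueError("selective motif set is empty")
    graph = nx.Graph()
    seen: set[str] = set()
    for rec in peptides:
        seq = _peptide_seq(rec)
        if seq in seen:
            continue
        seen.add(seq)
        present = [m for m in motifs if m in seq]
        for m in present:
            if not graph.has_node(m):
                graph.add_node(m, n_supporting_peptides=0)
            graph.nodes[m]["n_supporting_peptides"] += 1
        for idx, m_a in enumerate(present):
            for m_b in present[idx + 1 :]:
                overlap = _max_overlap(seq, m_a, m_b)
                if graph.has_edge(m_a, m_b):
                    graph[m_a][m_b]["weight"] += 1
                    graph[m_a][m_b]["max_overlap"] = max(
                        graph[m_a][m_b]["max_overlap"], overlap
                    )
                else:
                    graph.add_edge(m_a, m_b, weight=1, max_overlap=overlap)
    return graph


def filter_edges(graph: nx.Graph, min_weight: int = DEFAULT_MIN_EDGE_WEIGHT) -> nx.Graph:
    """Drop edges with weight strictly below ``min_weight``; nodes are kept
    (a node losing all its edges becomes isolated)."""
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    out = graph.copy()
    weak = [(u, v) for u, v, w in out.edges(data="weight") if w < min_weight]
    out.remove_edges_from(weak)
    return out


def classify_components(graph: nx.Graph, min_overlap: int = 1) -> dict[str, str]:
    """Classify each node's component as isolated / simple / complex.

    isolated: degree-0 node.  simple: every edge of the component joins motifs
    that overlap by at least ``min_overlap`` residues in some supporting
    peptide (chain extension of a primary EBU).  complex: any component with
    an edge whose motifs only co-occur without sufficient overlap.

    The classification is also stored on each node under ``classification``.
    """
    labels: dict[str, str] = {}
    for component in nx.connected_components(graph):
        nodes = list(component)
        if len(nodes) == 1 and graph.degree(nodes[0]) == 0:
            label = "isolated"
        else:
            sub = graph.subgraph(nodes)
            label = (
                "simple"
                if all(ov >= min_overlap for _, _, ov in sub.edges(data="max_overlap"))
                else "complex"
            )
        for n in nodes:
            labels[n] = label
            graph.nodes[n]["classification"] = label
    return labels


def peptide_family(
    peptides: Iterable[PeptideRecord | str],
    motifs: str | Sequence[str],
) -> pd.DataFrame:
    """All distinct peptides containing the given motif(s), with 0-based motif
    start positions, sorted lexicographically — a machine-readable version of
    a motif-family table."""
    if isinstance(motifs, str):
        motifs = [motifs]
    motifs = list(motifs)
    rows = []
    seen: set[str] = set()
    for rec in peptides:
        seq = _peptide_seq(rec)
        if seq in seen:
            continue
        seen.add(seq)
        positions = {m: motif_positions(seq, m) for m in motifs}
        if all(positions[m] for m in motifs):
            row = {"peptide": seq}
            for m in motifs:
                row[f"{m}_positions"] = ",".join(map(str, positions[m]))
            rows.append(row)
    df = pd.DataFrame(rows, columns=["peptide"] + [f"{m}_positions" for m in motifs])
    return df.sort_values("peptide").reset_index(drop=True)


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML or GEXF with integer edge weights and node
    attributes preserved."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gexf":
        nx.write_gexf(graph, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


def load_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        graph = nx.read_graphml(str(path))
    elif fmt == "gexf":
        graph = nx.read_gexf(str(path))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    # normalize attribute types after round-tripping through XML
    for _, _, data in graph.edges(data=True):
        data["weight"] = int(data["weight"])
        if "max_overlap" in data:
            data["max_overlap"] = int(data["max_overlap"])
    for _, data in graph.nodes(data=True):
        if "n_supporting_peptides" in data:
            data["n_supporting_peptides"] = int(data["n_supporting_peptides"])
    return graph


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"motif_a": u, "motif_b": v, "weight": d["weight"], "max_overlap": d.get("max_overlap")}
        for u, v, d in graph.edges(data=True)
    ]
    return (
        pd.DataFrame(rows, columns=["motif_a", "motif_b", "weight", "max_overlap"])
        .sort_values(["motif_a", "motif_b"])
        .reset_index(drop=True)
    )


def node_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "motif": n,
            "n_supporting_peptides": d.get("n_supporting_peptides"),
            "classification": d.get("classification"),
        }
        for n, d in graph.nodes(data=True)
    ]
    return (
        pd.DataFrame(rows, columns=["motif", "n_supporting_peptides", "classification"])
        .sort_values("motif")
        .reset_index(drop=True)
    )
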
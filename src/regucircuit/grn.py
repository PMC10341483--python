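"""Condition-specific gene regulatory networks.

A regulatory network is a directed graph of TF -> target edges (a
:class:`networkx.DiGraph`).  Node attributes carry the evidence layers the
pipeline integrates: differential-expression status, promoter-acetylation
status and CRE-acetylation status (each in {up, down, ns, absent}); edges
carry an optional regulation mode and the source databases they came from.

Contextualization restricts a general network to the outgoing edges of TFs
expressed in the condition under study; targets are kept regardless of their
own expression.  Node sets after contextualization are the endpoints of the
retained edges (isolated nodes are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .diffcount import CountMatrix, size_factors

__all__ = [
    "RegulatoryNetwork",
    "NetworkStats",
    "load_general_grn",
    "contextualize",
    "annotate",
    "compare_networks",
    "cre_regulatory_subnetwork",
    "expressed_genes",
    "write_graphml",
    "read_graphml",
    "write_edges_tsv",
]

# the in-memory network type; module functions maintain its attribute schema
RegulatoryNetwork = nx.DiGraph

STATUS_VALUES = ("up", "down", "ns", "absent")
MODES = ("activation", "repression", "unknown")


@dataclass(frozen=True)
class NetworkStats:
    """Bookkeeping of one network against another (totals and uniques)."""

    total_nodes: int
    total_tfs: int
    total_edges: int
    unique_nodes_vs_other: int
    unique_tfs_vs_other: int
    unique_edges_vs_other: int


def _network_tfs(net: RegulatoryNetwork) -> set[str]:
    """TFs of a network: nodes with at least one outgoing edge."""
    return {n for n in net.nodes if net.out_degree(n) > 0}


def _refresh_tf_flags(net: RegulatoryNetwork) -> None:
    tfs = _network_tfs(net)
    for n in net.nodes:
        net.nodes[n]["is_tf"] = n in tfs


def load_general_grn(paths: str | Path | Sequence[str | Path]) -> RegulatoryNetwork:
    """Union of edge-list files into one general TF -> target network.

    Each file is TSV with columns ``tf``, ``target`` and optionally ``mode``
    (activation/repression/unknown) and ``source``.  Duplicate (tf, target)
    pairs are merged: conflicting modes become ``unknown``, sources are
    concatenated.  Malformed rows raise with the file and line number.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    net = nx.DiGraph()
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                if lineno == 1 and line.split("\t")[:2] == ["tf", "target"]:
                    continue  # optional header row
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    raise ValueError(f"{path}: line {lineno}: need tf and target columns")
                tf, target = fields[0], fields[1]
                mode = fields[2] if len(fields) > 2 and fields[2] else "unknown"
                if mode not in MODES:
                    raise ValueError(f"{path}: line {lineno}: unknown mode {mode!r}")
                source = fields[3] if len(fields) > 3 and fields[3] else str(path)
                if net.has_edge(tf, target):
                    data = net.edges[tf, target]
                    if data["mode"] != mode:
                        data["mode"] = "unknown"
                    if source not in data["sources"]:
                        data["sources"] = data["sources"] + [source]
                else:
                    net.add_edge(tf, target, mode=mode, sources=[source])
    _refresh_tf_flags(net)
    return net


def contextualize(general: RegulatoryNetwork, expressed: set[str]) -> RegulatoryNetwork:
    """Keep the edge (tf, target) iff the tf is expressed.

    The node set of the result is exactly the endpoints of retained edges;
    node and edge attributes are preserved.
    """
    if not expressed:
        raise ValueError("expressed set is empty")
    net = nx.DiGraph()
    for tf, target, data in general.edges(data=True):
        if tf in expressed:
            net.add_edge(tf, target, **data)
    for n in net.nodes:
        net.nodes[n].update(general.nodes[n])
    _refresh_tf_flags(net)
    return net


def annotate(
    network: RegulatoryNetwork,
    de: pd.DataFrame | None = None,
    prom_acetyl: pd.DataFrame | None = None,
    cre_status: pd.Series | None = None,
) -> RegulatoryNetwork:
    """Fill node attributes from result tables (in place; returns the network).

    ``de`` and ``prom_acetyl`` are differential-result frames indexed by
    feature id with a ``status`` column; ``cre_status`` maps gene id to a
    CRE acetylation status (see :func:`regucircuit.cre.gene_cre_status`).
    Genes absent from a table get status ``absent``.  Idempotent.
    """
    for n in network.nodes:
        node = network.nodes[n]
        node["de_status"] = (
            str(de.loc[n, "status"]) if de is not None and n in de.index else "absent"
        )
        node["promoter_acetyl"] = (
            str(prom_acetyl.loc[n, "status"])
            if prom_acetyl is not None and n in prom_acetyl.index
            else "absent"
        )
        node["cre_acetyl"] = (
            str(cre_status.loc[n])
            if cre_status is not None and n in cre_status.index
            else "absent"
        )
    return network


def compare_networks(
    a: RegulatoryNetwork, b: RegulatoryNetwork
) -> tuple[NetworkStats, NetworkStats]:
    """Totals and one-sided unique counts for a pair of networks.

    Unique means present in one network and not the other (nodes, TFs and
    edges as sets); both stats are computed from the same union so
    ``unique_a + unique_b + shared`` reconstructs the union size.
    """
    nodes_a, nodes_b = set(a.nodes), set(b.nodes)
    tfs_a, tfs_b = _network_tfs(a), _network_tfs(b)
    edges_a, edges_b = set(a.edges), set(b.edges)

    def stats(nodes, tfs, edges, other_nodes, other_tfs, other_edges):
        return NetworkStats(
            total_nodes=len(nodes),
            total_tfs=len(tfs),
            total_edges=len(edges),
            unique_nodes_vs_other=len(nodes - other_nodes),
            unique_tfs_vs_other=len(tfs - other_tfs),
            unique_edges_vs_other=len(edges - other_edges),
        )

    return (
        stats(nodes_a, tfs_a, edges_a, nodes_b, tfs_b, edges_b),
        stats(nodes_b, tfs_b, edges_b, nodes_a, tfs_a, edges_a),
    )


def cre_regulatory_subnetwork(
    network: RegulatoryNetwork, regulator_ids: Iterable[str]
) -> RegulatoryNetwork:
    """Subnetwork of chosen regulators (e.g. Creb1/Crebbp) and their targets.

    Nodes: the regulators plus their direct targets; edges: only the edges
    out of the regulators.  Unknown regulator ids are skipped (a note is
    attached to the graph under ``graph['skipped_regulators']``).
    """
    regulators = sorted(set(regulator_ids))
    known = [r for r in regulators if r in network.nodes]
    skipped = [r for r in regulators if r not in network.nodes]
    sub = nx.DiGraph()
    for r in known:
        sub.add_node(r, **network.nodes[r])
        for _, target, data in network.out_edges(r, data=True):
            sub.add_edge(r, target, **data)
            sub.nodes[target].update(network.nodes[target])
    sub.graph["skipped_regulators"] = skipped
    return sub


def expressed_genes(
    counts: CountMatrix,
    condition: str | None = None,
    threshold: float = 10.0,
    factors: pd.Series | None = None,
) -> set[str]:
    """Genes whose mean normalized count reaches ``threshold``.

    With ``condition`` given, the mean is taken over that condition's samples
    only (size factors are still estimated from the full matrix, so both
    conditions are judged on the same scale).
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts.counts / factors
    if condition is not None:
        cols = [s for s in counts.sample_ids if counts.condition[s] == condition]
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        norm = norm[cols]
    means = norm.mean(axis=1)
    return set(means.index[means >= threshold])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _graphml_safe(net: RegulatoryNetwork) -> nx.DiGraph:
    out = net.copy()
    for _, _, data in out.edges(data=True):
        if isinstance(data.get("sources"), list):
            data["sources"] = ",".join(data["sources"])
    return out


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    """GraphML export with all attributes (for external viewers)."""
    nx.write_graphml(_graphml_safe(net), path)


def read_graphml(path: str | Path) -> RegulatoryNetwork:
    net = nx.read_graphml(path)
    out = nx.DiGraph()
    for n, data in sorted(net.nodes(data=True)):
        out.add_node(n, **data)
    for u, v, data in sorted(net.edges(data=True), key=lambda e: (e[0], e[1])):
        if isinstance(data.get("sources"), str):
            data = {**data, "sources": data["sources"].split(",")}
        out.add_edge(u, v, **data)
    return out


def write_edges_tsv(net: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tmode\tsource\n")
        for tf, target in sorted(net.edges):
            data = net.edges[tf, target]
            sources = data.get("sources", [])
            if isinstance(sources, list):
                sources = ",".join(sources)
            fh.write(f"{tf}\t{target}\t{data.get('mode', 'unknown')}\t{sources}\n")
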
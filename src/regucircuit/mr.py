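"""Master-regulator inference on contextualized regulatory networks.

The procedure mirrors the Davis & Rebay notion of a master regulator: a TF
inside a densely inter-regulating, physically interacting clique that sits
atop a regulatory cascade.  Starting from the differentially expressed
genes, their first- and second-level upstream regulators are collected (the
upstream neighborhood); the densest part of that neighborhood is isolated by
iteratively deleting minimum-out-degree nodes; the surviving TFs are MR
candidates, each validated by whether other candidates regulate it and
whether it physically interacts with another candidate.

Pruning details (all deterministic):

* the procedure operates on the largest weakly connected component;
* one node is deleted per iteration — the node of minimal current
  out-degree, ties broken by minimal in-degree then lexicographic id;
* a deletion is only committed if the remainder stays weakly connected,
  non-empty and at least ``min_core_size`` nodes; the offending deletion is
  not applied;
* when every remaining node has the same out-degree there is no node with a
  *lower* out-degree left to delete, and the pruning stops — this is the
  natural terminal state on a uniformly dense core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .grn import RegulatoryNetwork

__all__ = [
    "PhysicalInteractionSet",
    "MRReport",
    "upstream_neighborhood",
    "densest_core",
    "validate_mrs",
    "mr_condition_contrast",
]


class PhysicalInteractionSet:
    """Unordered protein-protein interaction pairs with symmetric lookup."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[tuple[str, str]] = set()
        self._adj: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-interaction {a!r} is not allowed")
        pair = (a, b) if a <= b else (b, a)
        self._pairs.add(pair)
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def has(self, a: str, b: str) -> bool:
        pair = (a, b) if a <= b else (b, a)
        return pair in self._pairs

    def partners(self, gene: str) -> set[str]:
        return set(self._adj.get(gene, ()))

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.has(*pair)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhysicalInteractionSet":
        """Two-column TSV of interacting gene pairs (header optional)."""
        out = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: need two columns")
                if lineno == 1 and fields[:2] == ["gene_a", "gene_b"]:
                    continue
                out.add(fields[0], fields[1])
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in sorted(self._pairs):
                fh.write(f"{a}\t{b}\n")


@dataclass
class MRReport:
    """Outcome of one MR inference run on one network."""

    seed_genes: frozenset[str]
    neighborhood_nodes: frozenset[str]
    core_candidates: tuple[str, ...]
    deletion_trace: tuple[tuple[str, int], ...]
    validated_mrs: frozenset[str]
    per_candidate_evidence: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("candidate\tregulated_by\tphysical_partners\tvalidated\n")
            for c in self.core_candidates:
                ev = self.per_candidate_evidence.get(c, {})
                reg = ",".join(sorted(ev.get("regulated_by_candidates", ()))) or "."
                ppi = ",".join(sorted(ev.get("physical_partners_in_candidates", ()))) or "."
                fh.write(f"{c}\t{reg}\t{ppi}\t{int(c in self.validated_mrs)}\n")

    def trace_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tdeleted_node\tout_degree_at_deletion\n")
            for i, (node, deg) in enumerate(self.deletion_trace, 1):
                fh.write(f"{i}\t{node}\t{deg}\n")


def upstream_neighborhood(
    network: RegulatoryNetwork, de_genes: Iterable[str], depth: int = 2
) -> RegulatoryNetwork:
    """Induced subgraph of the DE genes and their upstream regulators.

    Walk regulatory edges in reverse (target -> regulator) for ``depth``
    steps from the seed genes; the returned graph is the subgraph of
    ``network`` induced by all reached nodes (every edge of the network among
    them, not only the walked ones).  Seeds absent from the network are
    skipped; if none remain, an error is raised.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    seeds = {g for g in de_genes if g in network.nodes}
    if not seeds:
        raise ValueError("none of the seed genes occur in the network")
    nodes = set(seeds)
    frontier = seeds
    for _ in range(depth):
        frontier = {
            reg for node in frontier for reg in network.predecessors(node)
        } - nodes
        if not frontier:
            break
        nodes |= frontier
    sub = network.subgraph(nodes).copy()
    sub.graph["seed_genes"] = sorted(seeds)
    return sub


def _largest_weak_component(g: RegulatoryNetwork) -> RegulatoryNetwork:
    comps = sorted(nx.weakly_connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(comps[0]).copy()


def densest_core(
    subnetwork: RegulatoryNetwork, min_core_size: int = 2
) -> tuple[list[str], list[tuple[str, int]]]:
    """Iteratively strip minimum-out-degree nodes down to the dense core.

    Returns the sorted surviving node list and the ordered deletion trace of
    (node, out-degree at deletion).  See the module docstring for the exact
    deletion and stopping rules.
    """
    if subnetwork.number_of_nodes() == 0:
        raise ValueError("subnetwork is empty")
    g = _largest_weak_component(subnetwork)
    trace: list[tuple[str, int]] = []
    while g.number_of_nodes() > min_core_size:
        out_deg = dict(g.out_degree())
        degrees = set(out_deg.values())
        if len(degrees) == 1:
            break  # uniform out-degree: no node has a lower out-degree
        cand = min(g.nodes, key=lambda v: (out_deg[v], g.in_degree(v), v))
        remaining = [v for v in g.nodes if v != cand]
        h = g.subgraph(remaining)
        if len(remaining) == 0 or not nx.is_weakly_connected(h):
            break  # committing would disconnect (or empty) the remainder
        deg = out_deg[cand]
        g.remove_node(cand)
        trace.append((cand, deg))
    return sorted(g.nodes), trace


def validate_mrs(
    candidates: Iterable[str],
    network: RegulatoryNetwork,
    ppi: PhysicalInteractionSet,
    rule: str = "both",
    *,
    seed_genes: Iterable[str] = (),
    neighborhood_nodes: Iterable[str] = (),
    deletion_trace: Sequence[tuple[str, int]] = (),
) -> MRReport:
    """Check each candidate against the master-regulator definition.

    Evidence per candidate: (a) the other candidates with a regulatory edge
    into it, and (b) the other candidates physically interacting with it.
    ``rule='both'`` (default) requires both kinds of evidence — a pair of
    candidates that interact physically but do not regulate one another is
    *not* validated; ``'either'`` accepts one kind; ``'regulation_only'``
    ignores the interaction layer.
    """
    if rule not in ("both", "either", "regulation_only"):
        raise ValueError(f"unknown validation rule {rule!r}")
    candidates = sorted(set(candidates))
    missing = [c for c in candidates if c not in network.nodes]
    if missing:
        raise ValueError(f"candidates absent from the network: {missing}")
    cand_set = set(candidates)
    evidence: dict[str, dict[str, frozenset[str]]] = {}
    validated = set()
    for c in candidates:
        regulated_by = frozenset(
            other for other in network.predecessors(c) if other in cand_set and other != c
        )
        partners = frozenset(p for p in ppi.partners(c) if p in cand_set)
        evidence[c] = {
            "regulated_by_candidates": regulated_by,
            "physical_partners_in_candidates": partners,
        }
        if rule == "both":
            ok = bool(regulated_by) and bool(partners)
        elif rule == "either":
            ok = bool(regulated_by) or bool(partners)
        else:
            ok = bool(regulated_by)
        if ok:
            validated.add(c)
    return MRReport(
        seed_genes=frozenset(seed_genes),
        neighborhood_nodes=frozenset(neighborhood_nodes),
        core_candidates=tuple(candidates),
        deletion_trace=tuple(tuple(t) for t in deletion_trace),
        validated_mrs=frozenset(validated),
        per_candidate_evidence=evidence,
    )


def mr_condition_contrast(
    report_control: MRReport, report_mutant: MRReport
) -> dict[str, set[str]]:
    """Split validated MRs into shared / control-only / mutant-only sets."""
    a, b = set(report_control.validated_mrs), set(report_mutant.validated_mrs)
    return {
        "shared": a & b,
        "control_only": a - b,
        "mutant_only": b - a,
    }
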
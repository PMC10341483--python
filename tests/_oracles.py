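"""Independent brute-force oracles used to cross-check the implementations.

Every function here follows the literal definition of an operation with the
simplest possible algorithm (all-pairs scans, explicit BFS, set algebra),
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def intersect_oracle(peaks_a, peaks_b, min_overlap=1):
    """All-pairs report-A intersection."""
    out = []
    for a in sorted(peaks_a, key=lambda i: (i.chrom, i.start, i.end)):
        for b in peaks_b:
            if a.chrom != b.chrom:
                continue
            if min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                out.append(a)
                break
    return out


def size_factor_oracle(matrix: np.ndarray) -> np.ndarray:
    """Literal median-of-ratios definition, feature loop included."""
    m = np.asarray(matrix, dtype=float)
    keep = [i for i in range(m.shape[0]) if (m[i] > 0).all()]
    geo = [np.exp(np.mean([np.log(v) for v in m[i]])) for i in keep]
    factors = []
    for j in range(m.shape[1]):
        ratios = sorted(m[i, j] / g for i, g in zip(keep, geo))
        factors.append(float(np.median(ratios)))
    return np.array(factors)


def cre_assign_oracle(motifs, genes_with_tss, max_distance=3000):
    """All-pairs midpoint-to-TSS distance check; returns (motif_id, gene_id) set."""
    pairs = set()
    for m in motifs:
        mid = (m.interval.start + m.interval.end) // 2
        for gene_id, chrom, tss in genes_with_tss:
            if m.interval.chrom == chrom and abs(tss - mid) <= max_distance:
                pairs.add((m.motif_id, gene_id))
    return pairs


def classify_oracle(region, genes, window_half=1000, downstream_extent=1000):
    """Literal precedence rule on the region midpoint; genes are GeneRecords."""
    pos = (region.start + region.end) // 2

    def tss(g):
        return g.start if g.strand == "+" else g.end - 1

    def candidates(pred):
        hits = [g for g in genes if g.chrom == region.chrom and pred(g)]
        hits.sort(key=lambda g: (abs(tss(g) - pos), g.gene_id))
        return hits

    promo = candidates(
        lambda g: max(0, tss(g) - window_half) <= pos < tss(g) + window_half + 1
    )
    if promo:
        return "promoter", promo[0].gene_id
    body = candidates(lambda g: g.start <= pos < g.end)
    if body:
        return "gene_body", body[0].gene_id
    down = candidates(
        lambda g: (g.strand == "+" and g.end <= pos < g.end + downstream_extent)
        or (g.strand == "-" and g.start - downstream_extent <= pos < g.start)
    )
    if down:
        return "downstream", down[0].gene_id
    return "intergenic", None


def upstream_oracle(edges, seeds, depth=2):
    """Reverse BFS truncated at depth; edges is an iterable of (tf, target)."""
    preds = {}
    nodes_all = set()
    for u, v in edges:
        preds.setdefault(v, set()).add(u)
        nodes_all |= {u, v}
    frontier = set(seeds) & nodes_all
    reached = set(frontier)
    for _ in range(depth):
        frontier = {p for n in frontier for p in preds.get(n, ())} - reached
        reached |= frontier
    return reached


def contextualize_oracle(edges, expressed):
    """Literal filter: keep (tf, target) iff tf is expressed."""
    return {(u, v) for u, v in edges if u in expressed}


def compare_oracle(nodes_a, edges_a, nodes_b, edges_b):
    """Set-algebra totals and uniques; returns two dicts."""

    def tfs(edges):
        return {u for u, _ in edges}

    def stats(nodes, edges, onodes, oedges):
        return {
            "total_nodes": len(nodes),
            "total_tfs": len(tfs(edges)),
            "total_edges": len(edges),
            "unique_nodes_vs_other": len(nodes - onodes),
            "unique_tfs_vs_other": len(tfs(edges) - tfs(oedges)),
            "unique_edges_vs_other": len(edges - oedges),
        }

    return (
        stats(nodes_a, edges_a, nodes_b, edges_b),
        stats(nodes_b, edges_b, nodes_a, edges_a),
    )


def densest_core_oracle(edges, nodes, min_core_size=2):
    """Step-by-step simulation of the documented pruning rule.

    Pure-python adjacency bookkeeping: largest weak component, delete the
    (min out-degree, min in-degree, lexicographic) node, stop when remaining
    out-degrees are all equal, when a deletion would disconnect the
    remainder, or at min_core_size.
    """
    edges = {(u, v) for u, v in edges}
    nodes = set(nodes)

    def weak_components(ns, es):
        adj = {n: set() for n in ns}
        for u, v in es:
            if u in ns and v in ns:
                adj[u].add(v)
                adj[v].add(u)
        seen, comps = set(), []
        for n in sorted(ns):
            if n in seen:
                continue
            stack, comp = [n], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(comp)
        return comps

    comps = sorted(weak_components(nodes, edges), key=lambda c: (-len(c), min(c)))
    current = set(comps[0])
    trace = []
    while len(current) > min_core_size:
        out_deg = {n: sum(1 for u, v in edges if u == n and v in current) for n in current}
        in_deg = {n: sum(1 for u, v in edges if v == n and u in current) for n in current}
        if len(set(out_deg.values())) == 1:
            break
        cand = min(current, key=lambda n: (out_deg[n], in_deg[n], n))
        rest = current - {cand}
        if len(weak_components(rest, edges)) != 1:
            break
        trace.append((cand, out_deg[cand]))
        current = rest
    return sorted(current), trace


def validate_oracle(candidates, edges, ppi_pairs, rule="both"):
    """Literal validation rule over candidate pairs."""
    cand = set(candidates)
    pp = {frozenset(p) for p in ppi_pairs}
    validated = set()
    for c in cand:
        reg = {u for u, v in edges if v == c and u in cand and u != c}
        phys = {o for o in cand if o != c and frozenset((c, o)) in pp}
        ok = {
            "both": bool(reg) and bool(phys),
            "either": bool(reg) or bool(phys),
            "regulation_only": bool(reg),
        }[rule]
        if ok:
            validated.add(c)
    return validated
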
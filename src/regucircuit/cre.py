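"""CRE-element handling: motif-to-gene assignment and genomic location labels.

A motif occurrence (e.g. a CREB-binding motif found by a genome scan) is
assigned to every gene whose TSS lies within ``max_distance`` bases of the
occurrence midpoint, on the same chromosome.  Differentially acetylated
regions are additionally classified by where their midpoint falls relative
to gene models: promoter window, gene body, the strand-aware region just
downstream of the 3' end, or none of these.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import (
    BedParseError,
    GeneRecord,
    GenomeAnnotation,
    Interval,
    PromoterWindow,
    build_promoter_windows,
    tss_of,
)

__all__ = [
    "MotifOccurrence",
    "CREAssignment",
    "LocationIndex",
    "assign_cre_genes",
    "classify_location",
    "cre_acetylation_table",
    "read_motif_bed",
    "write_motif_bed",
    "write_assignments_tsv",
]

LOCATIONS = ("promoter", "gene_body", "downstream", "upstream_distal", "intergenic")


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif hit on the genome (scan score carried, strand unused)."""

    interval: Interval
    motif_id: str
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"motif {self.motif_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class CREAssignment:
    """A (motif occurrence, putatively regulated gene) pair."""

    motif: MotifOccurrence
    gene_id: str
    distance: int  # unsigned midpoint-to-TSS distance, bp
    location: str  # relative to the assigned gene

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location label {self.location!r}")


class LocationIndex:
    """Reusable index answering midpoint-location queries against gene models.

    Precedence: promoter > gene_body > downstream > intergenic, evaluated on
    the region midpoint.  Downstream means within ``downstream_extent`` bases
    past the 3' end, on the strand-appropriate side.  Ties within a category
    are broken by nearest TSS, then lexicographic gene id.
    """

    def __init__(
        self,
        annotation: GenomeAnnotation,
        promoter_windows: Sequence[PromoterWindow] | None = None,
        downstream_extent: int = 1000,
    ) -> None:
        if promoter_windows is None:
            promoter_windows = build_promoter_windows(annotation)
        self.annotation = annotation
        self.downstream_extent = downstream_extent
        self._tss = {g.gene_id: tss_of(g) for g in annotation}
        self._promoters: dict[str, IntervalTree] = {}
        for w in promoter_windows:
            self._promoters.setdefault(w.interval.chrom, IntervalTree()).addi(
                w.interval.start, w.interval.end, w.gene_id
            )
        self._bodies: dict[str, IntervalTree] = {}
        self._downstream: dict[str, IntervalTree] = {}
        for g in annotation:
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
            if g.strand == "+":
                ds = Interval(g.chrom, g.end, g.end + downstream_extent)
            else:
                if g.start == 0:
                    continue
                ds = Interval(g.chrom, max(0, g.start - downstream_extent), g.start)
            self._downstream.setdefault(g.chrom, IntervalTree()).addi(ds.start, ds.end, g.gene_id)

    def _best(self, chrom: str, pos: int, trees: Mapping[str, IntervalTree]) -> str | None:
        tree = trees.get(chrom)
        if tree is None:
            return None
        hits = [h.data for h in tree.at(pos)]
        if not hits:
            return None
        return min(hits, key=lambda gid: (abs(self._tss[gid] - pos), gid))

    def classify(self, region: Interval) -> tuple[str, str | None]:
        """Label the region midpoint; returns (location, gene_id or None)."""
        pos = region.midpoint
        for label, trees in (
            ("promoter", self._promoters),
            ("gene_body", self._bodies),
            ("downstream", self._downstream),
        ):
            gid = self._best(region.chrom, pos, trees)
            if gid is not None:
                return label, gid
        return "intergenic", None


def classify_location(
    region: Interval,
    annotation: GenomeAnnotation,
    promoter_windows: Sequence[PromoterWindow] | None = None,
    downstream_extent: int = 1000,
) -> tuple[str, str | None]:
    """Convenience one-shot wrapper around :class:`LocationIndex`."""
    return LocationIndex(annotation, promoter_windows, downstream_extent).classify(region)


def _locate_for_gene(pos: int, gene: GeneRecord, window_half: int, downstream_extent: int) -> str:
    t = tss_of(gene)
    if max(0, t - window_half) <= pos < t + window_half + 1:
        return "promoter"
    if gene.start <= pos < gene.end:
        return "gene_body"
    if gene.strand == "+" and gene.end <= pos < gene.end + downstream_extent:
        return "downstream"
    if gene.strand == "-" and gene.start - downstream_extent <= pos < gene.start:
        return "downstream"
    return "upstream_distal"


def assign_cre_genes(
    motifs: Iterable[MotifOccurrence],
    annotation: GenomeAnnotation,
    max_distance: int = 3000,
    nearest_only: bool = False,
    window_half: int = 1000,
    downstream_extent: int = 1000,
) -> list[CREAssignment]:
    """Assign each motif occurrence to genes with a TSS within ``max_distance``.

    Distance is the unsigned gap between the motif midpoint and the gene TSS;
    the threshold is inclusive.  By default every in-range gene on the motif's
    chromosome is assigned (one :class:`CREAssignment` per pair);
    ``nearest_only`` keeps only the closest (ties: lexicographic gene id).
    The ``location`` label is computed relative to the assigned gene.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append((tss_of(g), g.gene_id))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    out: list[CREAssignment] = []
    for m in motifs:
        entries = by_chrom.get(m.interval.chrom)
        if not entries:
            continue
        mid = m.interval.midpoint
        positions = [t for t, _ in entries]
        lo = bisect.bisect_left(positions, mid - max_distance)
        hi = bisect.bisect_right(positions, mid + max_distance)
        in_range = [
            (abs(t - mid), gid, t)
            for t, gid in entries[lo:hi]
            if abs(t - mid) <= max_distance
        ]
        if not in_range:
            continue
        in_range.sort(key=lambda x: (x[0], x[1]))
        if nearest_only:
            in_range = in_range[:1]
        for dist, gid, _t in in_range:
            loc = _locate_for_gene(mid, annotation[gid], window_half, downstream_extent)
            out.append(CREAssignment(m, gid, dist, loc))
    return out


def cre_acetylation_table(
    assignments: Iterable[CREAssignment],
    diff: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Merge CRE-gene assignments with region-level differential results.

    ``diff`` is a differential-result frame indexed by region/motif id (as
    produced by :func:`regucircuit.diffcount.nb_test`).  Returns the merged
    table (one row per assignment, with the region's acetylation status) and
    the list of assignment identifiers missing from ``diff`` — reported, not
    silently dropped; their status is recorded as ``absent``.

    A gene reachable from at least one differentially acetylated region is
    flagged through the ``acetyl_status`` column; a gene with both an up and
    a down region keeps both rows (no collapsing).
    """
    rows = []
    unmatched: list[str] = []
    for a in assignments:
        mid = a.motif.motif_id
        if mid in diff.index:
            status = str(diff.loc[mid, "status"])
            pval = float(diff.loc[mid, "p_value"])
        else:
            unmatched.append(mid)
            status, pval = "absent", float("nan")
        rows.append(
            {
                "motif_id": mid,
                "chrom": a.motif.interval.chrom,
                "midpoint": a.motif.interval.midpoint,
                "gene_id": a.gene_id,
                "distance": a.distance,
                "location": a.location,
                "acetyl_status": status,
                "p_value": pval,
            }
        )
    cols = [
        "motif_id",
        "chrom",
        "midpoint",
        "gene_id",
        "distance",
        "location",
        "acetyl_status",
        "p_value",
    ]
    table = pd.DataFrame(rows, columns=cols)
    return table, sorted(set(unmatched))


def gene_cre_status(table: pd.DataFrame) -> pd.Series:
    """Collapse a merged CRE table to one acetylation status per gene.

    A gene keeps the status of its most significant differential region
    (smallest p-value; ties by motif id); genes whose regions are all
    non-significant get ``ns``.  The full per-region detail stays in the
    table — this summary only feeds network node attributes.
    """
    out: dict[str, str] = {}
    called = table[table["acetyl_status"].isin(["up", "down"])]
    called = called.sort_values(["p_value", "motif_id"], kind="mergesort")
    for _, row in called.iterrows():
        out.setdefault(row["gene_id"], row["acetyl_status"])
    for gid in table["gene_id"].unique():
        out.setdefault(gid, "ns")
    return pd.Series(out, name="cre_acetyl")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_motif_bed(path: str | Path) -> list[MotifOccurrence]:
    """Read motif occurrences from a BED6-like file.

    Columns: chrom, start, end, motif_id, score, strand (0-based half-open,
    the coordinate layout FIMO hits take after conversion to BED).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: need at least 4 fields for motifs")
            chrom, start, end, motif_id = fields[:4]
            try:
                iv = Interval(chrom, int(start), int(end))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else "+"
            out.append(MotifOccurrence(iv, motif_id, strand, score))
    return out


def write_motif_bed(motifs: Iterable[MotifOccurrence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            iv = m.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{m.motif_id}\t{m.score:g}\t{m.strand}\n"
            )


def write_assignments_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
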
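"""Gene models, promoter windows, peak sets and interval algebra.

All in-memory coordinates follow the BED convention: 0-based starts and
half-open ``[start, end)`` intervals.  GTF files (1-based, closed) are
converted at the I/O boundary and nowhere else, so every comparison and
overlap computation inside the package uses a single convention.

The promoter window of a gene is the symmetric region of ``window_half``
bases on either side of the transcription start site (TSS), including the
TSS base itself, i.e. ``2 * window_half + 1`` bp when not truncated by the
chromosome start.  The TSS is strand-aware: the leftmost base of a plus
strand gene and the rightmost base of a minus strand gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "GeneRecord",
    "GenomeAnnotation",
    "PromoterWindow",
    "GtfParseError",
    "BedParseError",
    "tss_of",
    "build_promoter_windows",
    "read_gtf",
    "write_promoter_gtf",
    "read_promoter_gtf",
    "read_bed",
    "write_bed",
    "intersect_common",
]


class GtfParseError(ValueError):
    """A GTF file could not be parsed; the message carries the line number."""


class BedParseError(ValueError):
    """A BED file could not be parsed; the message carries the line number."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "Interval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene model (no transcript/exon structure)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return tss_of(self)


def tss_of(gene: GeneRecord) -> int:
    """0-based position of the first transcribed base.

    ``start`` for a plus-strand gene, ``end - 1`` for a minus-strand gene.
    """
    return gene.start if gene.strand == "+" else gene.end - 1


class GenomeAnnotation:
    """An ordered collection of :class:`GeneRecord` with unique gene ids."""

    def __init__(self, genes: Iterable[GeneRecord] = ()) -> None:
        self._genes: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._genes[gene_id]

    def get(self, gene_id: str) -> GeneRecord | None:
        return self._genes.get(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        """Genes grouped by chromosome, each group sorted by (start, end)."""
        out: dict[str, list[GeneRecord]] = {}
        for g in self:
            out.setdefault(g.chrom, []).append(g)
        for chrom in out:
            out[chrom].sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out


@dataclass(frozen=True)
class PromoterWindow:
    """Fixed-width window around a gene TSS used to quantify promoter marks."""

    gene_id: str
    interval: Interval
    tss: int

    def __post_init__(self) -> None:
        if not self.interval.contains(self.interval.chrom, self.tss):
            raise ValueError(
                f"promoter window of {self.gene_id} does not span its TSS"
            )


def build_promoter_windows(
    annotation: GenomeAnnotation, window_half: int = 1000
) -> list[PromoterWindow]:
    """One window per gene spanning ``[tss - window_half, tss + window_half]``.

    Windows are clipped at position 0 (chromosome start) only; an untruncated
    window is ``2 * window_half + 1`` bp long and always contains the TSS.
    """
    if window_half <= 0:
        raise ValueError("window_half must be positive")
    windows = []
    for gene in annotation:
        t = tss_of(gene)
        iv = Interval(gene.chrom, max(0, t - window_half), t + window_half + 1)
        windows.append(PromoterWindow(gene.gene_id, iv, t))
    return windows


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_gtf_fields(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GtfParseError(
            f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
        )
    chrom, _source, feature, start, end, _score, strand, _frame, attr_col = fields
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
    if start_i < 1 or end_i < start_i:
        raise GtfParseError(f"line {lineno}: invalid 1-based span {start}-{end}")
    attrs = dict(_ATTR_RE.findall(attr_col))
    if "gene_id" not in attrs:
        raise GtfParseError(f"line {lineno}: missing gene_id attribute")
    return chrom, feature, start_i - 1, end_i, strand, attrs


def read_gtf(
    path: str | Path, feature_types: Sequence[str] | None = ("gene",)
) -> GenomeAnnotation:
    """Read gene features from a GTF file into a :class:`GenomeAnnotation`.

    GTF 1-based closed coordinates become 0-based half-open.  Duplicate gene
    ids are rejected.  ``feature_types=None`` keeps every feature row.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            chrom, feature, start, end, strand, attrs = _parse_gtf_fields(line, lineno)
            if feature_types is not None and feature not in feature_types:
                continue
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: unknown strand symbol {strand!r}")
            genes.append(GeneRecord(attrs["gene_id"], chrom, start, end, strand))
    return GenomeAnnotation(genes)


def write_promoter_gtf(
    windows: Sequence[PromoterWindow], path: str | Path, source: str = "regucircuit"
) -> None:
    """Write promoter windows as a GTF usable for window-level read counting.

    One ``promoter`` feature per window; the 0-based TSS is preserved in a
    ``tss`` attribute so the file round-trips exactly through
    :func:`read_promoter_gtf`.
    """
    if not windows:
        raise ValueError("refusing to write an empty promoter GTF")
    with open(path, "w") as fh:
        for w in windows:
            iv = w.interval
            fh.write(
                f"{iv.chrom}\t{source}\tpromoter\t{iv.start + 1}\t{iv.end}"
                f"\t.\t.\t.\tgene_id \"{w.gene_id}\"; tss \"{w.tss}\";\n"
            )


def read_promoter_gtf(path: str | Path) -> list[PromoterWindow]:
    """Read a promoter GTF written by :func:`write_promoter_gtf`."""
    windows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            chrom, feature, start, end, _strand, attrs = _parse_gtf_fields(line, lineno)
            if feature != "promoter":
                continue
            if "tss" not in attrs:
                raise GtfParseError(f"line {lineno}: promoter feature lacks tss attribute")
            windows.append(
                PromoterWindow(attrs["gene_id"], Interval(chrom, start, end), int(attrs["tss"]))
            )
    return windows


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED3/BED5 file (0-based half-open; name col 4, score col 5)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"line {lineno}: invalid span {start}-{end} (need 0 <= start < end)"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: non-numeric score") from exc
            out.append(Interval(chrom, start, end, name=name, score=score))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED3 (or BED5 when any name/score is present)."""
    intervals = list(intervals)
    five = any(iv.name is not None or iv.score is not None for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if five:
                name = iv.name if iv.name is not None else "."
                score = repr(iv.score) if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def _sort_key(iv: Interval):
    return (iv.chrom, iv.start, iv.end)


def intersect_common(
    peaks_a: Iterable[Interval],
    peaks_b: Iterable[Interval],
    min_overlap: int = 1,
    fragments: bool = False,
) -> list[Interval]:
    """Intervals of ``peaks_a`` supported by at least one ``peaks_b`` interval.

    Report-A semantics (like ``bedtools intersect -u``): each A interval
    overlapping some B interval by at least ``min_overlap`` bases is reported
    once, in sorted (chrom, start) order.  Half-open intervals that merely
    abut do not overlap.  With ``fragments=True`` the overlapping fragments
    are reported instead (one per overlapping A/B pair, like the bedtools
    default output).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for iv in peaks_b:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    out: list[Interval] = []
    for iv in sorted(peaks_a, key=_sort_key):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.end))
        if fragments:
            for h in hits:
                s, e = max(iv.start, h.begin), min(iv.end, h.end)
                if e - s >= min_overlap:
                    out.append(Interval(iv.chrom, s, e, name=iv.name))
        else:
            if any(
                min(iv.end, h.end) - max(iv.start, h.begin) >= min_overlap
                for h in hits
            ):
                out.append(iv)
    return out
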
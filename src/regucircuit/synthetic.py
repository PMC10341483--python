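"""Synthetic study generator with planted structure.

Emulates the data shapes the analysis consumes — a toy genome of stranded
genes, motif occurrences near a subset of TSSs, negative-binomial count
tables for genes / promoter windows / CRE regions in a control-vs-mutant,
two-time-point design, and a general TF -> target regulatory network with a
densely inter-regulating, physically interacting TF core — while recording
the planted ground truth so recovery can be scored exactly.

Counts are drawn from a gamma-Poisson (negative binomial) model:
``y ~ NB(mu, alpha)`` with per-gene lognormal baseline means, planted log2
fold-changes in the mutant group, and lognormal per-sample library-size
multipliers.  Effects scale with the time point (smaller at the earlier
time), mimicking a disease course that deepens with age; this is a
qualitative choice, not a quantitative claim about any real dataset.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``; a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .annotation import GeneRecord, GenomeAnnotation, Interval
from .cre import MotifOccurrence, write_motif_bed
from .diffcount import CountMatrix
from .grn import RegulatoryNetwork, write_edges_tsv, _refresh_tf_flags
from .mr import PhysicalInteractionSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_annotation",
    "simulate_grn",
    "simulate_counts",
    "simulate_all",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults describe a small striatum-like two-time-point design:
    triplicate control and mutant libraries at an early and a later time
    point, a few hundred genes of which a tenth carry a 4-fold expression
    change in the mutant, moderate NB overdispersion (0.1, typical for bulk
    tissue replicates), and a 6-TF fully inter-regulating core whose targets
    host the planted differential genes.
    """

    seed: int = 0
    n_genes: int = 300           # total genes, TF genes included
    n_tfs: int = 30
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_500_000, "chr2": 2_500_000}
    )
    replicates_per_group: int = 3
    baseline_log2_mean: float = 6.64   # ~100 reads per feature
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0             # 4-fold planted expression effects
    acetyl_fraction: float = 0.15
    acetyl_effect_log2fc: float = 1.5
    core_size: int = 6
    core_density: float = 1.0
    core_out_fanout: int = 20
    peripheral_max_targets: int = 3
    motif_gene_fraction: float = 0.3
    motif_background_rate: float = 0.02  # occurrences per kb off-TSS
    library_size_sigma: float = 0.2
    times: tuple[str, ...] = ("4wk", "6wk")
    time_effect_scale: Mapping[str, float] = field(
        default_factory=lambda: {"4wk": 0.5, "6wk": 1.0}
    )
    tf_min_mean: float = 50.0          # TF genes are kept clearly expressed
    expression_threshold: float = 10.0  # normalized-mean cutoff for "expressed"
    mr_time: str = "6wk"

    def __post_init__(self) -> None:
        if self.core_size > self.n_tfs:
            raise ValueError("core_size cannot exceed n_tfs")
        if self.n_tfs >= self.n_genes:
            raise ValueError("need more genes than TFs")
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.acetyl_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.core_density <= 0 or self.core_density > 1:
            raise ValueError("core_density must lie in (0, 1]")
        for t in self.times:
            if t not in self.time_effect_scale:
                raise ValueError(f"no effect scale for time {t!r}")
        if self.mr_time not in self.times:
            raise ValueError("mr_time must be one of times")

    @property
    def tf_ids(self) -> list[str]:
        return [f"Tf{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def target_ids(self) -> list[str]:
        return [f"Gene{i:04d}" for i in range(1, self.n_genes - self.n_tfs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return self.tf_ids + self.target_ids

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "times" in raw:
            raw["times"] = tuple(raw["times"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted structure, recorded while generating."""

    de_effects: dict[str, float]        # gene -> signed log2fc (at scale 1)
    promoter_effects: dict[str, float]  # gene -> signed log2fc of its promoter
    cre_effects: dict[str, float]       # motif id -> signed log2fc
    cre_gene_map: dict[str, str]        # planted near-TSS motif -> gene
    core_tfs: tuple[str, ...]
    ppi_pairs: tuple[tuple[str, str], ...]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["core_tfs"] = list(self.core_tfs)
        data["ppi_pairs"] = [list(p) for p in self.ppi_pairs]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["core_tfs"] = tuple(data["core_tfs"])
        data["ppi_pairs"] = tuple(tuple(p) for p in data["ppi_pairs"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Genome + motifs
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeAnnotation, list[MotifOccurrence], dict[str, str]]:
    """Place non-overlapping stranded genes and motif occurrences.

    A fraction of genes receives a motif planted uniformly within +/-3 kb of
    its TSS (recorded in the returned truth map); background occurrences are
    sprinkled Poisson-uniformly along each chromosome.
    """
    chroms = sorted(config.chrom_sizes)
    pos = {c: 5000 for c in chroms}
    genes: list[GeneRecord] = []
    for gid in config.gene_ids:
        placed = False
        order = list(rng.permutation(len(chroms)))
        for ci in order:
            c = chroms[ci]
            length = int(rng.integers(2000, 8001))
            gap = int(rng.integers(2000, 8001))
            start = pos[c] + gap
            if start + length + 5000 > config.chrom_sizes[c]:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(gid, c, start, start + length, strand))
            pos[c] = start + length
            placed = True
            break
        if not placed:
            raise ValueError(
                f"genome too small to place {config.n_genes} genes; "
                "increase chrom_sizes"
            )
    annotation = GenomeAnnotation(genes)

    motifs: list[MotifOccurrence] = []
    cre_gene_map: dict[str, str] = {}
    n_planted = int(round(config.motif_gene_fraction * len(genes)))
    chosen_idx = sorted(rng.choice(len(genes), size=n_planted, replace=False))
    counter = 1
    for i in chosen_idx:
        g = genes[i]
        tss = g.tss
        offset = int(rng.integers(-2995, 2996))
        start = max(0, tss + offset - 5)
        motif_id = f"cre{counter:05d}"
        counter += 1
        motifs.append(
            MotifOccurrence(
                Interval(g.chrom, start, start + 10),
                motif_id,
                strand="+" if rng.random() < 0.5 else "-",
                score=float(np.round(rng.uniform(8, 20), 3)),
            )
        )
        cre_gene_map[motif_id] = g.gene_id
    for c in chroms:
        n_bg = rng.poisson(config.motif_background_rate * config.chrom_sizes[c] / 1000)
        for _ in range(int(n_bg)):
            start = int(rng.integers(0, config.chrom_sizes[c] - 10))
            motif_id = f"cre{counter:05d}"
            counter += 1
            motifs.append(
                MotifOccurrence(
                    Interval(c, start, start + 10),
                    motif_id,
                    strand="+" if rng.random() < 0.5 else "-",
                    score=float(np.round(rng.uniform(8, 20), 3)),
                )
            )
    motifs.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.motif_id))
    return annotation, motifs, cre_gene_map


# ---------------------------------------------------------------------------
# Regulatory network + physical interactions
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, items: Sequence[str], k: int) -> list[str]:
    """Sample k items without replacement, as plain sorted strings."""
    idx = rng.choice(len(items), size=k, replace=False)
    return sorted(items[i] for i in idx)


def simulate_grn(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[RegulatoryNetwork, PhysicalInteractionSet, dict[str, float], tuple[str, ...]]:
    """General GRN with a planted dense TF core.

    Core TFs regulate each other with probability ``core_density`` and each
    fans out to ``core_out_fanout`` targets from a shared pool; the planted
    differentially expressed genes are drawn from that pool, so the upstream
    neighborhood of the DE genes contains the whole core.  Peripheral TFs are
    regulated by a core TF (keeping them weakly attached, hence cleanly
    prunable) and regulate a handful of random targets.  Physical
    interactions are planted between every pair of core TFs.

    Returns (network, ppi, de_effects, core_tfs).
    """
    tfs = config.tf_ids
    targets = config.target_ids
    core = tuple(_pick(rng, tfs, config.core_size))
    periphery = [t for t in tfs if t not in core]

    net = nx.DiGraph()
    for u in core:
        for v in core:
            if u != v and rng.random() < config.core_density:
                net.add_edge(u, v, mode="unknown", sources=["synthetic"])

    pool_size = max(
        config.core_out_fanout,
        min(len(targets), config.core_size * config.core_out_fanout // 2),
    )
    pool = _pick(rng, targets, pool_size)
    covered: set[str] = set()
    for u in core:
        fan = _pick(rng, pool, min(config.core_out_fanout, len(pool)))
        for t in fan:
            net.add_edge(u, t, mode="unknown", sources=["synthetic"])
            covered.add(t)

    for p in periphery:
        boss = core[int(rng.integers(0, len(core)))]
        net.add_edge(boss, p, mode="unknown", sources=["synthetic"])
        k = int(rng.integers(1, config.peripheral_max_targets + 1))
        fan = _pick(rng, targets, k)
        for t in fan:
            net.add_edge(p, t, mode="unknown", sources=["synthetic"])
    _refresh_tf_flags(net)

    core_targets = sorted(covered)
    n_de = min(len(core_targets), int(round(config.de_fraction * config.n_genes)))
    de_genes = _pick(rng, core_targets, n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    de_effects = {g: float(s * config.de_log2fc) for g, s in zip(de_genes, signs)}

    ppi = PhysicalInteractionSet()
    for i, a in enumerate(core):
        for b in core[i + 1 :]:
            ppi.add(a, b)
    return net, ppi, de_effects, core


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion < 1e-7:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.times:
        for cond in ("control", "mutant"):
            for r in range(1, config.replicates_per_group + 1):
                rows.append(
                    {"sample_id": f"{cond}_{t}_rep{r}", "condition": cond, "time": t}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _counts_matrix(
    config: SimulationConfig,
    rng: np.random.Generator,
    feature_ids: Sequence[str],
    base_log2: np.ndarray,
    effects: Mapping[str, float],
    samples: pd.DataFrame,
    lib_factors: np.ndarray,
) -> CountMatrix:
    n_feat, n_samp = len(feature_ids), len(samples)
    log2_mu = np.tile(base_log2[:, None], (1, n_samp))
    idx = {f: i for i, f in enumerate(feature_ids)}
    for j, (sid, row) in enumerate(samples.iterrows()):
        if row["condition"] != "mutant":
            continue
        scale = config.time_effect_scale[row["time"]]
        for feat, eff in effects.items():
            if feat in idx:
                log2_mu[idx[feat], j] += eff * scale
    mu = np.exp2(log2_mu) * lib_factors[None, :]
    counts = _nb_draw(rng, mu, config.dispersion)
    frame = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                         columns=samples.index)
    return CountMatrix(frame, samples["condition"], samples["time"])


def simulate_counts(
    config: SimulationConfig,
    rng: np.random.Generator,
    de_effects: Mapping[str, float],
    motif_ids: Sequence[str],
    cre_gene_map: Mapping[str, str],
) -> tuple[CountMatrix, CountMatrix, CountMatrix, dict[str, float], dict[str, float]]:
    """NB count matrices for genes, promoter windows and CRE regions.

    Gene counts carry the planted expression effects; promoter and CRE
    matrices carry independent planted acetylation effects (promoters are
    sampled across all genes, CRE effects across the planted near-TSS
    motifs).  One shared lognormal library-size multiplier per sample.

    Returns (genes, promoters, cre, promoter_effects, cre_effects).
    """
    samples = _sample_frame(config)
    lib = np.exp(rng.normal(0.0, config.library_size_sigma, size=len(samples)))

    gene_ids = config.gene_ids
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(gene_ids))
    n_tf = config.n_tfs
    base[:n_tf] = np.maximum(base[:n_tf], np.log2(config.tf_min_mean))
    genes = _counts_matrix(config, rng, gene_ids, base, de_effects, samples, lib)

    prom_base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(gene_ids))
    n_prom = int(round(config.acetyl_fraction * len(gene_ids)))
    prom_idx = sorted(rng.choice(len(gene_ids), size=n_prom, replace=False))
    prom_signs = rng.choice([-1.0, 1.0], size=n_prom)
    promoter_effects = {
        gene_ids[i]: float(s * config.acetyl_effect_log2fc)
        for i, s in zip(prom_idx, prom_signs)
    }
    promoters = _counts_matrix(
        config, rng, gene_ids, prom_base, promoter_effects, samples, lib
    )

    cre_base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(motif_ids))
    planted = sorted(cre_gene_map)
    n_cre = max(1, len(planted) // 2) if planted else 0
    cre_pick = sorted(rng.choice(len(planted), size=n_cre, replace=False)) if planted else []
    cre_signs = rng.choice([-1.0, 1.0], size=len(cre_pick))
    cre_effects = {
        planted[i]: float(s * config.acetyl_effect_log2fc)
        for i, s in zip(cre_pick, cre_signs)
    }
    cre = _counts_matrix(config, rng, list(motif_ids), cre_base, cre_effects, samples, lib)
    return genes, promoters, cre, promoter_effects, cre_effects


# ---------------------------------------------------------------------------
# Whole-study wrapper
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: GenomeAnnotation
    motifs: list[MotifOccurrence]
    gene_counts: CountMatrix
    promoter_counts: CountMatrix
    cre_counts: CountMatrix
    grn: RegulatoryNetwork
    ppi: PhysicalInteractionSet
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write every table in its on-disk exchange format."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genes.gtf", "w") as fh:
            for g in self.annotation:
                fh.write(
                    f"{g.chrom}\tregucircuit\tgene\t{g.start + 1}\t{g.end}"
                    f"\t.\t{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
                )
        write_motif_bed(self.motifs, outdir / "motifs.bed")
        for name, cm in (
            ("counts_genes.tsv", self.gene_counts),
            ("counts_promoters.tsv", self.promoter_counts),
            ("counts_cre.tsv", self.cre_counts),
        ):
            cm.counts.to_csv(outdir / name, sep="\t")
        sheet = pd.DataFrame(
            {"condition": self.gene_counts.condition, "time": self.gene_counts.time}
        )
        sheet.index.name = "sample_id"
        sheet.to_csv(outdir / "samples.tsv", sep="\t")
        write_edges_tsv(self.grn, outdir / "grn.tsv")
        self.ppi.to_tsv(outdir / "ppi.tsv")
        self.truth.to_json(outdir / "truth.json")


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study from one seed."""
    rng = np.random.default_rng(config.seed)
    annotation, motifs, cre_gene_map = simulate_annotation(config, rng)
    grn_net, ppi, de_effects, core = simulate_grn(config, rng)
    motif_ids = [m.motif_id for m in motifs]
    genes, promoters, cre, promoter_effects, cre_effects = simulate_counts(
        config, rng, de_effects, motif_ids, cre_gene_map
    )
    truth = GroundTruth(
        de_effects=de_effects,
        promoter_effects=promoter_effects,
        cre_effects=cre_effects,
        cre_gene_map=cre_gene_map,
        core_tfs=core,
        ppi_pairs=tuple(sorted(ppi.pairs)),
    )
    return SimulatedStudy(
        config=config,
        annotation=annotation,
        motifs=motifs,
        gene_counts=genes,
        promoter_counts=promoters,
        cre_counts=cre,
        grn=grn_net,
        ppi=ppi,
        truth=truth,
    )
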
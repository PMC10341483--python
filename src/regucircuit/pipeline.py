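"""End-to-end orchestration: simulate -> differential tests -> networks -> MRs.

This is the glue that runs the whole analysis on a synthetic study in one
call, mirroring how the stages combine on real data: differential expression
(BH-adjusted) and differential acetylation (raw p, the convention for the
promoter/CRE count tables), CRE-to-gene assignment, contextualization of the
general network per condition, node annotation, and master-regulator
inference contrasted between conditions.

Every artifact can be written to an output directory; writing is fully
deterministic for a fixed config, so two runs from the same seed produce
byte-identical files (including the MR deletion traces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cre as cre_mod
from . import grn as grn_mod
from . import mr as mr_mod
from .diffcount import DiffConfig, nb_test, write_results_tsv
from .mr import MRReport
from .synthetic import SimulatedStudy, SimulationConfig, simulate_all

__all__ = ["PipelineResult", "run_pipeline", "infer_mrs"]


@dataclass
class PipelineResult:
    study: SimulatedStudy
    de: pd.DataFrame
    de_genes: list[str]
    promoter_diff: pd.DataFrame
    cre_diff: pd.DataFrame
    cre_table: pd.DataFrame
    expressed_control: set[str]
    expressed_mutant: set[str]
    network_control: grn_mod.RegulatoryNetwork
    network_mutant: grn_mod.RegulatoryNetwork
    report_control: MRReport
    report_mutant: MRReport
    contrast: dict[str, set[str]]


def infer_mrs(
    network: grn_mod.RegulatoryNetwork,
    de_genes,
    general: grn_mod.RegulatoryNetwork,
    ppi: mr_mod.PhysicalInteractionSet,
    depth: int = 2,
    rule: str = "both",
    min_core_size: int = 2,
) -> MRReport:
    """Upstream neighborhood -> densest core -> candidate validation.

    Candidates are the surviving nodes that are TFs in the *general* network
    (the definition concerns regulators, even if a TF kept no outgoing edge
    in this particular context).  Returns an empty report if no seed gene
    occurs in the network.
    """
    seeds = sorted(set(de_genes) & set(network.nodes))
    if not seeds:
        return MRReport(
            seed_genes=frozenset(),
            neighborhood_nodes=frozenset(),
            core_candidates=(),
            deletion_trace=(),
            validated_mrs=frozenset(),
        )
    sub = mr_mod.upstream_neighborhood(network, seeds, depth=depth)
    core, trace = mr_mod.densest_core(sub, min_core_size=min_core_size)
    candidates = [n for n in core if general.out_degree(n) > 0]
    return mr_mod.validate_mrs(
        candidates,
        network,
        ppi,
        rule=rule,
        seed_genes=seeds,
        neighborhood_nodes=sub.nodes,
        deletion_trace=trace,
    )


def run_pipeline(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
    rule: str = "both",
    depth: int = 2,
) -> PipelineResult:
    """Run the full synthetic-study analysis at ``config.mr_time``."""
    config = config or SimulationConfig()
    study = simulate_all(config)
    t = config.mr_time

    genes_t = study.gene_counts.subset_time(t)
    de = nb_test(genes_t, DiffConfig(alpha=0.05, use_adjusted=True))
    de_genes = sorted(de.index[de["status"] != "ns"])

    prom_diff = nb_test(
        study.promoter_counts.subset_time(t), DiffConfig(alpha=0.05, use_adjusted=False)
    )
    cre_diff = nb_test(
        study.cre_counts.subset_time(t), DiffConfig(alpha=0.05, use_adjusted=False)
    )
    assignments = cre_mod.assign_cre_genes(study.motifs, study.annotation)
    cre_table, _unmatched = cre_mod.cre_acetylation_table(assignments, cre_diff)
    cre_status = cre_mod.gene_cre_status(cre_table)

    expressed_control = grn_mod.expressed_genes(
        genes_t, condition="control", threshold=config.expression_threshold
    )
    expressed_mutant = grn_mod.expressed_genes(
        genes_t, condition="mutant", threshold=config.expression_threshold
    )
    net_c = grn_mod.contextualize(study.grn, expressed_control)
    net_m = grn_mod.contextualize(study.grn, expressed_mutant)
    for net in (net_c, net_m):
        grn_mod.annotate(net, de=de, prom_acetyl=prom_diff, cre_status=cre_status)

    report_c = infer_mrs(net_c, de_genes, study.grn, study.ppi, depth=depth, rule=rule)
    report_m = infer_mrs(net_m, de_genes, study.grn, study.ppi, depth=depth, rule=rule)
    contrast = mr_mod.mr_condition_contrast(report_c, report_m)

    result = PipelineResult(
        study=study,
        de=de,
        de_genes=de_genes,
        promoter_diff=prom_diff,
        cre_diff=cre_diff,
        cre_table=cre_table,
        expressed_control=expressed_control,
        expressed_mutant=expressed_mutant,
        network_control=net_c,
        network_mutant=net_m,
        report_control=report_c,
        report_mutant=report_m,
        contrast=contrast,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.study.write(outdir / "sim")
    write_results_tsv(result.de, outdir / "de.tsv")
    write_results_tsv(result.promoter_diff, outdir / "diff_promoters.tsv")
    write_results_tsv(result.cre_diff, outdir / "diff_cre.tsv")
    cre_mod.write_assignments_tsv(result.cre_table, outdir / "cre_genes.tsv")
    for name, genes in (
        ("expressed_control.txt", result.expressed_control),
        ("expressed_mutant.txt", result.expressed_mutant),
    ):
        with open(outdir / name, "w") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")
    grn_mod.write_graphml(result.network_control, outdir / "net_control.graphml")
    grn_mod.write_graphml(result.network_mutant, outdir / "net_mutant.graphml")
    stats_c, stats_m = grn_mod.compare_networks(
        result.network_control, result.network_mutant
    )
    with open(outdir / "network_stats.tsv", "w") as fh:
        fh.write(
            "network\ttotal_nodes\ttotal_tfs\ttotal_edges"
            "\tunique_nodes\tunique_tfs\tunique_edges\n"
        )
        for name, s in (("control", stats_c), ("mutant", stats_m)):
            fh.write(
                f"{name}\t{s.total_nodes}\t{s.total_tfs}\t{s.total_edges}"
                f"\t{s.unique_nodes_vs_other}\t{s.unique_tfs_vs_other}"
                f"\t{s.unique_edges_vs_other}\n"
            )
    result.report_control.to_tsv(outdir / "mr_control.tsv")
    result.report_control.trace_to_tsv(outdir / "mr_control_trace.tsv")
    result.report_mutant.to_tsv(outdir / "mr_mutant.tsv")
    result.report_mutant.trace_to_tsv(outdir / "mr_mutant_trace.tsv")
    with open(outdir / "mr_contrast.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in result.contrast.items()}, fh, indent=1)
        fh.write("\n")
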
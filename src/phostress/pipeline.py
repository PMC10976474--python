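"""End-to-end orchestration: simulate inputs, run every stage, write a report.

The pipeline wires the stages in dependency order — synthetic genome →
promoter scan; synthetic tree pair → congruence test; synthetic counts →
differential expression; packaged DE-gene table → genomic clustering;
synthetic growth/qPCR series → kinetics calls; budget and the
genotype–phenotype association on the phage panel table.  Each stage writes
its outputs before the next starts; the report carries per-stage summaries
plus a provenance block (config hash, seed) and is written as JSON and
plain text.  Runs are deterministic for a fixed config: stage seeds are
derived from the global seed by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import budget as budget_mod
from . import congruence as congruence_mod
from . import de as de_mod
from . import formats, homology, kinetics, phobox, simulate
from .exceptions import ConfigurationError

DEFAULT_STAGES = ("scan", "congruence", "de", "cluster", "kinetics", "budget", "association")


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "phostress_run"
    stages: tuple[str, ...] = DEFAULT_STAGES
    window: int = phobox.DEFAULT_WINDOW
    max_mismatch: int = phobox.DEFAULT_MAX_MISMATCH
    spacer: int = 3
    alpha: float = de_mod.DEFAULT_ALPHA
    max_gap: int = de_mod.DEFAULT_MAX_GAP
    drop_fraction: float = kinetics.DEFAULT_DROP_FRACTION
    delay_threshold: float = kinetics.DEFAULT_DELAY_THRESHOLD
    rate_window: tuple[float, float] = kinetics.DEFAULT_RATE_WINDOW
    tree_leaves: int = 20
    tree_transfers: int = 4
    tree_noise_sd: float = 0.2
    panel_table: tuple[tuple[int, int], tuple[int, int]] = ((17, 0), (0, 1))

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.window < 1 or self.max_gap < 0 or self.max_mismatch < 0:
            raise ConfigurationError("window/max_gap/max_mismatch out of range")

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "rate_window" in raw:
            raw["rate_window"] = tuple(raw["rate_window"])
        if "panel_table" in raw:
            raw["panel_table"] = tuple(tuple(r) for r in raw["panel_table"])
        return cls(**raw)

    def canonical(self) -> str:
        # outdir is a filesystem detail, not part of the analysis identity
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        return json.dumps(payload, sort_keys=True, default=list)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return (and write) the pipeline report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {"seed": config.seed, "config_sha256_16": config.digest()},
        "stages": {},
    }
    if "scan" in config.stages:
        report["stages"]["scan"] = _stage_scan(config, out)
    if "congruence" in config.stages:
        report["stages"]["congruence"] = _stage_congruence(config, out)
    if "de" in config.stages:
        report["stages"]["de"] = _stage_de(config, out)
    if "cluster" in config.stages:
        report["stages"]["cluster"] = _stage_cluster(config, out)
    if "kinetics" in config.stages:
        report["stages"]["kinetics"] = _stage_kinetics(config, out)
    if "budget" in config.stages:
        report["stages"]["budget"] = _stage_budget(out)
    if "association" in config.stages:
        report["stages"]["association"] = _stage_association(config, out)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "report.txt").write_text(_render_report(report))
    return report


def _stage_scan(config: PipelineConfig, out: Path) -> dict:
    model = phobox.compile_motif(
        spacer_lengths={config.spacer}, max_mismatch=config.max_mismatch
    )
    annotation, truth = simulate.simulate_genome(
        simulate.GenomeSimConfig(seed=config.seed + 1), model
    )
    fasta, tsv = formats.write_genome_table(annotation)
    (out / "genome.fasta").write_text(fasta)
    (out / "features.tsv").write_text(tsv)
    hits = phobox.find_pho_boxes(annotation, model, config.window)
    hits.to_csv(out / "phobox_hits.tsv", sep="\t", index=False)
    (out / "phobox_hits.bed").write_text(phobox.hits_to_bed(annotation, hits))
    planted = truth["planted_boxes"]
    recovered = sum(
        1
        for gene, info in planted.items()
        if ((hits["gene_id"] == gene) & (hits["position"] == info["offset"])).any()
    )
    return {
        "genes_scanned": len(annotation.features),
        "boxes_planted": len(planted),
        "boxes_found": int(len(hits)),
        "planted_recovered": recovered,
    }


def _stage_congruence(config: PipelineConfig, out: Path) -> dict:
    core, gene, truth = simulate.simulate_tree_pair(
        simulate.TreeSimConfig(
            seed=config.seed + 2,
            n_leaves=config.tree_leaves,
            transfer_events=config.tree_transfers,
            length_noise_sd=config.tree_noise_sd,
        )
    )
    (out / "core.nwk").write_text(formats.write_newick(core) + "\n")
    (out / "gene.nwk").write_text(formats.write_newick(gene) + "\n")
    rf = congruence_mod.robinson_foulds(core, gene)
    res = congruence_mod.congruence_test(
        core, gene, permutations=199, seed=config.seed + 3
    )
    m1 = congruence_mod.patristic_matrix(core)
    m2 = congruence_mod.patristic_matrix(gene, m1.labels)
    pd.DataFrame(
        {"core_distance": m1.upper_triangle(), "gene_distance": m2.upper_triangle()}
    ).to_csv(out / "pair_distances.tsv", sep="\t", index=False)
    summary = {
        "transfers_simulated": truth["transfers"],
        "rf_unweighted": rf.unweighted,
        "rf_weighted": rf.weighted,
        "pearson_r": res.pearson_r,
        "p_value": res.p_value,
        "mantel_p": res.permutation_p,
        "n_pairs": res.n_pairs,
    }
    (out / "congruence.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_de(config: PipelineConfig, out: Path) -> dict:
    matrix, truth = simulate.simulate_counts(
        simulate.regulon_counts_config(seed=config.seed + 4)
    )
    counts = pd.DataFrame(matrix.counts, index=matrix.genes, columns=matrix.samples)
    counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        {
            "sample": matrix.samples,
            "condition": matrix.conditions,
            "total_reads": matrix.totals.astype(int),
        }
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    results = de_mod.nb_wald_test(matrix, alpha=config.alpha)
    results.to_csv(out / "de_results.tsv", sep="\t", index=False)
    significant = de_mod.de_filter(results, alpha=config.alpha)
    regulon = truth["regulon"]
    return {
        "genes_tested": len(results),
        "significant": len(significant),
        "regulon_size": len(regulon),
        "regulon_recovered": len(set(significant) & set(regulon)),
    }


def _stage_cluster(config: PipelineConfig, out: Path) -> dict:
    table = formats.load_de_gene_table()
    genes = list(table.loc[~table["misannotated"], "cds_id"])
    clusters = de_mod.cluster_de_genes(genes, table, max_gap=config.max_gap)
    pd.DataFrame(
        {
            "size": [c.size for c in clusters],
            "span_start": [c.span[0] for c in clusters],
            "span_stop": [c.span[1] for c in clusters],
            "members": [",".join(c.members) for c in clusters],
        }
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    return {
        "de_genes": len(genes),
        "n_clusters": len(clusters),
        "largest_cluster": clusters[0].size if clusters else 0,
        "largest_members": clusters[0].members if clusters else [],
    }


def _stage_kinetics(config: PipelineConfig, out: Path) -> dict:
    curves, truth = simulate.simulate_growth_curves(
        simulate.GrowthSimConfig(seed=config.seed + 5)
    )
    _write_long_csv(
        out / "growth.csv",
        ["replicate", "condition", "infected", "time_h", "od750"],
        (
            (c.replicate, c.condition, int(c.infected), t, v)
            for c in curves
            for t, v in zip(c.times, c.od)
        ),
    )
    series, qtruth = simulate.simulate_qpcr(
        simulate.QpcrSimConfig(seed=config.seed + 6)
    )
    _write_long_csv(
        out / "qpcr.csv",
        ["replicate", "condition", "time_h", "percent_initial_dna"],
        (
            (s.replicate, s.condition, t, v)
            for s in series
            for t, v in zip(s.times, s.percent)
        ),
    )
    pair = {}
    for condition in ("replete", "deplete"):
        control = next(c for c in curves if c.condition == condition and not c.infected)
        infected = next(c for c in curves if c.condition == condition and c.infected)
        pair[condition] = (infected, control)
    call = kinetics.lysis_delay(
        pair["replete"],
        pair["deplete"],
        threshold=config.delay_threshold,
        drop_fraction=config.drop_fraction,
    )
    slopes = {
        condition: [
            kinetics.replication_rate(s, config.rate_window)
            for s in series
            if s.condition == condition
        ]
        for condition in ("replete", "deplete")
    }
    comparison = kinetics.two_sample_t(slopes["replete"], slopes["deplete"])
    summary = {
        "lysis_time_replete_h": call.lysis_time_replete,
        "lysis_time_deplete_h": call.lysis_time_deplete,
        "delay_h": call.delay,
        "delayed": call.delayed,
        "true_delay_h": truth["config"].delay,
        "slope_replete_mean": float(np.mean(slopes["replete"])),
        "slope_deplete_mean": float(np.mean(slopes["deplete"])),
        "true_slopes": qtruth["slopes"],
        "t": comparison.t,
        "df": comparison.df,
        "p": comparison.p,
    }
    (out / "kinetics.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_budget(out: Path) -> dict:
    result = budget_mod.phosphate_released()
    both = budget_mod.phosphate_released(
        budget_mod.BudgetInput(count_both_strands=True)
    )
    summary = {
        "total_phosphate": result.total_phosphate,
        "order_of_magnitude": result.order_of_magnitude,
        "both_strand_total": both.total_phosphate,
        "both_strand_order": both.order_of_magnitude,
    }
    (out / "budget.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_association(config: PipelineConfig, out: Path) -> dict:
    result = homology.association_test(config.panel_table)
    summary = {
        "contingency": [list(r) for r in result.contingency],
        "odds_direction": result.odds_direction,
        "fisher_p_one_sided": result.fisher_p_one_sided,
        "fisher_p_two_sided": result.fisher_p_two_sided,
    }
    (out / "association.json").write_text(json.dumps(summary, indent=2))
    return summary


def _write_long_csv(path: Path, header: list[str], rows) -> None:
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")


def _render_report(report: dict) -> str:
    lines = [
        "phostress pipeline report",
        f"seed: {report['provenance']['seed']}",
        f"config hash: {report['provenance']['config_sha256_16']}",
        "",
    ]
    for stage, summary in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, value in summary.items():
            lines.append(f"  {key}: {value}")
        lines.append("")
    return "\n".join(lines)
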
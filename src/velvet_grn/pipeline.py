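"""End-to-end orchestration: promoters -> assignment -> DEG calling ->
target classification -> peak matching -> motif elicitation -> GRN -> core ->
enrichment -> summary report.

Every stage is an ordinary library call, so each is independently testable;
this module only wires them in dependency order, logs row counts, and
collects the headline statistics into a :class:`SummaryReport` whose every
percentage recomputes from its own counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from velvet_grn import annotation_io, enrich_stats, grn_build, motif_elicit, peak_ops
from velvet_grn import target_classify as tc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and stage parameters for a full pipeline run."""

    genome_fasta: str
    gene_models: str
    peaks_a: str
    peaks_b: str
    de_a: str
    de_b: str
    string_links: str
    aliases: str
    regulator_a: str = "veA"
    regulator_b: str = "laeA"
    gmt: str | None = None
    gene_models_format: str = "tsv"
    peak_format: str = "narrowPeak"
    upstream_bp: int = 1500
    alpha: float = 0.05
    min_fold: float = 2.0
    max_dist: int = 100
    k: int = 10
    half_width: int = 100
    n_motifs: int = 2
    min_score: int = 150
    p_cut: float = 0.05
    rng_seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        required = ["genome_fasta", "gene_models", "peaks_a", "peaks_b",
                    "de_a", "de_b", "string_links", "aliases"]
        for name in required:
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise FileNotFoundError(f"gmt: {self.gmt} does not exist")
        if not (0 < self.alpha < 1 and 0 < self.p_cut < 1):
            raise ValueError("alpha and p_cut must lie in (0, 1)")
        if min(self.upstream_bp, self.max_dist, self.k, self.half_width,
               self.n_motifs) <= 0 or self.min_score < 0 or self.min_fold <= 1:
            raise ValueError("stage parameter outside its documented range")


@dataclass
class SummaryReport:
    """Headline statistics of a run, in the inventory style of the study report."""

    per_regulator: dict[str, dict] = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    motifs: list[dict] = field(default_factory=list)
    enrichment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    report: SummaryReport
    targets: dict[str, list[tc.TargetRecord]]
    peak_genes: dict[str, set[str]]
    matches: list[peak_ops.PeakMatch]
    motifs: list[motif_elicit.MotifModel]
    grns: dict
    cores: dict
    enrichment: dict[str, list[enrich_stats.EnrichmentRow]]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage in dependency order and return outputs plus report.

    Deterministic for a fixed ``rng_seed`` (the motif background shuffle is
    the only stochastic stage). Fails before any stage runs if a referenced
    input is missing.
    """
    config.validate()
    report = SummaryReport()

    genome_index, genome_seqs = annotation_io.read_fasta(config.genome_fasta)
    genes = annotation_io.read_gene_models(config.gene_models, format=config.gene_models_format)
    windows = annotation_io.promoter_windows(genes, genome_index, config.upstream_bp)
    logger.info("promoters: %d genes, %d windows", len(genes), len(windows))

    universe = [g.gene_id for g in genes]
    peaks, peak_genes, de_calls, targets, counts = {}, {}, {}, {}, {}
    regs = {"a": config.regulator_a, "b": config.regulator_b}
    for which in ("a", "b"):
        pk = peak_ops.read_peaks(getattr(config, f"peaks_{which}"), format=config.peak_format)
        assignments, gene_ids = peak_ops.assign_peaks_to_promoters(pk, windows)
        de = tc.read_de_table(getattr(config, f"de_{which}"))
        calls = tc.classify_degs(de, alpha=config.alpha, min_fold=config.min_fold)
        recs, cts = tc.classify_targets(gene_ids, calls, universe)
        peaks[which], peak_genes[which] = pk, gene_ids
        de_calls[which], targets[which], counts[which] = calls, recs, cts
        n_deg = sum(1 for c in calls if c.is_deg)
        n_up = sum(1 for c in calls if c.direction == "up")
        report.per_regulator[regs[which]] = {
            "n_genes_universe": len(universe),
            "n_deg": n_deg,
            "pct_deg": tc.percent(n_deg, len(universe), 2),
            "n_up": n_up,
            "n_down": n_deg - n_up,
            "n_peak_associated": len(gene_ids),
            "n_direct": cts["n_direct"],
            "pct_direct": tc.percent(cts["n_direct"], len(universe), 2),
            "n_putative": cts["n_putative"],
        }
        logger.info("regulator %s: %d peaks, %d bound genes, %d direct",
                    regs[which], len(pk), len(gene_ids), cts["n_direct"])

    common_direct, summary = tc.common_direct_targets(targets["a"], targets["b"])
    common_putative, excl = tc.common_putative_targets(peak_genes["a"], peak_genes["b"])
    matches = peak_ops.match_overlapping_peaks(peaks["a"], peaks["b"], config.max_dist)
    report.pairwise = {
        "n_common_direct": summary.n_common,
        "n_same_direction": summary.n_same_direction,
        "n_both_up": summary.n_both_up,
        "n_both_down": summary.n_both_down,
        "pct_same_direction": summary.pct_same_direction,
        "n_common_putative": len(common_putative),
        **excl,
        "n_overlapping_peaks": len(matches),
    }

    # motif elicitation on the overlapping peaks (regulator-A member of each pair)
    matched_a = {m.peak_id_a for m in matches}
    overlap_peaks = [p for p in peaks["a"] if p.peak_id in matched_a]
    target_seqs = motif_elicit.extract_peak_sequences(
        genome_seqs, overlap_peaks, half_width=config.half_width)
    motifs = motif_elicit.discover_motifs(
        target_seqs, k=config.k, n_motifs=config.n_motifs, seed=config.rng_seed)
    report.motifs = [
        {"rank": i + 1, "consensus": m.consensus, "gamma": round(m.gamma, 4),
         "pct_with_motif": round(m.pct_with_motif, 2), "log10_p": round(m.log10_p, 2)}
        for i, m in enumerate(motifs)
    ]

    raw_edges = grn_build.read_string_links(config.string_links)
    alias = grn_build.read_alias(config.aliases)
    edges, _ = grn_build.map_edges_to_genes(raw_edges, alias)
    grns, cores = {}, {}
    for which in ("a", "b"):
        grn = grn_build.build_grn(targets[which], edges, regs[which], config.min_score)
        grns[which] = grn
        report.network[f"grn_{regs[which]}"] = {
            "n_nodes": grn.number_of_nodes(), "n_edges": grn.number_of_edges()}
        if regs[which] in grn:
            core = grn_build.core_section(grn, [regs[which]])
            cores[which] = core
            report.network[f"core_{regs[which]}"] = {
                "n_nodes": core.number_of_nodes(), "n_edges": core.number_of_edges(),
                "n_direct": sum(1 for _, s in core.nodes(data="status") if s == "direct"),
                "n_putative": sum(1 for _, s in core.nodes(data="status")
                                  if s == "putative_direct"),
            }
    common_statuses = grn_build.common_grn_statuses(targets["a"], targets["b"])
    common_grn = grn_build.build_grn(common_statuses, edges, regs["a"], config.min_score)
    grns["common"] = common_grn
    report.network["grn_common"] = {
        "n_nodes": common_grn.number_of_nodes(), "n_edges": common_grn.number_of_edges()}
    common_seeds = [r for r in regs.values() if r in common_grn]
    if common_seeds:
        cores["common"] = grn_build.core_section(common_grn, common_seeds)
        report.network["core_common"] = {
            "n_nodes": cores["common"].number_of_nodes(),
            "n_edges": cores["common"].number_of_edges()}

    enrichment: dict[str, list[enrich_stats.EnrichmentRow]] = {}
    if config.gmt is not None:
        annotation = enrich_stats.read_gmt(config.gmt)
        for which in ("a", "b"):
            if which not in cores:
                continue
            query = [g for g in cores[which].nodes if g != regs[which]]
            rows = enrich_stats.enrich(query, annotation, universe, p_cut=config.p_cut)
            enrichment[regs[which]] = rows
            report.enrichment[regs[which]] = [
                {"term_id": r.term_id, "k": r.k, "K": r.K, "p": r.p} for r in rows[:10]]

    result = PipelineResult(report, targets, peak_genes, matches, motifs,
                            grns, cores, enrichment)
    if config.outdir is not None:
        _write_outputs(config, result)
    return result


def _write_outputs(config: RunConfig, result: PipelineResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regs = {"a": config.regulator_a, "b": config.regulator_b}
    for which in ("a", "b"):
        tc.write_target_table(result.targets[which], outdir / f"targets_{regs[which]}.tsv")
    with open(outdir / "overlapping_peaks.tsv", "w") as fh:
        fh.write("peak_id_a\tpeak_id_b\tcenter_distance\n")
        for m in result.matches:
            fh.write(f"{m.peak_id_a}\t{m.peak_id_b}\t{m.center_distance}\n")
    motif_elicit.write_motif_report(result.motifs, outdir / "motifs.tsv")
    motif_elicit.write_meme_minimal(result.motifs, outdir / "motifs.meme")
    for name, grn in result.grns.items():
        if grn.number_of_nodes():
            grn_build.export_graph(grn, outdir / f"grn_{name}")
    for name, core in result.cores.items():
        grn_build.export_graph(core, outdir / f"core_{name}")
    for reg, rows in result.enrichment.items():
        enrich_stats.write_enrichment(rows, outdir / f"enrichment_{reg}.tsv")
    render_report(result.report, outdir / "report.json", format="json")
    render_report(result.report, outdir / "report.txt", format="text")
    manifest = {"config": dataclasses.asdict(config), "seed": config.rng_seed}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def render_report(report: SummaryReport, path: str | Path, format: str = "text") -> Path:
    """Render the summary report as json, tsv, or publication-style text."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        return path
    if format == "tsv":
        lines = ["section\tkey\tvalue"]
        flat: list[tuple[str, str, object]] = []
        for reg, stats in report.per_regulator.items():
            flat += [(f"regulator:{reg}", k, v) for k, v in stats.items()]
        flat += [("pairwise", k, v) for k, v in report.pairwise.items()]
        for sect, stats in report.network.items():
            flat += [(f"network:{sect}", k, v) for k, v in stats.items()]
        lines += [f"{s}\t{k}\t{v}" for s, k, v in flat]
        path.write_text("\n".join(lines) + "\n")
        return path
    if format != "text":
        raise ValueError(f"unknown report format: {format!r}")
    lines = []
    for reg, s in report.per_regulator.items():
        lines.append(f"[{reg}]")
        lines.append(f"  DEGs: {s['n_deg']} ({s['pct_deg']}% of {s['n_genes_universe']} genes);"
                     f" {s['n_up']} up, {s['n_down']} down")
        lines.append(f"  peak-associated genes: {s['n_peak_associated']}")
        lines.append(f"  direct targets: {s['n_direct']} ({s['pct_direct']}% of"
                     f" {s['n_genes_universe']} genes); putative direct: {s['n_putative']}")
    p = report.pairwise
    if p:
        lines.append("[pairwise]")
        lines.append(f"  common direct targets: {p['n_common_direct']};"
                     f" same regulation pattern: {p['n_same_direction']}"
                     f" ({p['pct_same_direction']}%);"
                     f" {p['n_both_up']} both up, {p['n_both_down']} both down")
        lines.append(f"  common putative targets: {p['n_common_putative']};"
                     f" overlapping peaks: {p['n_overlapping_peaks']}")
    for i, m in enumerate(report.motifs, 1):
        lines.append(f"[motif {i}] 5'-{m['consensus']}-3' ({m['pct_with_motif']}% of input"
                     f" peaks with a log10 P value of {m['log10_p']})")
    if report.network:
        lines.append("[network]")
        for sect, s in report.network.items():
            lines.append(f"  {sect}: {s['n_nodes']} nodes, {s['n_edges']} edges")
    else:
        lines.append("[network] empty - no section to report")
    path.write_text("\n".join(lines) + "\n")
    return path
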
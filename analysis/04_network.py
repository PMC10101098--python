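"""Build the regulator-mediated GRNs, extract first-neighbor cores, and test
the core gene sets for over-representation in the bundled annotation.

Overlays each regulator's direct + putative-direct targets on the STRING-
format PPI table (combined score >= 150, both endpoints targets), extracts
the first neighbors of the regulator, and runs hypergeometric enrichment of
the core genes against the bundled GMT. Graph exports go to scratch/,
summaries to results/.
"""

import json
from pathlib import Path

from velvet_grn import annotation_io, enrich_stats, grn_build, peak_ops
from velvet_grn import target_classify as tc
from velvet_grn.synthetic_data import SimConfig

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    cfg = SimConfig()
    genome, _ = annotation_io.read_fasta(BUNDLE / "genome.fa")
    genes = annotation_io.read_gene_models(BUNDLE / "genes.tsv", format="tsv")
    windows = annotation_io.promoter_windows(genes, genome)
    universe = [g.gene_id for g in genes]

    raw = grn_build.read_string_links(BUNDLE / "string_links.tsv")
    alias = grn_build.read_alias(BUNDLE / "aliases.tsv")
    edges, _ = grn_build.map_edges_to_genes(raw, alias)
    annotation = enrich_stats.read_gmt(BUNDLE / "gene_sets.gmt")

    regs = {"a": cfg.regulator_a, "b": cfg.regulator_b}
    summary = {}
    targets = {}
    for which in ("a", "b"):
        peaks = peak_ops.read_peaks(BUNDLE / f"peaks_{which}.narrowPeak")
        _, gene_ids = peak_ops.assign_peaks_to_promoters(peaks, windows)
        calls = tc.classify_degs(tc.read_de_table(BUNDLE / f"de_{which}.tsv"))
        targets[which], _ = tc.classify_targets(gene_ids, calls, universe)
        grn = grn_build.build_grn(targets[which], edges, regs[which])
        core = grn_build.core_section(grn, [regs[which]])
        grn_build.export_graph(grn, ROOT / "scratch" / f"grn_{which}")
        grn_build.export_graph(core, ROOT / "scratch" / f"core_{which}")
        rows = enrich_stats.enrich(
            [g for g in core.nodes if g != regs[which]], annotation, universe)
        summary[regs[which]] = {
            "grn": {"n_nodes": grn.number_of_nodes(), "n_edges": grn.number_of_edges()},
            "core": {"n_nodes": core.number_of_nodes(), "n_edges": core.number_of_edges()},
            "top_enriched_terms": [
                {"term_id": r.term_id, "k": r.k, "K": r.K, "p": r.p} for r in rows[:3]],
        }

    common_statuses = grn_build.common_grn_statuses(targets["a"], targets["b"])
    common = grn_build.build_grn(common_statuses, edges, cfg.regulator_a)
    summary["common"] = {
        "n_universe": len(common_statuses),
        "grn": {"n_nodes": common.number_of_nodes(), "n_edges": common.number_of_edges()},
    }
    out = ROOT / "results" / "04_network_summary.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
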
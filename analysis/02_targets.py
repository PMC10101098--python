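"""Classify direct / putative-direct targets of both regulators.

Reads the bundle produced by 01_simulate.py, derives promoter windows,
assigns peaks, calls DEGs, classifies target statuses, and summarizes the
per-regulator and pairwise target statistics (common direct targets, shared
regulation direction, exclusive fractions) under results/.
"""

import json
from pathlib import Path

from velvet_grn import (
    annotation_io,
    peak_ops,
)
from velvet_grn import target_classify as tc

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    genome, _ = annotation_io.read_fasta(BUNDLE / "genome.fa")
    genes = annotation_io.read_gene_models(BUNDLE / "genes.tsv", format="tsv")
    windows = annotation_io.promoter_windows(genes, genome)
    universe = [g.gene_id for g in genes]

    targets, peak_genes, summary = {}, {}, {}
    for which in ("a", "b"):
        peaks = peak_ops.read_peaks(BUNDLE / f"peaks_{which}.narrowPeak")
        _, gene_ids = peak_ops.assign_peaks_to_promoters(peaks, windows)
        calls = tc.classify_degs(tc.read_de_table(BUNDLE / f"de_{which}.tsv"))
        recs, counts = tc.classify_targets(gene_ids, calls, universe)
        targets[which], peak_genes[which] = recs, gene_ids
        n_deg = sum(c.is_deg for c in calls)
        summary[which] = {
            "n_peak_associated": len(gene_ids),
            "n_deg": n_deg,
            "pct_deg": tc.percent(n_deg, len(universe), 2),
            **counts,
        }
        tc.write_target_table(recs, ROOT / "scratch" / f"targets_{which}.tsv")

    common, cds = tc.common_direct_targets(targets["a"], targets["b"])
    _, excl = tc.common_putative_targets(peak_genes["a"], peak_genes["b"])
    summary["pairwise"] = {
        "n_common_direct": cds.n_common,
        "n_same_direction": cds.n_same_direction,
        "pct_same_direction": cds.pct_same_direction,
        **excl,
    }
    out = ROOT / "results" / "02_target_summary.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
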
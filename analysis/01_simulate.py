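"""Generate the default synthetic study bundle (1,000 genes, two regulators).

Writes the full input bundle (genome, gene models, peak sets, DE tables,
STRING-format PPI table, gene sets, ground truth) under scratch/bundle/ and
a small summary of the planted conditions under results/.
"""

import json
from pathlib import Path

from velvet_grn import SimConfig, simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimConfig()
    outdir = ROOT / "scratch" / "bundle"
    paths, truth = simulate(cfg, outdir)
    summary = {
        "outdir": str(outdir),
        "n_genes": cfg.n_genes,
        "rng_seed": cfg.rng_seed,
        "planted": {
            "n_bound_a": int(truth.genes.bound_by_a.sum()),
            "n_bound_b": int(truth.genes.bound_by_b.sum()),
            "n_shared_bound": int(
                ((truth.genes.bound_by_a == 1) & (truth.genes.bound_by_b == 1)).sum()),
            "status_counts_a": truth.status_counts("a"),
            "status_counts_b": truth.status_counts("b"),
            "n_peaks_with_motif": int(truth.peaks.has_motif.sum()),
            "n_peaks": len(truth.peaks),
            "motif": cfg.motif,
            "n_core_a": len(truth.core_a),
            "n_core_b": len(truth.core_b),
        },
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "01_simulation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"bundle written to {outdir}")
    print(json.dumps(summary["planted"], indent=2))


if __name__ == "__main__":
    main()
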
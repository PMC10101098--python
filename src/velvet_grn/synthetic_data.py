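"""Seeded synthetic multi-omic bundle generator with planted ground truth.

Emulates the statistical structure the pipeline expects of a real regulator
study: a multi-chromosome genome with evenly spaced genes on random strands;
per-regulator ChIP peak sets placed inside promoter windows of a chosen
fraction of genes, with a consensus motif planted in a fraction of peaks and
with shared-bound genes receiving near-coincident peak pairs; DE tables in
which bound genes are enriched for differential expression; and a STRING-
format PPI table with a planted hub of high-confidence edges around each
regulator over a sea of random low-score background edges.

DE tables are generated directly rather than via simulated read counts — the
DE model fit is upstream of this pipeline — and are threshold-consistent by
construction (every DEG row satisfies padj < 0.05 and |log2fc| > 1; every
non-DEG row violates at least one), so the planted ground truth is exact.
One seed yields a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from velvet_grn.motif_elicit import hamming, revcomp
from velvet_grn.target_classify import (
    STATUS_DEG_ONLY,
    STATUS_DIRECT,
    STATUS_NONE,
    STATUS_PUTATIVE,
    TargetRecord,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    The bound fractions and conditional DEG probabilities approximate the
    scale of a genome-wide regulator study (roughly 15-30% of genes bound,
    DEG probability modestly higher for bound than unbound genes); the
    planted motif defaults to the common consensus element 5'-TGATTGGCTG-3'.
    """

    n_chrom: int = 3
    n_genes: int = 1000
    gene_spacing_bp: int = 3000
    upstream_bp: int = 1500
    frac_bound_a: float = 0.29
    frac_bound_b: float = 0.17
    frac_shared_bound: float = 0.59  # of B-bound genes, fraction also A-bound
    frac_shared_close: float = 0.8   # of shared-bound genes, fraction with centers <= 100 bp apart
    p_de_given_bound: float = 0.30
    p_de_given_unbound: float = 0.25
    lfc_magnitude: float = 2.0
    motif: str = "TGATTGGCTG"
    frac_peaks_with_motif: float = 0.4
    n_core_genes: int = 20
    p_background_edge: float = 0.01
    core_score_range: tuple[int, int] = (400, 1000)
    background_score_range: tuple[int, int] = (0, 399)
    regulator_a: str = "veA"
    regulator_b: str = "laeA"
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for name in ("frac_bound_a", "frac_bound_b", "frac_shared_bound",
                     "frac_shared_close", "p_de_given_bound", "p_de_given_unbound",
                     "frac_peaks_with_motif", "p_background_edge"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_de_given_bound <= self.p_de_given_unbound:
            raise ValueError("p_de_given_bound must exceed p_de_given_unbound")
        if len(self.motif) > 2 * 100:
            raise ValueError("motif longer than the promoter peak window")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over ACGT")


@dataclass
class GroundTruth:
    """Planted per-gene, per-peak and network truth for a simulated bundle."""

    genes: pd.DataFrame      # gene_id, chrom, strand, tss, bound/deg/direction/status fields
    peaks: pd.DataFrame      # peak_id, regulator, gene_id, center, has_motif, offset, strand
    core_a: list[str]
    core_b: list[str]
    config: SimConfig

    @classmethod
    def load(cls, outdir: str | Path, config: SimConfig | None = None) -> "GroundTruth":
        outdir = Path(outdir)
        genes = pd.read_csv(outdir / "ground_truth.tsv", sep="\t")
        peaks = pd.read_csv(outdir / "ground_truth_peaks.tsv", sep="\t")
        core = pd.read_csv(outdir / "ground_truth_core.tsv", sep="\t")
        return cls(
            genes=genes,
            peaks=peaks,
            core_a=core.loc[core.regulator == "a", "gene_id"].tolist(),
            core_b=core.loc[core.regulator == "b", "gene_id"].tolist(),
            config=config or SimConfig(),
        )

    def status_counts(self, which: str) -> dict[str, int]:
        col = f"true_status_{which}"
        return self.genes[col].value_counts().to_dict()


def _true_status(bound: bool, deg: bool) -> str:
    if bound and deg:
        return STATUS_DIRECT
    if bound:
        return STATUS_PUTATIVE
    if deg:
        return STATUS_DEG_ONLY
    return STATUS_NONE


def _draw_lfc_deg(rng: np.random.Generator, magnitude: float) -> float:
    while True:
        lfc = (magnitude + rng.normal(0, 0.25)) * (1 if rng.random() < 0.5 else -1)
        if abs(lfc) > 1:
            return lfc


def _draw_lfc_nondeg(rng: np.random.Generator) -> float:
    while True:
        lfc = rng.normal(0, 0.3)
        if abs(lfc) <= 1:
            return lfc


def simulate(config: SimConfig, outdir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Write a complete input bundle plus ground-truth manifest to ``outdir``.

    Files: genome.fa, genes.tsv, genes.gff3, promoters reference is derivable;
    peaks_a.narrowPeak / peaks_b.narrowPeak; de_a.tsv / de_b.tsv;
    string_links.tsv / aliases.tsv; gene_sets.gmt; ground_truth*.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    half = 100  # peak half-width around the placed center
    w = len(config.motif)

    # --- gene layout ---------------------------------------------------
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    genes_rows = []
    gi = 0
    chrom_lengths = {}
    for ci, n_on in enumerate(per_chrom, 1):
        chrom = f"chr{ci}"
        chrom_lengths[chrom] = n_on * config.gene_spacing_bp + 200
        for slot in range(n_on):
            gi += 1
            gene_id = f"g{gi:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            slot_start = slot * config.gene_spacing_bp
            if strand == "+":
                tss = slot_start + config.upstream_bp
                win = (slot_start, tss)
            else:
                tss = slot_start + config.gene_spacing_bp - config.upstream_bp - 1
                win = (tss + 1, tss + 1 + config.upstream_bp)
            genes_rows.append((gene_id, chrom, strand, tss, win[0], win[1]))
    genes = pd.DataFrame(genes_rows,
                         columns=["gene_id", "chrom", "strand", "tss", "win_start", "win_end"])

    # --- genome --------------------------------------------------------
    genome = {c: rng.integers(0, 4, size=L).astype(np.int8) for c, L in chrom_lengths.items()}

    # --- bound genes ---------------------------------------------------
    n = config.n_genes
    n_bound_a = round(config.frac_bound_a * n)
    n_bound_b = round(config.frac_bound_b * n)
    all_ids = genes.gene_id.to_numpy()
    bound_a = set(rng.choice(all_ids, size=n_bound_a, replace=False))
    n_shared = min(round(config.frac_shared_bound * n_bound_b), n_bound_a)
    shared = set(rng.choice(sorted(bound_a), size=n_shared, replace=False))
    pool_b_only = np.array(sorted(set(all_ids) - bound_a))
    b_only = set(rng.choice(pool_b_only, size=n_bound_b - n_shared, replace=False))
    bound_b = shared | b_only

    # --- peaks + motif planting ---------------------------------------
    gene_info = genes.set_index("gene_id")
    peak_rows = []   # (regulator, peak_id, chrom, start, end, center, gene_id)
    truth_peaks = []  # dicts
    planted_sites: dict[str, tuple[int, int, str]] = {}  # gene -> (site_start, site_end, strand)
    counters = {"a": 0, "b": 0}

    def place_peak(reg: str, gene_id: str, center: int) -> None:
        counters[reg] += 1
        info = gene_info.loc[gene_id]
        peak_id = f"{reg}_pk{counters[reg]:05d}"
        start, end = center - half, center + half
        has_motif = bool(rng.random() < config.frac_peaks_with_motif)
        offset = strand = None
        if has_motif:
            prior = planted_sites.get(gene_id)
            if prior is not None and prior[0] >= start and prior[1] <= end:
                offset, strand = prior[0], prior[2]
            else:
                lo, hi = start, end - w
                if prior is not None:
                    # avoid overwriting an earlier planted site in this promoter
                    choices = list(range(lo, prior[0] - w + 1)) + list(range(prior[1], hi + 1))
                else:
                    choices = list(range(lo, hi + 1))
                if choices:
                    offset = int(choices[rng.integers(len(choices))])
                    strand = "+" if rng.random() < 0.5 else "-"
                    site = config.motif if strand == "+" else revcomp(config.motif)
                    enc = np.frombuffer(site.encode(), dtype=np.uint8)
                    code = np.zeros_like(enc, dtype=np.int8)
                    for bi, base in enumerate(b"ACGT"):
                        code[enc == base] = bi
                    genome[info.chrom][offset : offset + w] = code
                    planted_sites[gene_id] = (offset, offset + w, strand)
                else:
                    has_motif = False
        peak_rows.append((reg, peak_id, info.chrom, start, end, center, gene_id))
        truth_peaks.append(dict(peak_id=peak_id, regulator=reg, gene_id=gene_id,
                                center=center, has_motif=int(has_motif),
                                motif_offset=-1 if offset is None else offset,
                                motif_strand="." if strand is None else strand))

    centers_a: dict[str, int] = {}
    for gene_id in sorted(bound_a):
        info = gene_info.loc[gene_id]
        c = int(rng.integers(info.win_start + half, info.win_end - half))
        centers_a[gene_id] = c
        place_peak("a", gene_id, c)
    for gene_id in sorted(bound_b):
        info = gene_info.loc[gene_id]
        if gene_id in shared and rng.random() < config.frac_shared_close:
            c = centers_a[gene_id] + int(rng.integers(-50, 51))
            c = int(np.clip(c, info.win_start + half, info.win_end - half - 1))
        else:
            c = int(rng.integers(info.win_start + half, info.win_end - half))
        place_peak("b", gene_id, c)

    # --- DE tables -----------------------------------------------------
    de_tables = {}
    truth_de = {}
    for reg, bound in (("a", bound_a), ("b", bound_b)):
        rows = []
        flags = {}
        for gene_id in genes.gene_id:
            p = config.p_de_given_bound if gene_id in bound else config.p_de_given_unbound
            is_deg = rng.random() < p
            if is_deg:
                lfc = _draw_lfc_deg(rng, config.lfc_magnitude)
                padj = rng.uniform(1e-6, 0.04)
            else:
                lfc = _draw_lfc_nondeg(rng)
                padj = rng.uniform(0.06, 1.0)
            rows.append((gene_id, lfc, padj))
            flags[gene_id] = (is_deg, "up" if is_deg and lfc > 0 else
                              ("down" if is_deg else "none"))
        de_tables[reg] = pd.DataFrame(rows, columns=["gene_id", "log2FoldChange", "padj"])
        truth_de[reg] = flags

    # --- PPI table with planted hubs -----------------------------------
    # hubs must be drawn from bound genes or their regulator edges would not
    # survive the both-endpoints-are-targets rule downstream
    n_core_a = min(config.n_core_genes, len(bound_a))
    n_core_b = min(config.n_core_genes, len(bound_b))
    core_a = sorted(rng.choice(sorted(bound_a), size=n_core_a, replace=False))
    core_b = sorted(rng.choice(sorted(bound_b), size=n_core_b, replace=False))
    lo_c, hi_c = config.core_score_range
    lo_b, hi_b = config.background_score_range
    edges = []
    for g in core_a:
        edges.append((config.regulator_a, g, int(rng.integers(lo_c, hi_c + 1))))
    for g in core_b:
        edges.append((config.regulator_b, g, int(rng.integers(lo_c, hi_c + 1))))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < config.p_background_edge
    for i, j in zip(iu[mask], ju[mask]):
        edges.append((all_ids[i], all_ids[j], int(rng.integers(lo_b, hi_b + 1))))

    # --- gene sets (GMT) ------------------------------------------------
    # one term per planted core plus random decoy terms of comparable size
    gmt_terms = [("CORE_A", "planted regulator-A core module", list(core_a)),
                 ("CORE_B", "planted regulator-B core module", list(core_b))]
    for t in range(8):
        size = int(rng.integers(15, 40))
        members = sorted(rng.choice(all_ids, size=size, replace=False))
        gmt_terms.append((f"DECOY_{t + 1}", f"random gene set {t + 1}", members))

    # --- assemble ground truth -----------------------------------------
    gt = genes.copy()
    gt["bound_by_a"] = gt.gene_id.isin(bound_a).astype(int)
    gt["bound_by_b"] = gt.gene_id.isin(bound_b).astype(int)
    for reg in ("a", "b"):
        gt[f"is_deg_{reg}"] = [int(truth_de[reg][g][0]) for g in gt.gene_id]
        gt[f"direction_{reg}"] = [truth_de[reg][g][1] for g in gt.gene_id]
        gt[f"true_status_{reg}"] = [
            _true_status(bool(b), bool(d))
            for b, d in zip(gt[f"bound_by_{reg}"], gt[f"is_deg_{reg}"])
        ]

    # --- write files ----------------------------------------------------
    paths = {name: outdir / fname for name, fname in [
        ("genome", "genome.fa"), ("genes_tsv", "genes.tsv"), ("genes_gff3", "genes.gff3"),
        ("peaks_a", "peaks_a.narrowPeak"), ("peaks_b", "peaks_b.narrowPeak"),
        ("de_a", "de_a.tsv"), ("de_b", "de_b.tsv"),
        ("links", "string_links.tsv"), ("aliases", "aliases.tsv"),
        ("gmt", "gene_sets.gmt"),
        ("truth", "ground_truth.tsv"), ("truth_peaks", "ground_truth_peaks.tsv"),
        ("truth_core", "ground_truth_core.tsv"),
    ]}
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = BASES[genome[chrom]].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    genes[["gene_id", "chrom", "strand", "tss"]].to_csv(paths["genes_tsv"], sep="\t", index=False)
    with open(paths["genes_gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            if row.strand == "+":
                cds = (row.tss + 1, min(row.tss + 500, chrom_lengths[row.chrom]))
            else:
                cds = (max(1, row.tss + 1 - 499), row.tss + 1)
            fh.write(f"{row.chrom}\t.\tgene\t{cds[0]}\t{cds[1]}\t.\t{row.strand}\t.\t"
                     f"ID={row.gene_id}\n")
            fh.write(f"{row.chrom}\t.\tCDS\t{cds[0]}\t{cds[1]}\t.\t{row.strand}\t0\t"
                     f"ID={row.gene_id}.cds;Parent={row.gene_id}\n")
    for reg, key in (("a", "peaks_a"), ("b", "peaks_b")):
        with open(paths[key], "w") as fh:
            for r, pid, chrom, start, end, center, _g in [p for p in peak_rows if p[0] == reg]:
                # narrowPeak: chrom start end name score strand signal p q summit
                fh.write(f"{chrom}\t{start}\t{end}\t{pid}\t100\t.\t1.0\t-1\t-1\t{center - start}\n")
    for reg, key in (("a", "de_a"), ("b", "de_b")):
        df = de_tables[reg].copy()
        df["log2FoldChange"] = df["log2FoldChange"].map(lambda v: f"{v:.6f}")
        df["padj"] = df["padj"].map(lambda v: f"{v:.8g}")
        df.to_csv(paths[key], sep="\t", index=False)
    with open(paths["links"], "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, s in edges:
            fh.write(f"pr.{a} pr.{b} {s}\n")
    with open(paths["aliases"], "w") as fh:
        fh.write("protein_id\tgene_id\n")
        for g in [config.regulator_a, config.regulator_b, *all_ids]:
            fh.write(f"pr.{g}\t{g}\n")
    with open(paths["gmt"], "w") as fh:
        for term_id, name, members in gmt_terms:
            fh.write("\t".join([term_id, name, *members]) + "\n")
    gt.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(truth_peaks).to_csv(paths["truth_peaks"], sep="\t", index=False)
    core_df = pd.DataFrame(
        [("a", g) for g in core_a] + [("b", g) for g in core_b],
        columns=["regulator", "gene_id"])
    core_df.to_csv(paths["truth_core"], sep="\t", index=False)

    truth = GroundTruth(genes=gt, peaks=pd.DataFrame(truth_peaks),
                        core_a=list(core_a), core_b=list(core_b), config=config)
    return paths, truth


def config_to_file(config: SimConfig, path: str | Path) -> None:
    """Persist a config as a flat key=value file."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")


def verify_recovery(
    truth: GroundTruth,
    targets_a: list[TargetRecord],
    targets_b: list[TargetRecord],
    matches=None,
    core_a_nodes: set[str] | None = None,
    core_b_nodes: set[str] | None = None,
    motif_consensus: str | None = None,
) -> dict:
    """Compare pipeline outputs against the planted ground truth.

    Reports per-regulator exact status agreement, overlap-peak recovery
    against the realized close peak pairs, core-section node-set equality,
    and the strand-aware Hamming distance of the recovered motif consensus
    to the planted motif.
    """
    if not targets_a or not targets_b:
        raise ValueError("verify_recovery: classified target lists are required")
    report: dict = {}
    for which, targets in (("a", targets_a), ("b", targets_b)):
        true_status = dict(zip(truth.genes.gene_id, truth.genes[f"true_status_{which}"]))
        n_match = sum(1 for t in targets if true_status.get(t.gene_id) == t.status)
        report[f"status_agreement_{which}"] = {
            "n_genes": len(targets), "n_agree": n_match,
            "exact": n_match == len(targets) == len(true_status),
        }
    if matches is not None:
        pk = truth.peaks
        ca = pk[pk.regulator == "a"].set_index("gene_id").center
        cb = pk[pk.regulator == "b"].set_index("gene_id").center
        shared_genes = ca.index.intersection(cb.index)
        true_close = {g for g in shared_genes if abs(int(ca[g]) - int(cb[g])) <= 100}
        id_to_gene = dict(zip(pk.peak_id, pk.gene_id))
        matched_gene_pairs = {
            (id_to_gene[m.peak_id_a], id_to_gene[m.peak_id_b]) for m in matches}
        recovered = {g for g in true_close if (g, g) in matched_gene_pairs}
        report["peak_matching"] = {
            "n_matches": len(matches), "n_true_close_pairs": len(true_close),
            "n_recovered": len(recovered),
        }
    for which, nodes, core in (("a", core_a_nodes, truth.core_a),
                               ("b", core_b_nodes, truth.core_b)):
        if nodes is None:
            continue
        reg = truth.config.regulator_a if which == "a" else truth.config.regulator_b
        report[f"core_{which}"] = {
            "expected": sorted(core), "observed": sorted(nodes),
            "exact": set(nodes) == set(core) | {reg},
        }
    if motif_consensus is not None:
        planted = truth.config.motif
        if len(motif_consensus) == len(planted):
            d = min(hamming(motif_consensus, planted),
                    hamming(motif_consensus, revcomp(planted)))
        else:
            d = max(len(planted), len(motif_consensus))
        report["motif"] = {"planted": planted, "recovered": motif_consensus,
                           "hamming": d}
    return report
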
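"""Classification of regulator target genes from DE tables and peak-bound genes.

A gene is a *direct* target when its promoter carries a regulator ChIP peak
AND it is differentially expressed in the regulator's null mutant (adjusted
p < 0.05 and more than 2-fold change, both strict); a peak-bound gene without
an expression change is a *putative direct* target; a DEG without a promoter
peak is expression-only evidence. The direct and putative-direct classes
partition the peak-associated gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

STATUS_DIRECT = "direct"
STATUS_PUTATIVE = "putative_direct"
STATUS_DEG_ONLY = "deg_only"
STATUS_NONE = "none"


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"{self.gene_id}: padj {self.padj} outside [0, 1]")


@dataclass(frozen=True)
class DEGCall:
    gene_id: str
    is_deg: bool
    direction: str  # up / down / none

    def __post_init__(self) -> None:
        if self.is_deg != (self.direction != "none"):
            raise ValueError(f"{self.gene_id}: direction inconsistent with DEG flag")


@dataclass(frozen=True)
class TargetRecord:
    gene_id: str
    peak_associated: bool
    status: str
    direction: str


@dataclass(frozen=True)
class CommonTargetSummary:
    n_common: int
    n_same_direction: int
    n_both_up: int
    n_both_down: int
    pct_same_direction: float  # NaN when n_common == 0


# DESeq2 output headers accepted as aliases for the canonical column names.
_DE_ALIASES = {
    "gene_id": ("gene_id", "gene", "id", "row", "gene_name"),
    "log2fc": ("log2fc", "log2foldchange", "lfc"),
    "padj": ("padj", "p_adj", "adjusted_p", "fdr", "qvalue"),
}


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a differential-expression table (TSV with a header).

    Canonical columns are gene_id, log2fc, padj; DESeq2's column names
    (log2FoldChange, padj) are accepted. Missing padj (NA) is kept as None.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    resolved = {}
    for canon, aliases in _DE_ALIASES.items():
        for a in aliases:
            if a in cols:
                resolved[canon] = cols[a]
                break
        else:
            raise ValueError(f"DE table {path} missing a {canon} column")
    out = []
    for row in df.itertuples(index=False):
        padj = getattr(row, resolved["padj"], None)
        gene = str(getattr(row, resolved["gene_id"]))
        lfc = float(getattr(row, resolved["log2fc"]))
        out.append(DERecord(gene, lfc, None if padj is None or math.isnan(padj) else float(padj)))
    return out


def classify_degs(records: Iterable[DERecord], alpha: float = 0.05,
                  min_fold: float = 2.0) -> list[DEGCall]:
    """Call DEGs: padj present and < alpha, and |log2fc| strictly above log2(min_fold)."""
    lfc_cut = math.log2(min_fold)
    calls = []
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene_id in DE records: {r.gene_id}")
        seen.add(r.gene_id)
        is_deg = r.padj is not None and r.padj < alpha and abs(r.log2fc) > lfc_cut
        direction = "none" if not is_deg else ("up" if r.log2fc > 0 else "down")
        calls.append(DEGCall(r.gene_id, is_deg, direction))
    return calls


def classify_targets(
    peak_gene_ids: set[str],
    deg_calls: Iterable[DEGCall],
    universe: Iterable[str],
) -> tuple[list[TargetRecord], dict[str, int]]:
    """Per-gene target status over a gene universe.

    Genes absent from the DE calls (untested) count as non-DEG, so a bound
    but untested gene is putative_direct. Returns the records and the counts
    ``{"n_direct", "n_putative", "n_deg_only"}``.
    """
    universe = list(dict.fromkeys(universe))
    unknown = peak_gene_ids - set(universe)
    if unknown:
        raise ValueError(f"peak-associated genes outside the universe: {sorted(unknown)[:5]}")
    call_by_gene = {c.gene_id: c for c in deg_calls}
    records = []
    counts = {"n_direct": 0, "n_putative": 0, "n_deg_only": 0}
    for g in universe:
        call = call_by_gene.get(g)
        is_deg = call.is_deg if call else False
        direction = call.direction if call else "none"
        bound = g in peak_gene_ids
        if bound and is_deg:
            status = STATUS_DIRECT
            counts["n_direct"] += 1
        elif bound:
            status = STATUS_PUTATIVE
            counts["n_putative"] += 1
        elif is_deg:
            status = STATUS_DEG_ONLY
            counts["n_deg_only"] += 1
        else:
            status = STATUS_NONE
        records.append(TargetRecord(g, bound, status, direction))
    return records, counts


def common_direct_targets(
    targets_a: Iterable[TargetRecord], targets_b: Iterable[TargetRecord]
) -> tuple[set[str], CommonTargetSummary]:
    """Genes direct in both regulators, with a same-regulation-pattern summary.

    Direction agreement compares the sign of the expression change in the two
    mutants independently of magnitude. With no common targets the percentage
    is undefined and reported as NaN.
    """
    dir_a = {t.gene_id: t.direction for t in targets_a if t.status == STATUS_DIRECT}
    dir_b = {t.gene_id: t.direction for t in targets_b if t.status == STATUS_DIRECT}
    common = set(dir_a) & set(dir_b)
    both_up = sum(1 for g in common if dir_a[g] == "up" and dir_b[g] == "up")
    both_down = sum(1 for g in common if dir_a[g] == "down" and dir_b[g] == "down")
    n_same = both_up + both_down
    pct = percent(n_same, len(common), 2) if common else float("nan")
    return common, CommonTargetSummary(len(common), n_same, both_up, both_down, pct)


def common_putative_targets(
    peak_genes_a: set[str], peak_genes_b: set[str]
) -> tuple[set[str], dict[str, float]]:
    """Intersection of two peak-associated gene sets, with exclusivity stats."""
    common = peak_genes_a & peak_genes_b
    stats: dict[str, float] = {
        "n_common": len(common),
        "n_exclusive_a": len(peak_genes_a - peak_genes_b),
        "n_exclusive_b": len(peak_genes_b - peak_genes_a),
    }
    stats["pct_exclusive_a"] = (
        percent(stats["n_exclusive_a"], len(peak_genes_a), 1) if peak_genes_a else float("nan"))
    stats["pct_exclusive_b"] = (
        percent(stats["n_exclusive_b"], len(peak_genes_b), 1) if peak_genes_b else float("nan"))
    return common, stats


def percent(numerator: int, denominator: int, dp: int = 2) -> float:
    """100 * numerator / denominator rounded half-away-from-zero to dp decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-dp)
    return float(frac.quantize(quantum, rounding=ROUND_HALF_UP))


def write_target_table(records: Iterable[TargetRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.gene_id, t.status, t.direction, int(t.peak_associated)) for t in records],
        columns=["gene_id", "status", "direction", "peak_associated"],
    )
    df.to_csv(path, sep="\t", index=False)
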
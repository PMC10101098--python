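"""Gene-set over-representation analysis by exact hypergeometric tail.

Format-agnostic replacement for web-based GO enrichment: gene sets come from
a GMT file, the universe from the analysis at hand, and each term is tested
with the one-sided hypergeometric over-representation test. The default
mirrors a raw p-value cutoff of 0.05 with no multiple-testing correction;
Benjamini-Hochberg adjustment is available. Tails are accumulated in log
space so tiny p-values keep full precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)


@dataclass
class GeneSetAnnotation:
    """term id -> (term name, gene id set)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float


def _log_hypergeom_pmf(x: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P[X = x] for X ~ Hypergeom(N, K, n), via log-gamma."""
    x = np.asarray(x, dtype=float)

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(K, x) + logc(N - K, n - x) - logc(N, n)


def log_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Natural-log upper tail log P[X >= k]; exact summation in log space."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k <= max(0, n + K - N):
        return 0.0  # the whole support is >= k
    xs = np.arange(k, min(K, n) + 1)
    return float(logsumexp(_log_hypergeom_pmf(xs, N, K, n)))


def log10_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    return log_hypergeom_tail(k, K, n, N) / math.log(10)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P[X >= k] of drawing k or more annotated genes.

    X counts annotated genes in a size-n draw, without replacement, from a
    universe of N genes of which K are annotated.
    """
    return math.exp(log_hypergeom_tail(k, K, n, N))


def read_gmt(path: str | Path) -> GeneSetAnnotation:
    """Read gene sets from GMT (term, description, genes...). Empty sets raise."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, name, >=1 gene")
            term_id, name, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {term_id}")
            terms[term_id] = (name, genes)
    return GeneSetAnnotation(terms)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def enrich(
    query_genes: Iterable[str],
    annotation: GeneSetAnnotation,
    universe: Iterable[str],
    p_cut: float = 0.05,
    adjust: str = "none",
) -> list[EnrichmentRow]:
    """Over-representation of ``query_genes`` in each annotated term.

    Genes outside the universe are dropped (logged); term sizes are taken
    within the universe. One row per term with at least one overlapping
    gene, filtered at p (or BH-adjusted p when adjust="BH") below ``p_cut``,
    sorted ascending by p with term-id tie-break.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    outside = query - universe_set
    if outside:
        logger.warning("enrich: %d query genes outside universe dropped", len(outside))
        query &= universe_set
    n, N = len(query), len(universe_set)
    rows = []
    for term_id, (name, genes) in sorted(annotation.terms.items()):
        in_universe = genes & universe_set
        if len(in_universe) < len(genes):
            logger.info("term %s: %d genes outside universe dropped",
                        term_id, len(genes) - len(in_universe))
        K = len(in_universe)
        k = len(in_universe & query)
        if k < 1:
            continue
        p = hypergeom_tail(k, K, n, N)
        rows.append(EnrichmentRow(term_id, name, k, K, n, N, p, p))
    if not rows:
        return []
    padj = bh_adjust(np.array([r.p for r in rows]))
    rows = [EnrichmentRow(r.term_id, r.name, r.k, r.K, r.n, r.N, r.p, float(a))
            for r, a in zip(rows, padj)]
    key = (lambda r: r.p_adj) if adjust == "BH" else (lambda r: r.p)
    rows = [r for r in rows if key(r) < p_cut]
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def write_enrichment(rows: list[EnrichmentRow], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in rows]).to_csv(path, sep="\t", index=False)
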
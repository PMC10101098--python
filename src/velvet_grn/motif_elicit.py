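"""De novo motif elicitation from ChIP-seq peak sequences.

Two-stage discovery in the style of classical enriched-oligo motif finders:

1. *Seeding* — every k-mer occurring in at least two peak sequences is scored
   for over-representation against a background set (by default dinucleotide-
   shuffled copies of the peaks) with a one-sided hypergeometric test on
   sequence presence counts, either strand counting once. The top seeds are
   kept after a Hamming-distance redundancy filter.
2. *Refinement* — each seed initialises a position weight matrix that is
   refined by expectation-maximization under the ZOOPS model (zero or one
   motif occurrence per sequence, either strand), which tolerates the
   motif-free peaks that real peak sets plainly contain.

The refined motif is then scanned back over target and background to report
the fraction of peaks carrying a site and a log10 hypergeometric enrichment
p-value, the same report shape produced by standard motif-elicitation tools.
All randomness flows through an explicit seed; significance is computed in
log space so magnitudes like 1e-80 do not underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from velvet_grn.enrich_stats import log10_hypergeom_tail
from velvet_grn.peak_ops import Peak, peak_center

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceSet:
    """Fixed-length DNA sequences with provenance (target or background)."""

    records: list[tuple[str, str]]
    provenance: str = "target"
    dropped_count: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.records]


@dataclass(frozen=True)
class KmerSeed:
    kmer: str
    n_target_with: int
    n_bg_with: int
    p_value: float
    rank: int


@dataclass
class MotifModel:
    """A PWM motif with its ZOOPS occurrence prior and enrichment report.

    ``pwm`` is 4 x w (rows A, C, G, T; columns sum to 1); ``gamma`` is the
    prior probability that a sequence contains one site; ``consensus`` is the
    per-column argmax base. ``pct_with_motif`` and ``log10_p`` are filled by
    :func:`scan_and_report`.
    """

    pwm: np.ndarray
    gamma: float
    background_freqs: np.ndarray
    log_likelihood: float
    consensus: str
    pct_with_motif: float | None = None
    log10_p: float | None = None
    ll_trajectory: list[float] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pwm.shape[1]


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int
    strand: str
    log_odds: float


def extract_peak_sequences(
    genome_seqs: dict[str, str], peaks: Sequence[Peak], half_width: int = 100,
    provenance: str = "target",
) -> SequenceSet:
    """Forward-strand windows [center - half_width, center + half_width).

    Peaks whose window would run off the chromosome are dropped and counted.
    """
    records: list[tuple[str, str]] = []
    dropped = 0
    for p in peaks:
        if p.chrom not in genome_seqs:
            raise KeyError(f"chromosome {p.chrom!r} absent from genome FASTA")
        c = peak_center(p)
        chrom_seq = genome_seqs[p.chrom]
        lo, hi = c - half_width, c + half_width
        if lo < 0 or hi > len(chrom_seq):
            dropped += 1
            continue
        records.append((p.peak_id, chrom_seq[lo:hi].upper()))
    if dropped:
        logger.info("extract_peak_sequences: dropped %d clipped peaks", dropped)
    return SequenceSet(records, provenance=provenance, dropped_count=dropped)


def dinuc_shuffle(sequence: str, rng: np.random.Generator | int) -> str:
    """Uniform dinucleotide-preserving shuffle (Eulerian-walk construction).

    Returns a sequence with the identical dinucleotide count multiset and the
    same first and last base, sampled uniformly from all such arrangements;
    deterministic for a fixed seed. Sequences shorter than 2 bases come back
    unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(sequence)
    if n < 2:
        return sequence
    # Multigraph on the bases present: one edge per dinucleotide.
    out_edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        out_edges.setdefault(a, []).append(b)
    sink = sequence[-1]
    vertices = sorted(out_edges)
    # Pick each non-sink vertex's *last* exit edge such that the last-edge
    # graph is a tree pointing at the sink (Altschul-Erickson condition);
    # rejection sampling over random choices converges fast on <= 4 vertices.
    while True:
        last_edge = {v: out_edges[v][rng.integers(len(out_edges[v]))]
                     for v in vertices if v != sink}
        if _all_reach_sink(last_edge, sink):
            break
    shuffled = {}
    for v in vertices:
        edges = list(out_edges[v])
        if v != sink:
            edges.remove(last_edge[v])
        rng.shuffle(edges)
        if v != sink:
            edges.append(last_edge[v])
        shuffled[v] = edges
    # Walk the Eulerian path from the original first base.
    out = [sequence[0]]
    pos = {v: 0 for v in vertices}
    v = sequence[0]
    for _ in range(n - 1):
        nxt = shuffled[v][pos[v]]
        pos[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _all_reach_sink(last_edge: dict[str, str], sink: str) -> bool:
    for v in last_edge:
        seen = {v}
        cur = v
        while cur != sink:
            cur = last_edge.get(cur)
            if cur is None or cur in seen:
                return False
            seen.add(cur)
    return True


def make_background(target: SequenceSet, rng: np.random.Generator | int,
                    copies: int = 1) -> SequenceSet:
    """Dinucleotide-shuffled copies of the target set (N-containing dropped)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    records = []
    for c in range(copies):
        for seq_id, seq in target.records:
            if set(seq) - set(BASES):
                continue
            records.append((f"bg{c}_{seq_id}", dinuc_shuffle(seq, rng)))
    return SequenceSet(records, provenance="background")


def _presence_sets(seqs: Iterable[str], k: int) -> list[set[str]]:
    """Per sequence, the set of canonical k-mers present on either strand."""
    out = []
    for seq in seqs:
        present: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            present.add(min(kmer, revcomp(kmer)))
        out.append(present)
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def seed_kmers(
    target: SequenceSet,
    background: SequenceSet,
    k: int = 10,
    top_s: int = 10,
    min_hamming: int = 3,
) -> list[KmerSeed]:
    """Rank k-mers by hypergeometric over-representation in target sequences.

    Presence counts a sequence once, on either strand (a k-mer and its
    reverse complement are the same motif). Only k-mers present in >= 2
    target sequences are candidates. Seeds within Hamming distance
    ``min_hamming`` of an already-accepted seed or its reverse complement
    are skipped; ties in p are broken lexicographically.
    """
    if not target.records:
        raise ValueError("empty target sequence set")
    if not 4 <= k <= min(len(s) for s in target.sequences):
        raise ValueError(f"k={k} outside [4, sequence length]")
    t_sets = _presence_sets(target.sequences, k)
    b_sets = _presence_sets(background.sequences, k)
    t_counts: dict[str, int] = {}
    for s in t_sets:
        for kmer in s:
            t_counts[kmer] = t_counts.get(kmer, 0) + 1
    candidates = sorted(kmer for kmer, c in t_counts.items() if c >= 2)
    if not candidates:
        return []
    b_counts = {kmer: 0 for kmer in candidates}
    cand_set = set(candidates)
    for s in b_sets:
        for kmer in s & cand_set:
            b_counts[kmer] += 1
    n_t, n_b = len(t_sets), len(b_sets)
    N = n_t + n_b
    pvals = {
        kmer: 10.0 ** log10_hypergeom_tail(t_counts[kmer], t_counts[kmer] + b_counts[kmer], n_t, N)
        for kmer in candidates
    }
    ranked = sorted(candidates, key=lambda kmer: (pvals[kmer], kmer))
    seeds: list[KmerSeed] = []
    for kmer in ranked:
        if len(seeds) >= top_s:
            break
        redundant = any(
            min(hamming(kmer, s.kmer), hamming(kmer, revcomp(s.kmer))) < min_hamming
            for s in seeds
        )
        if redundant:
            continue
        seeds.append(KmerSeed(kmer, t_counts[kmer], b_counts[kmer], pvals[kmer], len(seeds) + 1))
    return seeds


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    out = np.zeros_like(arr, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    out[arr == ord("N")] = -1
    return out


def _init_pwm_from_kmer(kmer: str, match_prob: float = 0.7) -> np.ndarray:
    w = len(kmer)
    pwm = np.full((4, w), (1 - match_prob) / 3)
    for j, base in enumerate(kmer):
        pwm[_CODE[base], j] = match_prob
    return pwm


def em_refine_zoops(
    seed: KmerSeed | str,
    seqs: SequenceSet,
    pseudocount: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MotifModel:
    """Refine a seed k-mer into a PWM by ZOOPS expectation-maximization.

    The model: with prior gamma a sequence carries exactly one motif site at
    a position/strand drawn uniformly; otherwise it is pure background
    (0-order base frequencies of the input). The E-step computes per-sequence
    posteriors over {no site} and every (offset, strand); the M-step
    re-estimates the PWM (with pseudocounts) and gamma. The objective
    (the pseudocount-regularized log-likelihood, recorded in
    ``ll_trajectory``) is non-decreasing across iterations; iteration stops
    when the improvement drops below ``tol`` or after ``max_iter`` rounds.
    """
    kmer = seed.kmer if isinstance(seed, KmerSeed) else seed
    w = len(kmer)
    usable = [s for s in seqs.sequences if len(s) >= w and not set(s) - set(BASES)]
    if not usable:
        raise ValueError(f"no usable sequences of length >= {w}")
    if len(usable) < 2:
        raise ValueError("ZOOPS refinement needs at least 2 sequences")
    if len({len(s) for s in usable}) != 1:
        raise ValueError("sequences must share a common length")
    S = _encode(usable)
    n, L = S.shape
    if w > L:
        raise ValueError(f"motif width {w} exceeds sequence length {L}")
    m = L - w + 1
    bg = np.bincount(S.ravel(), minlength=4).astype(float)
    bg = np.maximum(bg, 1.0)
    bg /= bg.sum()
    log_bg = np.log(bg)
    log_p0 = log_bg[S].sum(axis=1)  # per-sequence all-background log-likelihood

    windows = sliding_window_view(S, w, axis=1)  # (n, m, w)
    cols = np.arange(w)
    pwm = _init_pwm_from_kmer(kmer)
    gamma = 0.5
    prev_ll = -np.inf
    trajectory: list[float] = []
    for _ in range(max_iter):
        low = np.log(pwm) - log_bg[:, None]          # (4, w) log-odds
        low_rc = low[::-1, ::-1]                     # complement rows, reverse cols
        llr_f = low[windows, cols].sum(axis=2)       # (n, m)
        llr_r = low_rc[windows, cols].sum(axis=2)
        site_prior = np.log(gamma) - np.log(2 * m) if gamma > 0 else -np.inf
        null_prior = np.log1p(-gamma) if gamma < 1 else -np.inf
        log_site = site_prior + np.concatenate([llr_f, llr_r], axis=1)  # (n, 2m)
        mx = np.maximum(log_site.max(axis=1), null_prior)
        denom = np.exp(null_prior - mx) + np.exp(log_site - mx[:, None]).sum(axis=1)
        ll = float((log_p0 + mx + np.log(denom)).sum())
        # objective EM monotonically improves: the Dirichlet(pseudocount+1)-
        # regularized (MAP) log-likelihood; the raw ll can dip ~1e-4 at
        # convergence because the M-step includes pseudocounts
        obj = ll + pseudocount * float(np.log(pwm).sum())
        trajectory.append(obj)
        z = np.exp(log_site - mx[:, None]) / denom[:, None]  # site posteriors
        z_f, z_r = z[:, :m], z[:, m:]
        # M-step
        site_mass = z.sum()
        gamma = float(min(1.0, max(0.0, site_mass / n)))
        counts = np.full((4, w), pseudocount)
        for t in range(w):
            counts[:, t] += np.bincount(windows[:, :, t].ravel(),
                                        weights=z_f.ravel(), minlength=4)
            counts[:, t] += np.bincount((3 - windows[:, :, w - 1 - t]).ravel(),
                                        weights=z_r.ravel(), minlength=4)
        pwm = counts / counts.sum(axis=0, keepdims=True)
        if obj - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = obj
    consensus = "".join(BASES[i] for i in pwm.argmax(axis=0))
    return MotifModel(pwm=pwm, gamma=gamma, background_freqs=bg,
                      log_likelihood=trajectory[-1], consensus=consensus,
                      ll_trajectory=trajectory)


def best_hits(model: MotifModel, seqs: SequenceSet) -> list[MotifHit]:
    """Best-scoring site (log-odds vs background) per sequence, either strand."""
    w = model.width
    low = np.log(model.pwm) - np.log(model.background_freqs)[:, None]
    low_rc = low[::-1, ::-1]
    hits = []
    for seq_id, seq in seqs.records:
        best = None
        for strand, mat in (("+", low), ("-", low_rc)):
            for j in range(len(seq) - w + 1):
                window = seq[j : j + w]
                if "N" in window:
                    continue
                score = sum(mat[_CODE[b], t] for t, b in enumerate(window))
                if best is None or score > best.log_odds:
                    best = MotifHit(seq_id, j, strand, score)
        if best is not None:
            hits.append(best)
    return hits


def _best_scores(model: MotifModel, seqs: list[str]) -> np.ndarray:
    """Vectorised per-sequence best log-odds over positions and strands."""
    w = model.width
    low = np.log(model.pwm) - np.log(model.background_freqs)[:, None]
    low_rc = low[::-1, ::-1]
    cols = np.arange(w)
    scores = np.empty(len(seqs))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for length, idx in by_len.items():
        sub = [seqs[i].replace("N", "A") for i in idx]  # N scored as A; rare, conservative
        S = _encode(sub)
        windows = sliding_window_view(S, w, axis=1)
        sc_f = low[windows, cols].sum(axis=2)
        sc_r = low_rc[windows, cols].sum(axis=2)
        best = np.maximum(sc_f.max(axis=1), sc_r.max(axis=1))
        scores[idx] = best
    return scores


def scan_and_report(
    model: MotifModel,
    target: SequenceSet,
    background: SequenceSet,
    threshold_frac: float = 0.6,
) -> MotifModel:
    """Fill in the motif's occurrence and enrichment report.

    A sequence is motif-positive when its best log-odds score reaches
    ``threshold_frac`` of the PWM's maximum achievable log-odds.
    ``pct_with_motif`` is the motif-positive percentage of targets;
    ``log10_p`` is the log10 hypergeometric tail of positives in target
    versus background.
    """
    low = np.log(model.pwm) - np.log(model.background_freqs)[:, None]
    max_score = low.max(axis=0).sum()
    cut = threshold_frac * max_score
    pos_t = int((_best_scores(model, target.sequences) >= cut).sum())
    pos_b = int((_best_scores(model, background.sequences) >= cut).sum())
    n_t, n_b = len(target), len(background)
    model.pct_with_motif = 100.0 * pos_t / n_t if n_t else float("nan")
    model.log10_p = log10_hypergeom_tail(pos_t, pos_t + pos_b, n_t, n_t + n_b)
    return model


def discover_motifs(
    target: SequenceSet,
    background: SequenceSet | None = None,
    k: int = 10,
    n_motifs: int = 2,
    seed: int = 0,
    threshold_frac: float = 0.6,
    **seed_kwargs,
) -> list[MotifModel]:
    """End-to-end elicitation: background, seeding, ZOOPS-EM, reporting.

    Returns up to ``n_motifs`` refined motifs ranked by seed significance,
    each with its occurrence percentage and log10 enrichment p filled in.
    """
    if background is None:
        background = make_background(target, np.random.default_rng(seed))
    seeds = seed_kmers(target, background, k=k, **seed_kwargs)
    models = []
    for s in seeds[:n_motifs]:
        model = em_refine_zoops(s, target)
        scan_and_report(model, target, background, threshold_frac=threshold_frac)
        models.append(model)
    return models


def write_motif_report(models: list[MotifModel], path) -> None:
    """TSV report (rank, consensus, width, pct_with_motif, log10_p) + PWM blocks."""
    with open(path, "w") as fh:
        fh.write("rank\tconsensus\twidth\tgamma\tpct_with_motif\tlog10_p\n")
        for i, mdl in enumerate(models, 1):
            fh.write(f"{i}\t{mdl.consensus}\t{mdl.width}\t{mdl.gamma:.4f}\t"
                     f"{mdl.pct_with_motif:.2f}\t{mdl.log10_p:.2f}\n")
        for i, mdl in enumerate(models, 1):
            fh.write(f"\n# PWM {i} ({mdl.consensus}), rows A C G T\n")
            for r in range(4):
                fh.write("\t".join(f"{v:.4f}" for v in mdl.pwm[r]) + "\n")


def write_meme_minimal(models: list[MotifModel], path) -> None:
    """Export motifs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = models[0].background_freqs if models else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.4f}" for b, f in zip(BASES, bg)) + "\n\n")
        for mdl in models:
            fh.write(f"MOTIF {mdl.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {mdl.width}\n")
            for j in range(mdl.width):
                fh.write(" ".join(f"{mdl.pwm[r, j]:.6f}" for r in range(4)) + "\n")
            fh.write("\n")
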
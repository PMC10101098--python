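"""ChIP-seq peak handling: parsing, promoter assignment, and peak matching.

Peaks are associated with genes by their *center* (the reported summit when
one is available, otherwise the interval midpoint), which must fall inside a
gene's promoter window. Two regulators' peak sets are matched one-to-one when
peak centers lie within a maximum distance of each other (default 100 bp,
inclusive), using a deterministic greedy-by-distance rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from intervaltree import IntervalTree

from velvet_grn.annotation_io import PromoterWindow


@dataclass(frozen=True)
class Peak:
    peak_id: str
    chrom: str
    start: int
    end: int
    summit_offset: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.peak_id}: start >= end")
        if self.summit_offset is not None and not 0 <= self.summit_offset < self.end - self.start:
            raise ValueError(f"peak {self.peak_id}: summit offset outside interval")


@dataclass(frozen=True)
class PeakAssignment:
    peak_id: str
    gene_id: str


@dataclass(frozen=True)
class PeakMatch:
    peak_id_a: str
    peak_id_b: str
    center_distance: int


def read_peaks(path: str | Path, format: str = "narrowPeak") -> list[Peak]:
    """Read peaks from BED (3+ columns) or ENCODE narrowPeak (10 columns).

    narrowPeak column 10 is the summit offset relative to start; -1 means
    absent. Peaks come back sorted by (chrom, start); a "." or missing name
    gets an auto-generated id. A line with the wrong column count raises an
    error naming the line.
    """
    path = Path(path)
    peaks: list[Peak] = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if format == "narrowPeak":
                if len(parts) != 10:
                    raise ValueError(
                        f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(parts)}")
                summit = int(parts[9])
                summit_offset = None if summit < 0 else summit
                score = float(parts[4]) if parts[4] not in (".", "") else None
            elif format == "bed":
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED requires at least 3 columns")
                summit_offset = None
                score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else None
            else:
                raise ValueError(f"unknown peak format: {format!r}")
            name = parts[3] if len(parts) > 3 else "."
            if name == "." or not name:
                auto += 1
                name = f"peak_{auto}"
            peaks.append(Peak(name, parts[0], int(parts[1]), int(parts[2]),
                              summit_offset=summit_offset, score=score))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
    return peaks


def peak_center(peak: Peak) -> int:
    """Peak center: start + summit offset when present, else the floored midpoint."""
    if peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end) // 2


def assign_peaks_to_promoters(
    peaks: list[Peak], windows: list[PromoterWindow]
) -> tuple[list[PeakAssignment], set[str]]:
    """Assign each peak to every promoter window containing its center.

    A peak between two divergent genes can be assigned to both; a gene can
    receive several peaks. Returns the assignment list (deterministically
    ordered) and the deduplicated set of peak-associated gene ids.
    """
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        if len(w) == 0:
            continue
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w.gene_id)
    assignments: list[PeakAssignment] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        c = peak_center(p)
        for hit in tree.at(c):
            assignments.append(PeakAssignment(p.peak_id, hit.data))
    assignments.sort(key=lambda a: (a.gene_id, a.peak_id))
    return assignments, {a.gene_id for a in assignments}


def match_overlapping_peaks(
    peaks_a: list[Peak], peaks_b: list[Peak], max_dist: int = 100
) -> list[PeakMatch]:
    """One-to-one matching of two peak sets by center distance.

    Candidate pairs are same-chromosome pairs whose centers lie within
    ``max_dist`` bp (inclusive). Pairs are accepted greedily in order of
    increasing distance; ties are broken on the sorted center pair and then
    on peak ids so the result is order-independent and symmetric in the two
    arguments. Each peak appears in at most one match.
    """
    centers_a = [(p, peak_center(p)) for p in peaks_a]
    centers_b = [(p, peak_center(p)) for p in peaks_b]
    by_chrom_b: dict[str, list[tuple[Peak, int]]] = {}
    for p, c in centers_b:
        by_chrom_b.setdefault(p.chrom, []).append((p, c))
    for lst in by_chrom_b.values():
        lst.sort(key=lambda pc: pc[1])

    import bisect

    candidates = []
    for pa, ca in centers_a:
        lst = by_chrom_b.get(pa.chrom, [])
        keys = [c for _, c in lst]
        lo = bisect.bisect_left(keys, ca - max_dist)
        hi = bisect.bisect_right(keys, ca + max_dist)
        for pb, cb in lst[lo:hi]:
            d = abs(ca - cb)
            candidates.append(
                (d, pa.chrom, min(ca, cb), max(ca, cb),
                 tuple(sorted((pa.peak_id, pb.peak_id))), pa, pb))
    candidates.sort(key=lambda t: t[:5])
    used_a: set[str] = set()
    used_b: set[str] = set()
    matches: list[PeakMatch] = []
    for d, _, _, _, _, pa, pb in candidates:
        if pa.peak_id in used_a or pb.peak_id in used_b:
            continue
        used_a.add(pa.peak_id)
        used_b.add(pb.peak_id)
        matches.append(PeakMatch(pa.peak_id, pb.peak_id, d))
    matches.sort(key=lambda m: (m.center_distance, m.peak_id_a, m.peak_id_b))
    return matches
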
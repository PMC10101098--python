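"""Peak parsing, center-based promoter assignment, and one-to-one matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from velvet_grn.annotation_io import PromoterWindow
from velvet_grn.peak_ops import (
    Peak,
    assign_peaks_to_promoters,
    match_overlapping_peaks,
    peak_center,
    read_peaks,
)


def test_read_narrowpeak_summit(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text(
        "chr1\t1000\t1200\tpk1\t50\t.\t2.0\t-1\t-1\t75\n"
        "chr1\t2000\t2200\t.\t50\t.\t2.0\t-1\t-1\t-1\n"
    )
    peaks = read_peaks(p, format="narrowPeak")
    assert peaks[0].summit_offset == 75
    assert peaks[1].summit_offset is None
    assert peaks[1].peak_id == "peak_1"  # auto-generated for "."


def test_read_bed3_has_no_summit_no_score(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t10\t30\n")
    (pk,) = read_peaks(p, format="bed")
    assert pk.summit_offset is None and pk.score is None


def test_malformed_column_count_names_the_line(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t1\t2\tpk\t0\t.\t1\t-1\t-1\t0\nchr1\t3\t4\n")
    with pytest.raises(ValueError, match=":2"):
        read_peaks(p, format="narrowPeak")


@pytest.mark.parametrize(
    "start, end, summit, expected",
    [(1000, 1200, None, 1100), (1000, 1201, None, 1100), (1000, 1200, 75, 1075)],
)
def test_peak_center(start, end, summit, expected):
    assert peak_center(Peak("p", "chr1", start, end, summit_offset=summit)) == expected


def _w(gene, start, end, chrom="chr1"):
    return PromoterWindow(gene, chrom, start, end)


def test_assignment_half_open_boundaries():
    win = [_w("g", 3500, 5000)]
    inside = Peak("in", "chr1", 4998, 5000)     # center 4999
    outside = Peak("out", "chr1", 4999, 5001)   # center 5000
    asg, genes = assign_peaks_to_promoters([inside, outside], win)
    assert [(a.peak_id, a.gene_id) for a in asg] == [("in", "g")]
    assert genes == {"g"}


def test_peak_between_divergent_promoters_assigned_twice():
    # + gene tss=5500 window [4000,5500); - gene tss=4500 window [4501,6001)
    windows = [_w("plus", 4000, 5500), _w("minus", 4501, 6001)]
    peak = Peak("pk", "chr1", 4500, 4700)  # center 4600, inside both
    asg, genes = assign_peaks_to_promoters([peak], windows)
    assert genes == {"plus", "minus"}
    assert len(asg) == 2


def test_assignment_invariant_under_peak_ordering():
    windows = [_w(f"g{i}", i * 1000, i * 1000 + 500) for i in range(5)]
    peaks = [Peak(f"p{i}", "chr1", i * 1000 + 100, i * 1000 + 300) for i in range(5)]
    fwd, _ = assign_peaks_to_promoters(peaks, windows)
    rev, _ = assign_peaks_to_promoters(peaks[::-1], windows)
    assert fwd == rev


def _peaks(centers, prefix):
    return [Peak(f"{prefix}{i}", "chr1", c - 10, c + 10) for i, c in enumerate(centers)]


def test_matching_boundary_is_inclusive_at_100():
    assert len(match_overlapping_peaks(_peaks([50], "a"), _peaks([150], "b"))) == 1
    assert len(match_overlapping_peaks(_peaks([50], "a"), _peaks([151], "b"))) == 0


def test_greedy_prefers_smaller_distance():
    # A centers {100, 210}, B center {160}: d=60 vs d=50 -> (210,160) wins
    matches = match_overlapping_peaks(_peaks([100, 210], "a"), _peaks([160], "b"))
    assert [(m.peak_id_a, m.peak_id_b, m.center_distance) for m in matches] == [("a1", "b0", 50)]


def _brute_force_match(peaks_a, peaks_b, max_dist=100):
    """Independent oracle: minimal-distance-first over the full pair list."""
    cands = []
    for pa in peaks_a:
        for pb in peaks_b:
            if pa.chrom != pb.chrom:
                continue
            d = abs(peak_center(pa) - peak_center(pb))
            if d <= max_dist:
                ca, cb = peak_center(pa), peak_center(pb)
                cands.append((d, pa.chrom, min(ca, cb), max(ca, cb),
                              tuple(sorted((pa.peak_id, pb.peak_id))), pa, pb))
    cands.sort(key=lambda t: t[:5])
    used_a, used_b, out = set(), set(), []
    for d, *_, pa, pb in cands:
        if pa.peak_id not in used_a and pb.peak_id not in used_b:
            used_a.add(pa.peak_id)
            used_b.add(pb.peak_id)
            out.append((pa.peak_id, pb.peak_id, d))
    return sorted(out)


@settings(max_examples=150, deadline=None)
@given(
    ca=st.lists(st.integers(0, 800), min_size=0, max_size=20),
    cb=st.lists(st.integers(0, 800), min_size=0, max_size=20),
    max_dist=st.integers(0, 200),
)
def test_matching_equals_bruteforce_and_is_symmetric(ca, cb, max_dist):
    pa, pb = _peaks([c + 20 for c in ca], "a"), _peaks([c + 20 for c in cb], "b")
    got = sorted((m.peak_id_a, m.peak_id_b, m.center_distance)
                 for m in match_overlapping_peaks(pa, pb, max_dist))
    assert got == _brute_force_match(pa, pb, max_dist)
    swapped = sorted((m.peak_id_b, m.peak_id_a, m.center_distance)
                     for m in match_overlapping_peaks(pb, pa, max_dist))
    assert got == swapped
    assert len(got) <= min(len(pa), len(pb))


def test_matches_monotone_in_max_dist():
    rng = np.random.default_rng(0)
    pa = _peaks(rng.integers(100, 5000, 15).tolist(), "a")
    pb = _peaks(rng.integers(100, 5000, 15).tolist(), "b")
    prev: set = set()
    for d in (0, 25, 50, 100, 400):
        cur = {(m.peak_id_a, m.peak_id_b) for m in match_overlapping_peaks(pa, pb, d)}
        assert prev <= cur
        prev = cur
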
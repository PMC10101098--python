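"""DEG calling, direct/putative target classification, and ratio statistics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from velvet_grn.target_classify import (
    DEGCall,
    DERecord,
    TargetRecord,
    classify_degs,
    classify_targets,
    common_direct_targets,
    common_putative_targets,
    percent,
    read_de_table,
)


@pytest.mark.parametrize(
    "log2fc, padj, is_deg, direction",
    [
        (1.5, 0.01, True, "up"),
        (1.0, 0.01, False, "none"),    # exactly 2-fold is not "more than"
        (-3.0, None, False, "none"),   # missing padj -> untested
        (-1.2, 0.049, True, "down"),
        (1.2, 0.05, False, "none"),    # alpha boundary is strict
    ],
)
def test_deg_thresholds(log2fc, padj, is_deg, direction):
    (call,) = classify_degs([DERecord("g", log2fc, padj)])
    assert (call.is_deg, call.direction) == (is_deg, direction)


def test_duplicate_gene_raises():
    with pytest.raises(ValueError, match="duplicate"):
        classify_degs([DERecord("g", 2, 0.01), DERecord("g", 2, 0.01)])


def test_classify_targets_toy_universe():
    universe = [f"g{i}" for i in range(1, 11)]
    peak_set = {"g1", "g2", "g3", "g4", "g5"}
    calls = [DEGCall(g, True, "up") for g in ("g3", "g4", "g5", "g6", "g7")]
    records, counts = classify_targets(peak_set, calls, universe)
    by_status = {}
    for t in records:
        by_status.setdefault(t.status, set()).add(t.gene_id)
    assert by_status["direct"] == {"g3", "g4", "g5"}
    assert by_status["putative_direct"] == {"g1", "g2"}
    assert by_status["deg_only"] == {"g6", "g7"}
    assert counts == {"n_direct": 3, "n_putative": 2, "n_deg_only": 2}


@settings(max_examples=100, deadline=None)
@given(st.data())
def test_classification_equals_bruteforce_sets(data):
    n = data.draw(st.integers(1, 50))
    universe = [f"g{i}" for i in range(n)]
    peak_set = set(data.draw(st.lists(st.sampled_from(universe), max_size=n)))
    deg_set = set(data.draw(st.lists(st.sampled_from(universe), max_size=n)))
    calls = [DEGCall(g, True, "up") for g in deg_set]
    records, counts = classify_targets(peak_set, calls, universe)
    assert counts["n_direct"] == len(peak_set & deg_set)
    assert counts["n_putative"] == len(peak_set - deg_set)
    assert counts["n_deg_only"] == len(deg_set - peak_set)
    # direct and putative partition the peak-associated set
    assert counts["n_direct"] + counts["n_putative"] == len(peak_set)


def test_deg_monotonicity_in_thresholds():
    records = [DERecord(f"g{i}", lfc, p) for i, (lfc, p) in enumerate(
        [(1.1, 0.01), (2.5, 0.04), (-1.5, 0.002), (0.9, 0.001), (3.0, 0.2)])]
    n_deg = lambda a, f: sum(c.is_deg for c in classify_degs(records, alpha=a, min_fold=f))
    assert n_deg(0.01, 2.0) <= n_deg(0.05, 2.0)
    assert n_deg(0.05, 4.0) <= n_deg(0.05, 2.0)


def _direct(gene, direction):
    return TargetRecord(gene, True, "direct", direction)


def test_common_direct_targets_direction_summary():
    a = [_direct("g1", "up"), _direct("g2", "down")]
    b = [_direct("g1", "up"), _direct("g2", "up")]
    common, s = common_direct_targets(a, b)
    assert common == {"g1", "g2"}
    assert (s.n_common, s.n_same_direction, s.n_both_up, s.n_both_down) == (2, 1, 1, 0)
    assert s.pct_same_direction == 50.0


def test_common_direct_targets_symmetric_and_empty():
    a = [_direct("g1", "up")]
    b = [_direct("g2", "down")]
    common, s = common_direct_targets(a, b)
    assert common == set() and s.n_common == 0
    assert math.isnan(s.pct_same_direction)
    c1 = common_direct_targets(a, b)[1]
    c2 = common_direct_targets(b, a)[1]
    assert (c1.n_common, c1.n_same_direction) == (c2.n_common, c2.n_same_direction)


def test_common_putative_targets_exclusive_fractions():
    common, stats = common_putative_targets({"1", "2", "3"}, {"3", "4"})
    assert common == {"3"}
    assert stats["n_exclusive_b"] == 1 and stats["pct_exclusive_b"] == 50.0
    same, stats2 = common_putative_targets({"1"}, {"1"})
    assert stats2["pct_exclusive_a"] == 0.0 and stats2["pct_exclusive_b"] == 0.0


@pytest.mark.parametrize(
    "num, den, dp, expected",
    [
        (3268, 10988, 2, 29.74),
        (978, 10988, 1, 8.9),
        (166, 178, 2, 93.26),  # 93.258...% rounds half-away-from-zero to 93.26
        (0, 7, 2, 0.0),
        (1, 8, 2, 12.5),
    ],
)
def test_percent_examples(num, den, dp, expected):
    assert percent(num, den, dp) == expected


def test_percent_zero_denominator_raises():
    with pytest.raises(ValueError):
        percent(1, 0, 2)


def test_read_de_table_deseq2_aliases(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text("gene_id\tlog2FoldChange\tpadj\ng1\t2.0\t0.001\ng2\t0.1\tNA\n")
    recs = read_de_table(p)
    assert recs[0].log2fc == 2.0 and recs[0].padj == 0.001
    assert recs[1].padj is None
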
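"""Similarity binning, Welch test, sampling and correlation statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from spatialgo.association import (
    FactorThresholds,
    assign_similarity_bin,
    bin_statistics,
    correlation_report,
    distance_decile_bins,
    identify_high_similarity_pairs,
    normalize_counts_for_plot,
    sample_distance_matched_pairs,
    sample_noninteracting_pairs,
    split_by_median_distance,
    welch_t_test,
)
from spatialgo.genome import Gene, GeneCatalog


@pytest.mark.parametrize(
    "score,expected",
    [(0.95, 10), (0.0, 1), (1.0, 10), (0.9, 10), (0.8999, 9), (0.05, 1), (0.1, 2)],
)
def test_similarity_bin_boundaries(score, expected):
    assert assign_similarity_bin(score) == expected


def test_similarity_bin_rejects_out_of_range():
    for bad in (-0.01, 1.01):
        with pytest.raises(ValueError):
            assign_similarity_bin(bad)


def test_bin_partition_property():
    rng = np.random.default_rng(0)
    scores = rng.random(500)
    bins = [assign_similarity_bin(s) for s in scores]
    assert all(1 <= b <= 10 for b in bins)
    for s, b in zip(scores, bins):
        lo, hi = (b - 1) / 10, b / 10
        assert lo <= s < hi or (b == 10 and 0.9 <= s <= 1.0)


def _pair_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "contact_count", "distance",
            "sim_BP", "sim_CC", "sim_MF", "lcs_identity",
        ],
    )


def test_bin_statistics_single_pair_and_fixture():
    single = _pair_frame([["a", "b", 100, 5.0, 0.95, np.nan, np.nan, 0.5]])
    out = bin_statistics(single, "contact_count", "BP")
    assert out.loc[10, "mean"] == 100 and out.loc[10, "median"] == 100
    assert out.loc[10, "n"] == 1 and out.loc[1, "n"] == 0

    # six pairs over two bins: values chosen for hand-checkable stats
    rows = [
        ["a", "b", 10, 1, 0.05, np.nan, np.nan, 0.1],
        ["a", "c", 20, 1, 0.06, np.nan, np.nan, 0.1],
        ["a", "d", 30, 1, 0.07, np.nan, np.nan, 0.1],
        ["b", "c", 100, 1, 0.95, np.nan, np.nan, 0.1],
        ["b", "d", 200, 1, 0.96, np.nan, np.nan, 0.1],
        ["c", "d", 600, 1, 0.97, np.nan, np.nan, 0.1],
    ]
    out = bin_statistics(_pair_frame(rows), "contact_count", "BP")
    assert out.loc[1, "mean"] == 20 and out.loc[1, "median"] == 20
    assert out.loc[10, "mean"] == 300 and out.loc[10, "median"] == 200
    assert out.loc[10, "n"] == 3
    # undefined similarity excluded entirely
    assert out["n"].sum() == 6


def test_welch_identical_groups():
    res = welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert res["t"] == 0.0 and res["p_value"] == pytest.approx(1.0)


def test_welch_matches_hand_computation():
    a, b = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    res = welch_t_test(a, b)
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    t = (ma - mb) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 5)
    assert res["t"] == pytest.approx(t)
    assert res["df"] == pytest.approx(df)
    from scipy import stats

    assert res["p_value"] == pytest.approx(2 * stats.t.sf(abs(t), df))


def test_welch_separated_groups_tiny_p():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, size=50)
    b = rng.normal(10, 1, size=50)
    assert welch_t_test(a, b)["p_value"] < 1e-10


def test_welch_degenerate_groups_rejected():
    with pytest.raises(ValueError):
        welch_t_test([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        welch_t_test([2.0, 2.0], [3.0, 3.0])


def test_welch_p_decreases_with_separation():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 1, size=40)
    shifted = rng.normal(0, 1, size=40)
    p_values = [welch_t_test(base, shifted + delta)["p_value"] for delta in (0.5, 1.0, 2.0, 4.0)]
    assert p_values == sorted(p_values, reverse=True)


def test_distance_deciles_equal_counts_and_remainder():
    rows = [["a", f"g{i}", 1, float(i), 0.5, np.nan, np.nan, 0.1] for i in range(20)]
    out = distance_decile_bins(_pair_frame(rows), "BP")
    assert list(out["n"]) == [2] * 10

    rows23 = [["a", f"g{i}", 1, float(i), 0.5, np.nan, np.nan, 0.1] for i in range(23)]
    out23 = distance_decile_bins(_pair_frame(rows23), "BP")
    assert list(out23["n"]) == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    with pytest.raises(ValueError):
        distance_decile_bins(_pair_frame(rows23[:5]), "BP")


def test_distance_decile_ties_resolved_by_stable_sort():
    # all distances equal: assignment must follow (distance, gene_a, gene_b)
    rows = [["a", f"g{i:02d}", 1, 7.0, float(i) / 30, np.nan, np.nan, 0.1] for i in range(20)]
    out = distance_decile_bins(_pair_frame(rows), "BP")
    # first bin must hold the lexicographically first pairs g00, g01
    assert out.loc[1, "mean_similarity"] == pytest.approx((0 + 1) / 2 / 30)


def _grid_catalog(n=30, spacing=1000):
    return GeneCatalog(
        [Gene(f"G{i:02d}", "", "chr1", 1 + i * spacing, 1 + i * spacing + 10) for i in range(n)]
    )


def test_sample_noninteracting_invariants():
    cat = _grid_catalog()
    pairs = {("G00", "G01"): 5, ("G02", "G03"): 2}
    sample = sample_noninteracting_pairs(cat, pairs, n=50, seed=3)
    assert len(sample) == 50
    assert len(set(sample)) == 50
    assert all(p not in pairs for p in sample)
    assert sample == sample_noninteracting_pairs(cat, pairs, n=50, seed=3)  # determinism


def test_sample_noninteracting_exhaustion_returns_all():
    cat = GeneCatalog([Gene(f"G{i}", "", "chr1", 1 + i * 100, 50 + i * 100) for i in range(4)])
    pairs = {("G0", "G1"): 1}
    sample = sample_noninteracting_pairs(cat, pairs, n=100, seed=0)
    assert len(sample) == 5  # C(4,2) - 1
    assert all(p not in pairs for p in sample)


def test_distance_matched_sampling_within_tolerance():
    cat = _grid_catalog(n=40, spacing=1000)
    pairs = {("G00", "G05"): 30}  # reference pair, distance 5000
    matched = sample_distance_matched_pairs([("G00", "G05")], cat, pairs, tolerance_bp=35, seed=1)
    assert len(matched) == 1
    a, b = matched[0]
    d = abs(cat[a].start - cat[b].start)
    assert abs(d - 5000) <= 35
    assert matched[0] not in pairs


def test_distance_matched_sampling_skips_unmatchable():
    cat = _grid_catalog(n=10, spacing=1000)
    # reference distance 1234 has no grid pair within 35 bp
    cat2 = GeneCatalog(list(cat) + [Gene("REF", "", "chr1", 100000, 100010),
                                    Gene("REF2", "", "chr1", 101234, 101244)])
    matched = sample_distance_matched_pairs([("REF", "REF2")], cat2, {("REF", "REF2"): 99},
                                            tolerance_bp=35, seed=1)
    assert matched == []


def test_correlation_exact_lines_and_fixture():
    x = np.arange(10.0)
    frame = _pair_frame(
        [["a", f"g{i}", int(2 * v + 1), np.nan, np.nan, np.nan, np.nan, v] for i, v in enumerate(x)]
    )
    assert correlation_report(frame, "lcs_identity", "contact_count")["r"] == pytest.approx(1.0)
    frame["contact_count"] = -frame["lcs_identity"]
    assert correlation_report(frame, "lcs_identity", "contact_count")["r"] == pytest.approx(-1.0)

    xs = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
    ys = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
    fix = _pair_frame(
        [["a", f"g{i}", 1, np.nan, np.nan, np.nan, np.nan, 0.1] for i in range(5)]
    )
    fix["x"], fix["y"] = xs, ys
    r_hand = ((xs - xs.mean()) * (ys - ys.mean())).sum() / math.sqrt(
        ((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum()
    )
    assert correlation_report(fix, "x", "y")["r"] == pytest.approx(r_hand)


def test_correlation_constant_input_flagged():
    frame = _pair_frame(
        [["a", f"g{i}", 5, np.nan, np.nan, np.nan, np.nan, 0.5] for i in range(5)]
    )
    assert correlation_report(frame, "lcs_identity", "contact_count")["r"] is None


def test_normalize_counts_examples():
    out = normalize_counts_for_plot(list(range(1, 31)), drop_top=20)
    assert out.min() == 0.0 and out.max() == 1.0
    assert np.allclose(out, np.arange(10) / 9)
    assert np.allclose(normalize_counts_for_plot([7, 7, 7, 9], drop_top=1), 0.0)
    with pytest.raises(ValueError):
        normalize_counts_for_plot([1, 2], drop_top=20)


def test_factor_threshold_sets():
    rows = [
        # sim 0.95, passes all three factors (BP: 50 / 1 Mb / 25 %)
        ["a", "b", 60, 5e5, 0.95, np.nan, np.nan, 0.30],
        # fails only identity
        ["a", "c", 60, 5e5, 0.95, np.nan, np.nan, 0.10],
        # high similarity but fails every factor
        ["a", "d", 10, 5e6, 0.92, np.nan, np.nan, 0.05],
        # low similarity: excluded from every set
        ["b", "c", 999, 1e3, 0.50, np.nan, np.nan, 0.99],
    ]
    sets = identify_high_similarity_pairs(_pair_frame(rows), FactorThresholds(), "BP")
    assert sets["intersection_all"] == {("a", "b")}
    assert sets["by_interactions"] == {("a", "b"), ("a", "c")}
    assert ("a", "c") not in sets["by_identity"]
    assert ("b", "c") not in sets["by_distance"]

    empty = identify_high_similarity_pairs(_pair_frame([]), FactorThresholds(), "BP")
    assert all(v == set() for v in empty.values())


def test_median_split_rules():
    frame = _pair_frame(
        [["a", f"g{i}", 1, d, 0.5, np.nan, np.nan, 0.1] for i, d in enumerate([1.0, 2.0, 3.0, 4.0])]
    )
    short, long_ = split_by_median_distance(frame)
    assert sorted(short["distance"]) == [1.0, 2.0]
    assert sorted(long_["distance"]) == [3.0, 4.0]

    ties = _pair_frame(
        [["a", f"g{i}", 1, 5.0, 0.5, np.nan, np.nan, 0.1] for i in range(4)]
    )
    short, long_ = split_by_median_distance(ties)
    assert len(short) == 4 and len(long_) == 0  # ties go short

    odd = _pair_frame(
        [["a", f"g{i}", 1, d, 0.5, np.nan, np.nan, 0.1] for i, d in enumerate([1.0, 2.0, 3.0])]
    )
    short, long_ = split_by_median_distance(odd)
    assert 2.0 in set(short["distance"])  # median element goes short
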
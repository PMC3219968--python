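"""Dot-point densification, window scanning, trimming, merging, regions."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from mesoscan import GenomeIndex, MatchSet, densify, pair_regions, scan_windows
from mesoscan.colinearity import (
    SyntenicRegion,
    Window,
    blocking_spans,
    extract_regions,
    merge_windows,
    trim_windows,
)

from conftest import make_index, make_match


class TestDensify:
    def test_identity_match_interpolates_identically(self):
        pts = densify([make_match("a", "b", 1, 10_000, 1, 10_000)])
        assert len(pts) == 11
        assert all(p.a_pos == p.b_pos for p in pts)
        assert pts[-1].a_pos == 10_000

    def test_antiparallel_match_reflects(self):
        pts = densify(
            [make_match("a", "b", 1, 10_000, 1, 10_000, orientation="antiparallel")]
        )
        assert len(pts) == 11
        assert all(p.b_pos == 10_001 - p.a_pos for p in pts)

    def test_short_match_keeps_exact_endpoint(self):
        pts = densify([make_match("a", "b", 1, 1_500, 1, 1_500)])
        assert [p.a_pos for p in pts] == [1, 1_001, 1_500]


def scan_single_window(x, y, **kw):
    """Run the scan with one window covering all points."""
    x = np.asarray(x, dtype=float)
    windows = scan_windows(
        x, np.asarray(y, dtype=float), int(x.max()), "a",
        window=10_000_000, step=10_000_000, **kw,
    )
    return windows[0]


class TestScanWindows:
    def test_perfect_diagonal_is_colinear(self):
        x = np.arange(1, 20_001, 1_000, dtype=float)  # 20 points
        w = scan_single_window(x, x + 5)
        assert w.r2 == pytest.approx(1.0)
        assert w.slope == pytest.approx(1.0)
        assert w.colinear

    def test_fourteen_points_are_not_enough(self):
        x = np.arange(1, 14_001, 1_000, dtype=float)  # 14 points
        w = scan_single_window(x, x)
        assert w.n_points == 14
        assert not w.colinear
        assert not w.blocking  # sparse, not evidence against co-linearity

    def test_low_r2_window_with_data_blocks(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.integers(1, 20_000, size=40)).astype(float)
        y = rng.integers(1, 1_000_000, size=40).astype(float)
        w = scan_single_window(x, y)
        assert not w.colinear
        assert w.blocking

    def test_degenerate_zero_variance_is_undefined(self):
        x = np.full(20, 5_000.0)
        w = scan_single_window(x, np.arange(20, dtype=float) * 100 + 1)
        assert math.isnan(w.r2)
        assert not w.colinear
        x2 = np.arange(1, 20_001, 1_000, dtype=float)
        w2 = scan_single_window(x2, np.full_like(x2, 777.0))
        assert math.isnan(w2.r2)
        assert not w2.colinear

    def test_windows_tile_at_fixed_width_and_step(self):
        x = np.array([1.0, 50_000.0])
        windows = scan_windows(x, x, 60_000, "a")
        assert all(w.length == 20_000 for w in windows)
        assert windows[0].start == 1
        assert windows[1].start - windows[0].start == 2_000
        assert windows[-1].start == 40_001

    def test_matches_closed_form_regression_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(15, 60))
            base = int(rng.integers(1, 2_000_000))
            x = np.sort(rng.integers(base, base + 20_000, size=n)).astype(float)
            y = np.round(
                rng.uniform(-2, 2) * x + rng.normal(0, rng.uniform(1, 5_000), size=n)
            )
            w = scan_single_window(x, y)
            lr = stats.linregress(x, y)
            assert w.r2 == pytest.approx(lr.rvalue**2, abs=1e-9)
            assert w.slope == pytest.approx(lr.slope, abs=1e-9)


def colinear_window(start, end, slope=1.0, n=20):
    x = np.linspace(start, end, n)
    return Window(
        axis="a", start=start, end=end, n_points=n, r2=1.0, slope=slope,
        colinear=True, blocking=False, _x=x, _y=slope * x,
    )


def blocking_window(start, end, n=30):
    x = np.linspace(start, end, n)
    return Window(
        axis="a", start=start, end=end, n_points=n, r2=0.1, slope=0.0,
        colinear=False, blocking=True, _x=x, _y=x * 0,
    )


class TestTrimWindows:
    def test_overlapping_blocker_shrinks_the_window(self):
        windows = [colinear_window(1, 20_000), blocking_window(14_001, 34_000)]
        (trimmed,) = trim_windows(windows)
        assert (trimmed.start, trimmed.end) == (1, 14_000)

    def test_no_blockers_leaves_windows_unchanged(self):
        windows = [colinear_window(1, 20_000)]
        (trimmed,) = trim_windows(windows)
        assert (trimmed.start, trimmed.end) == (1, 20_000)

    def test_window_inside_blocker_span_is_dropped(self):
        windows = [colinear_window(10_001, 30_000), blocking_window(1, 40_000)]
        assert trim_windows(windows) == []

    def test_split_keeps_left_and_right_remainders(self):
        windows = [colinear_window(1, 50_000), blocking_window(20_001, 30_000)]
        trimmed = trim_windows(windows)
        assert [(w.start, w.end) for w in trimmed] == [(1, 20_000), (30_001, 50_000)]


class TestMergeWindows:
    def test_similar_slopes_within_gap_merge(self):
        w1 = colinear_window(1, 20_000, slope=1.0)
        w2 = colinear_window(30_001, 50_000, slope=1.1)  # gap 10 kb, ratio 0.909
        (merged,) = merge_windows([w1, w2])
        assert (merged.start, merged.end) == (1, 50_000)

    def test_opposite_signs_never_merge(self):
        w1 = colinear_window(1, 20_000, slope=1.0)
        w2 = colinear_window(30_001, 50_000, slope=-1.0)
        assert len(merge_windows([w1, w2])) == 2

    def test_gap_beyond_fifty_kb_does_not_merge(self):
        w1 = colinear_window(1, 20_000, slope=1.0)
        w2 = colinear_window(80_001, 100_000, slope=1.0)  # gap 60 kb
        assert len(merge_windows([w1, w2])) == 2

    def test_blocking_span_in_the_gap_prevents_merging(self):
        w1 = colinear_window(1, 20_000, slope=1.0)
        w2 = colinear_window(30_001, 50_000, slope=1.0)
        merged = merge_windows([w1, w2], blocked_spans=[(22_000, 28_000)])
        assert len(merged) == 2

    def test_intermediate_points_are_pooled(self):
        w1 = colinear_window(1, 20_000, slope=1.0)
        w2 = colinear_window(30_001, 50_000, slope=1.0)
        all_x = np.arange(1, 50_001, 500, dtype=float)
        (merged,) = merge_windows([w1, w2], all_x=all_x, all_y=all_x.copy())
        assert merged.n_points == all_x.size  # gap points included

    def test_slope_ratio_boundaries_are_strict(self):
        w1 = colinear_window(1, 20_000, slope=1.2)
        w2 = colinear_window(22_001, 42_000, slope=1.0)  # ratio exactly 1.2
        assert len(merge_windows([w1, w2])) == 2


class TestExtractRegions:
    def test_surviving_window_becomes_region(self):
        (region,) = extract_regions([colinear_window(1, 30_000)], seq_a="a", seq_b="b")
        assert region.length == 30_000

    def test_short_window_yields_no_region(self):
        assert extract_regions([colinear_window(1, 4_000)]) == []

    def test_no_windows_yield_no_regions(self):
        assert extract_regions([]) == []


def identity_matchset(seq_len=1_000_000):
    g = make_index("G", ("chr1", seq_len))
    return MatchSet(g, g, (make_match("chr1", "chr1", 1, seq_len, 1, seq_len, 100.0),))


class TestPairRegions:
    def test_identity_pair_yields_full_length_region_per_axis(self):
        ms = identity_matchset()
        regions = pair_regions(ms, ("chr1", "chr1"))
        by_axis = {r.axis for r in regions}
        assert by_axis == {"a", "b"}
        assert all(r.length >= 900_000 for r in regions)
        mean_len = sum(r.length for r in regions) / len(regions)
        assert mean_len >= 20_000

    def test_shuffled_gene_sized_matches_yield_almost_no_regions(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ga = make_index("A", ("a", 1_000_000))
            gb = make_index("B", ("b", 1_000_000))
            matches = []
            for _ in range(300):
                rs = int(rng.integers(1, 997_000))
                qs = int(rng.integers(1, 997_000))
                span = int(rng.integers(1_000, 2_000))
                orientation = "parallel" if rng.random() < 0.5 else "antiparallel"
                matches.append(
                    make_match("a", "b", rs, rs + span, qs, qs + span, 80.0, orientation)
                )
            regions = pair_regions(MatchSet(ga, gb, tuple(matches)), ("a", "b"))
            counts.append(len(regions))
        assert np.mean(counts) < 2  # fewer than one region per axis on average

    def test_empty_pair_yields_no_regions(self):
        ms = identity_matchset()
        assert pair_regions(ms, ("chr1", "missing")) == []

    def test_translation_equivariance_at_step_aligned_offsets(self):
        offset = 40_000  # multiple of the 2-kb step
        ga = make_index("A", ("a", 400_000))
        gb = make_index("B", ("b", 400_000))
        matches = tuple(
            make_match("a", "b", s, s + 1_500, s, s + 1_500)
            for s in range(50_001, 150_001, 2_500)
        )
        base = pair_regions(MatchSet(ga, gb, matches), ("a", "b"))

        ga2 = make_index("A", ("a", 400_000 + offset))
        gb2 = make_index("B", ("b", 400_000 + offset))
        shifted_matches = tuple(
            make_match("a", "b", m.ref_start + offset, m.ref_end + offset,
                       m.qry_start + offset, m.qry_end + offset)
            for m in matches
        )
        shifted = pair_regions(MatchSet(ga2, gb2, shifted_matches), ("a", "b"))
        assert len(base) == len(shifted)
        for r1, r2 in zip(base, shifted):
            assert (r2.start - r1.start, r2.end - r1.end) == (offset, offset)

    def test_regions_never_overlap_blocking_spans(self):
        rng = np.random.default_rng(3)
        ga = make_index("A", ("a", 600_000))
        gb = make_index("B", ("b", 600_000))
        matches = []
        # a diagonal stretch, an inverted stretch, and noise in between
        for s in range(1, 200_001, 2_500):
            matches.append(make_match("a", "b", s, s + 1_500, s, s + 1_500))
        for s in range(300_001, 420_001, 2_500):
            q = 720_002 - s - 1_500
            matches.append(
                make_match("a", "b", s, s + 1_500, q, q + 1_500, 80.0, "antiparallel")
            )
        for _ in range(150):
            rs = int(rng.integers(200_001, 300_000))
            qs = int(rng.integers(1, 598_000))
            matches.append(make_match("a", "b", rs, rs + 1_200, qs, qs + 1_200))
        ms = MatchSet(ga, gb, tuple(matches))

        from mesoscan.colinearity import densify as _densify

        pts = _densify([m for m in ms.matches])
        x = np.sort(np.array([p.a_pos for p in pts], dtype=float))
        y = np.array([p.b_pos for p in sorted(pts, key=lambda p: p.a_pos)], dtype=float)
        raw = scan_windows(x, y, 600_000, "a")
        blocked = blocking_spans(raw)
        regions = [r for r in pair_regions(ms, ("a", "b")) if r.axis == "a"]
        assert regions  # the diagonals must be found
        for r in regions:
            for bs, be in blocked:
                assert r.end < bs or r.start > be
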
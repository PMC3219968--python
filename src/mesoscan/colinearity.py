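"""Co-linear region detection on per-pair dot plots.

Matches of a significantly conserved sequence pair are densified into
scatter points (one point every 1 kb along each match), then scanned in
20-kb windows stepping by 2 kb along one axis.  A window is co-linear
when it holds at least 15 points whose squared Pearson correlation
(R^2, identical to the coefficient of determination of the
least-squares line) is at least 0.9.  Co-linear windows are trimmed
against overlapping non-co-linear windows, merged across gaps of up to
50 kb when their slope ratio lies strictly in (0.8, 1.2), and the
survivors of at least 5 kb become "syntenic regions".  The mean region
length, pooled over both axes of all significant pairs, later decides
macro- versus mesosynteny.

R^2 is orientation-blind: anti-parallel matches produce negative
slopes but still count as co-linear (an inverted segment is still a
diagonal).  Slopes keep their sign, so windows of opposite orientation
never merge across an inversion breakpoint.

Windows that hold enough points (>= 15) but fail the R^2 test are
*blocking*: they are positive evidence against co-linearity, so they
trim overlapping co-linear windows and cannot be bridged by the 50-kb
merge rule.  Windows that merely lack data are sparse, not blocking,
and may be merged across — this is what lets a diagonal continue over
an unaligned stretch while an inversion breakpoint still splits it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ANTIPARALLEL, Match, MatchSet

DEFAULT_WINDOW = 20_000
DEFAULT_STEP = 2_000
DEFAULT_MIN_POINTS = 15
DEFAULT_MIN_R2 = 0.9
DEFAULT_MERGE_GAP = 50_000
DEFAULT_SLOPE_LO = 0.8
DEFAULT_SLOPE_HI = 1.2
DEFAULT_MIN_REGION_LEN = 5_000
DENSIFY_SPACING = 1_000

# Smallest centered sum of squares two distinct integer positions can
# have is 0.5 (two values 1 bp apart); below a quarter of that the
# coordinate is constant up to rounding noise.
_VAR_EPS = 0.25


@dataclass(frozen=True, slots=True)
class DotPoint:
    """One densified dot-plot point of a match."""

    a_pos: int
    b_pos: int
    match_index: int


@dataclass
class Window:
    """One scan window on a pair dot plot (raw, trimmed or merged)."""

    axis: str  # "a" or "b"
    start: int
    end: int
    n_points: int
    r2: float  # nan when undefined
    slope: float  # nan when undefined
    colinear: bool
    blocking: bool = False
    _x: np.ndarray = field(default=None, repr=False, compare=False)
    _y: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SyntenicRegion:
    """A merged co-linear window of at least 5 kb on one axis."""

    seq_a: str
    seq_b: str
    axis: str
    start: int
    end: int
    slope: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def densify(matches: Sequence[Match]) -> list[DotPoint]:
    """Convert matches into scatter points, one every 1 kb along each.

    Points sit at reference offsets 0, 1000, 2000, ... plus the exact
    match endpoint when it is not already on the grid; the query
    position is interpolated linearly along the match (descending for
    anti-parallel matches) and rounded to the nearest bp.
    """
    points: list[DotPoint] = []
    for idx, m in enumerate(matches):
        span_a = m.ref_end - m.ref_start
        span_b = m.qry_end - m.qry_start
        offsets = list(range(0, span_a + 1, DENSIFY_SPACING))
        if offsets[-1] != span_a:
            offsets.append(span_a)
        anti = m.orientation == ANTIPARALLEL
        for off in offsets:
            frac = off / span_a if span_a else 0.0
            delta = round(frac * span_b)
            b_pos = m.qry_end - delta if anti else m.qry_start + delta
            points.append(DotPoint(m.ref_start + off, b_pos, idx))
    return points


def _fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (r2, slope) of y on x; (nan, nan) when degenerate."""
    n = x.size
    if n < 2:
        return (math.nan, math.nan)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx <= _VAR_EPS or syy <= _VAR_EPS:
        return (math.nan, math.nan)
    return (sxy * sxy / (sxx * syy), sxy / sxx)


def scan_windows(
    x: np.ndarray,
    y: np.ndarray,
    seq_len: int,
    axis: str,
    *,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_points: int = DEFAULT_MIN_POINTS,
    min_r2: float = DEFAULT_MIN_R2,
) -> list[Window]:
    """Slide fixed-width windows along one axis and test co-linearity.

    ``x`` holds scan-axis positions sorted ascending with ``y`` the
    matching other-axis positions.  Windows are anchored at position 1
    and tile ``[1, seq_len]`` at ``step``; each is exactly ``window`` bp
    wide.  R^2 is the squared Pearson correlation of the two coordinate
    sets inside the window and the slope is the least-squares slope of
    the other axis on the scan axis.  Windows with fewer than two
    distinct positions or zero variance on either coordinate have
    undefined R^2 and are never co-linear.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    order = np.argsort(x, kind="stable")
    x = x[order]
    y = y[order]
    starts = np.arange(1, max(seq_len - window + 1, 1) + 1, step, dtype=np.int64)
    ends = starts + window - 1

    # Centered prefix sums keep the closed-form window statistics
    # accurate at chromosome-scale coordinates.
    x0 = x - (x.mean() if x.size else 0.0)
    y0 = y - (y.mean() if y.size else 0.0)
    z = np.zeros(1)
    cx = np.concatenate([z, np.cumsum(x0)])
    cy = np.concatenate([z, np.cumsum(y0)])
    cxx = np.concatenate([z, np.cumsum(x0 * x0)])
    cyy = np.concatenate([z, np.cumsum(y0 * y0)])
    cxy = np.concatenate([z, np.cumsum(x0 * y0)])

    lo = np.searchsorted(x, starts, side="left")
    hi = np.searchsorted(x, ends, side="right")
    out: list[Window] = []
    for s, e, l, h in zip(starts, ends, lo, hi):
        n = int(h - l)
        r2 = math.nan
        slope = math.nan
        if n >= 2:
            sx = cx[h] - cx[l]
            sy = cy[h] - cy[l]
            sxx = (cxx[h] - cxx[l]) - sx * sx / n
            syy = (cyy[h] - cyy[l]) - sy * sy / n
            sxy = (cxy[h] - cxy[l]) - sx * sy / n
            if sxx > _VAR_EPS and syy > _VAR_EPS:
                r2 = sxy * sxy / (sxx * syy)
                slope = sxy / sxx
        colinear = n >= min_points and not math.isnan(r2) and r2 >= min_r2
        out.append(
            Window(
                axis=axis,
                start=int(s),
                end=int(e),
                n_points=n,
                r2=r2,
                slope=slope,
                colinear=colinear,
                blocking=(not colinear) and n >= min_points,
                _x=x[l:h],
                _y=y[l:h],
            )
        )
    return out


def _union_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def blocking_spans(windows: Sequence[Window]) -> list[tuple[int, int]]:
    """Merged coordinate spans of all blocking (data-bearing failed) windows."""
    return _union_spans([(w.start, w.end) for w in windows if w.blocking])


def trim_windows(windows: Sequence[Window]) -> list[Window]:
    """Shrink co-linear windows away from overlapping non-co-linear spans.

    Each co-linear window is cut so it no longer overlaps the span of
    any blocking window.  When the blocking union splits a window, the
    maximal left and right remainders are kept; windows shrunk to
    nothing are dropped.  The fitted R^2/slope of the original window
    are carried over (merging refits on pooled points later).
    """
    blocked = blocking_spans(windows)
    out: list[Window] = []
    for w in windows:
        if not w.colinear:
            continue
        fragments = _subtract(w.start, w.end, blocked)
        if len(fragments) > 2:
            fragments = [fragments[0], fragments[-1]]
        for fs, fe in fragments:
            keep = (w._x >= fs) & (w._x <= fe) if w._x is not None else None
            out.append(
                Window(
                    axis=w.axis,
                    start=fs,
                    end=fe,
                    n_points=int(keep.sum()) if keep is not None else w.n_points,
                    r2=w.r2,
                    slope=w.slope,
                    colinear=True,
                    blocking=False,
                    _x=w._x[keep] if keep is not None else None,
                    _y=w._y[keep] if keep is not None else None,
                )
            )
    out.sort(key=lambda w: (w.start, w.end))
    return out


def _subtract(start: int, end: int, blocked: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    fragments: list[tuple[int, int]] = []
    cursor = start
    for bs, be in blocked:
        if be < cursor or bs > end:
            continue
        if bs > cursor:
            fragments.append((cursor, bs - 1))
        cursor = max(cursor, be + 1)
        if cursor > end:
            break
    if cursor <= end:
        fragments.append((cursor, end))
    return fragments


def _slope_ratio_ok(s1: float, s2: float, lo: float, hi: float) -> bool:
    if math.isnan(s1) or math.isnan(s2) or s2 == 0.0:
        return False
    ratio = s1 / s2
    return lo < ratio < hi


def merge_windows(
    windows: Sequence[Window],
    *,
    gap: int = DEFAULT_MERGE_GAP,
    slope_lo: float = DEFAULT_SLOPE_LO,
    slope_hi: float = DEFAULT_SLOPE_HI,
    blocked_spans: Sequence[tuple[int, int]] = (),
    all_x: np.ndarray | None = None,
    all_y: np.ndarray | None = None,
) -> list[Window]:
    """Merge trimmed co-linear windows into larger co-linear windows.

    Adjacent windows (sorted by start) merge when their axis gap is at
    most ``gap`` bp, no blocking span lies in the gap, and the signed
    ratio of their slopes is strictly inside ``(slope_lo, slope_hi)``.
    The merged window spans both, pools their points together with any
    intermediate points lying between them (``all_x``/``all_y`` are the
    full sorted point arrays of the axis), and refits slope and R^2 on
    the pooled points.  Merging proceeds left to right and repeats
    until stable.
    """
    current = sorted(windows, key=lambda w: (w.start, w.end))
    blocked = _union_spans(blocked_spans)

    def gap_blocked(a_end: int, b_start: int) -> bool:
        if b_start - a_end <= 1:
            return False
        for bs, be in blocked:
            if bs <= b_start - 1 and be >= a_end + 1:
                return True
        return False

    def pooled(start: int, end: int, w1: Window, w2: Window) -> tuple[np.ndarray, np.ndarray]:
        if all_x is not None:
            l = int(np.searchsorted(all_x, start, side="left"))
            h = int(np.searchsorted(all_x, end, side="right"))
            return all_x[l:h], all_y[l:h]
        xs = np.concatenate([w1._x, w2._x])
        ys = np.concatenate([w1._y, w2._y])
        order = np.argsort(xs, kind="stable")
        return xs[order], ys[order]

    while True:
        merged_any = False
        out: list[Window] = []
        cur: Window | None = None
        for w in current:
            if cur is None:
                cur = w
                continue
            gap_bp = w.start - cur.end - 1
            if (
                gap_bp <= gap
                and not gap_blocked(cur.end, w.start)
                and _slope_ratio_ok(cur.slope, w.slope, slope_lo, slope_hi)
            ):
                start = cur.start
                end = max(cur.end, w.end)
                px, py = pooled(start, end, cur, w)
                r2, slope = _fit(px, py)
                if math.isnan(slope):
                    slope = cur.slope  # degenerate pooled fit: keep going
                cur = Window(
                    axis=cur.axis,
                    start=start,
                    end=end,
                    n_points=int(px.size),
                    r2=r2,
                    slope=slope,
                    colinear=True,
                    blocking=False,
                    _x=px,
                    _y=py,
                )
                merged_any = True
            else:
                out.append(cur)
                cur = w
        if cur is not None:
            out.append(cur)
        current = out
        if not merged_any:
            return current


def extract_regions(
    windows: Sequence[Window],
    min_len: int = DEFAULT_MIN_REGION_LEN,
    *,
    seq_a: str = "",
    seq_b: str = "",
) -> list[SyntenicRegion]:
    """Turn surviving co-linear windows of >= ``min_len`` bp into regions."""
    return [
        SyntenicRegion(
            seq_a=seq_a,
            seq_b=seq_b,
            axis=w.axis,
            start=w.start,
            end=w.end,
            slope=w.slope,
        )
        for w in windows
        if w.colinear and w.length >= min_len
    ]


def _scan_axis(
    x: np.ndarray,
    y: np.ndarray,
    seq_len: int,
    axis: str,
    seq_a: str,
    seq_b: str,
    *,
    window: int,
    step: int,
    min_points: int,
    min_r2: float,
    merge_gap: int,
    slope_lo: float,
    slope_hi: float,
    min_region_len: int,
) -> list[SyntenicRegion]:
    order = np.argsort(x, kind="stable")
    x = np.asarray(x, dtype=np.float64)[order]
    y = np.asarray(y, dtype=np.float64)[order]
    raw = scan_windows(
        x, y, seq_len, axis, window=window, step=step, min_points=min_points, min_r2=min_r2
    )
    blocked = blocking_spans(raw)
    trimmed = trim_windows(raw)
    merged = merge_windows(
        trimmed,
        gap=merge_gap,
        slope_lo=slope_lo,
        slope_hi=slope_hi,
        blocked_spans=blocked,
        all_x=x,
        all_y=y,
    )
    return extract_regions(merged, min_region_len, seq_a=seq_a, seq_b=seq_b)


def pair_regions(
    matchset: MatchSet,
    pair: tuple[str, str],
    *,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_points: int = DEFAULT_MIN_POINTS,
    min_r2: float = DEFAULT_MIN_R2,
    merge_gap: int = DEFAULT_MERGE_GAP,
    slope_lo: float = DEFAULT_SLOPE_LO,
    slope_hi: float = DEFAULT_SLOPE_HI,
    min_region_len: int = DEFAULT_MIN_REGION_LEN,
) -> list[SyntenicRegion]:
    """Full scan -> trim -> merge -> extract pipeline for one pair.

    The scan runs along the axis of sequence A and is then repeated
    along the axis of sequence B; the returned regions are the
    concatenation of both passes.
    """
    seq_a, seq_b = (pair.seq_a, pair.seq_b) if hasattr(pair, "seq_a") else pair
    matches = [m for m in matchset.matches if m.ref_id == seq_a and m.qry_id == seq_b]
    if not matches:
        return []
    points = densify(matches)
    a = np.array([pt.a_pos for pt in points], dtype=np.float64)
    b = np.array([pt.b_pos for pt in points], dtype=np.float64)
    kwargs = dict(
        window=window,
        step=step,
        min_points=min_points,
        min_r2=min_r2,
        merge_gap=merge_gap,
        slope_lo=slope_lo,
        slope_hi=slope_hi,
        min_region_len=min_region_len,
    )
    regions = _scan_axis(
        a, b, matchset.genome_a.length_of(seq_a), "a", seq_a, seq_b, **kwargs
    )
    regions += _scan_axis(
        b, a, matchset.genome_b.length_of(seq_b), "b", seq_a, seq_b, **kwargs
    )
    return regions
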
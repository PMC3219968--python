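"""Significance of sequence conservation between sequence pairs.

Every combination of one retained sequence from genome A and one from
genome B is tested for a significant amount of shared (conserved)
sequence.  The observed conservation level of a pair,

    x = (conserved length on A * conserved length on B)
        / (length of A * length of B),

is compared against the genome-wide background density

    p = (total conserved length of genome A * total of genome B)
        / (total length of genome A * total of genome B)

via a one-tailed cumulative binomial probability with n = 100 trials:

    P_syn = P(X <= k),  X ~ Binomial(n, p),  k = round(n * x)  (half-up).

``P_syn`` is the probability that background-level conservation would
be at most the observed level; a pair is significantly conserved when
``P_syn >= 0.99`` and it has non-zero conserved length on both axes.

Conserved lengths are unions of match intervals (overlaps counted
once); the genome-wide totals use per-sequence unions over *all*
matches of each sequence, so a base matched to two different partners
counts once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import Match, MatchSet

#: Number of binomial trials used by the conservation test.
DEFAULT_N_TRIALS = 100

#: Significance gate on the cumulative binomial probability.
DEFAULT_P_SYN_THRESHOLD = 0.99


@dataclass(frozen=True)
class PairConservation:
    """Conservation statistics for one (sequence A, sequence B) pair."""

    seq_a: str
    seq_b: str
    conserved_len_a: int
    conserved_len_b: int
    x: float
    n: int
    p: float
    p_syn: float
    significant: bool


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals.

    Overlapping and adjacent intervals are counted once; the empty
    collection has length 0.
    """
    ivs = sorted(intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for start, end in ivs:
        if start > end:
            raise ValueError(f"interval ({start}, {end}) has start > end")
        if cur_start is None or start > cur_end + 1:
            if cur_start is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start + 1
    return total


def conserved_length(matches: Sequence[Match], axis: str) -> int:
    """Union length of match intervals projected on one axis.

    ``axis`` is ``"a"`` (reference projection) or ``"b"`` (query
    projection).  All matches are assumed to lie on a single sequence
    of that axis; an empty list yields 0.
    """
    if axis == "a":
        return union_length(m.ref_span for m in matches)
    if axis == "b":
        return union_length(m.qry_span for m in matches)
    raise ValueError(f"axis must be 'a' or 'b', got {axis!r}")


def per_sequence_conserved(matchset: MatchSet) -> tuple[dict[str, int], dict[str, int]]:
    """Per-sequence conserved lengths (interval unions over all matches).

    Returns ``(conserved_a, conserved_b)`` mapping every sequence id of
    the respective genome to its conserved length (0 when unmatched).
    """
    spans_a: dict[str, list[tuple[int, int]]] = {s: [] for s in matchset.genome_a.ids}
    spans_b: dict[str, list[tuple[int, int]]] = {s: [] for s in matchset.genome_b.ids}
    for m in matchset.matches:
        spans_a[m.ref_id].append(m.ref_span)
        spans_b[m.qry_id].append(m.qry_span)
    conserved_a = {s: union_length(v) for s, v in spans_a.items()}
    conserved_b = {s: union_length(v) for s, v in spans_b.items()}
    return conserved_a, conserved_b


def background_p(matchset: MatchSet) -> float:
    """Genome-wide background conservation probability ``p``.

    The product of the conserved fractions of the two genomes, using
    per-sequence interval unions summed over retained sequences.
    """
    total_a = matchset.genome_a.total_length
    total_b = matchset.genome_b.total_length
    if total_a == 0 or total_b == 0:
        raise ValueError("zero total genome length")
    conserved_a, conserved_b = per_sequence_conserved(matchset)
    return (sum(conserved_a.values()) / total_a) * (sum(conserved_b.values()) / total_b)


def binomial_cdf(k: int, n: int, p: float) -> float:
    """Cumulative binomial probability ``P(X <= k)`` for X ~ B(n, p).

    Computed by direct summation in log space (exact ``math.comb``
    log-binomial coefficients, rescaled by the largest term), which
    keeps the relative error near machine precision for moderate ``n``
    without any normal approximation.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if k < 0:
        return 0.0
    if k >= n:
        return 1.0
    if p == 0.0:
        return 1.0  # all mass at zero successes
    if p == 1.0:
        return 0.0  # all mass at n successes, and k < n here
    log_p = math.log(p)
    log_q = math.log1p(-p)
    log_terms = [
        math.log(math.comb(n, i)) + i * log_p + (n - i) * log_q for i in range(k + 1)
    ]
    m = max(log_terms)
    total = math.exp(m) * math.fsum(math.exp(t - m) for t in log_terms)
    return min(total, 1.0)  # guard against float overshoot of the full sum


def p_syn(x: float, p: float, n: int = DEFAULT_N_TRIALS) -> float:
    """Probability of synteny for one sequence pair.

    ``x`` is the pair's observed conservation level and ``p`` the
    genome-wide background; the observed success count is
    ``k = round(n * x)`` with half-up rounding.  Monotone non-decreasing
    in ``x`` at fixed ``p`` and non-increasing in ``p`` at fixed
    ``k < n``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x={x} outside [0, 1]")
    k = math.floor(n * x + 0.5)
    return binomial_cdf(k, n, p)


def significant_pairs(
    matchset: MatchSet,
    *,
    n: int = DEFAULT_N_TRIALS,
    p_syn_threshold: float = DEFAULT_P_SYN_THRESHOLD,
) -> list[PairConservation]:
    """Conservation statistics for every sequence pair sharing a match.

    Pairs with no matches are omitted (they cannot be evidence of
    synteny).  The ``significant`` flag requires ``p_syn >= threshold``
    and non-zero conserved length on both axes.  Output is sorted by
    ``(seq_a, seq_b)`` and independent of match order.
    """
    p = background_p(matchset)
    len_a = matchset.genome_a.lengths
    len_b = matchset.genome_b.lengths
    out: list[PairConservation] = []
    for (seq_a, seq_b), pair_matches in sorted(matchset.by_pair().items()):
        ca = conserved_length(pair_matches, "a")
        cb = conserved_length(pair_matches, "b")
        x = (ca / len_a[seq_a]) * (cb / len_b[seq_b])
        prob = p_syn(x, p, n)
        out.append(
            PairConservation(
                seq_a=seq_a,
                seq_b=seq_b,
                conserved_len_a=ca,
                conserved_len_b=cb,
                x=x,
                n=n,
                p=p,
                p_syn=prob,
                significant=prob >= p_syn_threshold and ca > 0 and cb > 0,
            )
        )
    return out


def pairs_table(pairs: Sequence[PairConservation]) -> pd.DataFrame:
    """Tabular (TSV-ready) report with one row per sequence pair."""
    return pd.DataFrame(
        [
            {
                "seq_a": pc.seq_a,
                "seq_b": pc.seq_b,
                "conserved_len_a": pc.conserved_len_a,
                "conserved_len_b": pc.conserved_len_b,
                "x": pc.x,
                "n": pc.n,
                "p": pc.p,
                "p_syn": pc.p_syn,
                "significant": pc.significant,
            }
            for pc in pairs
        ]
    )
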
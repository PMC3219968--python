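"""Whole-genome synteny verdicts: none / mesosynteny / macrosynteny.

The decision combines three statistics:

* **significant pair ratio** — the number of significantly conserved
  sequence pairs divided by the number expected under perfect
  whole-genome synteny, ``min(S_a, S_b)`` (one partner per sequence of
  the smaller-count genome).  A genome pair is syntenic at the whole
  genome level when the ratio is >= 0.25; otherwise the verdict is
  "none".
* **mean syntenic region length** — co-linear regions are extracted for
  every significant pair on both axes; a mean length >= 20 kb makes the
  pair macrosyntenic, anything less (including no regions at all, the
  hallmark of mesosynteny's diagonal-free boxes) mesosyntenic.
* **pair exclusivity** — for a pair (a, b), the fraction of all
  conserved length in a's row and b's column that resides inside their
  shared box, ``C_ab / (C_Ab + C_aB - C_ab)``.  Synteny is "degraded"
  when the maximum exclusivity over significant pairs is below 0.75.

Conserved-match lengths (the C terms) are interval-union lengths summed
over both projections of the pair, applied consistently to numerator
and denominator so the statistic is scale-free.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

from . import colinearity
from .conservation import PairConservation, conserved_length, significant_pairs
from .io import DEFAULT_MIN_SEQ_LEN, MatchSet, filter_matchset

CATEGORY_NONE = "none"
CATEGORY_MESO = "mesosynteny"
CATEGORY_MACRO = "macrosynteny"

_LABELS = {
    (CATEGORY_NONE, None): "None",
    (CATEGORY_MESO, False): "Meso",
    (CATEGORY_MESO, True): "Demeso",
    (CATEGORY_MACRO, False): "Macro",
    (CATEGORY_MACRO, True): "Demacro",
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the classification process (published defaults)."""

    min_seq_len: int = DEFAULT_MIN_SEQ_LEN
    n_trials: int = 100
    p_syn_threshold: float = 0.99
    pair_ratio_threshold: float = 0.25
    macro_min_region_len: int = 20_000
    exclusivity_threshold: float = 0.75
    #: "fraction": C_ab / (C_Ab + C_aB - C_ab); "min": min(C_ab/C_Ab, C_ab/C_aB)
    exclusivity_mode: str = "fraction"
    #: "max": degraded iff max exclusivity < threshold (the literal rule);
    #: "share": degraded iff fewer than ``degraded_share`` of significant
    #: pairs are individually exclusive.
    degraded_mode: str = "max"
    degraded_share: float = 0.5
    window: int = colinearity.DEFAULT_WINDOW
    step: int = colinearity.DEFAULT_STEP
    min_points: int = colinearity.DEFAULT_MIN_POINTS
    min_r2: float = colinearity.DEFAULT_MIN_R2
    merge_gap: int = colinearity.DEFAULT_MERGE_GAP
    slope_lo: float = colinearity.DEFAULT_SLOPE_LO
    slope_hi: float = colinearity.DEFAULT_SLOPE_HI
    min_region_len: int = colinearity.DEFAULT_MIN_REGION_LEN


@dataclass(frozen=True)
class SyntenyVerdict:
    """Genome-pair classification plus the statistics that produced it."""

    genome_a: str
    genome_b: str
    category: str
    degraded: bool | None  # None when category is "none" (not applicable)
    n_scp: int
    s_a: int
    s_b: int
    pair_ratio: float
    mean_region_len: float
    n_regions: int
    exclusivities: tuple[tuple[str, str, float], ...]
    max_exclusivity: float  # nan when no significant pairs
    pairs: tuple[PairConservation, ...] = field(default=(), repr=False)
    regions: tuple[colinearity.SyntenicRegion, ...] = field(default=(), repr=False)

    @property
    def label(self) -> str:
        """Short verdict label: None / Meso / Demeso / Macro / Demacro."""
        return _LABELS[(self.category, self.degraded)]


def significant_pair_ratio(n_scp: int, s_a: int, s_b: int) -> float:
    """Observed over expected count of significantly conserved pairs.

    Under perfect whole-genome synteny the expected count is one
    partner per sequence of the smaller-count genome, ``min(s_a, s_b)``,
    which makes the identity comparison score exactly 1.
    """
    if s_a < 1 or s_b < 1:
        raise ValueError("retained sequence counts must be >= 1")
    return n_scp / min(s_a, s_b)


def pair_exclusivity(c_ab: float, c_Ab: float, c_aB: float, mode: str = "fraction") -> float:
    """Fraction of a pair's row-and-column conserved length inside its box.

    ``c_ab`` is the conserved length between sequences a and b, ``c_Ab``
    between a and all of genome B, ``c_aB`` between b and all of genome
    A.  Returns ``c_ab / (c_Ab + c_aB - c_ab)`` (or the minimum of the
    row and column fractions in "min" mode); nan when the denominator
    is zero.
    """
    if not (0 <= c_ab <= c_Ab and c_ab <= c_aB):
        raise ValueError("require 0 <= c_ab <= c_Ab and c_ab <= c_aB")
    if mode == "fraction":
        denom = c_Ab + c_aB - c_ab
        return c_ab / denom if denom > 0 else math.nan
    if mode == "min":
        if c_Ab == 0 or c_aB == 0:
            return math.nan
        return min(c_ab / c_Ab, c_ab / c_aB)
    raise ValueError(f"unknown exclusivity mode {mode!r}")


def _conserved_by_pair(matchset: MatchSet) -> dict[tuple[str, str], int]:
    """C_ab for every matched pair: union lengths summed over both axes."""
    out: dict[tuple[str, str], int] = {}
    for pair, matches in matchset.by_pair().items():
        out[pair] = conserved_length(matches, "a") + conserved_length(matches, "b")
    return out


def pair_exclusivities(
    matchset: MatchSet,
    pairs: Sequence[tuple[str, str]],
    mode: str = "fraction",
) -> list[tuple[str, str, float]]:
    """Exclusivity value for each requested (seq_a, seq_b) pair.

    Pairs with an undefined exclusivity (no conserved length in their
    row and column) are skipped.
    """
    c_by_pair = _conserved_by_pair(matchset)
    row_total: dict[str, int] = {}
    col_total: dict[str, int] = {}
    for (a, b), c in c_by_pair.items():
        row_total[a] = row_total.get(a, 0) + c
        col_total[b] = col_total.get(b, 0) + c
    out: list[tuple[str, str, float]] = []
    for a, b in pairs:
        c_ab = c_by_pair.get((a, b), 0)
        value = pair_exclusivity(c_ab, row_total.get(a, 0), col_total.get(b, 0), mode)
        if not math.isnan(value):
            out.append((a, b, value))
    return out


def classify(matchset: MatchSet, config: ClassifierConfig | None = None) -> SyntenyVerdict:
    """Run the whole classification process on one genome pair.

    The match set is length-filtered (idempotent if already filtered),
    the conservation test enumerates significant pairs, co-linear
    regions are extracted for each significant pair on both axes, and
    the verdict is decided by the pair-ratio, mean-region-length and
    exclusivity thresholds.
    """
    config = config or ClassifierConfig()
    matchset = filter_matchset(matchset, config.min_seq_len)
    s_a = len(matchset.genome_a)
    s_b = len(matchset.genome_b)
    pairs = significant_pairs(
        matchset, n=config.n_trials, p_syn_threshold=config.p_syn_threshold
    )
    sig = [pc for pc in pairs if pc.significant]
    ratio = significant_pair_ratio(len(sig), s_a, s_b)

    regions: list[colinearity.SyntenicRegion] = []
    exclusivities: list[tuple[str, str, float]] = []
    if ratio >= config.pair_ratio_threshold:
        for pc in sig:
            regions.extend(
                colinearity.pair_regions(
                    matchset,
                    (pc.seq_a, pc.seq_b),
                    window=config.window,
                    step=config.step,
                    min_points=config.min_points,
                    min_r2=config.min_r2,
                    merge_gap=config.merge_gap,
                    slope_lo=config.slope_lo,
                    slope_hi=config.slope_hi,
                    min_region_len=config.min_region_len,
                )
            )
        exclusivities = pair_exclusivities(
            matchset, [(pc.seq_a, pc.seq_b) for pc in sig], config.exclusivity_mode
        )

    mean_region_len = (
        sum(r.length for r in regions) / len(regions) if regions else 0.0
    )
    max_excl = max((v for _, _, v in exclusivities), default=math.nan)

    if ratio < config.pair_ratio_threshold:
        category = CATEGORY_NONE
        degraded: bool | None = None
    else:
        category = (
            CATEGORY_MACRO
            if mean_region_len >= config.macro_min_region_len
            else CATEGORY_MESO
        )
        if config.degraded_mode == "max":
            degraded = bool(
                math.isnan(max_excl) or max_excl < config.exclusivity_threshold
            )
        elif config.degraded_mode == "share":
            n_excl = sum(
                1 for _, _, v in exclusivities if v >= config.exclusivity_threshold
            )
            degraded = bool(
                not exclusivities or n_excl / len(exclusivities) < config.degraded_share
            )
        else:
            raise ValueError(f"unknown degraded mode {config.degraded_mode!r}")

    return SyntenyVerdict(
        genome_a=matchset.genome_a.label,
        genome_b=matchset.genome_b.label,
        category=category,
        degraded=degraded,
        n_scp=len(sig),
        s_a=s_a,
        s_b=s_b,
        pair_ratio=ratio,
        mean_region_len=mean_region_len,
        n_regions=len(regions),
        exclusivities=tuple(exclusivities),
        max_exclusivity=max_excl,
        pairs=tuple(pairs),
        regions=tuple(regions),
    )


# ---------------------------------------------------------------------------
# serialization


def verdict_to_dict(verdict: SyntenyVerdict) -> dict:
    """JSON-ready dict of every verdict field (nan encoded as None)."""
    d = {
        "genome_a": verdict.genome_a,
        "genome_b": verdict.genome_b,
        "category": verdict.category,
        "degraded": verdict.degraded,
        "label": verdict.label,
        "n_scp": verdict.n_scp,
        "s_a": verdict.s_a,
        "s_b": verdict.s_b,
        "pair_ratio": verdict.pair_ratio,
        "mean_region_len": verdict.mean_region_len,
        "n_regions": verdict.n_regions,
        "exclusivities": [list(e) for e in verdict.exclusivities],
        "max_exclusivity": None
        if math.isnan(verdict.max_exclusivity)
        else verdict.max_exclusivity,
        "pairs": [asdict(pc) for pc in verdict.pairs],
        "regions": [asdict(r) for r in verdict.regions],
    }
    return d


def verdict_from_dict(d: dict) -> SyntenyVerdict:
    """Inverse of :func:`verdict_to_dict`."""
    return SyntenyVerdict(
        genome_a=d["genome_a"],
        genome_b=d["genome_b"],
        category=d["category"],
        degraded=d["degraded"],
        n_scp=d["n_scp"],
        s_a=d["s_a"],
        s_b=d["s_b"],
        pair_ratio=d["pair_ratio"],
        mean_region_len=d["mean_region_len"],
        n_regions=d["n_regions"],
        exclusivities=tuple((a, b, v) for a, b, v in d["exclusivities"]),
        max_exclusivity=math.nan
        if d["max_exclusivity"] is None
        else d["max_exclusivity"],
        pairs=tuple(PairConservation(**pc) for pc in d["pairs"]),
        regions=tuple(colinearity.SyntenicRegion(**r) for r in d["regions"]),
    )


def report(verdict: SyntenyVerdict, fmt: str = "text") -> str:
    """Serialize a verdict as ``json``, ``tsv`` or human-readable ``text``."""
    if fmt == "json":
        return json.dumps(verdict_to_dict(verdict), indent=2)
    if fmt == "tsv":
        d = verdict_to_dict(verdict)
        cols = [
            "genome_a", "genome_b", "label", "category", "degraded",
            "n_scp", "s_a", "s_b", "pair_ratio", "mean_region_len",
            "n_regions", "max_exclusivity",
        ]
        header = "\t".join(cols)
        row = "\t".join(str(d[c]) for c in cols)
        return f"{header}\n{row}\n"
    if fmt == "text":
        lines = [
            f"Genome pair: {verdict.genome_a} vs {verdict.genome_b}",
            f"Synteny: {verdict.label}",
            f"  significantly conserved pairs (N_scp): {verdict.n_scp}",
            f"  retained sequences: S_a={verdict.s_a}, S_b={verdict.s_b}",
            f"  significant pair ratio: {verdict.pair_ratio:.4f}",
            f"  mean syntenic region length: {verdict.mean_region_len:.1f} bp"
            f" ({verdict.n_regions} regions)",
            f"  max pair exclusivity: {verdict.max_exclusivity:.4f}"
            if not math.isnan(verdict.max_exclusivity)
            else "  max pair exclusivity: n/a",
        ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
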
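"""Shared fixtures: small hand-built comparisons and cached scenario runs."""

from __future__ import annotations

import time

import pytest

from mesoscan import GenomeIndex, Match, MatchSet, classify, scenario

N_SCENARIO_SEEDS = 20
SCENARIO_NAMES = ("colinear", "inversion_only", "translocation_rich", "unrelated")


def make_index(label: str, *seqs: tuple[str, int]) -> GenomeIndex:
    return GenomeIndex(label, tuple(seqs))


def make_match(ref, qry, rs, re_, qs, qe, pct=90.0, orientation="parallel") -> Match:
    return Match(ref, qry, rs, re_, qs, qe, pct, orientation)


@pytest.fixture(scope="session")
def scenario_runs():
    """Classify every scenario over a fixed panel of seeds, once per session.

    Returns ``{name: {"verdicts": [...], "extras": [...], "elapsed": s}}``
    where each extras entry records per-seed diagnostics used by several
    tests (ground-truth partner agreement, counts of long regions).
    """
    out = {}
    for name in SCENARIO_NAMES:
        verdicts = []
        extras = []
        t0 = time.time()
        for seed in range(N_SCENARIO_SEEDS):
            matchset, truth = scenario(name, seed)
            verdict = classify(matchset)
            verdicts.append(verdict)
            extras.append(
                {
                    "all_single_partner": all(
                        m.ref_id == m.qry_id for m in matchset.matches
                    ),
                    "n_matches": len(matchset.matches),
                    "n_long_regions": sum(
                        1 for r in verdict.regions if r.length >= 20_000
                    ),
                    "intended": truth.intended_class,
                }
            )
        out[name] = {
            "verdicts": verdicts,
            "extras": extras,
            "elapsed": time.time() - t0,
        }
    return out


@pytest.fixture(scope="session")
def colinear_matchset():
    """One cached colinear-scenario comparison for threshold-path tests."""
    matchset, _ = scenario("colinear", 0)
    return matchset
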
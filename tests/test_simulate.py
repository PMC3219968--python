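"""Ancestor construction, evolution operators, truth-log replay, projection."""

from __future__ import annotations

import numpy as np
import pytest

from mesoscan import SimConfig, genome_pair, make_ancestor, project_matches, scenario
from mesoscan.classification import pair_exclusivities
from mesoscan.simulate import Gene, Genome, evolve, layout, replay


def tiny_config(**kw) -> SimConfig:
    defaults = dict(n_chromosomes=1, genes_per_chromosome=3, gene_len=1_000, intergenic_len=500)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMakeAncestor:
    def test_layout_spacing_is_exact(self):
        ancestor = make_ancestor(tiny_config(seed=0))
        _, coords = layout(ancestor, 500)
        spans = [coords[f"c01g{i:04d}"][1:] for i in (1, 2, 3)]
        assert spans == [(1, 1_000), (1_501, 2_500), (3_001, 4_000)]

    def test_same_seed_gives_identical_maps(self):
        cfg = tiny_config(seed=11, gene_len_jitter=0.3, chromosome_len_jitter=0.2)
        assert make_ancestor(cfg) == make_ancestor(cfg)

    def test_zero_jitter_gives_equal_chromosome_lengths(self):
        cfg = SimConfig(seed=1, n_chromosomes=5, genes_per_chromosome=10)
        index, _ = layout(make_ancestor(cfg), cfg.intergenic_len)
        lengths = {l for _, l in index.sequences}
        assert len(lengths) == 1

    def test_invalid_config_is_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=0)


class TestEvolve:
    def test_zero_rates_reproduce_the_ancestor(self):
        cfg = SimConfig(seed=2, n_chromosomes=3, genes_per_chromosome=20)
        ancestor = make_ancestor(cfg, np.random.default_rng(2))
        derived, log = evolve(ancestor, cfg, np.random.default_rng(3), "A")
        assert derived.chromosomes == ancestor.chromosomes
        assert log.operations == ()

    def test_inversion_reverses_segment_and_flips_strands(self):
        genome = Genome(
            "g",
            {"chr1": [Gene(f"g{i}", 100, 1) for i in range(1, 5)]},
        )
        from mesoscan.simulate import _apply_operation

        _apply_operation(
            genome, {"kind": "inversion", "chromosome": "chr1", "start": 1, "end": 2}
        )
        assert [(g.gid, g.strand) for g in genome.chromosomes["chr1"]] == [
            ("g1", 1),
            ("g3", -1),
            ("g2", -1),
            ("g4", 1),
        ]

    def test_inversions_never_move_genes_between_chromosomes(self):
        cfg = SimConfig(seed=5, n_chromosomes=10, genes_per_chromosome=30, n_inversions=10)
        ancestor = make_ancestor(cfg, np.random.default_rng(5))
        derived, log = evolve(ancestor, cfg, np.random.default_rng(6), "A")
        assert derived.gene_chromosome() == ancestor.gene_chromosome()
        # and the log replays to exactly the same genome
        assert replay(ancestor, log).chromosomes == derived.chromosomes

    def test_truth_log_replay_reproduces_a_heavily_evolved_genome(self):
        cfg = SimConfig(
            seed=9,
            n_chromosomes=6,
            genes_per_chromosome=50,
            n_inversions=40,
            n_translocations=15,
            gene_loss_frac=0.2,
            n_private_chromosomes=2,
        )
        ancestor = make_ancestor(cfg, np.random.default_rng(9))
        derived, log = evolve(ancestor, cfg, np.random.default_rng(10), "B")
        assert replay(ancestor, log).chromosomes == derived.chromosomes

    def test_gene_loss_halves_the_match_count_within_three_sd(self):
        cfg = SimConfig(seed=21, n_chromosomes=4, genes_per_chromosome=100)
        rng = np.random.default_rng(21)
        ancestor = make_ancestor(cfg, rng)
        lossy = SimConfig(
            seed=21, n_chromosomes=4, genes_per_chromosome=100, gene_loss_frac=0.5
        )
        derived_a, _ = evolve(ancestor, cfg, rng, "A")  # no loss
        derived_b, _ = evolve(ancestor, lossy, rng, "B")  # 50% loss
        ms = project_matches(derived_a, derived_b, cfg)
        n = 400
        expected = n * 0.5
        sd = (n * 0.25) ** 0.5
        assert abs(len(ms.matches) - expected) <= 3 * sd


class TestProjection:
    def test_identity_pair_forms_exact_diagonals(self):
        cfg = SimConfig(seed=4, n_chromosomes=2, genes_per_chromosome=10)
        rng = np.random.default_rng(4)
        ancestor = make_ancestor(cfg, rng)
        a, _ = evolve(ancestor, cfg, rng, "A")
        b, _ = evolve(ancestor, cfg, rng, "B")
        ms = project_matches(a, b, cfg)
        assert len(ms.matches) == 20
        for m in ms.matches:
            assert m.ref_id == m.qry_id
            assert m.ref_span == m.qry_span
            assert m.orientation == "parallel"

    def test_private_chromosomes_emit_no_matches(self):
        cfg = SimConfig(
            seed=8, n_chromosomes=4, genes_per_chromosome=10, n_private_chromosomes=2
        )
        rng = np.random.default_rng(8)
        ancestor = make_ancestor(cfg, rng)
        a, _ = evolve(ancestor, cfg, rng, "A")
        b, _ = evolve(ancestor, cfg, rng, "B")
        ms = project_matches(a, b, cfg)
        touched = {m.ref_id for m in ms.matches} | {m.qry_id for m in ms.matches}
        assert touched == {"chr1", "chr2"}

    def test_inversion_only_matches_stay_inside_ancestral_boxes(self):
        cfg = SimConfig(
            seed=13, n_chromosomes=4, genes_per_chromosome=50, n_inversions=100
        )
        rng = np.random.default_rng(13)
        ancestor = make_ancestor(cfg, rng)
        a, _ = evolve(ancestor, cfg, rng, "A")
        b, _ = evolve(ancestor, cfg, rng, "B")
        ms = project_matches(a, b, cfg)
        assert ms.matches
        assert all(m.ref_id == m.qry_id for m in ms.matches)
        orientations = {m.orientation for m in ms.matches}
        assert orientations == {"parallel", "antiparallel"}


class TestScenarios:
    def test_same_seed_gives_identical_matchsets(self):
        ms1, _ = scenario("colinear", 3)
        ms2, _ = scenario("colinear", 3)
        assert ms1 == ms2

    def test_unknown_scenario_name_is_an_error(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("macro_only", 0)

    def test_scenarios_carry_their_intended_class(self):
        _, truth = scenario("unrelated", 0)
        assert truth.intended_class == "none"
        _, truth = scenario("inversion_only", 0)
        assert truth.intended_class == "mesosynteny"

    def test_more_translocations_lower_exclusivity_in_expectation(self):
        def mean_max_exclusivity(n_translocations: int) -> float:
            cfg = SimConfig(
                n_chromosomes=6,
                genes_per_chromosome=100,
                n_translocations=n_translocations,
            )
            values = []
            for seed in range(20):
                ms, _ = genome_pair(cfg, seed)
                pairs = sorted(ms.by_pair())
                excl = [v for _, _, v in pair_exclusivities(ms, pairs)]
                values.append(max(excl))
            return float(np.mean(values))

        few, many = mean_max_exclusivity(4), mean_max_exclusivity(40)
        assert many < few
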
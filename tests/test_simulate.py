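"""Synthetic-experiment generator: growth, placement, and observation noise."""

import math

import numpy as np
import pytest

from otoclone.clonecall import call_clones, false_positive_rate
from otoclone.simulate import (
    SimulationConfig,
    max_divisions,
    noise_free_config,
    simulate_clone,
    simulate_ear,
    simulate_experiment,
    simulate_picks,
)


class TestConfig:
    def test_defaults_encode_study_conditions(self):
        cfg = SimulationConfig()
        assert cfg.infection_window == 24.0
        assert cfg.cycle_time_range == (12.0, 18.0)
        assert cfg.early_deadline == 48.0 and cfg.late_deadline == 96.0
        assert 0.5 <= cfg.p_early_exit <= 0.7
        assert 12.0 <= cfg.section_thickness <= 14.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(infection_probability=1.5)

    def test_section_thickness_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(section_thickness=20.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, infection_probability=0.02)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestMaxDivisions:
    @pytest.mark.parametrize(
        "integration,cycle,deadline,expected",
        [
            (24, 18, 96, 4),  # 18 h cycles to E15.5: the canonical upper bound
            (24, 12, 96, 6),  # 12 h cycles permit six rounds over the same span
            (24, 18, 20, 0),  # deadline before integration
            (0, 12, 48, 4),
        ],
    )
    def test_floor_formula(self, integration, cycle, deadline, expected):
        assert max_divisions(integration, cycle, deadline) == expected

    def test_positive_cycle_required(self):
        with pytest.raises(ValueError):
            max_divisions(0, 0, 48)


class TestCloneGrowth:
    def test_deterministic_cycle_doubles_to_2_pow_divisions(self, rng):
        cfg = SimulationConfig(cycle_time_range=(18.0, 18.0))
        # founder infected at +6 h divides one full cycle later -> integration +24 h
        integration, deadline, n = simulate_clone(6.0, cfg, rng, deadline=96.0)
        expected = 2 ** max_divisions(integration, 18.0, 96.0)
        assert n == expected

    @pytest.mark.parametrize("cycle", [12.0, 14.0, 18.0])
    def test_deterministic_growth_over_many_draws(self, cycle):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(cycle_time_range=(cycle, cycle))
        for _ in range(200):
            integration, deadline, n = simulate_clone(
                rng.uniform(0, 24), cfg, rng
            )
            assert n == 2 ** max_divisions(integration, cycle, deadline)

    def test_deadline_at_integration_gives_single_cell(self, rng):
        cfg = SimulationConfig()
        _, _, n = simulate_clone(10.0, cfg, rng, deadline=10.0)
        assert n == 1

    def test_earlier_deadlines_increase_single_cell_fraction(self):
        # Monte-Carlo monotonicity oracle over a sweep of deadline shifts
        fractions = []
        for shift in (0.0, -12.0, -24.0, -36.0):
            rng = np.random.default_rng(11)
            cfg = SimulationConfig(
                early_deadline=48.0 + shift, late_deadline=96.0 + shift
            )
            sizes = [
                simulate_clone(rng.uniform(0, 24), cfg, rng)[2]
                for _ in range(10_000)
            ]
            fractions.append(np.mean([s == 1 for s in sizes]))
        assert fractions == sorted(fractions)


class TestSimulateEar:
    def test_zero_infection_probability_gives_empty_ear(self):
        cfg = SimulationConfig(infection_probability=0.0)
        assert simulate_ear(cfg, 1).clones == []

    def test_coinfection_probability_one_gives_multitag_founders(self):
        cfg = SimulationConfig(coinfection_probability=1.0, n_progenitors=100)
        ear = simulate_ear(cfg, 2)
        assert ear.clones
        assert all(len(c.tags) >= 2 for c in ear.clones)

    def test_seed_determinism(self):
        cfg = SimulationConfig()
        assert simulate_ear(cfg, 7).to_dict() == simulate_ear(cfg, 7).to_dict()

    def test_conservation_and_disjointness(self):
        cfg = SimulationConfig(n_progenitors=300)
        ear = simulate_ear(cfg, 3)
        assert ear.n_labeled_cells == sum(c.size for c in ear.clones)
        all_ids = [cell.cell_id for c in ear.clones for cell in c.cells]
        assert len(all_ids) == len(set(all_ids))
        for clone in ear.clones:
            assert len({cell.tags for cell in clone.cells}) == 1

    def test_small_realized_library_collides(self):
        # with 16 realized tags and dozens of founders, repeats are near-certain
        cfg = SimulationConfig(
            realized_library_size=16,
            n_progenitors=500,
            infection_probability=0.1,
        )
        ear = simulate_ear(cfg, 4)
        assert ear.tag_collisions

    def test_coinfection_fraction_converges(self):
        cfg = SimulationConfig(
            coinfection_probability=0.3,
            n_progenitors=20_000,
            infection_probability=0.6,
        )
        ear = simulate_ear(cfg, 6)
        multi = np.mean([len(c.tags) >= 2 for c in ear.clones])
        n = len(ear.clones)
        sd = math.sqrt(0.3 * 0.7 / n)
        assert abs(multi - 0.3) < 4 * sd


class TestSimulatePicks:
    def test_zero_fpr_no_negative_products(self):
        cfg = SimulationConfig(negative_fpr=0.0, negative_pick_fraction=0.5)
        ear = simulate_ear(cfg, 8)
        picks = simulate_picks(ear, cfg, 9)
        negatives = [p for p in picks if p.plap_status == "negative"]
        assert negatives
        assert all(p.outcome == "no_product" for p in negatives)

    def test_full_contamination_makes_all_positives_multitag(self):
        cfg = SimulationConfig(
            contamination_rate=1.0,
            coinfection_probability=0.0,
            pick_pcr_success=1.0,
            silent_fraction=0.0,
        )
        ear = simulate_ear(cfg, 10)
        picks = simulate_picks(ear, cfg, 11)
        positives = [p for p in picks if p.plap_status == "positive"]
        assert positives
        assert all(p.outcome == "multiple_tags" for p in positives)

    def test_pcr_success_rate_within_binomial_error(self):
        cfg = SimulationConfig(
            pick_pcr_success=0.5,
            n_progenitors=2000,
            infection_probability=0.2,
            silent_fraction=0.0,
            negative_pick_fraction=0.0,
        )
        ear = simulate_ear(cfg, 12)
        picks = simulate_picks(ear, cfg, 13)
        n = len(picks)
        assert n > 1000
        frac = np.mean([p.outcome != "no_product" for p in picks])
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_fpr_estimator_within_binomial_error(self):
        cfg = SimulationConfig(
            negative_fpr=0.05,
            negative_pick_fraction=1.0,
            n_progenitors=2000,
            infection_probability=0.3,
        )
        ear = simulate_ear(cfg, 14)
        picks = simulate_picks(ear, cfg, 15)
        n_neg = sum(p.plap_status == "negative" for p in picks)
        assert n_neg >= 1000
        estimate = false_positive_rate(picks)
        assert abs(estimate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_neg)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noise_free_clone_calling_recovers_ground_truth(self, seed):
        cfg = noise_free_config()
        ear = simulate_ear(cfg, seed)
        picks = simulate_picks(ear, cfg, seed + 1000)
        assert ear.tag_collisions == []
        called = call_clones(picks)
        truth = sorted((c.tags[0], c.size) for c in ear.clones)
        assert sorted((c.tag, c.size) for c in called) == truth

    def test_multi_ear_experiment_deterministic(self):
        cfg = noise_free_config()
        ears_a, picks_a = simulate_experiment(cfg, n_ears=2, seed=21)
        ears_b, picks_b = simulate_experiment(cfg, n_ears=2, seed=21)
        assert picks_a == picks_b
        assert [e.to_dict() for e in ears_a] == [e.to_dict() for e in ears_b]
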
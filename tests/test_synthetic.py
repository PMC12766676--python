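"""Layout presets and the strategy-mixture experiment generator."""

import dataclasses

import numpy as np
import pytest

from sunburst import (NullPolicy, SimConfig, StrategyMix, ValidationError,
                      analytic_null, categorize, closed_form_null,
                      make_layout, simulate_dataset, simulate_experiment,
                      to_percentages)
from sunburst.synthetic import load_sim_configs


class TestStrategyMix:
    def test_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            StrategyMix(p_shortcut=0.5, p_uniform=0.6)

    def test_no_negative_probabilities(self):
        with pytest.raises(ValidationError):
            StrategyMix(p_shortcut=-0.1, p_uniform=1.1)

    def test_dominant_helper(self):
        mix = StrategyMix.dominant("adjacent", 0.8)
        assert mix.p_adjacent == 0.8
        assert mix.p_uniform == pytest.approx(0.2)


class TestLayouts:
    def test_tolman_preset_geometry(self):
        layout = make_layout("tolman")
        scorable = [p for p in layout if not p.is_excluded]
        assert len(layout) == 18 and len(scorable) == 12
        assert [p.index for p in layout if p.is_excluded] == list(
            range(13, 19))
        assert [p.index for p in layout if p.is_shortcut] == [6]
        assert sum(p.is_adjacent for p in scorable) == 2
        assert sum(p.is_outer for p in scorable) == 2

    def test_enclosed_chance_level(self):
        layout = make_layout("enclosed")
        k = sum(not p.is_excluded for p in layout)
        mu, _ = closed_form_null(16, k)
        assert mu == 12.5

    def test_overlapping_shortcut_adjacent_preset(self):
        layout = make_layout("harley")
        overlap = [p for p in layout if p.is_shortcut and p.is_adjacent]
        assert len(overlap) == 1 and overlap[0].index == 4

    def test_incompatible_k_rejected(self):
        with pytest.raises(ValidationError):
            make_layout("tolman", K=12)
        with pytest.raises(ValidationError):
            make_layout("rhombus")


class TestSimulateExperiment:
    def config(self, mix, layout="tolman", N=50, seed=0, **kwargs):
        return SimConfig(experiment_id="e", layout=make_layout(layout),
                         N=N, seed=seed, mix=mix, **kwargs)

    def test_pure_beacon_lands_on_cued_path(self):
        cfg = self.config(StrategyMix.pure("beacon"), layout="circular",
                          N=30)
        rec = simulate_experiment(cfg)
        cued = next(p for p in rec.paths if p.is_cued)
        assert rec.count_of(cued.index) == 30

    def test_beacon_without_cue_falls_back_to_uniform(self):
        cfg = self.config(StrategyMix.pure("beacon"), layout="tolman", N=40)
        rec = simulate_experiment(cfg)  # no error; spread over arms
        assert rec.n_scored == 40

    def test_pure_uniform_approaches_chance_share(self):
        cfg = self.config(StrategyMix.pure("uniform"), N=20000, seed=4)
        rec = simulate_experiment(cfg)
        pct = to_percentages(rec)
        mu, _ = closed_form_null(rec.n_scored, rec.k_scorable)
        se = 100 * np.sqrt((1 / 12) * (11 / 12) / rec.n_scored)
        # 4 SE: the bound must hold jointly across all 12 arms
        for v in pct.values():
            assert abs(v - mu) < 4 * se

    def test_outer_reward_weighting(self):
        cfg = self.config(StrategyMix.pure("outer"), N=5000, seed=1,
                          outer_reward_weight=0.8)
        rec = simulate_experiment(cfg)
        reward = next(p for p in rec.paths if p.is_outer and p.reward_side)
        other = next(p for p in rec.paths
                     if p.is_outer and not p.reward_side
                     and not p.is_excluded)
        share = rec.count_of(reward.index) / rec.n_scored
        assert share == pytest.approx(0.8, abs=0.03)
        assert rec.count_of(reward.index) + rec.count_of(other.index) == 5000

    def test_smeared_shortcut_spreads_to_neighbours(self):
        cfg = self.config(StrategyMix.pure("shortcut"), N=5000, seed=2,
                          shortcut_smear=0.5)
        rec = simulate_experiment(cfg)
        assert rec.count_of(6) > rec.count_of(5) > rec.count_of(3)
        assert rec.count_of(6) < 5000  # graded, not peaked

    def test_no_choice_subjects_recorded_outside_counts(self):
        cfg = self.config(StrategyMix.pure("uniform"), N=200, seed=3,
                          p_no_choice=0.25)
        rec = simulate_experiment(cfg)
        assert rec.n_no_choice > 0
        assert rec.n_scored + rec.n_no_choice == 200

    def test_determinism_under_seed(self):
        cfg = self.config(StrategyMix.dominant("shortcut", 0.5), seed=99)
        assert simulate_experiment(cfg) == simulate_experiment(cfg)

    def test_seed_changes_counts_not_layout(self):
        a = simulate_experiment(self.config(StrategyMix.pure("uniform"),
                                            seed=1))
        b = simulate_experiment(self.config(StrategyMix.pure("uniform"),
                                            seed=2))
        assert a.paths == b.paths
        assert a.counts != b.counts

    def test_strategy_without_target_path_errors(self):
        # no outer arms in the enclosed preset and no fallback
        cfg = self.config(StrategyMix.pure("outer"), layout="enclosed")
        with pytest.raises(ValidationError, match="no matching path"):
            simulate_experiment(cfg)


class TestSimulateDataset:
    def test_one_record_per_config(self):
        configs = [SimConfig(experiment_id=f"e{i}",
                             layout=make_layout("tolman"), N=30, seed=i,
                             mix=StrategyMix.pure("uniform"))
                   for i in range(5)]
        ds = simulate_dataset(configs)
        assert len(ds) == 5

    def test_empty_config_list_errors(self):
        with pytest.raises(ValidationError):
            simulate_dataset([])

    def test_duplicate_ids_rejected(self):
        cfg = SimConfig(experiment_id="dup", layout=make_layout("tolman"),
                        N=10, seed=0, mix=StrategyMix.pure("uniform"))
        with pytest.raises(ValidationError, match="duplicate"):
            simulate_dataset([cfg, dataclasses.replace(cfg, seed=1)])

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_file = tmp_path / "gen.yaml"
        cfg_file.write_text(
            "experiments:\n"
            "  - experiment_id: a\n"
            "    preset: tolman\n"
            "    N: 25\n"
            "    seed: 7\n"
            "    mix: {adjacent: 0.6, uniform: 0.4}\n"
            "  - experiment_id: b\n"
            "    preset: enclosed\n"
            "    N: 16\n"
            "    seed: 8\n"
            "    mix: {uniform: 1.0}\n")
        configs = load_sim_configs(cfg_file)
        assert [c.experiment_id for c in configs] == ["a", "b"]
        assert configs[0].mix.p_adjacent == 0.6
        ds = simulate_dataset(configs)
        assert ds.records[1].k_scorable == 8

    def test_unknown_yaml_key_rejected(self, tmp_path):
        cfg_file = tmp_path / "gen.yaml"
        cfg_file.write_text(
            "experiments:\n"
            "  - experiment_id: a\n"
            "    preset: tolman\n"
            "    N: 25\n"
            "    seed: 7\n"
            "    turbo: yes\n"
            "    mix: {uniform: 1.0}\n")
        with pytest.raises(ValidationError, match="unknown keys"):
            load_sim_configs(cfg_file)


class TestParameterRecovery:
    @pytest.mark.parametrize("strategy, expected_category", [
        ("shortcut", "shortcut"), ("adjacent", "adjacent"),
        ("outer", "outer"),
    ])
    def test_dominant_strategy_recovered_at_large_n(self, strategy,
                                                    expected_category):
        """The argmax-probability strategy wins the categorization as N
        grows, for every preset carrying the targeted role."""
        hits = 0
        seeds = range(50)
        for seed in seeds:
            cfg = SimConfig(
                experiment_id="e", layout=make_layout("tolman"), N=10000,
                seed=seed, mix=StrategyMix.dominant(strategy, 0.5))
            rec = simulate_experiment(cfg)
            null = analytic_null(rec.n_scored, rec.k_scorable)
            if categorize(rec, null).category == expected_category:
                hits += 1
        assert hits == len(list(seeds))

    def test_prevalence_recovery_within_binomial_tolerance(self):
        """A generator-built dataset reproduces its intended category
        frequencies within 3 binomial standard errors."""
        spec = {"shortcut": 8, "adjacent": 15, "uniform": 12, "other": 6,
                "beacon": 3, "outer": 3}
        configs, i = [], 0
        for strategy, n_exp in spec.items():
            for _ in range(n_exp):
                layout = "circular" if strategy == "beacon" else "tolman"
                configs.append(SimConfig(
                    experiment_id=f"e{i}", layout=make_layout(layout),
                    N=50, seed=1000 + i,
                    mix=(StrategyMix.pure("uniform")
                         if strategy == "uniform"
                         else StrategyMix.dominant(strategy, 0.7))))
                i += 1
        ds = simulate_dataset(configs)
        from sunburst import prevalence
        prev = prevalence(ds, NullPolicy(method="analytic"))
        total = sum(spec.values())
        intended = {"shortcut": spec["shortcut"], "adjacent": spec["adjacent"],
                    "no_pref": spec["uniform"], "other": spec["other"],
                    "cued": spec["beacon"], "outer": spec["outer"]}
        for category, count in intended.items():
            p = count / total
            se = 100 * np.sqrt(p * (1 - p) / total)
            assert abs(prev[category] - 100 * p) <= 3 * se, category
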
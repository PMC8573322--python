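import math

import numpy as np
import pytest
from scipy.stats import chisquare

import searchshift as ss
from searchshift import AgentSpec, PipelineConfig, RTParams
from searchshift.synth import _build_agents


class TestSimulateChoice:
    def test_zero_sensitivity_is_a_fair_coin(self, exp2_pairs, rng):
        agent = AgentSpec("a", "EV", phi=0.0)
        draws = [ss.simulate_choice(agent, exp2_pairs[0], rng) for _ in range(4000)]
        assert abs(np.mean([d == "A" for d in draws]) - 0.5) < 0.03

    def test_saturated_sensitivity_is_deterministic(self, exp2_pairs, rng):
        # find a pair with a sizeable EV gap; phi=10 saturates the softmax
        pair = max(exp2_pairs, key=lambda p: abs(p.ev_a - p.ev_b))
        agent = AgentSpec("a", "EV", phi=10.0)
        draws = {ss.simulate_choice(agent, pair, rng) for _ in range(500)}
        assert draws == {pair.ev_favored()}

    def test_maximax_agent_takes_higher_outcome_on_conflict_pairs(self, exp2_pairs, rng):
        agent = AgentSpec("a", "MAXIMAX", phi=10.0)
        for pair in exp2_pairs[:10]:
            assert ss.simulate_choice(agent, pair, rng) == pair.maximax_favored()

    @pytest.mark.parametrize("phi", [0.1, 0.5])
    def test_choice_frequencies_match_softmax_law(self, exp2_pairs, phi):
        """Chi-square goodness of fit on 10^4 draws per (phi, pair) cell."""
        rng = np.random.default_rng(123)
        agent = AgentSpec("a", "EV", phi=phi)
        for pair in (exp2_pairs[0], exp2_pairs[7]):
            p_a = ss.choice_probability(ss.ev_value(pair.option_a), ss.ev_value(pair.option_b), phi)
            n = 10_000
            k = sum(ss.simulate_choice(agent, pair, rng) == "A" for _ in range(n))
            stat, p = chisquare([k, n - k], [n * p_a, n * (1 - p_a)])
            assert p > 0.01


class TestSimulateFixations:
    def test_pure_alternative_bias_never_switches_option(self, rng):
        seq = ss.simulate_fixations("ALT", 1.0, 0.0, 10, rng, start="A_PROB")
        assert seq.aois() == ["A_PROB", "A_OUT"] * 5 + ["A_PROB"]
        counts = ss.count_transitions(seq)
        assert counts.r_dim == 0 and counts.r_alt == 10

    def test_pure_dimension_bias_never_switches_dimension(self, rng):
        seq = ss.simulate_fixations("DIM", 1.0, 0.0, 10, rng, start="A_PROB")
        counts = ss.count_transitions(seq)
        assert counts.r_alt == 0 and counts.r_dim == 10

    def test_unbiased_walk_splits_evenly_in_the_long_run(self):
        rng = np.random.default_rng(9)
        seq = ss.simulate_fixations("ALT", 0.5, 0.5, 10_000, rng)
        c = ss.count_transitions(seq)
        assert abs(c.r_alt / (c.r_alt + c.r_dim) - 0.5) < 0.02

    def test_durations_truncated_above_filter_threshold(self, rng):
        seq = ss.simulate_fixations("ALT", 0.5, 0.5, 200, rng)
        assert all(f.duration_ms >= 60.0 for f in seq.fixations)

    def test_short_fixation_injection_exercises_filter_path(self):
        rng = np.random.default_rng(10)
        seq = ss.simulate_fixations("ALT", 0.5, 0.5, 200, rng, p_short=0.3)
        short = [f for f in seq.fixations if f.duration_ms < 50.0]
        assert short  # some sub-filter fixations present
        kept = ss.filter_fixations(seq)
        assert len(kept.fixations) == len(seq.fixations) - len(short)


class TestSimulateRT:
    @staticmethod
    def _agent(**kw):
        defaults = dict(
            baseline_log_s=math.log(4.0),
            task_effect_log_s=0.0,
            ev_slope_per_yuan=0.0,
            noise_sd_log_s=1e-12,
        )
        defaults.update(kw)
        return AgentSpec("a", "EV", rt_params=RTParams(**defaults))

    def test_closed_form_at_zero_noise(self, exp2_pairs, rng):
        rt = ss.simulate_rt(self._agent(), "DIM", exp2_pairs[0], rng)
        assert rt == pytest.approx(4.0, abs=1e-6)

    def test_task_effect_lengthens_alternativewise_trials(self, exp2_pairs, rng):
        agent = self._agent(task_effect_log_s=0.16)
        alt = ss.simulate_rt(agent, "ALT", exp2_pairs[0], rng)
        dim = ss.simulate_rt(agent, "DIM", exp2_pairs[0], rng)
        assert alt > dim
        assert math.log(alt) - math.log(dim) == pytest.approx(0.16, abs=1e-6)

    def test_larger_ev_gap_speeds_decisions(self, exp2_pairs, rng):
        agent = self._agent(ev_slope_per_yuan=0.006)
        ordered = sorted(exp2_pairs, key=lambda p: abs(p.ev_a - p.ev_b))
        slow = ss.simulate_rt(agent, "DIM", ordered[0], rng)
        fast = ss.simulate_rt(agent, "DIM", ordered[-1], rng)
        assert fast < slow


class TestSimulateExperiment:
    def test_within_subject_design_shape_and_counterbalance(self, small_experiment):
        cfg, trials, fixations, pairs = small_experiment
        assert len(trials) == cfg.n_participants * 2 * cfg.n_pairs
        per = trials.groupby("participant_id")["task"].nunique()
        assert (per == 2).all()
        orders = trials.groupby("participant_id")["task_order"].first()
        assert (orders == "ALT_FIRST").sum() == cfg.n_participants // 2
        assert (trials["rt_s"] > 0).all()

    def test_seeded_runs_are_byte_identical(self):
        cfg = PipelineConfig(seed=21, n_participants=4, n_pairs=6)
        t1, f1, _ = ss.simulate_experiment(cfg)
        t2, f2, _ = ss.simulate_experiment(cfg)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)
        assert f1.to_csv(index=False) == f2.to_csv(index=False)

    def test_saturated_ev_population_is_fully_ev_consistent(self):
        cfg = PipelineConfig(
            seed=5, n_participants=4, n_pairs=15,
            agent_mixture={"EV": 1.0, "MAXIMAX": 0.0, "GUESS": 0.0},
            phi=ss.PhiSpec(kind="fixed", value=10.0),
            search_coupling=0.0,
        )
        trials, _, pairs = ss.simulate_experiment(cfg)
        trials = ss.inference.add_ev_consistent(trials, pairs)
        assert trials["ev_consistent"].mean() > 0.99

    def test_mixture_apportionment_is_largest_remainder(self):
        cfg = PipelineConfig(
            n_participants=10, agent_mixture={"EV": 0.5, "MAXIMAX": 0.3, "GUESS": 0.2}
        )
        agents = _build_agents(cfg, np.random.default_rng(0))
        strategies = [a.strategy for a in agents]
        assert strategies.count("EV") == 5
        assert strategies.count("MAXIMAX") == 3
        assert strategies.count("GUESS") == 2

    def test_task_conditioned_biases_produce_opposite_sm_signs(self):
        cfg = PipelineConfig(seed=13, n_participants=6, n_pairs=10)
        _, fixations, _ = ss.simulate_experiment(cfg)
        sm = ss.sm_per_trial(fixations)
        assert sm.loc[sm["task"] == "ALT", "sm"].mean() > 0
        assert sm.loc[sm["task"] == "DIM", "sm"].mean() < 0
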
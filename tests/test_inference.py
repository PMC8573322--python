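import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import searchshift as ss
from searchshift import PhiSpec, PipelineConfig, RTParams
from searchshift.exceptions import (
    DegenerateDataError,
    InsufficientClustersError,
    SeparationError,
)


def _simulate(cfg):
    trials, fixations, pairs = ss.simulate_experiment(cfg)
    trials = ss.inference.add_ev_consistent(trials, pairs)
    return trials, fixations, pairs


def _mediation_frame(cfg):
    trials, fixations, _ = _simulate(cfg)
    sm = ss.sm_per_trial(fixations)
    return trials.merge(
        sm[["participant_id", "task", "pair_id", "sm"]],
        on=["participant_id", "task", "pair_id"],
        how="left",
    )


class TestTwoProportionTest:
    def test_reconstructed_counts_give_printed_statistics(self):
        z, p = ss.compare_classification_proportions(49, 50, 44, 50)
        assert z == pytest.approx(1.96, abs=0.005)
        assert p == pytest.approx(0.025, abs=0.0005)
        z, p = ss.compare_classification_proportions(43, 45, 39, 45)
        assert z == pytest.approx(1.48, abs=0.005)
        assert p == pytest.approx(0.069, abs=0.0005)

    def test_identical_proportions_are_null(self):
        z, p = ss.compare_classification_proportions(30, 40, 15, 20)
        assert z == 0.0 and p == 0.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ss.compare_classification_proportions(5, 0, 1, 10)
        with pytest.raises(ValueError):
            ss.compare_classification_proportions(11, 10, 1, 10)


class TestChoiceModel:
    def test_constant_response_raises_separation(self, small_experiment):
        _, trials, _, _ = small_experiment
        df = trials.copy()
        df["ev_consistent"] = 1
        with pytest.raises(SeparationError):
            ss.fit_choice_model(df)

    def test_task_scaled_sensitivity_yields_positive_effect(self):
        cfg = PipelineConfig(
            seed=31, n_participants=16, n_pairs=20,
            phi_task_scale={"ALT": 1.0, "DIM": 0.2},
            search_coupling=0.0,
        )
        trials, _, _ = _simulate(cfg)
        res = ss.fit_choice_model(trials)
        assert res.b > 0
        assert res.ci95[0] > 0
        assert res.odds_ratio == pytest.approx(np.exp(res.b), abs=1e-9)
        assert res.ci95[0] < res.ci95[1]

    def test_null_task_effect_ci_coverage(self):
        """Under no true task effect the 95% CI should cover 0 in >=93/100 runs."""
        cover = 0
        for rep in range(100):
            cfg = PipelineConfig(
                seed=5000 + rep, n_participants=20, n_pairs=20,
                bias_alt=0.5, bias_dim=0.5, search_coupling=0.0,
                phi=PhiSpec(kind="lognormal", mu=np.log(0.3), sigma=0.5),
                phi_task_scale={"ALT": 1.0, "DIM": 1.0},
                agent_mixture={"EV": 0.8, "MAXIMAX": 0.1, "GUESS": 0.1},
            )
            trials, _, _ = _simulate(cfg)
            res = ss.fit_choice_model(trials)
            if res.ci95[0] <= 0 <= res.ci95[1]:
                cover += 1
        assert cover >= 93


class TestRTModel:
    def test_recovers_generative_coefficients(self):
        """Mean recovered task and EV-gap slopes near truth over 30 replicates."""
        b_task, b_ev = [], []
        for rep in range(30):
            cfg = PipelineConfig(
                seed=7000 + rep, n_participants=20, n_pairs=20,
                rt_params=RTParams(task_effect_log_s=0.16, ev_slope_per_yuan=0.006),
            )
            trials, _, pairs = _simulate(cfg)
            res = ss.fit_rt_model(trials, pairs)
            b_task.append(res["task"].b)
            b_ev.append(res["ev_diff"].b)
        assert np.mean(b_task) == pytest.approx(0.16, abs=0.02)
        assert np.mean(b_ev) == pytest.approx(-0.006, abs=0.002)

    def test_null_effects_give_near_zero_slopes(self):
        cfg = PipelineConfig(
            seed=77, n_participants=12, n_pairs=15,
            rt_params=RTParams(
                task_effect_log_s=0.0, ev_slope_per_yuan=0.0, noise_sd_log_s=0.01
            ),
        )
        trials, _, pairs = _simulate(cfg)
        res = ss.fit_rt_model(trials, pairs)
        assert abs(res["task"].b) < 0.01
        assert abs(res["ev_diff"].b) < 0.001
        assert abs(res["outcome_diff"].b) < 0.001

    def test_nonpositive_response_time_rejected(self, small_experiment):
        _, trials, _, pairs = small_experiment
        bad = trials.copy()
        bad.loc[bad.index[0], "rt_s"] = 0.0
        with pytest.raises(DegenerateDataError):
            ss.fit_rt_model(bad, pairs)

    def test_agrees_with_lme4_oracle(self, tmp_path):
        """Cross-check the crossed random-intercept fit against R's lmer."""
        cfg = PipelineConfig(seed=91, n_participants=15, n_pairs=15)
        trials, _, pairs = _simulate(cfg)
        res = ss.fit_rt_model(trials, pairs)

        by_id = {p.pair_id: p for p in pairs}
        df = trials.copy()
        df["ln_rt"] = np.log(df["rt_s"])
        df["task01"] = (df["task"] == "ALT").astype(int)
        df["ev_diff"] = [abs(by_id[i].ev_a - by_id[i].ev_b) for i in df["pair_id"]]
        df["outcome_diff"] = [
            abs(by_id[i].option_a.outcome - by_id[i].option_b.outcome)
            for i in df["pair_id"]
        ]
        csv = tmp_path / "trials.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(ln_rt ~ task01 + ev_diff + outcome_diff +
                      (1|participant_id) + (1|pair_id), data=d, REML=TRUE)
            fe <- fixef(m)
            cat(fe["task01"], fe["ev_diff"], fe["outcome_diff"], "\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        b_task_r, b_ev_r, b_out_r = map(float, out.stdout.split())
        assert res["task"].b == pytest.approx(b_task_r, abs=2e-3)
        assert res["ev_diff"].b == pytest.approx(b_ev_r, abs=2e-4)
        assert res["outcome_diff"].b == pytest.approx(b_out_r, abs=2e-4)


class TestMediation:
    def test_effect_decomposition_holds_exactly(self):
        for seed in (1, 2, 3):
            cfg = PipelineConfig(seed=seed, n_participants=10, n_pairs=12)
            med = ss.mediation_analysis(_mediation_frame(cfg), n_boot=0)
            assert med.ab == pytest.approx(med.a * med.b_path, abs=1e-9)
            assert med.c_total == pytest.approx(med.c_prime + med.ab, abs=1e-6)

    def test_seeded_bootstrap_is_reproducible(self):
        cfg = PipelineConfig(seed=4, n_participants=10, n_pairs=12)
        frame = _mediation_frame(cfg)
        m1 = ss.mediation_analysis(frame, n_boot=200, seed=11)
        m2 = ss.mediation_analysis(frame, n_boot=200, seed=11)
        assert m1.ci95_ab == m2.ci95_ab

    def test_no_bootstrap_gives_point_estimates_only(self):
        cfg = PipelineConfig(seed=4, n_participants=10, n_pairs=12)
        med = ss.mediation_analysis(_mediation_frame(cfg), n_boot=0)
        assert med.ci95_ab is None and med.z_ab is None

    def test_too_few_participants_raise(self):
        cfg = PipelineConfig(seed=4, n_participants=2, n_pairs=12)
        with pytest.raises(InsufficientClustersError):
            ss.mediation_analysis(_mediation_frame(cfg), n_boot=0)

    def test_active_search_choice_chain_detected(self):
        cfg = PipelineConfig(seed=17, n_participants=20, n_pairs=30, search_coupling=0.5)
        med = ss.mediation_analysis(_mediation_frame(cfg), n_boot=500, seed=1)
        assert med.ab > 0
        assert med.ci95_ab[0] > 0

    def test_independent_mediator_gives_null_indirect_effect(self):
        cfg = PipelineConfig(
            seed=18, n_participants=20, n_pairs=20,
            bias_alt=0.5, bias_dim=0.5, search_coupling=0.0,
        )
        med = ss.mediation_analysis(_mediation_frame(cfg), n_boot=400, seed=2)
        assert med.ci95_ab[0] <= 0 <= med.ci95_ab[1]
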
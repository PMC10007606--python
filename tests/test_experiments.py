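"""Experiment drivers: paired trials, sweeps, and the alarm protocol."""

import math

import numpy as np
import pandas as pd
import pytest

from molesim import (
    AlgorithmSpec,
    AlarmConfig,
    CASE_A,
    CASE_B,
    ExperimentConfig,
    SCENARIO_1,
    SCENARIO_2,
    ScenarioSpec,
    alarm_decision,
    classify_alarm,
    experiment_asymmetry,
    experiment_catastrophe,
    experiment_handicap,
    experiment_mole_advantage,
    experiment_quality_sweep,
    run_trial,
    simulate_setting,
    turning_point,
)
from molesim.errors import ConfigurationError


def _adv_mean_se(scenario, n, seed, baseline, mole, sample_size=6, stream_size=10_000):
    rng = np.random.default_rng(seed)
    sim = simulate_setting(scenario, n, sample_size, stream_size, rng,
                           baseline=baseline, mole=mole)
    acc_b = 1.0 - np.abs(sim["p_true"] - sim["baseline"])
    acc_m = 1.0 - np.abs(sim["p_true"] - sim["mole"])
    ok = acc_b > 0
    adv = (acc_m[ok] - acc_b[ok]) / acc_b[ok]
    return adv.mean(), adv.std() / np.sqrt(ok.sum())


class TestRunTrial:
    def test_perfect_detector_on_pure_population(self):
        config = ExperimentConfig(experiment_id=1, stream_size=1000)
        records = run_trial(
            [AlgorithmSpec("baseline", quality=1.0)],
            ScenarioSpec.fixed(0.0),
            config,
            np.random.default_rng(0),
        )
        assert records["baseline"].estimate == 0.0
        assert records["baseline"].accuracy == 1.0

    def test_zero_delta_mole_estimates_match_baseline_in_distribution(self):
        # with delta 0 all three matrices coincide, so the consensus and the
        # baseline ESTIMATE have the same distribution (their accuracies do
        # not: averaging two readouts strictly reduces classification noise)
        config = ExperimentConfig(experiment_id=1, stream_size=2000)
        rng = np.random.default_rng(1)
        specs = [AlgorithmSpec("baseline"), AlgorithmSpec("mole", delta=0.0)]
        diffs = []
        for _ in range(10_000):
            recs = run_trial(specs, SCENARIO_1, config, rng)
            diffs.append(recs["mole"].estimate - recs["baseline"].estimate)
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std() / np.sqrt(diffs.size)

    def test_object_level_path_agrees_with_vectorized_engine(self):
        """The per-signal stream path and the hypergeometric engine sample
        the same distribution, so their mean accuracies must agree."""
        config = ExperimentConfig(experiment_id=1, stream_size=2000)
        spec = AlgorithmSpec("baseline", quality=0.75)
        rng = np.random.default_rng(2)
        acc_obj = np.array(
            [run_trial([spec], SCENARIO_1, config, rng)["baseline"].accuracy
             for _ in range(5_000)]
        )
        sim = simulate_setting(SCENARIO_1, 200_000, 6, 2000,
                               np.random.default_rng(3), baseline=spec)
        acc_vec = 1.0 - np.abs(sim["p_true"] - sim["baseline"])
        se = math.hypot(acc_obj.std() / np.sqrt(acc_obj.size),
                        acc_vec.std() / np.sqrt(acc_vec.size))
        assert abs(acc_obj.mean() - acc_vec.mean()) < 3 * se


class TestConsensusProperties:
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_mole_mean_matches_baseline_mean_when_unbiased(self, p):
        # MoSe and LeSe biases are symmetric around Q, so the expected
        # consensus estimate equals the expected baseline estimate
        n = 100_000
        rng = np.random.default_rng(int(p * 100))
        sim = simulate_setting(ScenarioSpec.fixed(p), n, 6, 10_000, rng,
                               baseline=AlgorithmSpec("baseline"),
                               mole=AlgorithmSpec("mole"))
        se = math.hypot(sim["baseline"].std(), sim["mole"].std()) / np.sqrt(n)
        assert abs(sim["baseline"].mean() - sim["mole"].mean()) < 3 * se

    def test_mole_variance_no_larger_than_baseline(self):
        n = 100_000
        rng = np.random.default_rng(42)
        sim = simulate_setting(ScenarioSpec.fixed(0.5), n, 6, 10_000, rng,
                               baseline=AlgorithmSpec("baseline"),
                               mole=AlgorithmSpec("mole"))
        assert sim["mole"].var() <= sim["baseline"].var()

    def test_estimate_lattices(self):
        rng = np.random.default_rng(5)
        sim = simulate_setting(SCENARIO_1, 5_000, 6, 10_000, rng,
                               baseline=AlgorithmSpec("baseline"),
                               mole=AlgorithmSpec("mole"))
        assert np.allclose(np.mod(sim["baseline"] * 6, 1), 0)
        assert np.allclose(np.mod(sim["mole"] * 12, 1), 0)


class TestQualitySweep:
    def test_table_shape_and_random_flatness(self):
        config = ExperimentConfig(
            experiment_id=1, master_seed=0, runs_per_setting=5_000,
            quality_grid=(0.25, 0.5, 0.75, 1.0),
        )
        df = experiment_quality_sweep(config)
        assert len(df) == 4 * 2 * 2  # grid x scenarios x {baseline, random}
        rand_s1 = df[(df.algorithm == "random") & (df.scenario == "uniform")]
        for _, row in rand_s1.iterrows():
            se = row.sd_accuracy / np.sqrt(row.runs)
            assert abs(row.mean_accuracy - 2 / 3) < 3.5 * se


class TestMoleAdvantageSweep:
    def test_sign_pattern_across_quality_delta_plane(self):
        config = ExperimentConfig(
            experiment_id=2, master_seed=0, runs_per_setting=50_000,
            scenarios=(SCENARIO_1,),
            quality_grid=(0.5, 0.6, 0.8), delta_grid=(0.1, 0.8),
        )
        df = experiment_mole_advantage(config)
        mole = df[df.algorithm == "mole"].set_index(["quality", "delta"])
        # low baseline quality: consensus clearly helps
        assert mole.loc[(0.5, 0.1), "mean_advantage"] > 0
        assert mole.loc[(0.6, 0.1), "mean_advantage"] > 0
        # both quality and delta high: baseline wins
        assert mole.loc[(0.8, 0.8), "mean_advantage"] < 0

    def test_zero_delta_shares_variance_without_bias(self):
        mean, se = _adv_mean_se(SCENARIO_2, 100_000, 6,
                                AlgorithmSpec("baseline"),
                                AlgorithmSpec("mole", delta=0.0))
        assert mean > -3 * se


class TestSensitivityBias:
    @pytest.mark.parametrize("theta", [-0.15, 0.15])
    def test_advantage_positive_for_biased_baselines_uniform_scenario(self, theta):
        # under a uniform population proportion the consensus beats a baseline
        # biased either way (the model is symmetric in theta there)
        mean, se = _adv_mean_se(SCENARIO_1, 200_000, 7,
                                AlgorithmSpec("baseline", sensitivity_bias=theta),
                                AlgorithmSpec("mole"))
        assert mean > 3 * se

    def test_specificity_biased_baseline_wins_in_low_stress_scenario(self):
        # with P concentrated near 0.1, a baseline tilted toward specificity
        # (theta = -0.15, TN-rate 0.9) is hard to beat
        mean, se = _adv_mean_se(SCENARIO_2, 100_000, 8,
                                AlgorithmSpec("baseline", sensitivity_bias=-0.15),
                                AlgorithmSpec("mole"))
        assert mean < -3 * se


class TestHandicap:
    def test_turning_point_extraction(self):
        grid = (0.0, 0.05, 0.10, 0.15, 0.20)
        assert turning_point(grid, (0.05, 0.02, 0.01, 0.005, -0.01)) == 0.20
        assert turning_point(grid, (0.05, 0.04, 0.03, 0.02, 0.01)) is None

    def test_advantage_nonincreasing_in_handicap_and_turning_points_exist(self):
        # scenario 2 is well behaved (P concentrated near 0.1); scenario 1's
        # per-run ratio is heavy tailed, so use generous slack there
        for scenario, n in ((SCENARIO_1, 50_000), (SCENARIO_2, 50_000)):
            stats = [
                _adv_mean_se(scenario, n, 20 + i, AlgorithmSpec("baseline"),
                             AlgorithmSpec("mole", handicap=eps))
                for i, eps in enumerate((0.0, 0.1, 0.2, 0.3))
            ]
            for (m0, s0), (m1, s1) in zip(stats, stats[1:]):
                assert m1 <= m0 + 3 * math.hypot(s0, s1)
            assert stats[0][0] > 0  # no handicap: consensus helps
            assert stats[-1][0] < 0  # heavy handicap: baseline wins

        _, points = experiment_handicap(
            ExperimentConfig(experiment_id=4, master_seed=0, runs_per_setting=10_000)
        )
        assert points["uniform"] is not None
        assert points["gaussian"] is not None


class TestAsymmetry:
    def test_symmetric_consensus_beats_baseline_at_half(self):
        config = ExperimentConfig(
            experiment_id=5, master_seed=0, runs_per_setting=10_000,
            p_grid=(0.5,), asymmetry_grid=(0.0,),
        )
        df = experiment_asymmetry(config)
        assert df[df.algorithm == "mole"].mean_advantage.iloc[0] > 0

    def test_lopsidedness_erodes_advantage_at_low_proportion(self):
        # tilting the consensus toward sensitivity hurts where the
        # population is mostly healthy
        symmetric, se_s = _adv_mean_se(ScenarioSpec.fixed(0.1), 50_000, 40,
                                       AlgorithmSpec("baseline"),
                                       AlgorithmSpec("mole", asymmetry=0.0))
        lopsided, se_l = _adv_mean_se(ScenarioSpec.fixed(0.1), 50_000, 41,
                                      AlgorithmSpec("baseline"),
                                      AlgorithmSpec("mole", asymmetry=1.0))
        assert symmetric - lopsided > 3 * math.hypot(se_s, se_l)

    def test_wide_lopsided_consensus_loses_at_low_proportion(self):
        # with a wider sensitivity spread the fully lopsided consensus is
        # biased enough to lose outright against the baseline
        mean, se = _adv_mean_se(ScenarioSpec.fixed(0.1), 50_000, 42,
                                AlgorithmSpec("baseline"),
                                AlgorithmSpec("mole", delta=0.2, asymmetry=1.0))
        assert mean < -3 * se

    def test_relabeling_symmetry(self):
        # swapping 0<->1 maps (P, a) onto (1-P, -a); their advantages agree
        means = []
        for p, a, seed in ((0.3, 0.5, 30), (0.7, -0.5, 31)):
            mean, se = _adv_mean_se(ScenarioSpec.fixed(p), 100_000, seed,
                                    AlgorithmSpec("baseline"),
                                    AlgorithmSpec("mole", asymmetry=a))
            means.append((mean, se))
        (m0, s0), (m1, s1) = means
        assert abs(m0 - m1) < 3 * math.hypot(s0, s1)


class TestAlarmProtocol:
    @pytest.mark.parametrize(
        "e1, e2, threshold, expected",
        [(0.5, 0.5, 0.4, True), (0.5, 0.25, 0.4, False), (0.41667, 0.45, 0.4, True),
         (0.4, 0.5, 0.4, False)],
    )
    def test_alarm_requires_both_measurements_above_threshold(self, e1, e2, threshold, expected):
        assert alarm_decision(e1, e2, threshold) is expected

    @pytest.mark.parametrize(
        "alarm, p, expected",
        [(True, 0.70, "TP"), (False, 0.70, "FN"), (True, 0.50, "FP"), (False, 0.50, "TN")],
    )
    def test_alarm_confusion_mapping(self, alarm, p, expected):
        assert classify_alarm(alarm, p, 0.66) == expected

    def test_alarm_case_validation(self):
        with pytest.raises(ConfigurationError):
            AlarmConfig(1.2, 0.4)
        with pytest.raises(ConfigurationError):
            AlarmConfig(0.66, 0.40, sample_sizes=(4, 6))

    def test_perfect_detector_extremes(self):
        config = ExperimentConfig(experiment_id=6, runs_per_setting=200,
                                  quality=1.0, delta=0.0)
        for p, field in ((1.0, "tp"), (0.0, "tn")):
            results = experiment_catastrophe(config, scenario=ScenarioSpec.fixed(p))
            for per_alg in results.values():
                for tally in per_alg.values():
                    assert getattr(tally, field) == tally.n == 200

    def test_consensus_reduces_missed_catastrophes(self):
        config = ExperimentConfig(experiment_id=6, master_seed=0)
        results = experiment_catastrophe(config)
        for case in (CASE_A, CASE_B):
            tallies = results[case.label]
            base, mole = tallies["baseline"], tallies["mole"]
            assert base.n == mole.n == config.runs
            assert mole.fn < base.fn
            # correct-classification rates stay close (the expected gap is
            # about 2 points in case A and 7 points in case B)
            correct_b = (base.tp + base.tn) / base.n
            correct_m = (mole.tp + mole.tn) / mole.n
            assert abs(correct_b - correct_m) < 0.08
            assert sum(base.proportions().values()) == pytest.approx(1.0)


class TestReproducibility:
    def test_same_master_seed_reproduces_tables_bit_identically(self):
        config = ExperimentConfig(experiment_id=4, master_seed=123, runs_per_setting=500)
        df1, pts1 = experiment_handicap(config)
        df2, pts2 = experiment_handicap(config)
        pd.testing.assert_frame_equal(df1, df2)
        assert pts1 == pts2
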
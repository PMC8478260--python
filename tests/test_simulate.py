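"""Trial loop, stimulus schedule, controls, calibration and scoring."""

import numpy as np
import pytest

from gazeblind import (ModelParams, SyntheticPairSpec, make_catch_pair,
                       run_control, run_trial, success_rate)
from gazeblind.simulate import (ImagePair, StimulusSchedule, SweepSpec,
                                calibrate_threshold, run_sweep)


class TestSchedule:
    def test_flicker_pattern(self):
        kinds = StimulusSchedule(2, 3, 12).kinds()
        assert kinds.tolist() == [0, 0, 1, 1, 1, 2, 2, 1, 1, 1, 0, 0]

    def test_default_cycle_length(self):
        kinds = StimulusSchedule(10, 10, 2400).kinds()
        assert kinds.size == 2400
        assert (kinds[:10] == 0).all() and (kinds[10:20] == 1).all()
        assert (kinds[20:30] == 2).all() and (kinds[30:40] == 1).all()


class TestRunTrial:
    def test_unreachable_threshold_gives_miss_without_false_alarm(
            self, small_catch_pair, small_params):
        params = small_params.with_(f_c=1e9, trial_bins=200)
        res = run_trial(small_catch_pair, params, seed=0)
        assert res.outcome == "miss"
        assert res.detection_bin is None

    def test_same_seed_reproduces_trial(self, small_pair, small_params,
                                        small_cache):
        a = run_trial(small_pair, small_params, seed=9, cache=small_cache)
        b = run_trial(small_pair, small_params, seed=9, cache=small_cache)
        assert a.outcome == b.outcome
        assert a.scanpath == b.scanpath
        assert a.detection_bin == b.detection_bin

    def test_mismatched_images_rejected(self):
        with pytest.raises(ValueError):
            ImagePair(a=np.zeros((24, 24, 3)), a_prime=np.zeros((24, 36, 3)))

    def test_scanpath_covers_trial(self, small_pair, small_params,
                                   small_cache):
        res = run_trial(small_pair, small_params, seed=3, cache=small_cache)
        total = sum(d for _, _, d in res.scanpath)
        end = res.detection_bin + 1 if res.detection_bin is not None \
            else small_params.trial_bins
        assert total == end
        onsets = [o for _, o, _ in res.scanpath]
        assert onsets == sorted(onsets)

    def test_fixation_schedule_is_respected(self, small_pair, small_params,
                                            small_cache):
        params = small_params.with_(f_c=1e9, trial_bins=120)
        res = run_trial(small_pair, params, seed=1, cache=small_cache,
                        fixation_schedule=[30, 20, 10])
        durations = [d for _, _, d in res.scanpath]
        assert durations[:3] == [30, 20, 10]
        assert all(d == 10 for d in durations[3:-1])

    def test_detection_only_with_real_change(self, small_pair, small_params,
                                             small_cache):
        """A strong localized change is detected and scored as a hit."""
        hits = sum(run_trial(small_pair, small_params, seed=s,
                             cache=small_cache).outcome == "hit"
                   for s in range(6))
        assert hits >= 4

    def test_all_blank_schedule_accrues_nothing(self, small_pair,
                                                small_params, small_cache):
        """Without image epochs no likelihood ever arrives: the trial
        can only end as a miss, never as a detection."""
        params = small_params.with_(image_bins=0, blank_bins=25,
                                    trial_bins=100)
        res = run_trial(small_pair, params, seed=0, cache=None)
        assert res.outcome == "miss"
        assert res.detection_bin is None


class TestControls:
    def test_control_requires_calibration(self, small_pair, small_params):
        with pytest.raises(ValueError):
            run_control(1, small_pair, small_params, seed=0)
        with pytest.raises(ValueError):
            run_control(4, small_pair, small_params, seed=0,
                        calibrated_threshold=1.0)

    def test_control1_with_infinite_threshold_misses(self, small_pair,
                                                     small_params,
                                                     small_cache):
        res = run_control(1, small_pair, small_params, seed=2,
                          calibrated_threshold=np.inf, cache=small_cache)
        assert res.outcome == "miss"

    def test_control2_constant_input_never_detects(self, small_catch_pair,
                                                   small_params):
        params = small_params.with_(trial_bins=200, noise_half_width=0.0)
        res = run_control(2, small_catch_pair, params, seed=0,
                          calibrated_threshold=50.0)
        assert res.outcome == "miss"

    def test_control3_matches_main_fixation_timing(self, small_pair,
                                                   small_params, small_cache):
        params = small_params.with_(trial_bins=300)
        main = run_trial(small_pair, params, seed=4, cache=small_cache)
        ctrl = run_control(3, small_pair, params, seed=4, cache=small_cache,
                           main_result=main)
        main_durs = [d for _, _, d in main.scanpath]
        ctrl_durs = [d for _, _, d in ctrl.scanpath]
        # identical durations until one of the two runs terminates
        k = min(len(main_durs), len(ctrl_durs)) - 1
        assert ctrl_durs[:k] == main_durs[:k]


@pytest.fixture(scope="module")
def catch_pairs():
    return [make_catch_pair(SyntheticPairSpec(
        width=144, height=108, n_objects=6, seed=20 + i))
        for i in range(3)]


class TestCalibration:
    def test_threshold_meets_bound_on_holdout(self, catch_pairs):
        params = ModelParams(trial_bins=300)
        seeds = [0, 1, 2, 3]
        thr = calibrate_threshold(1, catch_pairs, 0.1, params, seeds=seeds)
        fresh = [run_control(1, p, params, seed=s, calibrated_threshold=thr)
                 for p in catch_pairs for s in (10, 11, 12, 13)]
        fa = sum(r.outcome == "false_alarm" for r in fresh) / len(fresh)
        # a quantile threshold from n trials admitting k exceedances has
        # true exceedance probability ~ (k+1)/(n+1) by exchangeability
        n_calib = len(catch_pairs) * len(seeds)
        k = int(np.floor(0.1 * n_calib))
        p_true = (k + 1) / (n_calib + 1)
        assert fa <= p_true + 3 * np.sqrt(p_true * (1 - p_true) / len(fresh))

    def test_larger_thresholds_never_raise_false_alarms(self, catch_pairs):
        params = ModelParams(trial_bins=300)
        thr = calibrate_threshold(2, catch_pairs, 0.2, params, seeds=[0])
        rates = []
        for mult in (1.0, 2.0, 5.0):
            res = [run_control(2, p, params, seed=s,
                               calibrated_threshold=thr * mult)
                   for p in catch_pairs for s in (3,)]
            rates.append(sum(r.outcome == "false_alarm" for r in res))
        assert rates == sorted(rates, reverse=True)

    def test_trivial_bound_returns_minimal_threshold(self, catch_pairs):
        params = ModelParams(trial_bins=120)
        thr = calibrate_threshold(1, catch_pairs[:1], 1.0, params, seeds=[0])
        assert np.isfinite(thr)


class TestScoring:
    def _result(self, outcome):
        from gazeblind.simulate import TrialResult
        from gazeblind.image_pipeline import partition_grid
        return TrialResult(outcome=outcome, detection_bin=None,
                           detection_region=None, scanpath=[(0, 0, 10)],
                           seed=0, dt=0.025, grid=partition_grid(36, 24, 12))

    def test_success_rate_values(self):
        assert success_rate([self._result("hit")] * 4)[0] == 1.0
        assert success_rate([self._result("miss")] * 4)[0] == 0.0
        rate, sem = success_rate([self._result("hit")] * 3
                                 + [self._result("miss")])
        assert rate == 0.75
        assert sem == pytest.approx(np.sqrt(0.75 * 0.25 / 4))

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            success_rate([])


class TestSweep:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec("not_a_knob", [1.0])

    def test_empty_value_list_gives_empty_table(self, small_pair):
        df = run_sweep(SweepSpec("gamma", []), [small_pair], ModelParams())
        assert df.empty

    def test_blank_fraction_rebalances_schedule(self):
        spec = SweepSpec("blank_fraction", [0.2], flicker_total_bins=50)
        p = spec.apply(ModelParams(), 0.2)
        assert p.image_bins + p.blank_bins == 25
        assert p.blank_bins == 5

    def test_sweep_reports_gaze_metrics(self, small_pair, small_params):
        df = run_sweep(SweepSpec("temperature", [0.01], n_trials=2),
                       [small_pair], small_params.with_(trial_bins=200),
                       seed=1)
        assert {"success", "sem", "mean_fd_bins",
                "var_sa_grid"} <= set(df.columns)
        assert len(df) == 1
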
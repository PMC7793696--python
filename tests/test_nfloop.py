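"""Closed-loop protocol: thresholds, adaptation, bars, rewards, training."""

import numpy as np
import pytest

from smrcoh import (
    LearnerParams,
    ProtocolConfig,
    Recording,
    Thresholds,
    adapt_threshold,
    compute_thresholds,
    online_bars,
    run_training,
    score_rewards,
    simulate_run,
)
from smrcoh.nfloop import BarSeries


def _bars(coh, theta=None, beta=None):
    coh = np.asarray(coh, dtype=float)
    theta = np.full_like(coh, 1.0) if theta is None else np.asarray(theta, float)
    beta = np.full_like(coh, 1.0) if beta is None else np.asarray(beta, float)
    return BarSeries(coh=coh, theta=theta, beta=beta)


class TestThresholds:
    def test_constant_power_gives_zero_sd(self):
        b = _bars([0.4] * 10, theta=[2.0] * 10, beta=[3.0] * 10)
        thr = compute_thresholds(b)
        assert thr.theta_thr == pytest.approx(2.0)
        assert thr.beta_thr == pytest.approx(3.0)
        assert thr.coh_thr == pytest.approx(0.4)

    def test_hand_arithmetic_mean_plus_sd(self):
        b = _bars([0.5, 0.5, 0.5], theta=[1.0, 2.0, 3.0], beta=[2.0, 4.0, 6.0])
        thr = compute_thresholds(b)
        assert thr.theta_thr == pytest.approx(3.0)  # mean 2 + sample SD 1
        assert thr.beta_thr == pytest.approx(6.0)   # mean 4 + sample SD 2

    def test_brute_force_recomputation_from_logged_bars(self, default_run):
        bars = online_bars(default_run)
        thr = compute_thresholds(bars)
        coh = bars.coh[np.isfinite(bars.coh)]
        assert thr.coh_thr == pytest.approx(coh.mean(), abs=1e-12)
        assert thr.theta_thr == pytest.approx(
            bars.theta.mean() + bars.theta.std(ddof=1), abs=1e-12
        )
        assert thr.beta_thr == pytest.approx(
            bars.beta.mean() + bars.beta.std(ddof=1), abs=1e-12
        )

    def test_insufficient_baseline(self):
        with pytest.raises(ValueError):
            compute_thresholds(_bars([np.nan, 0.4]))


class TestAdaptation:
    def test_coherence_threshold_tracks_previous_run_mean(self):
        thr = Thresholds(0.3, 2.0, 3.0)
        new = adapt_threshold(_bars([0.4] * 20), thr)
        assert new.coh_thr == pytest.approx(0.4)

    def test_control_thresholds_never_change(self):
        thr = Thresholds(0.3, 2.0, 3.0)
        new = adapt_threshold(_bars(np.linspace(0, 1, 50)), thr)
        assert new.theta_thr == thr.theta_thr
        assert new.beta_thr == thr.beta_thr

    def test_six_updates_per_session(self):
        cfg = ProtocolConfig(run_s=20.0, n_sessions=1)
        _, records = run_training([LearnerParams()], cfg, seed=3)
        thr_series = records[0].thresholds
        assert len(thr_series) == 7
        coh_changes = sum(
            thr_series[i].coh_thr != thr_series[i + 1].coh_thr for i in range(6)
        )
        assert coh_changes == 6
        assert len({t.theta_thr for t in thr_series}) == 1
        assert len({t.beta_thr for t in thr_series}) == 1


class TestOnlineBars:
    def test_identical_channels_pin_coherence_at_one(self, default_run):
        x = default_run.channel("Cz")
        rec = Recording(np.vstack([x, x, default_run.channel("EOG")]))
        bars = online_bars(rec)
        finite = bars.coh[np.isfinite(bars.coh)]
        np.testing.assert_allclose(finite, 1.0, atol=1e-9)

    def test_update_count_and_first_estimable(self, default_run):
        bars = online_bars(default_run, ProtocolConfig(online_window_epochs=8))
        assert bars.n_updates == 180
        assert np.isnan(bars.coh[0])
        assert np.isfinite(bars.coh[1:]).all()

    def test_increasing_coupling_gives_positive_bar_trend(self):
        """Within-run coherence drift shows up in the online bar series with
        the same ordering as offline half-run coherence."""
        from smrcoh import SMR_BAND, coherence, epoch_spectra

        lp = LearnerParams(c0=0.2, noise_sd=0.0, blink_rate=0, muscle_rate=0)
        lo = simulate_run(lp, 1, 1, 90, seed=4)
        hi = simulate_run(
            LearnerParams(c0=0.8, noise_sd=0.0, blink_rate=0, muscle_rate=0),
            1, 1, 90, seed=4,
        )
        rec = Recording(np.hstack([lo.data, hi.data]))
        bars = online_bars(rec)
        first, second = np.nanmean(bars.coh[:90]), np.nanmean(bars.coh[90:])
        assert second > first

        def _off(r):
            x = r.data[0].reshape(90, 256)
            y = r.data[1].reshape(90, 256)
            return coherence(epoch_spectra(x, y), SMR_BAND).band_msc

        assert _off(hi) > _off(lo)  # offline ordering matches


class TestRewards:
    def test_always_green_counts_single_entry(self):
        thr = Thresholds(0.3, 2.0, 3.0)
        assert score_rewards(_bars([0.5] * 20), thr, "up") == 1

    def test_alternating_coherence(self):
        thr = Thresholds(0.3, 2.0, 3.0)
        coh = [0.5 if i % 2 == 0 else 0.1 for i in range(20)]
        assert score_rewards(_bars(coh), thr, "up") == 10  # ceil(20/2)

    def test_scripted_twenty_update_fixture(self):
        """Hand-enumerated trajectory: green at updates 3-5, 9, 14-16, 20
        (1-based) -> 4 entries; 'down' direction flips the coherence rule."""
        coh = np.array([.1, .1, .5, .6, .7, .2, .1, .2, .9, .2,
                        .1, .1, .2, .4, .5, .6, .1, .1, .2, .8])
        theta = np.array([1.] * 20)
        beta = np.array([1.] * 20)
        theta[8] = 3.0  # update 9: theta bar too high -> not green
        thr = Thresholds(coh_thr=0.3, theta_thr=2.0, beta_thr=2.0)
        bars = _bars(coh, theta, beta)
        # green updates (0-based): 2,3,4 | 13,14,15 | 19 -> 3 entries
        assert score_rewards(bars, thr, "up") == 3
        # down direction: coh < 0.3 and controls ok
        # ok updates: 0,1,5,6,7,9(theta bad),10,11,12,16,17,18 -> entries at 0,5,10,16
        assert score_rewards(bars, thr, "down") == 4

    def test_second_mode_counts_green_seconds(self):
        thr = Thresholds(0.3, 2.0, 3.0)
        assert score_rewards(_bars([0.5] * 20), thr, "up", mode="second") == 20

    def test_raising_coherence_never_loses_green_time(self, rng):
        thr = Thresholds(0.3, 2.0, 3.0)
        coh = rng.uniform(0, 1, 50)
        base = score_rewards(_bars(coh), thr, "up", mode="second")
        shifted = score_rewards(_bars(coh + 0.2), thr, "up", mode="second")
        assert shifted >= base


class TestRunTraining:
    def test_null_learner_dataset_shape(self):
        cfg = ProtocolConfig(run_s=20.0, n_sessions=10)
        ds, records = run_training([LearnerParams()], cfg, seed=1)
        assert len(ds) == 70  # 10 sessions x 7 runs
        assert sorted(ds["session"].unique()) == list(range(1, 11))
        assert sorted(ds["run"].unique()) == list(range(1, 8))
        assert len(records) == 10
        assert all(len(r.run_summaries) == 7 for r in records)

    def test_deterministic(self):
        cfg = ProtocolConfig(run_s=20.0, n_sessions=2)
        a, _ = run_training([LearnerParams()], cfg, seed=9)
        b, _ = run_training([LearnerParams()], cfg, seed=9)
        assert a.equals(b)

    def test_learning_cohort_coherence_rises_with_session(self):
        """Up-cohort with positive session slope: mean estimated coherence in
        late sessions exceeds early sessions (ground-truth slope sign)."""
        cfg = ProtocolConfig(run_s=30.0, n_sessions=6)
        cohort = [LearnerParams(c0=0.25, beta_session=0.08, noise_sd=0.01)
                  for _ in range(4)]
        ds, _ = run_training(cohort, cfg, seed=21)
        by_session = ds.groupby("session")["band_msc"].mean()
        assert by_session.loc[5:].mean() > by_session.loc[:2].mean()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_training([], ProtocolConfig())

    def test_running_mean_adaptation_smooths_thresholds(self):
        cfg_last = ProtocolConfig(run_s=20.0, n_sessions=1)
        cfg_run = ProtocolConfig(run_s=20.0, n_sessions=1, adaptation="running-mean")
        _, recs_last = run_training([LearnerParams()], cfg_last, seed=3)
        _, recs_run = run_training([LearnerParams()], cfg_run, seed=3)
        var_last = np.var([t.coh_thr for t in recs_last[0].thresholds])
        var_run = np.var([t.coh_thr for t in recs_run[0].thresholds])
        assert var_run <= var_last

    def test_session_records_serialize_to_json(self, tmp_path):
        from smrcoh.nfloop import records_to_json
        import json

        cfg = ProtocolConfig(run_s=20.0, n_sessions=1)
        _, records = run_training([LearnerParams()], cfg, seed=4)
        path = tmp_path / "records.json"
        records_to_json(records, path)
        loaded = json.loads(path.read_text())
        assert len(loaded) == 1
        assert loaded[0]["reward_count"] == records[0].reward_count
        assert len(loaded[0]["thresholds"]) == 7
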
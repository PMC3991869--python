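"""Event detection, per-cycle parameters, ensembles, walk summaries."""

import dataclasses

import numpy as np
import pytest

import vestigait as vg
from vestigait.errors import MalformedCycleError, TooFewStridesError
from vestigait.events import _events_for_peaks
from vestigait.nav import NAVSeries


PRESETS = [("control", "normal", "none"), ("vn", "lvn", "left"),
           ("vn", "rvn", "right")]


def nav_from_waveform(waveform, reps=10, dt=0.02):
    pitch = np.tile(waveform, reps)
    t = np.arange(len(pitch)) * dt
    nan = np.full_like(pitch, np.nan)
    return NAVSeries(t, pitch, nan, nan, nan, "left")


class TestPeakDetection:
    def test_one_peak_per_stride(self, control_params, quiet_config):
        series = vg.simulate_leg(control_params, 70,
                                 dataclasses.replace(quiet_config))
        a = vg.analyze_series(series, 88.8, with_spectrum=False)
        assert len(a.peak_times) == 70
        spacing = np.diff(a.peak_times)
        assert np.all(np.abs(spacing - 0.98) <= 0.021)

    def test_flat_signal_raises(self):
        nav = nav_from_waveform(np.zeros(49), reps=10)
        with pytest.raises(TooFewStridesError):
            vg.detect_midswing_peaks(nav)

    def test_noise_does_not_change_peak_count(self, control_params):
        """Broadband noise at 15 deg/s SD leaves the stride segmentation
        untouched (detection run on the known zero offsets, as such noise
        exceeds what the stationarity gate of calibration accepts)."""
        counts = {}
        for noise in (0.0, 15.0):
            cfg = vg.SimulationConfig(noise_sd=noise, stride_time_cv=0.0,
                                      amplitude_cv=0.0, seed=21)
            series = vg.simulate_leg(control_params, 30, cfg)
            t0 = vg.detect_sync_start(series)
            walking = series.slice_time(t0 + 0.06, series.timestamps[-1])
            nav = vg.pitch_nav(walking, cfg.lead_offsets)
            counts[noise] = len(vg.detect_midswing_peaks(nav))
        assert counts[0.0] == counts[15.0] == 30


class TestEventOracle:
    def test_detected_times_match_generator_schedule(self, quiet_leg,
                                                     quiet_analysis):
        """On zero-variability signals every detected event time agrees
        with the generator's analytic schedule to one sample (20 ms)."""
        _, truth = quiet_leg
        events = [c.events for c in quiet_analysis.cycles]
        for attr, key in [("t_toeoff", "toeoff_times"),
                          ("t_midswing", "midswing_times"),
                          ("t_heelstrike", "heelstrike_times")]:
            detected = np.array([getattr(e, attr) for e in events])
            analytic = np.asarray(truth[key])
            # match detected events to the nearest analytic event
            err = np.abs(detected[:, None] - analytic[None, :]).min(axis=1)
            assert err.max() <= 0.0201, attr

    def test_event_values_match_published_preset(self, quiet_analysis):
        m = quiet_analysis.summary.means
        assert m["min_nav"] == pytest.approx(-172.3, rel=0.02)
        assert m["max_nav"] == pytest.approx(368.6, rel=0.02)

    def test_zero_variability_cycles_identical(self, quiet_analysis):
        for param in vg.PARAMETERS:
            values = [getattr(c, param) for c in quiet_analysis.cycles]
            assert np.ptp(values) <= 1e-9, param

    def test_deeper_heelstrike_trough_flagged(self, control_params):
        """Adversarial template whose heel-strike trough undercuts toe-off:
        detection refuses the cycle instead of mislabeling events."""
        params = dataclasses.replace(control_params, a_heelstrike=-220.0)
        tmpl = vg.make_cycle_template(params, validate=False)
        nav = nav_from_waveform(tmpl.waveform, reps=10)
        peaks = vg.detect_midswing_peaks(nav)
        events = _events_for_peaks(nav, peaks)
        assert all(e is None for e in events[1:-1])


class TestCycleParameters:
    def test_definitional_identities_exact(self, quiet_analysis):
        for c in quiet_analysis.cycles:
            assert c.swing_time + c.stance_time == pytest.approx(
                c.stride_time, abs=1e-12)
            assert c.stance_ratio == pytest.approx(
                100.0 * c.stance_time / c.stride_time, abs=1e-9)
            assert c.up_slope > 0 > c.down_slope

    def test_control_round_trip_timing(self, quiet_analysis):
        m = quiet_analysis.summary.means
        assert m["stride_time"] == pytest.approx(0.98, abs=0.021)
        assert m["stance_time"] == pytest.approx(0.591, abs=0.021)
        ratio = 100.0 * 0.591 / 0.98
        assert m["stance_ratio"] == pytest.approx(ratio, rel=0.02)

    def test_control_round_trip_up_slope(self, quiet_analysis):
        assert quiet_analysis.summary.means["up_slope"] == pytest.approx(
            2968.7, rel=0.02)

    @pytest.mark.parametrize("group,column,side", PRESETS)
    def test_full_recovery_against_realized_template(self, group, column,
                                                     side):
        """All eight parameters are recovered from a noise-free simulation:
        amplitudes within 2 %, chord slopes within the one-sample timing
        quantization, durations within one sample."""
        params = vg.default_params(group, column)
        tmpl = vg.make_cycle_template(params)
        realized = tmpl.realized_params
        cfg = vg.SimulationConfig(group=group, lesion_side=side,
                                  noise_sd=0.0, stride_time_cv=0.0,
                                  amplitude_cv=0.0, seed=5)
        series = vg.simulate_leg(params, 30, cfg)
        m = vg.analyze_series(series, 88.8, with_spectrum=False).summary.means
        assert m["max_nav"] == pytest.approx(realized.a_midswing, rel=0.02)
        assert m["min_nav"] == pytest.approx(realized.a_toeoff, rel=0.02)
        assert m["up_slope"] == pytest.approx(realized.up_slope, rel=0.05)
        assert m["down_slope"] == pytest.approx(realized.down_slope,
                                                rel=0.05)
        for name, want in [("stride_time", realized.stride_time),
                           ("swing_time", realized.swing_time),
                           ("stance_time", realized.stance_time)]:
            assert abs(m[name] - want) <= 0.021, name

    def test_non_positive_duration_rejected(self, quiet_analysis):
        ev0 = quiet_analysis.cycles[0].events
        with pytest.raises(MalformedCycleError):
            vg.compute_cycle(ev0, ev0)


class TestEnsemble:
    def test_resolution_stable(self, quiet_analysis, control_params):
        a = quiet_analysis
        _, mean101, _ = vg.cycle_ensemble(a.nav, a.peak_times, 101)
        _, mean202, _ = vg.cycle_ensemble(a.nav, a.peak_times, 202)
        # linear resampling can shave the sharp mid-swing peak by up to
        # ~1 % at 101 points; doubling the grid must stay within that
        assert mean202.max() == pytest.approx(mean101.max(), rel=0.01)

    def test_needs_three_cycles(self, quiet_analysis):
        with pytest.raises(TooFewStridesError):
            vg.cycle_ensemble(quiet_analysis.nav,
                              quiet_analysis.peak_times[:3])


class TestWalkSummary:
    def test_gait_velocity_matches_generator_speed(self, noisy_walk):
        _, analyses = noisy_walk
        for leg in ("left", "right"):
            assert analyses[leg].summary.gait_velocity == pytest.approx(
                1.11, rel=0.03)

    def test_zero_variability_event_variance_zero(self, quiet_analysis):
        assert quiet_analysis.summary.var_toeoff_time <= 1e-12
        assert quiet_analysis.summary.var_heelstrike_time <= 1e-12

    def test_event_variance_grows_with_stride_cv(self, control_params):
        var = {}
        for cv in (0.02, 0.10):
            cfg = vg.SimulationConfig(noise_sd=0.0, stride_time_cv=cv,
                                      amplitude_cv=0.0, seed=17)
            series = vg.simulate_leg(control_params, 40, cfg)
            a = vg.analyze_series(series, 88.8, with_spectrum=False)
            var[cv] = a.summary.var_toeoff_time
        assert var[0.10] > var[0.02]

    def test_too_few_cycles_rejected(self):
        with pytest.raises(TooFewStridesError):
            vg.summarize_leg([], 88.8, "left")
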
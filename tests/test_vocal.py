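"""Vocal pipeline: cents scale, segmentation, classification, measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import faflab as fl
from faflab.vocal import (VocalEpoch, VocalMeasureConfig, _epoch_sample_counts,
                          measure_trial_matrix)


def make_epoch(values, fs=100.0, trial_id="t0"):
    n_base, n_resp = _epoch_sample_counts(fs)
    times = (np.arange(-n_base, n_resp) / fs) * 1000.0
    assert len(values) == times.size
    return VocalEpoch(trial_id, times, np.asarray(values, dtype=float))


class TestCentsScale:
    @pytest.mark.parametrize("hz,expected,tol", [
        (195.997, 0.0, 1e-9),                       # the reference itself
        (195.997 * 2 ** (1 / 12), 100.0, 1e-6),     # one semitone up
        (220.0, 200.0, 0.05),                       # independent hand value
        (195.997 * 2.0, 1200.0, 1e-6),              # one octave
    ])
    def test_known_conversions(self, hz, expected, tol):
        assert fl.hz_to_cents(hz) == pytest.approx(expected, abs=tol)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fl.hz_to_cents(0.0)
        with pytest.raises(ValueError):
            fl.hz_to_cents(-100.0)

    def test_nan_passes_through(self):
        out = fl.hz_to_cents(np.array([200.0, np.nan]))
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-2400, max_value=2400))
    def test_round_trip_identity(self, cents):
        assert fl.hz_to_cents(fl.cents_to_hz(cents)) == pytest.approx(cents, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=60.0, max_value=500.0),
           st.floats(min_value=1e-3, max_value=50.0))
    def test_strictly_increasing(self, hz, delta):
        assert fl.hz_to_cents(hz + delta) > fl.hz_to_cents(hz)


class TestF0Estimation:
    def test_pure_sine_recovered(self):
        fs = 16000.0
        t = np.arange(int(fs)) / fs
        tr = fl.estimate_f0(np.sin(2 * np.pi * 200.0 * t), fs)
        voiced = tr.values[np.isfinite(tr.values)]
        assert voiced.size > 50
        assert np.all(np.abs(voiced - 200.0) < 0.5)

    def test_reference_tone(self):
        fs = 16000.0
        t = np.arange(int(fs)) / fs
        tr = fl.estimate_f0(np.sin(2 * np.pi * 195.997 * t), fs)
        voiced = tr.values[np.isfinite(tr.values)]
        assert np.all(np.abs(voiced - 195.997) < 0.5)

    def test_silence_all_missing(self):
        with pytest.warns(UserWarning, match="silent"):
            tr = fl.estimate_f0(np.zeros(16000), 16000.0)
        assert np.all(~np.isfinite(tr.values))

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="8 kHz"):
            fl.estimate_f0(np.zeros(100), 4000.0)


class TestSegmentation:
    def make_trace(self, dur_s=3.0, fs=100.0, value=10.0):
        n = int(dur_s * fs)
        return fl.F0Trace(np.arange(n) / fs, np.full(n, value), "cents", fs)

    def test_epoch_window_and_counts(self):
        tr = self.make_trace()
        eps = fl.segment_vocal_trials(tr, [{"trial_id": "a", "onset_s": 1.6}])
        assert len(eps) == 1
        e = eps[0]
        # [-0.2, 0.7) s at 10 ms spacing: 20 baseline + 70 response frames
        assert e.times_ms.size == 90
        assert np.sum(e.times_ms < 0) == 20
        assert e.times_ms[0] == -200.0 and e.times_ms[-1] == 690.0

    def test_event_near_edge_is_bad(self):
        tr = self.make_trace()
        eps = fl.segment_vocal_trials(tr, [{"trial_id": "a", "onset_s": 0.1}])
        assert eps[0].label == "bad"
        assert "baseline" in eps[0].reason

    def test_one_epoch_per_event(self):
        tr = self.make_trace(dur_s=10.0)
        events = [{"trial_id": i, "onset_s": 1.0 + i} for i in range(8)]
        eps = fl.segment_vocal_trials(tr, events)
        assert len(eps) == 8 and all(e.label is None for e in eps)

    def test_hz_trace_rejected(self):
        tr = fl.F0Trace(np.arange(300) / 100.0, np.full(300, 200.0), "hz", 100.0)
        with pytest.raises(ValueError, match="cents"):
            fl.segment_vocal_trials(tr, [])


class TestClassification:
    def bump_epoch(self, amp, fs=100.0):
        n_base, n_resp = _epoch_sample_counts(fs)
        vals = np.zeros(n_base + n_resp)
        vals[n_base + 20 : n_base + 50] = amp     # 200-500 ms
        return make_epoch(vals)

    def test_upward_bump_compensatory_for_downward_shift(self):
        assert fl.classify_trial(self.bump_epoch(+20.0), -1) == "compensatory"

    def test_downward_deflection_following(self):
        assert fl.classify_trial(self.bump_epoch(-20.0), -1) == "following"

    def test_excess_missing_frames_bad(self):
        e = self.bump_epoch(20.0)
        e.values_cents[30:66] = np.nan            # 40% missing
        assert fl.classify_trial(e, -1) == "bad"
        assert "missing" in e.reason

    def test_outlier_excursion_bad(self):
        e = self.bump_epoch(20.0)
        e.values_cents[50] = 700.0                # beyond 600-cent bound
        assert fl.classify_trial(e, -1) == "bad"


class TestNormalizationAveraging:
    def test_constant_epoch_becomes_zero(self):
        e = fl.baseline_normalize(make_epoch(np.full(90, 30.0)))
        assert np.allclose(e.values_cents, 0.0)
        assert e.baseline_mean_cents == pytest.approx(30.0)

    def test_baseline_subtracted_from_post(self):
        vals = np.full(90, 10.0)
        vals[20:] = 25.0
        e = fl.baseline_normalize(make_epoch(vals))
        assert np.allclose(e.values_cents[20:], 15.0)

    def test_normalized_baseline_mean_is_zero(self, rng):
        e = fl.baseline_normalize(make_epoch(rng.normal(5, 3, 90)))
        assert np.mean(e.values_cents[e.times_ms < 0]) == pytest.approx(0.0, abs=1e-9)

    def test_empty_baseline_raises(self):
        e = make_epoch(np.full(90, 1.0))
        e.values_cents[:20] = np.nan
        with pytest.raises(ValueError, match="baseline"):
            fl.baseline_normalize(e)

    def test_average_of_identical_epochs(self):
        vals = np.concatenate([np.zeros(20), np.full(70, 12.0)])
        eps = [make_epoch(vals, trial_id=i) for i in range(3)]
        for e in eps:
            e.label = "compensatory"
        avg = fl.average_vocal_response(eps)
        assert avg.n_trials == 3
        assert np.allclose(avg.contour_cents, vals)

    def test_average_of_two_flat_responses(self):
        out = []
        for amp in (10.0, 30.0):
            vals = np.concatenate([np.zeros(20), np.full(70, amp)])
            e = make_epoch(vals)
            e.label = "compensatory"
            out.append(e)
        avg = fl.average_vocal_response(out)
        assert np.allclose(avg.contour_cents[20:], 20.0)

    def test_no_compensatory_epochs_flagged(self):
        e = make_epoch(np.zeros(90))
        e.label = "following"
        with pytest.warns(UserWarning, match="no-response"):
            avg = fl.average_vocal_response([e])
        assert avg.n_trials == 0

    def test_normalize_and_average_commute(self, rng):
        """Averaging then normalising equals normalising then averaging."""
        mats = rng.normal(10, 4, size=(5, 90))
        eps = [make_epoch(m, trial_id=i) for i, m in enumerate(mats)]
        for e in eps:
            e.label = "compensatory"
        a1 = fl.average_vocal_response(eps).contour_cents
        mean = mats.mean(axis=0)
        a2 = mean - mean[:20].mean()
        assert np.allclose(a1, a2, atol=1e-10)


class TestPeakMeasurement:
    def contour(self, vals):
        n_base = 20
        times = (np.arange(-n_base, 70) / 100.0) * 1000.0
        return fl.AveragedVocalResponse(times, np.asarray(vals, float), 10)

    def test_single_maximum(self):
        vals = np.zeros(90)
        vals[20 + 35] = 30.0                      # 350 ms
        mag, lat = fl.measure_vocal_peak(self.contour(vals))
        assert (mag, lat) == (30.0, 350.0)

    def test_monotone_rise_flags_edge_peak(self):
        vals = np.linspace(0, 50, 90)
        with pytest.warns(UserWarning, match="edge peak"):
            mag, lat = fl.measure_vocal_peak(self.contour(vals))
        assert lat == 690.0

    def test_plateau_tie_breaks_earliest(self):
        vals = np.zeros(90)
        vals[20 + 30 : 20 + 33] = 25.0            # equal maxima 300-320 ms
        _, lat = fl.measure_vocal_peak(self.contour(vals))
        assert lat == 300.0

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            fl.measure_vocal_peak(self.contour(np.zeros(90)),
                                  search_window_ms=(800.0, 900.0))


class TestBaselineVariability:
    def labelled(self, baselines):
        eps = []
        for i, b in enumerate(baselines):
            e = make_epoch(np.full(90, b), trial_id=i)
            e.label = "compensatory"
            eps.append(e)
        return eps

    def test_equal_baselines_zero(self):
        assert fl.baseline_variability(self.labelled([5.0] * 4)) == 0.0

    def test_hand_computed_sd(self):
        # SD of {-5, +5} with n-1 denominator: sqrt(2*25/1) = 7.0711
        assert fl.baseline_variability(self.labelled([-5.0, 5.0])) == \
            pytest.approx(7.0711, abs=1e-4)

    def test_single_epoch_undefined(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = fl.baseline_variability(self.labelled([3.0]))
        assert np.isnan(out)


class TestBatchConsistency:
    """The vectorised path must reproduce the per-epoch chain."""

    def test_matrix_matches_epochwise(self, rng):
        fs, T, n = 100.0, 300, 15
        cents = rng.normal(0, 5, (n, T))
        onset = rng.integers(150, 201, n)
        bump_cols = np.arange(10, 40)
        for i in range(n):
            cents[i, onset[i] + bump_cols] += 25.0
        res = measure_trial_matrix(cents, onset, fs, perturbation_sign=-1)

        tr_eps = []
        for i in range(n):
            tr = fl.F0Trace(np.arange(T) / fs, cents[i], "cents", fs)
            (ep,) = fl.segment_vocal_trials(
                tr, [{"trial_id": i, "onset_s": onset[i] / fs}])
            fl.classify_trial(ep, -1)
            tr_eps.append(ep)
        labels = [e.label for e in tr_eps]
        assert list(res["labels"]) == labels
        avg = fl.average_vocal_response(tr_eps)
        mag, lat = fl.measure_vocal_peak(avg)
        assert res["magnitude_cents"] == pytest.approx(mag, abs=1e-10)
        assert res["latency_ms"] == lat
        assert res["baseline_sd_cents"] == pytest.approx(
            fl.baseline_variability(tr_eps), abs=1e-10)

    def test_magnitude_invariant_to_absolute_pitch(self, noise_free_cohort):
        """Shifting a voice's register leaves cents-normalised output alone."""
        ds = noise_free_cohort
        s = ds.subjects[0]
        block = ds.vocal[(s.subject_id, -200.0)]
        cents = fl.hz_to_cents(block["f0_hz"])
        r1 = measure_trial_matrix(cents, block["onset_idx"], 100.0, -1)
        r2 = measure_trial_matrix(cents + 700.0, block["onset_idx"], 100.0, -1)
        assert r1["magnitude_cents"] == pytest.approx(r2["magnitude_cents"], abs=1e-6)
        assert r1["latency_ms"] == r2["latency_ms"]
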
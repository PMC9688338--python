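"""Filter chain, referencing, global field power and event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gswnet import preprocess
from gswnet.preprocess import (
    EventList,
    GFPSeries,
    SensorRecording,
    apply_filter_chain,
    common_average_reference,
    detect_spike_events,
    extract_epochs,
    global_field_power,
    select_rs_epochs,
)

FS = 256.0


def _sine_rec(freq, fs=FS, dur=10.0, n_ch=4, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return SensorRecording(np.tile(amp * np.sin(2 * np.pi * freq * t),
                                   (n_ch, 1)), fs)


class TestFilterChain:
    def test_zero_input_gives_zero_output(self):
        rec = SensorRecording(np.zeros((4, 1024)), FS)
        assert np.allclose(apply_filter_chain(rec).data, 0.0)

    def test_passband_10hz_rms_within_5_percent(self):
        rec = _sine_rec(10.0)
        out = apply_filter_chain(rec)
        sl = slice(512, -512)  # steady state away from edges
        rms_in = np.sqrt(np.mean(rec.data[:, sl] ** 2))
        rms_out = np.sqrt(np.mean(out.data[:, sl] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_50hz_notch_attenuates_30db(self):
        rec = _sine_rec(50.0)
        out = apply_filter_chain(rec)
        sl = slice(512, -512)
        p_in = np.mean(rec.data[:, sl] ** 2)
        p_out = np.mean(out.data[:, sl] ** 2)
        assert 10 * np.log10(p_in / p_out) >= 30.0

    def test_low_fs_skips_second_notch_with_warning(self):
        rec = SensorRecording(np.random.default_rng(0).normal(size=(2, 512)),
                              200.0)
        with pytest.warns(UserWarning, match="97-103"):
            apply_filter_chain(rec)

    def test_linearity(self, rng):
        a = _sine_rec(5.0)
        b = _sine_rec(12.0)
        summed = SensorRecording(a.data + b.data, FS)
        lhs = apply_filter_chain(summed).data
        rhs = apply_filter_chain(a).data + apply_filter_chain(b).data
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_nonfinite_input_rejected(self):
        data = np.zeros((2, 100))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            SensorRecording(data, FS)


class TestCommonAverageReference:
    def test_two_channel_example(self):
        rec = SensorRecording(np.array([[1.0, 1.0], [3.0, 3.0]]), FS)
        out = common_average_reference(rec)
        assert np.allclose(out.data, [[-1, -1], [1, 1]])

    def test_column_means_zero(self, rng):
        rec = SensorRecording(rng.normal(size=(19, 500)), FS)
        out = common_average_reference(rec)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        rec = SensorRecording(rng.normal(size=(7, 200)), FS)
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(SensorRecording(np.ones((1, 10)), FS))


class TestGlobalFieldPower:
    @pytest.mark.parametrize("field,expected", [
        ([3.0, 3.0, 3.0], 0.0),
        ([1.0, -1.0], 1.0),
        ([2.0, 0.0, -2.0, 0.0], np.sqrt(2.0)),
    ])
    def test_single_sample_values(self, field, expected):
        rec = SensorRecording(np.array(field)[:, None], FS)
        assert global_field_power(rec).values[0] == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-100, 100, allow_nan=False))
    def test_reference_invariance(self, offset):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(19, 40))
        a = global_field_power(SensorRecording(data, FS)).values
        b = global_field_power(SensorRecording(data + offset, FS)).values
        assert np.allclose(a, b, atol=1e-10)


class TestDetectSpikeEvents:
    def test_flat_gfp_gives_no_events(self):
        gfp = GFPSeries(np.ones(1000), FS)
        assert len(detect_spike_events(gfp)) == 0

    def test_ramp_midpoint(self):
        vals = np.zeros(300)
        vals[100:121] = np.linspace(0.0, 1.0, 21)
        vals[121:141] = np.linspace(1.0, 0.0, 21)[1:]
        ev = detect_spike_events(GFPSeries(vals, FS), min_prominence=0.5)
        assert list(ev) == [110]

    def test_refractory_keeps_larger_peak(self):
        vals = np.zeros(600)
        vals[100:111] = np.linspace(0, 1.0, 11)
        vals[111:121] = np.linspace(1.0, 0, 11)[1:]
        vals[115:126] = np.linspace(0, 2.0, 11)
        vals[126:136] = np.linspace(2.0, 0, 11)[1:]
        ev = detect_spike_events(GFPSeries(vals, FS), min_prominence=0.5,
                                 refractory=0.5)
        assert len(ev) == 1

    def test_cohort_events_within_two_samples(self, small_cohort):
        """Planted spike midpoints are recovered nearly exactly."""
        _, recordings, truths, _ = small_cohort
        for rec, truth in zip(recordings, truths):
            filt = common_average_reference(apply_filter_chain(rec))
            ev = np.array(list(detect_spike_events(
                global_field_power(filt))))
            for t in truth.spike_event_samples:
                assert np.min(np.abs(ev - t)) <= 2


class TestEpochs:
    def test_epoch_window_arithmetic(self):
        rec = SensorRecording(np.arange(19 * 2048, dtype=float
                                        ).reshape(19, 2048), FS)
        es = extract_epochs(rec, EventList(np.array([512])))
        assert es.data.shape == (1, 19, 1024)
        assert np.allclose(es.data[0], rec.data[:, 0:1024])

    def test_train_merges_to_first_spike(self):
        rec = SensorRecording(np.zeros((3, 4096)), FS)
        es = extract_epochs(rec, EventList(np.array([1024, 1280])))
        assert es.n_epochs == 1 and es.events[0] == 1024

    def test_no_events_empty_set(self):
        rec = SensorRecording(np.zeros((3, 2048)), FS)
        es = extract_epochs(rec, EventList(np.array([], dtype=int)))
        assert es.n_epochs == 0

    def test_out_of_bounds_event_skipped(self):
        rec = SensorRecording(np.zeros((3, 2048)), FS)
        with pytest.warns(UserWarning, match="out of bounds"):
            es = extract_epochs(rec, EventList(np.array([100])))
        assert es.n_epochs == 0

    def test_rs_count_matches_and_disjoint_from_events(self, small_cohort):
        cfg, recordings, truths, _ = small_cohort
        rec, truth = recordings[0], truths[0]
        events = EventList(truth.burst_event_samples)
        gsw = extract_epochs(rec, events)
        rs = select_rs_epochs(rec, events, n=gsw.n_epochs, seed=3)
        assert rs.n_epochs == gsw.n_epochs
        half = int(2 * rec.fs)
        win = int(4 * rec.fs)
        for start in rs.events:
            for e in events:
                assert start + win <= e - half or start >= e + half

    def test_rs_zero_request(self):
        rec = SensorRecording(np.zeros((3, 4096)), FS)
        rs = select_rs_epochs(rec, EventList(np.array([], dtype=int)), n=0)
        assert rs.n_epochs == 0

    def test_rs_insufficient_data_raises(self):
        rec = SensorRecording(np.zeros((3, 2000)), FS)
        with pytest.raises(ValueError, match="insufficient"):
            select_rs_epochs(rec, EventList(np.array([1000])), n=3)

    def test_rs_deterministic_under_seed(self, small_cohort):
        _, recordings, truths, _ = small_cohort
        rec = recordings[0]
        events = EventList(truths[0].burst_event_samples)
        a = select_rs_epochs(rec, events, n=3, seed=5)
        b = select_rs_epochs(rec, events, n=3, seed=5)
        assert np.array_equal(a.events, b.events)


def test_artifact_rejector_drops_large_epochs():
    data = np.zeros((2, 3, 100))
    data[1, 0, 50] = 500.0
    es = preprocess.EpochSet(data, FS, "GSW", np.array([10, 20]))
    kept = preprocess.reject_artifact_epochs(es, max_abs=300.0)
    assert kept.n_epochs == 1 and kept.events[0] == 10
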
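"""Synthetic cohort generator: waveform, coupling, lead field, determinism."""

import numpy as np
import pytest

from gswnet import connectivity, preprocess, syndata
from gswnet.syndata import (
    SynthConfig,
    generate_lead_field,
    make_spike_wave_template,
    synthesize_cohort,
    synthesize_coupled_sources,
)


class TestSpikeWaveTemplate:
    def test_zero_amplitude_gives_zero_waveform(self):
        w = make_spike_wave_template(256, 4, 2, 0.0)
        assert np.allclose(w, 0.0)

    def test_length_and_peak_position(self):
        w = make_spike_wave_template(256, 4, 1, 1.0)
        assert w.size == 64
        assert np.argmax(w) < 0.25 * w.size
        assert w.max() == pytest.approx(1.0)

    def test_dominant_frequency_at_repetition_rate(self):
        w = make_spike_wave_template(256, 3, 3, 1.0)
        spec = np.abs(np.fft.rfft(w))
        freqs = np.fft.rfftfreq(w.size, 1 / 256)
        peak = freqs[1:][np.argmax(spec[1:])]  # DC excluded
        assert abs(peak - 3.0) <= freqs[1]  # within one FFT bin

    def test_one_sharp_peak_per_cycle(self):
        w = make_spike_wave_template(256, 4, 3, 1.0)
        cycle = 64
        for c in range(3):
            seg = w[c * cycle:(c + 1) * cycle]
            assert np.sum(seg > 0.9) <= 3  # narrow spike apex only

    @pytest.mark.parametrize("kwargs", [
        dict(fs=256, f_sw=-1, n_cycles=1, amplitude=1.0),
        dict(fs=256, f_sw=4, n_cycles=1, amplitude=-1.0),
        dict(fs=10, f_sw=4, n_cycles=1, amplitude=1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_spike_wave_template(**kwargs)


class TestCoupledSources:
    def test_no_edges_gives_near_zero_imcoh(self):
        x, _ = synthesize_coupled_sources(4, [], 0.0, 4.0, 256, 60.0, 1.0,
                                          seed=5)
        im = connectivity.imaginary_coherence_matrix(x[None], 256)
        iu = np.triu_indices(4, 1)
        assert np.mean(np.abs(im[3][iu])) < 0.1

    def test_quarter_cycle_lag_fully_coherent(self):
        x, _ = synthesize_coupled_sources(2, [(0, 1)], np.pi / 2, 4.0, 256,
                                          60.0, 0.0, seed=5)
        im = connectivity.imaginary_coherence_matrix(x[None], 256)
        assert abs(im[3, 0, 1]) > 0.95

    def test_zero_lag_invisible_to_imcoh(self):
        x, _ = synthesize_coupled_sources(2, [(0, 1)], 1e-9, 4.0, 256,
                                          60.0, 0.1, seed=5)
        im = connectivity.imaginary_coherence_matrix(x[None], 256)
        assert abs(im[3, 0, 1]) < 0.1

    def test_determinism(self):
        a, _ = synthesize_coupled_sources(3, [(0, 2)], 1.0, 5.0, 256, 10.0,
                                          0.5, seed=9)
        b, _ = synthesize_coupled_sources(3, [(0, 2)], 1.0, 5.0, 256, 10.0,
                                          0.5, seed=9)
        assert np.array_equal(a, b)

    def test_zero_phase_lag_warns(self):
        with pytest.warns(UserWarning, match="invisible"):
            synthesize_coupled_sources(2, [(0, 1)], 0.0, 4.0, 256, 2.0, 0.0)

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            synthesize_coupled_sources(3, [(1, 1)], 1.0, 4.0, 256, 2.0, 0.0)


class TestLeadField:
    def test_shape_and_rank(self):
        lf = generate_lead_field(19, 60, seed=4)
        assert lf.gain.shape == (19, 60)
        assert np.linalg.matrix_rank(lf.gain) == 19

    def test_column_norms_order_one(self):
        lf = generate_lead_field(19, 60, seed=4)
        norms = np.linalg.norm(lf.gain, axis=0)
        assert np.all((norms >= 0.5) & (norms <= 2.0))

    def test_deterministic(self):
        a = generate_lead_field(10, 20, seed=2)
        b = generate_lead_field(10, 20, seed=2)
        assert np.array_equal(a.gain, b.gain)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            generate_lead_field(1, 5)


class TestCohort:
    def test_null_cohort_has_no_detectable_events(self):
        cfg = SynthConfig(n_subjects=1, n_gsw_epochs_per_subject=0, seed=2)
        recs, truths, _ = synthesize_cohort(cfg)
        assert truths[0].burst_event_samples.size == 0
        filt = preprocess.common_average_reference(
            preprocess.apply_filter_chain(recs[0]))
        ev = preprocess.detect_spike_events(
            preprocess.global_field_power(filt))
        assert len(ev) == 0

    def test_default_event_count_and_spacing(self):
        cfg = SynthConfig(seed=6)
        _, truths, _ = synthesize_cohort(cfg)
        total = sum(t.burst_event_samples.size for t in truths)
        assert total == 23 * 5
        for t in truths:
            gaps = np.diff(t.burst_event_samples) / cfg.fs
            assert np.all(gaps >= 4.0)

    def test_bit_identical_under_same_config(self):
        cfg = SynthConfig(n_subjects=2, seed=3)
        a, _, lfa = synthesize_cohort(cfg)
        b, _, lfb = synthesize_cohort(SynthConfig(n_subjects=2, seed=3))
        assert np.array_equal(lfa.gain, lfb.gain)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_noiseless_gsw_segment_spectrum_peaks_at_fsw(self):
        """The sensor signal of a noiseless discharge has its spectral
        maximum at the spike-wave repetition rate."""
        cfg = SynthConfig(n_subjects=1, seed=4, noise_sd=0.0,
                          alpha_amplitude=0.0, sensor_noise_sd=0.0,
                          coupling_gain=0.0)
        recs, truths, _ = synthesize_cohort(cfg)
        rec, truth = recs[0], truths[0]
        b = truth.burst_event_samples[0]
        burst_len = int(cfg.n_cycles_per_burst * cfg.fs / cfg.f_sw)
        seg = rec.data[:, b:b + burst_len]
        ch = int(np.argmax(np.sum(seg ** 2, axis=1)))
        spec = np.abs(np.fft.rfft(seg[ch] - seg[ch].mean(), n=4096))
        freqs = np.fft.rfftfreq(4096, 1 / cfg.fs)
        band = (freqs >= 1) & (freqs <= 30)
        peak = freqs[band][np.argmax(spec[band])]
        assert abs(peak - cfg.f_sw) <= 0.5

    def test_invalid_planted_edge_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_sources=4, planted_edges=[(0, 9)])


def test_weighted_small_world_preserves_weight_multiset():
    W = syndata.weighted_small_world(30, 4, 0.2, seed=1)
    W0 = syndata.weighted_small_world(30, 4, 0.0, seed=1)
    assert np.allclose(np.sort(W[W > 0]), np.sort(W0[W0 > 0]))
    assert np.allclose(W, W.T)
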
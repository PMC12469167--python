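import numpy as np
import pytest

from conftest import gaussian_pulse, make_waveform
from mngsort.preprocessing import (
    ALIGN_INDEX,
    AlignmentError,
    BoundaryError,
    ParameterError,
    align,
    build_waterfall,
    compute_template,
    differentiate,
    extract_aligned_waveforms,
    extract_window,
    resample_to_60,
)
from mngsort.recording import Recording, SpikeEvent
from mngsort.synthetic import SyntheticConfig, generate_recording


class TestExtractWindow:
    def test_ten_khz_window_is_thirty_samples_around_t(self):
        rec = Recording(signal=np.arange(10000, dtype=float), fs=10000.0)
        w = extract_window(rec, 0.5)  # sample 5000
        assert len(w) == 30
        np.testing.assert_array_equal(w, np.arange(4985, 5015))

    def test_thirty_khz_window_is_sixty_samples(self):
        rec = Recording(signal=np.zeros(30000), fs=30000.0)
        assert len(extract_window(rec, 0.5)) == 60

    def test_zero_signal_gives_zero_window(self):
        rec = Recording(signal=np.zeros(10000), fs=10000.0)
        assert not np.any(extract_window(rec, 0.5))

    def test_boundary_error_near_end(self):
        rec = Recording(signal=np.zeros(10000), fs=10000.0)
        with pytest.raises(BoundaryError):
            extract_window(rec, (10000 - 14) / 10000.0)


class TestResample:
    def test_constant_window(self):
        out = resample_to_60(np.full(30, 2.5))
        assert len(out) == 60
        np.testing.assert_allclose(out, 2.5)

    def test_sinusoid_frequency_preserved(self):
        # period 10 samples at the original rate -> period 20 at 60 points
        x30 = np.sin(2 * np.pi * np.arange(30) / 10)
        out = resample_to_60(x30)
        expect = np.sin(2 * np.pi * np.arange(60) / 20)
        np.testing.assert_allclose(out, expect, atol=1e-6)

    def test_sixty_sample_identity(self):
        x = np.random.default_rng(0).normal(size=60)
        np.testing.assert_array_equal(resample_to_60(x), x)

    def test_other_lengths_rejected(self):
        with pytest.raises(ParameterError):
            resample_to_60(np.zeros(40))


class TestDifferentiate:
    def test_linear_ramp(self):
        fd, sd = differentiate(3.0 * np.arange(60))
        np.testing.assert_allclose(fd, 3.0)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_constant(self):
        fd, sd = differentiate(np.full(60, 7.0))
        assert not np.any(fd) and not np.any(sd)

    def test_quadratic_second_derivative(self):
        i = np.arange(60, dtype=float)
        fd, sd = differentiate(i**2)
        # central-difference oracle: d2(i^2)/di2 = 2 in the interior
        np.testing.assert_allclose(sd[2:-2], 2.0, atol=1e-9)


class TestAlign:
    def test_idempotent_when_already_aligned(self):
        w = gaussian_pulse(3.0, center=27.0)  # fd min lands at 30 for sigma 3
        a1 = align(w)
        a2 = align(a1.samples)
        np.testing.assert_array_equal(a1.samples, a2.samples)
        assert a1.align_index == ALIGN_INDEX

    def test_shift_moves_fd_minimum_to_center(self):
        w = gaussian_pulse(3.0, center=22.0)  # fd min at 25
        fd0, _ = differentiate(w)
        assert np.argmin(fd0) == 25
        out = align(w)
        assert int(np.argmin(out.fd)) == ALIGN_INDEX
        # zero-pad shift: content moved right by 5
        np.testing.assert_allclose(out.samples[5:], w[:-5])

    def test_circular_shift_preserves_sample_multiset(self):
        w = gaussian_pulse(3.0, center=20.0)
        out = align(w, circular=True)
        np.testing.assert_allclose(np.sort(out.samples), np.sort(w))

    def test_constant_window_has_no_negative_peak(self):
        with pytest.raises(AlignmentError):
            align(np.full(60, 1.0))

    def test_wrong_length_rejected(self):
        with pytest.raises(ParameterError):
            align(np.zeros(30))


class TestComputeTemplate:
    def test_single_waveform_identity(self):
        w = make_waveform(gaussian_pulse(3.0))
        t = compute_template([w])
        np.testing.assert_array_equal(t.values, w.samples)
        assert t.n_spikes == 1

    def test_opposite_waveforms_cancel(self):
        v = gaussian_pulse(3.0)
        t = compute_template([make_waveform(v), make_waveform(-v)])
        np.testing.assert_allclose(t.values, 0.0, atol=1e-15)

    def test_commutes_with_scaling(self, two_fiber_waveforms):
        ws = [w for w in two_fiber_waveforms if w.track == "Track1"][:10]
        t1 = compute_template(ws)
        scaled = [make_waveform(3.0 * w.samples, track=w.track) for w in ws]
        t3 = compute_template(scaled)
        np.testing.assert_allclose(t3.values, 3.0 * t1.values, rtol=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ParameterError):
            compute_template([])

    def test_mixed_tracks_rejected(self):
        with pytest.raises(ParameterError):
            compute_template([make_waveform(gaussian_pulse(3), "a"),
                              make_waveform(gaussian_pulse(3), "b")])


class TestWaterfall:
    def test_zero_jitter_latencies_constant(self):
        rec = generate_recording(SyntheticConfig(
            n_sweeps=10, latency_jitter_sd_ms=0.0, noise_sd=0.0, seed=0))
        wf = build_waterfall(rec)
        per_track = {}
        for sweep in wf.sweeps:
            for lat, track in sweep.spike_latencies:
                per_track.setdefault(track, []).append(lat)
        for lats in per_track.values():
            assert max(lats) - min(lats) < 1e-9

    def test_ads_raises_latency_then_decays(self):
        rec = generate_recording(SyntheticConfig(
            n_sweeps=12, latency_jitter_sd_ms=0.0, noise_sd=0.0,
            extra_stimulus_schedule=((5, 2),), seed=0))
        wf = build_waterfall(rec)
        track1 = [
            next(l for l, tr in s.spike_latencies if tr == "Track1")
            for s in wf.sweeps
        ]
        assert track1[6] > track1[5]
        tail = track1[6:]
        assert all(a > b for a, b in zip(tail, tail[1:]))  # monotone recovery
        assert tail[-1] > track1[0]  # still above base while recovering

    def test_no_spikes_gives_empty_latency_lists(self):
        rec = Recording(signal=np.zeros(1000), fs=100.0,
                        stimulus_onsets=np.array([1.0, 5.0]))
        wf = build_waterfall(rec)
        assert len(wf.sweeps) == 2
        assert all(s.spike_latencies == () for s in wf.sweeps)

    def test_spike_before_first_onset_warns(self):
        rec = Recording(signal=np.zeros(1000), fs=100.0,
                        stimulus_onsets=np.array([5.0]),
                        spikes=(SpikeEvent(1.0, "Track1"),))
        with pytest.warns(UserWarning, match="precedes"):
            build_waterfall(rec)

    def test_requires_an_onset(self, two_fiber_recording):
        rec = two_fiber_recording.with_(stimulus_onsets=np.empty(0), spikes=())
        with pytest.raises(ParameterError):
            build_waterfall(rec)


class TestExclusionAccounting:
    def test_conservation_with_boundary_spike(self):
        cfg = SyntheticConfig(n_sweeps=5, seed=3)
        rec = generate_recording(cfg)
        # inject a labeled spike right at the signal edge (boundary) and
        # leave the flat tail as-is so it is excluded, not padded
        edge = rec.t0 + (len(rec.signal) - 2) / rec.fs
        rec = rec.with_(spikes=rec.spikes + (SpikeEvent(edge, "Track1"),))
        waveforms, exclusions = extract_aligned_waveforms(rec)
        assert len(waveforms) + len(exclusions) == len(rec.labeled_spikes)
        assert [r for _, r in exclusions] == ["boundary"]
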
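import numpy as np
import pandas as pd
import pytest
import h5py

from mngsort.io import (
    read_recording,
    read_recording_csv,
    write_recording,
    write_recording_csv,
)
from mngsort.recording import (
    DIALECT_A,
    DIALECT_B,
    DIALECT_GENERIC,
    DialectSpec,
    FormatError,
    Recording,
    SpikeEvent,
    ValidationError,
    apply_dialect,
)
from mngsort.synthetic import SyntheticConfig, generate_recording


def assert_recordings_equal(a: Recording, b: Recording, tol=1e-9):
    np.testing.assert_allclose(a.signal, b.signal, atol=tol)
    assert a.fs == pytest.approx(b.fs, abs=tol)
    assert a.t0 == pytest.approx(b.t0, abs=tol)
    np.testing.assert_allclose(a.stimulus_onsets, b.stimulus_onsets, atol=tol)
    assert len(a.spikes) == len(b.spikes)
    for ea, eb in zip(a.spikes, b.spikes):
        assert ea.time == pytest.approx(eb.time, abs=tol)
        assert ea.track == eb.track
    assert a.meta == b.meta


class TestModelInvariants:
    def test_rejects_nan_signal(self):
        with pytest.raises(ValidationError):
            Recording(signal=np.array([0.0, np.nan]), fs=10000.0)

    def test_rejects_nonmonotonic_onsets(self):
        with pytest.raises(ValidationError):
            Recording(signal=np.zeros(100), fs=100.0,
                      stimulus_onsets=np.array([0.5, 0.2]))

    def test_rejects_spike_outside_span(self):
        with pytest.raises(ValidationError):
            Recording(signal=np.zeros(100), fs=100.0,
                      spikes=(SpikeEvent(time=5.0),))

    def test_dialect_consistency_enforced(self):
        with pytest.raises(ValidationError):
            DialectSpec(name="B", polarity_invert=False)
        with pytest.raises(ValidationError):
            DialectSpec(name="A", pad_gaps=False)


class TestHdf5RoundTrip:
    def test_minimal_container(self, tmp_path):
        rec = Recording(
            signal=np.zeros(10000), fs=10000.0,
            stimulus_onsets=np.array([0.1, 0.5]),
            spikes=(SpikeEvent(0.3, "Track1"), SpikeEvent(0.7, "Track2")),
        )
        p = tmp_path / "rec.h5"
        write_recording(rec, p)
        back = read_recording(p)
        assert len(back.signal) == 10000
        assert len(back.spikes) == 2

    def test_synthetic_round_trip(self, tmp_path):
        rec = generate_recording(SyntheticConfig(n_sweeps=5, seed=11))
        p = tmp_path / "rec.h5"
        write_recording(rec, p)
        assert_recordings_equal(rec, read_recording(p))

    def test_empty_spike_table(self, tmp_path):
        rec = Recording(signal=np.zeros(100), fs=100.0)
        p = tmp_path / "rec.h5"
        write_recording(rec, p)
        assert read_recording(p).spikes == ()

    def test_missing_spike_table_is_format_error(self, tmp_path):
        p = tmp_path / "broken.h5"
        with h5py.File(p, "w") as f:
            f.create_group("signal").create_dataset("data", data=np.zeros(10))
        with pytest.raises(FormatError, match="signal/fs|spikes"):
            read_recording(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_recording(tmp_path / "nope.h5")


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        rec = generate_recording(SyntheticConfig(n_sweeps=3, seed=2))
        write_recording_csv(rec, tmp_path / "rec")
        back = read_recording_csv(tmp_path / "rec")
        np.testing.assert_allclose(rec.signal, back.signal, atol=1e-9)
        assert [e.track for e in rec.spikes] == [e.track for e in back.spikes]

    def test_missing_part(self, tmp_path):
        (tmp_path / "rec").mkdir()
        with pytest.raises(FormatError, match="signal.csv"):
            read_recording_csv(tmp_path / "rec")


class TestApplyDialect:
    def test_generic_is_identity(self, two_fiber_recording):
        out = apply_dialect(two_fiber_recording, DIALECT_GENERIC)
        assert out is two_fiber_recording

    def test_b_window_one_is_pure_negation(self):
        rec = Recording(signal=np.array([1.0, -2.0, 3.0]), fs=10.0)
        out = apply_dialect(rec, DialectSpec("B", polarity_invert=True,
                                             smoothing_window=1))
        np.testing.assert_array_equal(out.signal, [-1.0, 2.0, -3.0])

    def test_b_window_three_matches_hand_rolled_mean(self):
        sig = np.array([1.0, -2.0, 3.0])
        rec = Recording(signal=sig, fs=10.0)
        out = apply_dialect(rec, DIALECT_B)
        # centered rolling mean of the negated signal (pandas convention)
        expect = pd.Series(-sig).rolling(3, center=True, min_periods=1).mean()
        np.testing.assert_allclose(out.signal, expect.to_numpy())

    def test_b_preserves_length_and_fs(self, two_fiber_recording):
        out = apply_dialect(two_fiber_recording, DIALECT_B)
        assert len(out.signal) == len(two_fiber_recording.signal)
        assert out.fs == two_fiber_recording.fs

    def test_b_window_longer_than_signal(self):
        rec = Recording(signal=np.zeros(2), fs=10.0)
        with pytest.raises(ValidationError):
            apply_dialect(rec, DialectSpec("B", polarity_invert=True,
                                           smoothing_window=5))

    def test_a_pads_declared_gaps_with_zeros(self):
        rec = Recording(signal=np.ones(100), fs=100.0, gaps=((0.5, 0.6),))
        out = apply_dialect(rec, DIALECT_A)
        assert len(out.signal) == 110
        np.testing.assert_array_equal(out.signal[50:60], np.zeros(10))
        assert out.gaps == ()

    def test_gap_round_trips_through_container(self, tmp_path):
        rec = Recording(signal=np.ones(100), fs=100.0, gaps=((0.2, 0.3),))
        write_recording(rec, tmp_path / "g.h5")
        out = read_recording(tmp_path / "g.h5", DIALECT_A)
        assert len(out.signal) == 110
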
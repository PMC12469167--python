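"""Harmonized recording data model.

A microneurography session is reduced to the minimal unit of analysis used
throughout the package: one continuous single-channel voltage trace, the
onsets of the low-frequency background electrical stimulation, and the
spike events that were time-locked ("tracked") via the marking method.
Each tracked spike carries the label of the C-fiber track it belongs to;
those labels are the ground truth every evaluation in this package is
scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Track label carried by spikes that were detected but never assigned to a
#: fiber track. They survive I/O round trips but are excluded from every
#: evaluation (only tracked spikes have ground truth).
UNLABELED = "__unlabeled__"


class ValidationError(ValueError):
    """A Recording (or one of its fields) violates a model invariant."""


class FormatError(ValueError):
    """A container on disk is missing a required group or field."""


@dataclass(frozen=True)
class SpikeEvent:
    """One spike: occurrence time in seconds and its fiber-track label."""

    time: float
    track: str = UNLABELED

    def __post_init__(self) -> None:
        if not np.isfinite(self.time):
            raise ValidationError(f"spike time must be finite, got {self.time}")
        if not self.track:
            raise ValidationError("track label must be non-empty; use UNLABELED")

    @property
    def labeled(self) -> bool:
        return self.track != UNLABELED


@dataclass(frozen=True)
class DialectSpec:
    """Lab-dialect corrections applied when harmonizing a recording.

    Two acquisition chains feed this pipeline. Lab dialect ``B`` (30 kHz
    system) records with inverted voltage polarity, so its signal is negated
    and then smoothed with a centered rolling mean. Lab dialect ``A``
    (10 kHz system) occasionally drops short stretches of signal during
    acquisition; the declared gaps are padded with zeros so the time base
    stays uniform. ``generic`` applies no correction.
    """

    name: str = "generic"
    polarity_invert: bool = False
    smoothing_window: int = 1
    pad_gaps: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("A", "B", "generic"):
            raise ValidationError(f"unknown dialect {self.name!r}")
        if self.smoothing_window < 1:
            raise ValidationError("smoothing_window must be >= 1")
        if self.name == "B" and not self.polarity_invert:
            raise ValidationError("dialect B implies polarity inversion")
        if self.name == "A" and not self.pad_gaps:
            raise ValidationError("dialect A implies gap padding")


DIALECT_A = DialectSpec(name="A", pad_gaps=True)
DIALECT_B = DialectSpec(name="B", polarity_invert=True, smoothing_window=3)
DIALECT_GENERIC = DialectSpec()


@dataclass(frozen=True)
class Recording:
    """One harmonized recording.

    Parameters
    ----------
    signal : ndarray of float64
        Continuous voltage trace in volts, uniform sampling.
    fs : float
        Sampling rate in Hz (10 kHz and 30 kHz are the expected rates).
    t0 : float
        Time of the first sample in seconds. Sample ``i`` covers the
        half-open interval ``[t0 + i/fs, t0 + (i+1)/fs)``.
    stimulus_onsets : ndarray of float64
        Background-stimulation onset times in seconds, strictly increasing.
    spikes : tuple of SpikeEvent
        Tracked (and possibly untracked) spike events.
    gaps : tuple of (float, float)
        Acquisition gaps as (start, end) second pairs, present only before
        dialect-A padding has been applied.
    meta : dict of str -> str
        Free-form metadata (dataset id, lab dialect, ...).
    """

    signal: np.ndarray
    fs: float
    t0: float = 0.0
    stimulus_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    spikes: tuple = ()
    gaps: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=np.float64))
        object.__setattr__(
            self, "stimulus_onsets", np.asarray(self.stimulus_onsets, dtype=np.float64)
        )
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.signal.ndim != 1:
            raise ValidationError("signal must be one-dimensional")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite values")
        if self.stimulus_onsets.size and np.any(np.diff(self.stimulus_onsets) <= 0):
            raise ValidationError("stimulus onsets must be strictly increasing")
        end = self.t0 + len(self.signal) / self.fs
        for ev in self.spikes:
            if not (self.t0 <= ev.time <= end):
                raise ValidationError(
                    f"spike at {ev.time} s outside recording span [{self.t0}, {end}]"
                )

    # -- convenience -----------------------------------------------------
    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.signal) / self.fs

    @property
    def labeled_spikes(self) -> tuple:
        return tuple(ev for ev in self.spikes if ev.labeled)

    @property
    def tracks(self) -> tuple:
        """Sorted distinct track labels of the labeled spikes."""
        return tuple(sorted({ev.track for ev in self.labeled_spikes}))

    def sample_index(self, t: float) -> int:
        """Index of the sample whose half-open interval contains time ``t``."""
        return int(np.floor((t - self.t0) * self.fs))

    def with_(self, **kw) -> "Recording":
        return replace(self, **kw)


def apply_dialect(rec: Recording, dialect: DialectSpec) -> Recording:
    """Apply lab-dialect corrections and return a new Recording.

    Dialect ``B``: the signal is negated (polarity fix) and smoothed with a
    centered rolling mean of ``smoothing_window`` samples (window 1 is a
    pure negation). Dialect ``A``: every declared acquisition gap is filled
    with zeros so downstream window extraction sees a uniform time base;
    spike and stimulus times are already on the wall clock and unchanged.
    ``generic`` is the identity.
    """
    if dialect.name == "generic":
        return rec
    if dialect.name == "B":
        if dialect.smoothing_window > len(rec.signal):
            raise ValidationError("smoothing window longer than signal")
        sig = -rec.signal
        if dialect.smoothing_window > 1:
            sig = _centered_rolling_mean(sig, dialect.smoothing_window)
        meta = dict(rec.meta, dialect="B")
        return rec.with_(signal=sig, meta=meta)
    # dialect A: pad declared gaps with zeros
    sig = rec.signal
    for start, end in sorted(rec.gaps):
        n_pad = int(round((end - start) * rec.fs))
        if n_pad <= 0:
            continue
        idx = int(round((start - rec.t0) * rec.fs))
        sig = np.concatenate([sig[:idx], np.zeros(n_pad), sig[idx:]])
    meta = dict(rec.meta, dialect="A")
    return rec.with_(signal=sig, gaps=(), meta=meta)


def _centered_rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the edges.

    Matches the pandas ``rolling(window, center=True, min_periods=1)``
    convention so edge samples are averages over the available neighbors.
    """
    half_l = (window - 1) // 2
    half_r = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.clip(np.arange(n) - half_l, 0, n)
    hi = np.clip(np.arange(n) + half_r + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
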
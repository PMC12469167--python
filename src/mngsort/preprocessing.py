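"""Per-spike window extraction, alignment, templates and the waterfall view.

An extracellular C-fiber spike is roughly 3 ms wide, so a short window
centered on the annotated spike time captures the waveform: 30 samples
(``[t - 15, t + 15]``) at 10 kHz, 60 samples (``[t - 30, t + 30]``) at
30 kHz. 30-sample windows are
band-limited (Fourier) resampled to 60 points so both acquisition systems
land on one common grid and derivative estimates gain precision. Spikes are
then aligned on the maximum negative peak of the first derivative — the
steepest falling flank — which is a far more stable landmark than the
annotated time itself. Per-track templates are plain averages of the
aligned waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .recording import Recording

#: Common waveform grid length after resampling.
WAVEFORM_LEN = 60
#: Canonical position of the first-derivative negative peak after alignment
#: (window center, 0-based).
ALIGN_INDEX = 30


class BoundaryError(ValueError):
    """Spike window would cross the edge of the recorded signal."""


class AlignmentError(ValueError):
    """The first derivative has no usable negative peak (flat waveform)."""


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedWaveform:
    """A spike on the common 60-sample grid, derivative-aligned.

    ``fd`` and ``sd`` are the first and second derivatives in volts/sample;
    ``align_index`` is the position of the most negative ``fd`` value.
    """

    samples: np.ndarray
    fd: np.ndarray
    sd: np.ndarray
    align_index: int
    source_time: float
    track: str


@dataclass(frozen=True)
class Template:
    """Per-track mean waveform on the aligned 60-sample grid."""

    track: str
    values: np.ndarray
    n_spikes: int


@dataclass(frozen=True)
class Sweep:
    """One waterfall line: a stimulus onset, its signal segment, and the
    latencies (ms) of the spikes that followed it, with their track labels."""

    onset: float
    segment: np.ndarray
    spike_latencies: tuple  # of (latency_ms, track)


@dataclass(frozen=True)
class Waterfall:
    sweeps: tuple  # of Sweep


# ---------------------------------------------------------------------------
# window-level operations


def window_half_samples(fs: float) -> int:
    """Half-width of the extraction window in samples.

    15 samples (window [t-15, t+15], 3 ms) at the 10 kHz acquisition rate
    and 30 samples (window [t-30, t+30]) at 30 kHz, so windows arrive as
    30 or 60 data points — a C-fiber spike is roughly 3 ms wide.
    """
    return 15 if fs < 20000 else 30


def extract_window(rec: Recording, t: float) -> np.ndarray:
    """Raw window of ``2 * half`` samples centered on the sample containing ``t``.

    30 samples at 10 kHz, 60 at 30 kHz. Raises :class:`BoundaryError` when
    the window would cross the signal edge; such spikes are excluded (and
    counted) rather than zero-padded.
    """
    half = window_half_samples(rec.fs)
    i = rec.sample_index(t)
    if i - half < 0 or i + half > len(rec.signal):
        raise BoundaryError(
            f"window [{i - half}, {i + half}) exceeds signal bounds "
            f"[0, {len(rec.signal)})"
        )
    return rec.signal[i - half : i + half].copy()


def resample_to_60(window: np.ndarray) -> np.ndarray:
    """Resample a 30-sample window to 60 points (Fourier method).

    60-sample inputs are returned unchanged; other lengths are rejected.
    """
    window = np.asarray(window, dtype=np.float64)
    if len(window) == WAVEFORM_LEN:
        return window
    if len(window) == 30:
        return scipy.signal.resample(window, WAVEFORM_LEN)
    raise ParameterError(f"expected a 30- or 60-sample window, got {len(window)}")


def differentiate(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives in volts/sample.

    Central differences in the interior, one-sided at the ends
    (``numpy.gradient`` convention); the second derivative is the gradient
    of the first.
    """
    samples = np.asarray(samples, dtype=np.float64)
    fd = np.gradient(samples)
    sd = np.gradient(fd)
    return fd, sd


def _argmin_first(x: np.ndarray) -> int:
    """Index of the minimum; ties broken by the earliest index."""
    return int(np.argmin(x))


def _shift(w: np.ndarray, k: int, circular: bool) -> np.ndarray:
    """Shift so that ``new[i] = old[i + k]``; pad with zeros unless circular."""
    if circular:
        return np.roll(w, -k)
    out = np.zeros_like(w)
    src_lo, src_hi = max(0, k), min(len(w), len(w) + k)
    out[src_lo - k : src_hi - k] = w[src_lo:src_hi]
    return out


def align(
    window60: np.ndarray,
    fd: np.ndarray | None = None,
    sd: np.ndarray | None = None,
    *,
    circular: bool = False,
    source_time: float = np.nan,
    track: str = "",
) -> AlignedWaveform:
    """Align a 60-sample window so argmin(fd) sits at index 30.

    Operates on the window alone (no access to the raw signal): the content
    is shifted with zero padding, or circularly when ``circular=True``.
    Derivatives are recomputed after the shift. A flat first derivative
    (constant waveform) has no negative peak and raises
    :class:`AlignmentError`.
    """
    w = np.asarray(window60, dtype=np.float64)
    if len(w) != WAVEFORM_LEN:
        raise ParameterError(f"expected {WAVEFORM_LEN} samples, got {len(w)}")
    if fd is None or sd is None:
        fd, sd = differentiate(w)
    if np.ptp(fd) == 0:
        raise AlignmentError("first derivative is constant; no negative peak")
    k = _argmin_first(fd) - ALIGN_INDEX
    if k != 0:
        w = _shift(w, k, circular)
        fd, sd = differentiate(w)
    return AlignedWaveform(
        samples=w, fd=fd, sd=sd, align_index=_argmin_first(fd),
        source_time=source_time, track=track,
    )


def extract_aligned(rec: Recording, t: float, track: str = "") -> AlignedWaveform:
    """Extract, resample and align one spike, re-extracting from the raw
    signal to realize the alignment shift.

    Shifting by re-extraction (move the window center along the raw trace
    until the fd negative peak lands on index 30) avoids the wrap-around and
    zero-pad artifacts of in-window shifting. Sub-sample residual shifts
    (possible at 10 kHz, where one grid step is half a raw sample) fall back
    to a zero-padded in-window shift.
    """
    half = window_half_samples(rec.fs)
    ratio = WAVEFORM_LEN / (2 * half)  # grid steps per raw sample
    center = rec.sample_index(t)
    for _ in range(8):
        lo, hi = center - half, center + half
        if lo < 0 or hi > len(rec.signal):
            raise BoundaryError("alignment shift pushed window out of bounds")
        w60 = resample_to_60(rec.signal[lo:hi])
        fd, sd = differentiate(w60)
        if np.ptp(fd) == 0:
            raise AlignmentError("first derivative is constant; no negative peak")
        k = _argmin_first(fd) - ALIGN_INDEX
        if k == 0:
            return AlignedWaveform(w60, fd, sd, ALIGN_INDEX, t, track)
        step = int(round(k / ratio))
        if step == 0:
            break  # sub-sample residual: finish with an in-window shift
        center += step
    return align(w60, fd, sd, source_time=t, track=track)


def extract_aligned_waveforms(rec: Recording):
    """Aligned waveforms for every labeled spike, with exclusion accounting.

    Returns ``(waveforms, exclusions)`` where ``exclusions`` is a list of
    ``(SpikeEvent, reason)`` pairs, reason in {"boundary", "alignment"}.
    The conservation ``len(waveforms) + len(exclusions) == number of labeled
    spikes`` always holds, mirroring per-feature-set spike accounting.
    """
    waveforms, exclusions = [], []
    for ev in rec.labeled_spikes:
        try:
            waveforms.append(extract_aligned(rec, ev.time, ev.track))
        except BoundaryError:
            exclusions.append((ev, "boundary"))
        except AlignmentError:
            exclusions.append((ev, "alignment"))
    return waveforms, exclusions


# ---------------------------------------------------------------------------
# templates and waterfall


def compute_template(waveforms) -> Template:
    """Average the aligned spikes of one track into a template."""
    waveforms = list(waveforms)
    if not waveforms:
        raise ParameterError("cannot compute a template from zero waveforms")
    tracks = {w.track for w in waveforms}
    if len(tracks) > 1:
        raise ParameterError(f"waveforms span multiple tracks: {sorted(tracks)}")
    values = np.mean([w.samples for w in waveforms], axis=0)
    return Template(track=waveforms[0].track, values=values, n_spikes=len(waveforms))


def compute_templates(waveforms) -> dict:
    """Per-track templates, keyed and ordered by track label."""
    by_track: dict[str, list] = {}
    for w in waveforms:
        by_track.setdefault(w.track, []).append(w)
    return {t: compute_template(ws) for t, ws in sorted(by_track.items())}


def build_waterfall(rec: Recording) -> Waterfall:
    """Stack the recording into per-stimulus sweeps.

    Each background-stimulus onset starts one sweep whose segment runs to
    the next onset (or the end of the signal). Every labeled spike is
    assigned to the sweep of the latest onset at or before its time, with
    its latency in milliseconds. In a marking-method recording the spikes of
    one fiber line up vertically across sweeps — the "track".
    """
    onsets = rec.stimulus_onsets
    if onsets.size == 0:
        raise ParameterError("waterfall requires at least one stimulus onset")
    bounds = np.append(onsets, rec.t0 + rec.duration)
    latencies: list[list] = [[] for _ in onsets]
    for ev in rec.labeled_spikes:
        j = int(np.searchsorted(onsets, ev.time, side="right")) - 1
        if j < 0:
            import warnings

            warnings.warn(
                f"spike at {ev.time} s precedes the first stimulus; "
                "latency taken relative to recording start",
                stacklevel=2,
            )
            j, ref = 0, rec.t0
        else:
            ref = onsets[j]
        latencies[j].append(((ev.time - ref) * 1e3, ev.track))
    sweeps = []
    for j, onset in enumerate(onsets):
        lo = rec.sample_index(onset)
        hi = rec.sample_index(bounds[j + 1]) if j + 1 < len(bounds) else len(rec.signal)
        hi = min(max(hi, lo), len(rec.signal))
        sweeps.append(
            Sweep(
                onset=float(onset),
                segment=rec.signal[max(lo, 0) : hi].copy(),
                spike_latencies=tuple(sorted(latencies[j])),
            )
        )
    return Waterfall(sweeps=tuple(sweeps))
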
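"""Shape-, phase- and distribution-based (SPDF) spike features.

SPDF features describe a spike through its first derivative (fd) and second
derivative (sd) rather than the raw voltage trace: shape features capture
the time-domain geometry of fd, phase features relate fd and sd amplitudes
at landmark points, and distribution features summarize the amplitude
distributions of fd and sd.

All features are anchored on six *fundamental points* — landmark sample
indices of the aligned waveform:

==== =====================================================================
P1   first zero-crossing of fd (scanning from the window start); for a
     positive-going spike this is the voltage peak. A spike whose fd never
     changes sign has no P1 and is excluded from SPDF feature sets.
P2   position of the fd maximum (steepest rising flank)
P3   position of the fd minimum (steepest falling flank; the alignment
     landmark, canonically index 30)
P4   first zero-crossing of fd after P3 (the after-potential trough);
     falls back to the window end when fd does not cross zero again
P5   position of the sd maximum
P6   position of the sd minimum
==== =====================================================================

The full feature vector has 23 entries, f1–f3 and f5–f24 (feature 4 of the
original 24-feature catalogue depends on an external reference waveform and
is dropped). Three definitions are fixed by construction and shared with
the reduced FV3 set: f14 = max(fd), f18 = max(sd), f19 = min(sd); f8 is the
mean of the squared fd amplitudes from the window start up to P1. The
remaining entries follow this module's documented interpretation of the
shape/phase/distribution taxonomy; each is a pure registered function so it
can be inspected and tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .preprocessing import AlignedWaveform

#: Names of the 23 SPDF features, in vector order (feature 4 excluded).
SPDF_FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 25) if i != 4)

#: The reduced three-feature subset: fd positive peak and the two sd peaks.
FV3_FEATURE_NAMES = ("f14", "f18", "f19")


@dataclass(frozen=True)
class FundamentalPoints:
    """The six landmark indices of one aligned waveform.

    ``defined`` is False when fd has no zero-crossing, in which case the
    spike is excluded from the SPDF feature sets.
    """

    p1: int
    p2: int
    p3: int
    p4: int
    p5: int
    p6: int
    defined: bool


def _first_zero_crossing(x: np.ndarray, start: int = 0) -> int | None:
    """Index of the first sample after a sign change of ``x`` at/after ``start``.

    A zero-crossing is a sign change between consecutive samples; exact
    zeros count as a change when the neighbors differ in sign or one side
    is zero while the other is not.
    """
    s = np.sign(x)
    for i in range(max(start, 0), len(x) - 1):
        if s[i] != s[i + 1]:
            return i + 1
    return None


def fundamental_points(w: AlignedWaveform) -> FundamentalPoints:
    """Locate the six fundamental points of an aligned waveform."""
    fd, sd = w.fd, w.sd
    p1 = _first_zero_crossing(fd)
    if p1 is None:
        return FundamentalPoints(0, 0, 0, 0, 0, 0, defined=False)
    p2 = int(np.argmax(fd))
    p3 = int(np.argmin(fd))
    p4 = _first_zero_crossing(fd, start=p3)
    if p4 is None:
        p4 = len(fd) - 1
    p5 = int(np.argmax(sd))
    p6 = int(np.argmin(sd))
    return FundamentalPoints(p1, p2, p3, p4, p5, p6, defined=True)


# ---------------------------------------------------------------------------
# feature registry

_REGISTRY: dict = {}


def _feature(name):
    def deco(fn):
        _REGISTRY[name] = fn
        return fn

    return deco


def _balanced_ratio(a: float, b: float) -> float:
    """Bounded asymmetry index (a - b) / (|a| + |b|), 0 for a == b == 0.

    Used instead of raw ratios so degenerate near-zero denominators cannot
    produce unbounded feature values.
    """
    denom = abs(a) + abs(b)
    return 0.0 if denom == 0 else (a - b) / denom


def _moment(x: np.ndarray, fn) -> float:
    """Skewness/kurtosis guarded against zero-variance input."""
    if np.ptp(x) == 0:
        return 0.0
    return float(fn(x))


# -- shape: time-domain geometry of the first derivative --------------------

@_feature("f1")
def _f1(w, fp):
    """Flank interval: samples between the fd extrema, P3 - P2."""
    return float(fp.p3 - fp.p2)


@_feature("f2")
def _f2(w, fp):
    """fd lobe width: samples between the fd zero-crossings, P4 - P1."""
    return float(fp.p4 - fp.p1)


@_feature("f3")
def _f3(w, fp):
    """fd peak-to-peak amplitude: fd[P2] - fd[P3]."""
    return float(w.fd[fp.p2] - w.fd[fp.p3])


@_feature("f5")
def _f5(w, fp):
    """Mean fd slope between the fd extrema (sd proxy across the peak)."""
    dt = fp.p3 - fp.p2
    return float((w.fd[fp.p3] - w.fd[fp.p2]) / dt) if dt != 0 else 0.0


@_feature("f6")
def _f6(w, fp):
    """Total variation of the waveform: sum of |fd| over the window."""
    return float(np.sum(np.abs(w.fd)))


@_feature("f7")
def _f7(w, fp):
    """Temporal asymmetry of the flanks around P1: (P3 - P1) - (P1 - P2)."""
    return float((fp.p3 - fp.p1) - (fp.p1 - fp.p2))


@_feature("f8")
def _f8(w, fp):
    """Mean of the squared fd amplitudes before P1 (pre-peak fd energy).

    Averages fd(i)^2 over i from the window start s up to (excluding) P1,
    dividing by P1 - s, so the value is a proper mean of squares.
    """
    if fp.p1 <= 0:
        return 0.0
    seg = w.fd[: fp.p1]
    return float(np.sum(seg**2) / fp.p1)


@_feature("f9")
def _f9(w, fp):
    """Number of fd zero-crossings in the window (waveform oscillation)."""
    s = np.sign(w.fd)
    return float(np.sum(s[:-1] != s[1:]))


@_feature("f10")
def _f10(w, fp):
    """Voltage at P1 (the spike peak for a positive-going spike)."""
    return float(w.samples[fp.p1])


@_feature("f11")
def _f11(w, fp):
    """Voltage at P4 (the after-potential trough)."""
    return float(w.samples[fp.p4])


@_feature("f12")
def _f12(w, fp):
    """Rise/fall slope balance: bounded ratio of fd[P2] vs |fd[P3]|."""
    return _balanced_ratio(w.fd[fp.p2], -w.fd[fp.p3])


@_feature("f13")
def _f13(w, fp):
    """Root-mean-square fd amplitude over the whole window."""
    return float(np.sqrt(np.mean(w.fd**2)))


# -- phase: fd and sd amplitudes at the fundamental points ------------------

@_feature("f14")
def _f14(w, fp):
    """Positive peak of the first derivative, max(fd)."""
    return float(np.max(w.fd))


@_feature("f15")
def _f15(w, fp):
    """Negative peak of the first derivative, min(fd)."""
    return float(np.min(w.fd))


@_feature("f16")
def _f16(w, fp):
    """sd amplitude at P2 (curvature at the steepest rise)."""
    return float(w.sd[fp.p2])


@_feature("f17")
def _f17(w, fp):
    """sd amplitude at P3 (curvature at the steepest fall)."""
    return float(w.sd[fp.p3])


@_feature("f18")
def _f18(w, fp):
    """Positive peak of the second derivative, max(sd)."""
    return float(np.max(w.sd))


@_feature("f19")
def _f19(w, fp):
    """Negative peak of the second derivative, min(sd)."""
    return float(np.min(w.sd))


# -- distribution: amplitude-distribution moments of fd and sd --------------

@_feature("f20")
def _f20(w, fp):
    """Variance of the fd amplitude distribution."""
    return float(np.var(w.fd))


@_feature("f21")
def _f21(w, fp):
    """Skewness of the fd amplitude distribution."""
    return _moment(w.fd, scipy.stats.skew)


@_feature("f22")
def _f22(w, fp):
    """Excess kurtosis of the fd amplitude distribution."""
    return _moment(w.fd, scipy.stats.kurtosis)


@_feature("f23")
def _f23(w, fp):
    """Skewness of the sd amplitude distribution."""
    return _moment(w.sd, scipy.stats.skew)


@_feature("f24")
def _f24(w, fp):
    """Excess kurtosis of the sd amplitude distribution."""
    return _moment(w.sd, scipy.stats.kurtosis)


assert tuple(_REGISTRY) == SPDF_FEATURE_NAMES


def spdf_vector(w: AlignedWaveform, fp: FundamentalPoints | None = None):
    """The 23-entry SPDF feature vector, or ``None`` when P1 is undefined."""
    if fp is None:
        fp = fundamental_points(w)
    if not fp.defined:
        return None
    return np.array([_REGISTRY[name](w, fp) for name in SPDF_FEATURE_NAMES])


def fv3_vector(w: AlignedWaveform, fp: FundamentalPoints | None = None):
    """The reduced [f14, f18, f19] vector, sharing the SPDF exclusion rule."""
    if fp is None:
        fp = fundamental_points(w)
    if not fp.defined:
        return None
    return np.array([_REGISTRY[name](w, fp) for name in FV3_FEATURE_NAMES])
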
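"""Synthetic marking-method microneurography recordings with ground truth.

The generator emulates the study conditions of a C-nociceptor
microneurography session: low-frequency background electrical stimulation
(0.25 Hz by default), one spike per fiber per stimulus at a near-constant
per-fiber response latency (the *track*), activity-dependent slowing (ADS)
after extra stimuli with exponential recovery toward the base latency,
parametric tri-lobe spike waveforms of controllable pairwise similarity,
and additive Gaussian noise of controllable amplitude. Every generated
spike carries its true fiber label, so each downstream module can be
validated without recorded data.

The ADS model is deliberately minimal: a per-fiber slowing state ``s``
(ms) grows by a fixed increment per evoked extra spike and decays
exponentially with time constant ``tau`` between background stimuli,

    latency(sweep k) = base + s_k + jitter,   s_{k+1} = (s_k + inc * m_k) * exp(-dt * /tau)

with ``m_k`` extra spikes in interval k and ``dt`` the stimulation period.
This is the simplest dynamics in which the slowing magnitude tracks the
number of previously elicited spikes and latencies recover to baseline
under continued background stimulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import resample_to_60, window_half_samples
from .recording import Recording, SpikeEvent

WAVEFORM_LEN = 60


class GenerationError(ValueError):
    """The requested configuration cannot produce a clean recording
    (e.g. spike windows would overlap)."""


# ---------------------------------------------------------------------------
# parametric spike shapes


@dataclass(frozen=True)
class ParametricTemplate:
    """Tri-lobe (negative-positive-negative) spike shape.

    ``lobes`` are ``(amplitude, center, sigma)`` Gaussian lobes in
    60-sample grid units; amplitudes are arbitrary volts. The shape is
    evaluated on the raw extraction grid of the target sampling rate (30
    samples at 10 kHz, 60 at 30 kHz) by scaling centers and widths.
    """

    lobes: tuple

    def waveform(self, fs: float = 30000.0) -> np.ndarray:
        n = 2 * window_half_samples(fs)
        scale = n / WAVEFORM_LEN
        i = np.arange(n)
        out = np.zeros(n)
        for amp, center, sigma in self.lobes:
            out += amp * np.exp(-((i - center * scale) ** 2) / (2 * (sigma * scale) ** 2))
        return out

    def aligned60(self, fs: float = 30000.0) -> np.ndarray:
        """The shape as the pipeline sees it: raw grid resampled to 60."""
        return resample_to_60(self.waveform(fs))


#: Two base shapes bracketing the morph family. The positive lobe dominates
#: and the falling flank is positioned so that both shapes (and therefore
#: every convex morph of the pair) have their first-derivative minimum at
#: the canonical alignment index.
BASE_SHAPE_A = ParametricTemplate(
    lobes=((-1.9, 18.0, 3.0), (5.2, 26.0, 3.5), (-2.4, 36.0, 4.5))
)
BASE_SHAPE_B = ParametricTemplate(
    lobes=((-0.3, 17.0, 3.5), (1.05, 25.5, 4.5), (-0.45, 37.0, 5.5))
)


@dataclass(frozen=True)
class MorphTemplate:
    """Convex interpolation between two base shapes.

    ``lam = 0`` is shape A, ``lam = 1`` shape B. Because interpolation,
    Fourier resampling and averaging are all linear, distances between
    morphs scale exactly linearly in ``lam``:
    ``RMSE(T(0), T(lam)) = lam * RMSE(T(0), T(1))`` on the aligned grid.
    """

    base_a: ParametricTemplate = BASE_SHAPE_A
    base_b: ParametricTemplate = BASE_SHAPE_B
    lam: float = 0.0

    def waveform(self, fs: float = 30000.0) -> np.ndarray:
        return (1.0 - self.lam) * self.base_a.waveform(fs) + self.lam * self.base_b.waveform(fs)

    def aligned60(self, fs: float = 30000.0) -> np.ndarray:
        return resample_to_60(self.waveform(fs))

    def peak(self, fs: float = 30000.0) -> float:
        return float(np.max(self.waveform(fs)))


def template_rmse(t1: MorphTemplate, t2: MorphTemplate, fs: float = 30000.0) -> float:
    d = t1.aligned60(fs) - t2.aligned60(fs)
    return float(np.sqrt(np.mean(d**2)))


def make_template_pair(
    target_rmse: float,
    base_a: ParametricTemplate = BASE_SHAPE_A,
    base_b: ParametricTemplate = BASE_SHAPE_B,
    fs: float = 30000.0,
):
    """A template pair whose aligned-grid RMSE equals ``target_rmse`` exactly.

    The second template is the morph ``T(lam)`` with
    ``lam = target_rmse / RMSE(A, B)``; by linearity of the morph the pair
    distance is exact. ``target_rmse`` may not exceed the base-pair RMSE.
    """
    t0 = MorphTemplate(base_a, base_b, 0.0)
    t1 = MorphTemplate(base_a, base_b, 1.0)
    full = template_rmse(t0, t1, fs)
    if target_rmse < 0 or target_rmse > full:
        raise GenerationError(
            f"target RMSE {target_rmse} outside [0, {full:.4f}] reachable "
            "by this base pair"
        )
    lam = target_rmse / full
    return t0, MorphTemplate(base_a, base_b, lam)


def morph_family(n: int, lam_max: float = 1.0):
    """``n`` morph templates evenly spaced in lam over [0, lam_max]."""
    lams = np.linspace(0.0, lam_max, n)
    return tuple(MorphTemplate(lam=float(l)) for l in lams)


# ---------------------------------------------------------------------------
# recording generator


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic recording.

    Defaults emulate a routine marking-method session: background
    stimulation at 0.25 Hz for 80 sweeps (~80 labeled spikes per fiber,
    about 320 s of recording), two fibers with distinct conduction
    latencies in the 200-600 ms range typical of human C-fibers, latency
    jitter of 0.05 ms (the "almost constant" conduction velocity), additive
    white Gaussian noise, ADS increment of 2 ms per evoked extra spike and
    a 30 s recovery time constant.
    """

    fs: float = 10000.0
    n_fibers: int = 2
    stim_freq: float = 0.25
    n_sweeps: int = 80
    base_latency_ms: tuple = (250.0, 420.0)
    latency_jitter_sd_ms: float = 0.05
    templates: tuple = ()
    noise_sd: float = 0.3
    ads_increment_ms: float = 2.0
    ads_recovery_tau_s: float = 30.0
    extra_stimulus_schedule: tuple = ()  # of (sweep index, n extra pulses)
    overlap_guard_ms: float = 3.0
    pink_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise GenerationError("need at least one fiber")
        if len(self.base_latency_ms) != self.n_fibers:
            # evenly spread defaults when the tuple was not customized
            lat = tuple(np.linspace(200.0, 600.0, self.n_fibers))
            object.__setattr__(self, "base_latency_ms", lat)
        if len(set(self.base_latency_ms)) != self.n_fibers:
            raise GenerationError("base latencies must be distinct")
        if not self.templates:
            object.__setattr__(self, "templates", morph_family(self.n_fibers))
        if len(self.templates) != self.n_fibers:
            raise GenerationError("one template per fiber required")
        if self.latency_jitter_sd_ms < 0 or self.noise_sd < 0:
            raise GenerationError("standard deviations must be >= 0")
        if self.stim_freq <= 0 or self.n_sweeps < 1:
            raise GenerationError("invalid stimulation parameters")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "fs": self.fs, "n_fibers": self.n_fibers,
                "stim_freq": self.stim_freq, "n_sweeps": self.n_sweeps,
                "base_latency_ms": list(self.base_latency_ms),
                "jitter": self.latency_jitter_sd_ms,
                "lams": [getattr(t, "lam", None) for t in self.templates],
                "noise_sd": self.noise_sd,
                "ads_inc": self.ads_increment_ms,
                "ads_tau": self.ads_recovery_tau_s,
                "extra": list(map(list, self.extra_stimulus_schedule)),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / np.std(out)


def generate_recording(cfg: SyntheticConfig) -> Recording:
    """Generate one labeled recording under the given study conditions.

    Deterministic given ``cfg.seed``. Raises :class:`GenerationError` when
    two spikes would fall closer than the overlap guard (recordings with
    overlapping spikes are excluded from this analysis by design).
    """
    rng = np.random.default_rng(cfg.seed)
    margin = 1.0  # s of plain noise before the first and after the last sweep
    period = 1.0 / cfg.stim_freq
    duration = 2 * margin + cfg.n_sweeps * period
    n_samples = int(round(duration * cfg.fs))
    if cfg.noise_sd > 0:
        noise = _pink(rng, n_samples) if cfg.pink_noise else rng.standard_normal(n_samples)
        signal = cfg.noise_sd * noise
    else:
        signal = np.zeros(n_samples)

    onsets = margin + period * np.arange(cfg.n_sweeps)
    extra = dict(cfg.extra_stimulus_schedule)
    half = window_half_samples(cfg.fs)
    shapes = [t.waveform(cfg.fs) for t in cfg.templates]

    events: list[tuple[float, int]] = []  # (time, fiber)
    slowing = np.zeros(cfg.n_fibers)
    for k in range(cfg.n_sweeps):
        for f in range(cfg.n_fibers):
            jit = rng.normal(0.0, cfg.latency_jitter_sd_ms) if cfg.latency_jitter_sd_ms else 0.0
            lat_ms = cfg.base_latency_ms[f] + slowing[f] + jit
            events.append((onsets[k] + lat_ms * 1e-3, f))
        # extra stimulation between this sweep and the next
        n_pulses = int(extra.get(k, 0))
        if n_pulses:
            pulse_times = onsets[k] + period * (np.arange(1, n_pulses + 1) / (n_pulses + 1))
            for pt in pulse_times:
                for f in range(cfg.n_fibers):
                    jit = (rng.normal(0.0, cfg.latency_jitter_sd_ms)
                           if cfg.latency_jitter_sd_ms else 0.0)
                    lat_ms = cfg.base_latency_ms[f] + slowing[f] + jit
                    events.append((pt + lat_ms * 1e-3, f))
                slowing += cfg.ads_increment_ms  # each pulse marks every fiber
        slowing *= np.exp(-period / cfg.ads_recovery_tau_s)

    # overlap guard: windows of distinct spikes must not collide
    times = np.array(sorted(t for t, _ in events))
    if len(times) > 1:
        min_sep = float(np.min(np.diff(times)))
        if min_sep * 1e3 < cfg.overlap_guard_ms:
            raise GenerationError(
                f"spike separation {min_sep * 1e3:.3f} ms below the "
                f"{cfg.overlap_guard_ms} ms overlap guard"
            )

    spikes = []
    for t, f in events:
        i = int(np.floor(t * cfg.fs))
        if i - half < 0 or i + half > n_samples:
            raise GenerationError("spike window outside the generated signal")
        signal[i - half : i + half] += shapes[f]
        spikes.append(SpikeEvent(time=t, track=f"Track{f + 1}"))

    return Recording(
        signal=signal,
        fs=cfg.fs,
        t0=0.0,
        stimulus_onsets=onsets,
        spikes=tuple(sorted(spikes, key=lambda ev: ev.time)),
        meta={
            "dataset": f"synthetic-{cfg.config_hash()}",
            "generator": "mngsort.synthetic",
            "seed": str(cfg.seed),
            "config_hash": cfg.config_hash(),
        },
    )


def generate_benchmark_suite(
    n_fibers_grid=(2,),
    target_rmse_grid=(None,),
    noise_sd_grid=(0.3,),
    seeds=(0,),
    **cfg_kw,
):
    """Reproducible grid of recordings with a manifest.

    ``target_rmse`` (when not None) sets the aligned-grid RMSE between the
    two *extreme* templates of the recording; the fibers' templates are
    spaced evenly along the morph path between them. Returns a list of
    ``(Recording, manifest_entry)`` pairs; the manifest entry carries the
    grid point, seed and config hash.
    """
    out = []
    for n_fibers in n_fibers_grid:
        for target in target_rmse_grid:
            for noise_sd in noise_sd_grid:
                for seed in seeds:
                    kw = dict(cfg_kw)
                    if target is not None:
                        fs = kw.get("fs", 10000.0)
                        _, t_end = make_template_pair(target, fs=fs)
                        kw["templates"] = morph_family(n_fibers, lam_max=t_end.lam)
                    cfg = SyntheticConfig(
                        n_fibers=n_fibers, noise_sd=noise_sd, seed=seed, **kw
                    )
                    rec = generate_recording(cfg)
                    out.append(
                        (
                            rec,
                            {
                                "n_fibers": n_fibers,
                                "target_rmse": target,
                                "noise_sd": noise_sd,
                                "seed": seed,
                                "config_hash": cfg.config_hash(),
                                "dataset": rec.meta["dataset"],
                            },
                        )
                    )
    return out
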